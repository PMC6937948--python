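"""Hierarchical ABC test of simultaneous divergence across population pairs.

Three co-distributed population pairs are simulated with identical
divergence times; the hierarchical posterior over the number of divergence
events (Ψ) and the dispersion index Ω = Var(τ)/E(τ) should then support a
single synchronous event (Ω ≤ 0.01).  The mean divergence time E(τ) is
converted to years via T_div = E(τ)·(θ_AVE/μ)·g.

Runs in a couple of minutes at this reduced simulation count.
"""

import numpy as np

from mesophylo import habc, synthdata

configs = [
    habc.PairConfig(f"pair{i}", n1=5, n2=5, L=1000, kappa=6.0,
                    theta_upper=0.01, barrier="shared lowland barrier")
    for i in range(3)
]
theta_ave = habc.theta_ave_of(configs)

# observed data: all three pairs split at tau = 2 (units of 4*N_AVE generations)
pairs, truth = synthdata.generate_pairs(
    [2.0, 2.0, 2.0], [0.002] * 3, 1000, seed=5, theta_ave=theta_ave
)
observed = habc.observed_pair_stats(pairs)
print(f"true tau per pair: {truth.pair_taus}\n")

post = habc.habc_posterior(
    observed, configs, n_sims=60_000, tolerance=0.005, seed=99, tau_max=5.0
)
print("P(Psi = k | data):", np.round(post.psi_pmf, 3))
print(f"Psi posterior mode: {post.psi_mode}")
print(f"Omega mode: {post.omega_mode:.4f} "
      f"(95% HPD {post.omega_hpd[0]:.4f}-{post.omega_hpd[1]:.4f})")
verdict = "synchronous" if post.synchronous else "asynchronous"
print(f"verdict: {verdict} (threshold Omega <= 0.01)")

conv = habc.tdiv_convert(post.e_tau_mode, theta_ave, mu=0.0042,
                         mu_unit="per_Myr", generation_time=2.0)
print(f"\nE(tau) mode {post.e_tau_mode:.2f} -> "
      f"T_div ~ {conv.t_div_years/1e6:.2f} Myr "
      f"(mu = 0.0042 subs/site/Myr, g = 2 yr)")
print(
    "\nPsi mode 1 with Omega at the boundary means one shared divergence "
    "pulse explains all pairs; T_div places that pulse in absolute time."
)
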