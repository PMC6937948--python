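"""ABC model choice between competing divergence scenarios.

Simulates an 'observed' dataset under an old two-population split, builds a
reference table for three candidate histories (recent split, old split, old
split with recent admixture), and reports rejection and logistic-regression
posterior probabilities plus a regression-adjusted split-time posterior
converted to years at a two-year generation time.

Runs in about a minute at this reduced reference-table size.
"""

import warnings

import numpy as np

from mesophylo import abc_select as A
from mesophylo.coalsim import (
    Admixture, DemographicScenario, MutationModel, Split, simulate_dataset,
)

N = "N"
scenarios = [
    DemographicScenario("recent-split", {"A": 5, "B": 5}, {"A": N, "B": N},
                        (Split("t_recent", ("A", "B"), "anc", N),)),
    DemographicScenario("old-split", {"A": 5, "B": 5}, {"A": N, "B": N},
                        (Split("t_old", ("A", "B"), "anc", N),)),
    DemographicScenario("old-split-admixed", {"A": 5, "B": 5},
                        {"A": N, "B": N, "Bcont": N},
                        (Admixture("t_adm", "B", ("A", "Bcont"), "r_adm"),
                         Split("t_old", ("A", "Bcont"), "anc", N))),
]
priors = A.PriorSet(
    {
        "N": A.Uniform(5e3, 5e4, "log"),
        "t_recent": A.Uniform(100.0, 5e3, "log"),
        "t_old": A.Uniform(5e4, 4e5, "log"),
        "t_adm": A.Uniform(1e3, 1e4, "log"),
        "r_adm": A.Uniform(0.05, 0.95, "logit"),
        # per-generation mutation-rate prior (2.0e-8/yr at g = 2 years)
        "mu": A.TruncatedGamma(4e-8, 3.2e-8, 5.8e-8),
    },
    order_constraints=(("t_adm", "t_old"),),
)
cfg = A.SimulationConfig(L=500)
rng = np.random.default_rng(42)

truth = A.sample_prior(priors, rng)
observed_ds = simulate_dataset(
    scenarios[1], truth, MutationModel(kappa=cfg.kappa, u=truth["mu"]),
    cfg.L, rng,
)
_, observed = A.abc_statistics(observed_ds.alignment, observed_ds.assignment)
print(f"observed data simulated under 'old-split' with t_old = "
      f"{truth['t_old']:.0f} generations\n")

table = A.build_reference_table(scenarios, priors, 3000, cfg, rng)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    post = A.select_scenario(table, observed, tolerance=0.01)
print("scenario            rejection PP   regression PP")
for name, r, g in zip(post.scenario_names, post.rejection_pp, post.regression_pp):
    print(f"  {name:<20}{r:>10.3f}{g:>14.3f}")
print(f"selected: {post.scenario_names[post.selected]} "
      f"(95% CI {post.ci_low:.3f}-{post.ci_high:.3f})\n")

params = A.estimate_parameters(table, observed, priors, post.selected, 0.01)
med = params.point["t_old"]["median"]
lo, hi = params.interval["t_old"]
g_years = priors.generation_time
print(f"t_old posterior: median {med:.0f} generations "
      f"({A.convert_generations_to_years(med, g_years):.0f} years at g = {g_years}), "
      f"95% interval [{lo:.0f}, {hi:.0f}] generations")
print(
    "\nThe highest regression PP identifies the best-supported history; "
    "the adjusted posterior interval should bracket the true t_old above."
)
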