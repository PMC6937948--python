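"""Hierarchical ABC test of simultaneous divergence across population pairs.

Co-distributed population pairs that were sundered by the same landscape
event should share a divergence time.  The hierarchical model places a
hyperprior on the number of distinct divergence times Ψ (uniform on
1..n_pairs, the conventional choice) and on the divergence-time vector τ
(one value per pair, in coalescent units of 4·N_AVE generations), simulates
per-pair summary statistics under each hyperparameter draw, and approximates
the joint hyperposterior by acceptance/rejection on the distance between
simulated and observed statistics.

The dispersion index Ω = Var(τ)/E(τ) summarises concordance: synchronous
diversification is inferred when the posterior mode of Ω ≤ 0.01.  Mean
divergence times are converted to years with T_div = E(τ)·(θ_AVE/μ)·g.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

from . import _kernels
from .popdata import MISSING, SequenceAlignment

__all__ = [
    "PairConfig",
    "HyperDraw",
    "HyperPosterior",
    "TimeConversion",
    "TiTvEstimate",
    "estimate_titv",
    "sample_hyperprior",
    "omega_of",
    "simulate_pair_stats",
    "habc_posterior",
    "tdiv_convert",
]

#: Synchrony threshold on the posterior mode of Ω.
OMEGA_SYNCHRONY_THRESHOLD = 0.01

PAIR_STAT_NAMES = _kernels.PAIR_STAT_NAMES

#: Nominal per-site per-generation rate used internally to scale θ into
#: effective sizes; results depend only on θ and τ, not on this value.
_NOMINAL_U = 1e-8


@dataclass(frozen=True)
class PairConfig:
    """One co-distributed population pair entering the hierarchical test."""

    label: str
    n1: int
    n2: int
    L: int
    kappa: float = 4.0
    theta_upper: float = 0.02
    barrier: str = ""

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("both populations need n >= 2")
        if self.L < 100:
            raise ValueError("locus length must be >= 100")
        if self.theta_upper <= 0:
            raise ValueError("theta_upper must be positive")


@dataclass(frozen=True)
class HyperDraw:
    """One hyperparameter state: Ψ, the τ vector, and per-pair θ draws."""

    psi: int
    tau: np.ndarray  # one per pair
    classes: np.ndarray  # pair -> class index in [0, psi)
    theta1: np.ndarray
    theta2: np.ndarray
    theta_anc: np.ndarray

    def __post_init__(self) -> None:
        n_pairs = len(self.tau)
        if not (1 <= self.psi <= n_pairs):
            raise ValueError("psi outside 1..n_pairs")
        if len(np.unique(np.round(self.tau, 12))) != self.psi:
            raise ValueError("tau must contain exactly psi distinct values")
        if np.any(self.tau < 0):
            raise ValueError("tau must be non-negative")


@dataclass(frozen=True)
class HyperPosterior:
    psi_pmf: np.ndarray  # index j -> P(psi = j+1)
    omega_samples: np.ndarray
    omega_mode: float
    omega_hpd: tuple[float, float]
    e_tau_samples: np.ndarray
    e_tau_mode: float
    e_tau_hpd: tuple[float, float]
    tolerance: float
    n_accepted: int

    @property
    def psi_mode(self) -> int:
        return int(np.argmax(self.psi_pmf)) + 1

    @property
    def synchronous(self) -> bool:
        return self.omega_mode <= OMEGA_SYNCHRONY_THRESHOLD


@dataclass(frozen=True)
class TimeConversion:
    """Record of the coalescent-units → years conversion."""

    e_tau: float
    theta_ave: float
    mu: float
    mu_unit: Literal["per_generation", "per_year", "per_Myr"]
    generation_time: float
    t_div_generations: float
    t_div_years: float


@dataclass(frozen=True)
class TiTvEstimate:
    ratio: float
    method: Literal["K80-ML", "raw-count", "default"]
    flagged: bool = False


# ---------------------------------------------------------------------------
# ti/tv estimation
# ---------------------------------------------------------------------------

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def estimate_titv(
    aln: SequenceAlignment,
    default: float = 4.0,
    cap: float = 50.0,
) -> TiTvEstimate:
    """Transition/transversion ratio κ for a pair alignment.

    Maximum-likelihood under the two-parameter (K80-style) model from the
    mean pairwise transition proportion P and transversion proportion Q:
    κ̂ = 2s/v with s = −½ln(1−2P−Q) + ¼ln(1−2Q) and v = −½ln(1−2Q); this is
    the per-type rate ratio α/β used by the HKY simulator.  The raw-count
    fallback (used when the log arguments are non-positive) is the plain
    transitions/transversions count ratio with both transversion classes
    pooled — half the per-type value when the three change types are equally
    frequent.  Returns ``default`` flagged when there is no variable site,
    and ``cap`` flagged when no transversions were seen.
    """
    n = aln.n_samples
    if n < 2:
        return TiTvEstimate(default, "default", True)
    miss = np.isin(aln.matrix, list(MISSING))
    ts_total = tv_total = comp_total = 0
    for i in range(n):
        for j in range(i + 1, n):
            both = ~(miss[i] | miss[j])
            a, b = aln.matrix[i, both], aln.matrix[j, both]
            diff = a != b
            comp_total += int(both.sum())
            for x, y in zip(a[diff], b[diff]):
                if (x in _PURINES) == (y in _PURINES):
                    ts_total += 1
                else:
                    tv_total += 1
    if ts_total + tv_total == 0:
        return TiTvEstimate(default, "default", True)
    if tv_total == 0:
        return TiTvEstimate(cap, "raw-count", True)
    n_pairs = n * (n - 1) // 2
    p = ts_total / (comp_total / n_pairs) / n_pairs
    q = tv_total / (comp_total / n_pairs) / n_pairs
    w1, w2 = 1.0 - 2.0 * p - q, 1.0 - 2.0 * q
    if w1 > 0 and w2 > 0:
        s = -0.5 * math.log(w1) + 0.25 * math.log(w2)
        v = -0.5 * math.log(w2)
        if v > 0 and s > 0:
            return TiTvEstimate(min(2.0 * s / v, cap), "K80-ML", False)
    return TiTvEstimate(min(ts_total / tv_total, cap), "raw-count", False)


# ---------------------------------------------------------------------------
# Hyperprior and Ω
# ---------------------------------------------------------------------------

def sample_hyperprior(
    configs: Sequence[PairConfig],
    tau_max: float,
    rng: np.random.Generator,
) -> HyperDraw:
    """Draw (Ψ, τ, class assignment, per-pair θ) from the hyperprior.

    Ψ is uniform on 1..n_pairs; the Ψ distinct τ values are uniform on
    (0, τ_max]; pairs are assigned to classes uniformly conditioned on every
    class being non-empty; each θ is uniform on (0, θ_upper] of its pair.
    """
    n_pairs = len(configs)
    psi = int(rng.integers(1, n_pairs + 1))
    tau_values = tau_max * (1.0 - rng.random(psi))  # in (0, tau_max]
    while len(np.unique(tau_values)) < psi:  # virtually never
        tau_values = tau_max * (1.0 - rng.random(psi))
    while True:
        classes = rng.integers(0, psi, size=n_pairs)
        if len(np.unique(classes)) == psi:
            break
    tau = tau_values[classes]
    uppers = np.array([c.theta_upper for c in configs])
    theta1 = uppers * (1.0 - rng.random(n_pairs))
    theta2 = uppers * (1.0 - rng.random(n_pairs))
    theta_anc = uppers * (1.0 - rng.random(n_pairs))
    return HyperDraw(psi, tau, classes, theta1, theta2, theta_anc)


def omega_of(tau: np.ndarray | Sequence[float]) -> float:
    """Ω = population variance of τ over its mean (0 when all τ are 0)."""
    tau = np.asarray(tau, dtype=float)
    if len(tau) == 0:
        raise ValueError("tau vector is empty")
    if np.all(tau == tau[0]):
        return 0.0  # exact, not subject to floating-point var round-off
    m = float(tau.mean())
    if m == 0.0:
        raise ValueError("negative tau values")
    return float(tau.var()) / m


def theta_ave_of(
    configs: Sequence[PairConfig],
    definition: Literal["half-upper", "upper"] = "half-upper",
) -> float:
    """θ_AVE across pairs: mean of the uniform θ prior (upper/2) by default,
    or the mean upper bound itself with ``definition='upper'``."""
    uppers = np.array([c.theta_upper for c in configs])
    return float(uppers.mean()) * (0.5 if definition == "half-upper" else 1.0)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_pair_stats(
    draw: HyperDraw,
    configs: Sequence[PairConfig],
    theta_ave: float,
) -> np.ndarray:
    """Per-pair statistic vectors for one hyperparameter draw (concatenated).

    Each pair is a two-population split at its τ (converted to generations
    through θ_AVE = 4·N_AVE·u), HKY mutation with the pair's ti/tv, giving
    {π_total, π_within×2, π_net, θ_W, D×2}.  Uses the jit kernel; seed it
    via :func:`seed_kernel` / the ``seed`` argument of the callers.
    """
    if len(configs) != len(draw.tau):
        raise ValueError("configs inconsistent with draw length")
    u = _NOMINAL_U
    out = np.empty(len(configs) * _kernels.N_PAIR_STATS)
    for i, cfg in enumerate(configs):
        t_split = draw.tau[i] * theta_ave / u
        vec = _kernels.pair_stats(
            cfg.n1,
            cfg.n2,
            t_split,
            draw.theta1[i] / (4.0 * u),
            draw.theta2[i] / (4.0 * u),
            draw.theta_anc[i] / (4.0 * u),
            cfg.kappa,
            0.25, 0.25, 0.25, 0.25,
            u,
            cfg.L,
        )
        out[i * _kernels.N_PAIR_STATS : (i + 1) * _kernels.N_PAIR_STATS] = vec
    return out


def observed_pair_stats(
    pair_alignments: Sequence[tuple[SequenceAlignment, SequenceAlignment]],
) -> np.ndarray:
    """Observed per-pair statistic vector from (pop1, pop2) alignments.

    Alignments of the two populations of each pair must share a length; the
    statistics mirror the simulated vector exactly.
    """
    from .sumstats import pairwise_difference_matrix, tajimas_d, segregating_sites

    chunks = []
    for aln1, aln2 in pair_alignments:
        if aln1.n_sites != aln2.n_sites:
            raise ValueError("pair alignments differ in length")
        n1, n2 = aln1.n_samples, aln2.n_samples
        ids = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
        merged = SequenceAlignment(
            tuple(ids), np.vstack([aln1.matrix, aln2.matrix])
        )
        L = merged.n_sites
        d = pairwise_difference_matrix(merged)
        iu = np.triu_indices(n1 + n2, 1)
        pi_total = float(d[iu].mean()) / L
        w1 = d[:n1, :n1][np.triu_indices(n1, 1)]
        w2 = d[n1:, n1:][np.triu_indices(n2, 1)]
        pi_w1 = float(w1.mean()) / L if len(w1) else 0.0
        pi_w2 = float(w2.mean()) / L if len(w2) else 0.0
        pi_b = float(d[:n1, n1:].mean()) / L
        pi_net = pi_b - 0.5 * (pi_w1 + pi_w2)
        s_tot, _ = segregating_sites(merged)
        a1 = sum(1.0 / i for i in range(1, n1 + n2))
        theta_w = s_tot / a1 / L
        s1, _ = segregating_sites(aln1)
        s2, _ = segregating_sites(aln2)
        d1 = tajimas_d(n1, s1, float(w1.mean()) if len(w1) else 0.0)
        d2 = tajimas_d(n2, s2, float(w2.mean()) if len(w2) else 0.0)
        chunks.append(
            np.array([
                pi_total, pi_w1, pi_w2, pi_net, theta_w,
                d1 if math.isfinite(d1) else 0.0,
                d2 if math.isfinite(d2) else 0.0,
            ])
        )
    return np.concatenate(chunks)


# ---------------------------------------------------------------------------
# Posterior
# ---------------------------------------------------------------------------

def _hyperprior_arrays(
    configs: Sequence[PairConfig],
    tau_max: float,
    n_sims: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised hyperprior draws, identical in law to :func:`sample_hyperprior`."""
    n_pairs = len(configs)
    psis = rng.integers(1, n_pairs + 1, size=n_sims)
    tau_vals = tau_max * (1.0 - rng.random((n_sims, n_pairs)))
    classes = np.zeros((n_sims, n_pairs), dtype=np.int64)
    for k in range(1, n_pairs + 1):
        rows = np.flatnonzero(psis == k)
        if len(rows) == 0:
            continue
        if k == 1:
            continue
        pending = rows
        while len(pending):
            draw = rng.integers(0, k, size=(len(pending), n_pairs))
            covered = np.ones(len(pending), dtype=bool)
            for c in range(k):
                covered &= (draw == c).any(axis=1)
            classes[pending[covered]] = draw[covered]
            pending = pending[~covered]
    tau = np.take_along_axis(tau_vals, classes, axis=1)
    uppers = np.array([c.theta_upper for c in configs])
    th1 = uppers * (1.0 - rng.random((n_sims, n_pairs)))
    th2 = uppers * (1.0 - rng.random((n_sims, n_pairs)))
    tha = uppers * (1.0 - rng.random((n_sims, n_pairs)))
    return psis, tau, th1, th2, tha

def _hpd_interval(x: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the sample."""
    xs = np.sort(x)
    n = len(xs)
    m = max(int(math.ceil(mass * n)), 1)  # points the interval must contain
    if m >= n:
        return float(xs[0]), float(xs[-1])
    widths = xs[m - 1 :] - xs[: n - m + 1]
    i = int(np.argmin(widths))
    return float(xs[i]), float(xs[i + m - 1])


def _sample_mode(x: np.ndarray, lower_bound: float | None = None) -> float:
    """Gaussian-KDE mode (Silverman bandwidth); degenerate samples short-circuit.

    For quantities supported on [lower_bound, ∞) the sample is reflected at
    the bound before fitting, the standard correction for the Gaussian
    kernel's boundary bias — without it a point mass sitting exactly on the
    bound (Ψ = 1 draws have Ω = 0) gets half its density pushed outside the
    support and the mode drifts inward.
    """
    if np.ptp(x) == 0:
        return float(x[0])
    if lower_bound is not None:
        fit_sample = np.concatenate([x, 2.0 * lower_bound - x])
    else:
        fit_sample = x
    kde = sps.gaussian_kde(fit_sample, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def habc_posterior(
    observed: np.ndarray,
    configs: Sequence[PairConfig],
    n_sims: int,
    tolerance: float,
    seed: int,
    tau_max: float = 0.5,
    theta_ave_definition: Literal["half-upper", "upper"] = "half-upper",
) -> HyperPosterior:
    """Acceptance/rejection posterior for (Ψ, Ω, E(τ)).

    Simulates ``n_sims`` hyperprior draws, accepts the closest
    ``tolerance`` fraction by Euclidean distance on MAD-scaled concatenated
    statistics, and summarises Ψ (pmf), Ω and E(τ) (KDE modes with 95% HPD
    intervals).  The draw is synchronous when the Ω mode ≤ 0.01.
    """
    if n_sims * tolerance < 200:
        raise ValueError("n_sims * tolerance must be >= 200")
    n_pairs = len(configs)
    rng = np.random.default_rng(seed)
    _kernels.seed_kernel(int(rng.integers(0, 2**31 - 1)))
    theta_ave = theta_ave_of(configs, theta_ave_definition)
    psis, tau, th1, th2, tha = _hyperprior_arrays(configs, tau_max, n_sims, rng)
    u = _NOMINAL_U
    stats = np.empty((n_sims, n_pairs * _kernels.N_PAIR_STATS))
    ns = _kernels.N_PAIR_STATS
    for j, cfg in enumerate(configs):
        _kernels.batch_pair_stats(
            cfg.n1, cfg.n2,
            tau[:, j] * theta_ave / u,
            th1[:, j] / (4.0 * u), th2[:, j] / (4.0 * u), tha[:, j] / (4.0 * u),
            cfg.kappa, 0.25, 0.25, 0.25, 0.25, u, cfg.L,
            stats[:, j * ns : (j + 1) * ns],
        )
    bad = ~np.all(np.isfinite(stats), axis=1)
    if bad.any():  # pragma: no cover - defensive
        stats[bad] = 0.0
    omegas = tau.var(axis=1) / np.where(tau.mean(axis=1) > 0, tau.mean(axis=1), 1.0)
    omegas[psis == 1] = 0.0  # exact zero, immune to var() round-off
    e_taus = tau.mean(axis=1)
    med = np.median(stats, axis=0)
    mad = np.median(np.abs(stats - med), axis=0)
    mad[mad == 0.0] = 1.0
    dist = np.sqrt((((stats - observed) / mad) ** 2).sum(axis=1))
    n_accept = max(int(math.ceil(tolerance * n_sims)), 1)
    idx = np.argsort(dist, kind="stable")[:n_accept]
    if len(np.unique(np.round(dist[idx], 12))) < 2 and n_accept < n_sims:
        warnings.warn("degenerate accepted set; widening tolerance")
        n_accept = min(2 * n_accept, n_sims)
        idx = np.argsort(dist, kind="stable")[:n_accept]
    acc_psi = psis[idx]
    pmf = np.bincount(acc_psi, minlength=n_pairs + 1)[1:].astype(float)
    pmf /= pmf.sum()
    acc_om = omegas[idx]
    acc_et = e_taus[idx]
    return HyperPosterior(
        psi_pmf=pmf,
        omega_samples=acc_om,
        omega_mode=_sample_mode(acc_om, lower_bound=0.0),
        omega_hpd=_hpd_interval(acc_om),
        e_tau_samples=acc_et,
        e_tau_mode=_sample_mode(acc_et, lower_bound=0.0),
        e_tau_hpd=_hpd_interval(acc_et),
        tolerance=tolerance,
        n_accepted=n_accept,
    )


# ---------------------------------------------------------------------------
# Absolute-time conversion
# ---------------------------------------------------------------------------

def tdiv_convert(
    e_tau: float,
    theta_ave: float,
    mu: float,
    mu_unit: Literal["per_generation", "per_year", "per_Myr"] = "per_Myr",
    generation_time: float = 2.0,
) -> TimeConversion:
    """T_div = E(τ)·(θ_AVE/μ)·g with explicit unit normalisation.

    τ is in units of 4·N_AVE generations and θ_AVE = 4·N_AVE·μ_gen, so
    E(τ)·θ_AVE/μ_gen is a number of generations and ×g converts to years.
    μ may be declared per generation, per year, or per Myr; it is converted
    to per generation (via g) before the arithmetic — never silently.
    """
    if e_tau < 0 or theta_ave <= 0 or mu <= 0 or generation_time <= 0:
        raise ValueError("all conversion inputs must be positive (e_tau >= 0)")
    if mu_unit == "per_generation":
        mu_gen = mu
    elif mu_unit == "per_year":
        mu_gen = mu * generation_time
    elif mu_unit == "per_Myr":
        mu_gen = mu / 1e6 * generation_time
    else:
        raise ValueError(f"unknown mu unit {mu_unit!r}")
    generations = e_tau * theta_ave / mu_gen
    return TimeConversion(
        e_tau=e_tau,
        theta_ave=theta_ave,
        mu=mu,
        mu_unit=mu_unit,
        generation_time=generation_time,
        t_div_generations=generations,
        t_div_years=generations * generation_time,
    )
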