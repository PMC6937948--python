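"""Approximate Bayesian computation for demographic-scenario choice.

Implements the reference-table workflow popularised for event-list
demographic models: draw parameters from priors, simulate datasets under
each competing scenario, summarise them with the same statistics computed on
the observed data, then

* choose among scenarios by rejection (scenario frequencies among the
  closest simulations) and by multinomial logistic regression on the
  accepted set evaluated at the observed point, with a 95% CI for the
  winning posterior probability;
* estimate parameters of the chosen scenario by local-linear regression
  adjustment of the accepted draws (log scale for sizes and times, logit for
  proportions);
* quantify confidence via type I / type II error rates from pseudo-observed
  datasets (PODs) and a PCA model check.

Distances are Euclidean on statistics scaled by their reference-table median
absolute deviation, so the choice of raw units is immaterial.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import integrate, stats as sps

from . import sumstats
from .coalsim import (
    DemographicScenario,
    MutationModel,
    simulate_dataset,
)
from .popdata import PopulationAssignment, SequenceAlignment

__all__ = [
    "Uniform",
    "TruncatedGamma",
    "PriorSet",
    "SimulationConfig",
    "ReferenceTable",
    "ScenarioPosterior",
    "ErrorRates",
    "ParameterPosterior",
    "PcaCheck",
    "sample_prior",
    "abc_statistics",
    "build_reference_table",
    "select_scenario",
    "compute_error_rates",
    "estimate_parameters",
    "model_check_pca",
    "convert_generations_to_years",
]

Transform = Literal["identity", "log", "logit"]


from functools import lru_cache


@lru_cache(maxsize=32)
def _frozen_gamma(shape: float, mean_value: float):
    return sps.gamma(shape, scale=mean_value / shape)


@lru_cache(maxsize=32)
def _gamma_cdf_bounds(shape: float, mean_value: float, low: float, high: float):
    dist = _frozen_gamma(shape, mean_value)
    return float(dist.cdf(low)), float(dist.cdf(high))


@dataclass(frozen=True)
class Uniform:
    """Uniform prior on [low, high]; ``transform`` controls the regression scale."""

    low: float
    high: float
    transform: Transform = "identity"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.low) and math.isfinite(self.high)):
            raise ValueError("prior bounds must be finite")
        if self.high < self.low:
            raise ValueError("prior bounds out of order")

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(self.low, self.high))

    @property
    def support(self) -> tuple[float, float]:
        return (self.low, self.high)

    def mean(self) -> float:
        return 0.5 * (self.low + self.high)


@dataclass(frozen=True)
class TruncatedGamma:
    """Gamma prior with a given mean, truncated to [low, high].

    The shape parameter is configurable (the scale follows from the mean);
    sampling is by rejection, which is cheap for the mutation-rate prior this
    exists for (mean 2.0e−8, truncated to [1.6e−8, 2.9e−8] subs/site/year).
    """

    mean_value: float
    low: float
    high: float
    shape: float = 2.0
    transform: Transform = "log"

    def __post_init__(self) -> None:
        if not (0 < self.low <= self.mean_value <= self.high):
            raise ValueError("require 0 < low <= mean <= high")

    def _dist(self):
        return _frozen_gamma(self.shape, self.mean_value)

    def sample(self, rng: np.random.Generator) -> float:
        dist = self._dist()
        lo_q, hi_q = _gamma_cdf_bounds(self.shape, self.mean_value, self.low, self.high)
        # inverse-CDF on the truncated quantile range: exact, no rejection loop
        return float(dist.ppf(lo_q + rng.random() * (hi_q - lo_q)))

    @property
    def support(self) -> tuple[float, float]:
        return (self.low, self.high)

    def mean(self) -> float:
        """Mean of the truncated distribution, by numeric integration."""
        dist = self._dist()
        z = dist.cdf(self.high) - dist.cdf(self.low)
        num, _ = integrate.quad(lambda x: x * dist.pdf(x), self.low, self.high)
        return num / z


Prior = Uniform | TruncatedGamma


@dataclass(frozen=True)
class PriorSet:
    """Named priors plus declared order constraints (e.g. t1 < t2 < t3).

    ``order_constraints`` is a list of (smaller, larger) parameter-name
    pairs; it must form a partial order (no cycles).  ``generation_time`` is
    the generation time g in years used when converting times.
    """

    priors: Mapping[str, Prior]
    order_constraints: tuple[tuple[str, str], ...] = ()
    generation_time: float = 2.0

    def __post_init__(self) -> None:
        for a, b in self.order_constraints:
            for name in (a, b):
                if name not in self.priors:
                    raise ValueError(f"constraint references unknown parameter '{name}'")
        # cycle check via Kahn's algorithm
        edges = {n: set() for n in self.priors}
        indeg = {n: 0 for n in self.priors}
        for a, b in self.order_constraints:
            if b not in edges[a]:
                edges[a].add(b)
                indeg[b] += 1
        queue = [n for n, d in indeg.items() if d == 0]
        seen = 0
        while queue:
            n = queue.pop()
            seen += 1
            for m in edges[n]:
                indeg[m] -= 1
                if indeg[m] == 0:
                    queue.append(m)
        if seen != len(self.priors):
            raise ValueError("order constraints contain a cycle")


def sample_prior(
    priors: PriorSet,
    rng: np.random.Generator,
    max_tries: int = 10_000,
) -> dict[str, float]:
    """One joint draw satisfying all order constraints (rejection re-draw).

    Raises when the constraint-satisfaction probability appears to be below
    1/``max_tries`` — a sign the priors should be revised.
    """
    for _ in range(max_tries):
        draw = {name: p.sample(rng) for name, p in priors.priors.items()}
        if all(draw[a] < draw[b] for a, b in priors.order_constraints):
            return draw
    raise RuntimeError(
        f"no draw satisfied the order constraints in {max_tries} attempts; "
        "the declared constraints are nearly incompatible with the prior "
        "bounds — revise the priors"
    )


# ---------------------------------------------------------------------------
# Summary statistics for ABC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """What a single reference-table simulation looks like.

    ``kappa`` and ``frequencies`` parameterise the HKY model; ``mu_param``
    names the prior holding the per-site per-generation mutation rate (after
    any per-year → per-generation conversion done by the caller).
    """

    L: int
    mu_param: str = "mu"
    kappa: float = 4.0
    frequencies: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)


def abc_statistics(
    aln: SequenceAlignment, assign: PopulationAssignment
) -> tuple[tuple[str, ...], np.ndarray]:
    """The default ABC feature vector.

    Per population: Hd, π, k, S, Tajima's D (D set to 0 where undefined, so
    the feature stays informative rather than forcing a resimulation); per
    ordered population pair: mean between-population pairwise differences
    and the point ΦST.  Population order follows the assignment.
    """
    names: list[str] = []
    values: list[float] = []
    pops = assign.populations
    subsets = {}
    for p in pops:
        sub = aln.subset(list(assign.samples_in_population(p)))
        subsets[p] = sub
        st = sumstats.summarize(sub) if sub.n_samples >= 2 else None
        if st is None:
            row = [0.0, 0.0, 0.0, 0.0, 0.0]
        else:
            row = [
                st.Hd if math.isfinite(st.Hd) else 0.0,
                st.pi if math.isfinite(st.pi) else 0.0,
                st.k if math.isfinite(st.k) else 0.0,
                float(st.S),
                st.D if math.isfinite(st.D) else 0.0,
            ]
        names += [f"{p}:{s}" for s in ("Hd", "pi", "k", "S", "D")]
        values += row
    d2 = sumstats.pairwise_difference_matrix(aln)
    index = {s: i for i, s in enumerate(aln.sample_ids)}
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            a = [index[s] for s in assign.samples_in_population(pops[i])]
            b = [index[s] for s in assign.samples_in_population(pops[j])]
            between = float(d2[np.ix_(a, b)].mean())
            names.append(f"{pops[i]}|{pops[j]}:k_between")
            values.append(between)
            phist = sumstats._two_level_phist(d2, [np.array(a), np.array(b)])
            names.append(f"{pops[i]}|{pops[j]}:PhiST")
            values.append(phist if math.isfinite(phist) else 0.0)
    return tuple(names), np.asarray(values)


# ---------------------------------------------------------------------------
# Reference table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceTable:
    """(scenario, parameter draw, statistics) rows plus the MAD scale record."""

    scenario_names: tuple[str, ...]
    scenario_idx: np.ndarray
    params: tuple[dict[str, float], ...]
    stats: np.ndarray
    stat_names: tuple[str, ...]
    scales: np.ndarray

    @property
    def n_rows(self) -> int:
        return len(self.scenario_idx)

    def scaled(self) -> np.ndarray:
        return self.stats / self.scales

    def scale_vector(self, observed: np.ndarray) -> np.ndarray:
        return np.asarray(observed, dtype=float) / self.scales


def _mad(x: np.ndarray) -> np.ndarray:
    med = np.median(x, axis=0)
    return np.median(np.abs(x - med), axis=0)


def build_reference_table(
    scenarios: Sequence[DemographicScenario],
    priors: PriorSet,
    n_per_scenario: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    max_resim: int = 50,
) -> ReferenceTable:
    """Simulate a balanced reference table and record per-statistic MAD scales.

    Non-finite statistic rows are resimulated (with a fresh prior draw); MAD
    scales of 0 (constant columns) are replaced by 1 so scaling never
    divides by zero.
    """
    if len(scenarios) < 1:
        raise ValueError("need at least one scenario")
    rows_stats: list[np.ndarray] = []
    rows_params: list[dict[str, float]] = []
    rows_scn: list[int] = []
    stat_names: tuple[str, ...] | None = None
    for s_idx, scenario in enumerate(scenarios):
        done = 0
        resims = 0
        while done < n_per_scenario:
            draw = sample_prior(priors, rng)
            model = MutationModel(
                kappa=config.kappa,
                frequencies=config.frequencies,
                u=draw.get(config.mu_param, 1e-8),
            )
            ds = simulate_dataset(scenario, draw, model, config.L, rng)
            names, vec = abc_statistics(ds.alignment, ds.assignment)
            if stat_names is None:
                stat_names = names
            if not np.all(np.isfinite(vec)):
                resims += 1
                if resims > max_resim * n_per_scenario:
                    raise RuntimeError("too many non-finite statistic rows")
                continue
            rows_stats.append(vec)
            rows_params.append(draw)
            rows_scn.append(s_idx)
            done += 1
    stats_arr = np.vstack(rows_stats)
    scales = _mad(stats_arr)
    scales[scales == 0.0] = 1.0
    return ReferenceTable(
        tuple(s.name for s in scenarios),
        np.asarray(rows_scn),
        tuple(rows_params),
        stats_arr,
        stat_names or (),
        scales,
    )


# ---------------------------------------------------------------------------
# Scenario choice
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioPosterior:
    scenario_names: tuple[str, ...]
    rejection_pp: np.ndarray
    regression_pp: np.ndarray
    selected: int
    ci_low: float
    ci_high: float
    tolerance: float
    n_accepted: int
    ci_method: str = "delta"


def _accepted_indices(
    table: ReferenceTable, observed: np.ndarray, tolerance: float
) -> tuple[np.ndarray, np.ndarray]:
    scaled = table.scaled()
    obs = table.scale_vector(observed)
    dist = np.sqrt(((scaled - obs) ** 2).sum(axis=1))
    n_accept = max(int(math.ceil(tolerance * table.n_rows)), 1)
    idx = np.argsort(dist, kind="stable")[:n_accept]
    return idx, dist


def select_scenario(
    table: ReferenceTable,
    observed: np.ndarray,
    tolerance: float = 0.01,
) -> ScenarioPosterior:
    """Scenario posterior probabilities by rejection and logistic regression.

    Rejection: scenario frequencies among the closest ``tolerance`` fraction
    of rows (Euclidean distance on MAD-scaled statistics).  Regression:
    multinomial logistic regression of the scenario label on the statistic
    offsets within the accepted set, evaluated at the observed point, with a
    95% CI for the selected scenario's probability from the asymptotic
    covariance (delta method); when the regression cannot be fitted (e.g.
    perfect separation) the CI falls back to the binomial rejection interval.
    Scenarios absent from the accepted set get probability 0 with a warning.
    """
    k = len(table.scenario_names)
    idx, _ = _accepted_indices(table, observed, tolerance)
    labels = table.scenario_idx[idx]
    n_acc = len(idx)
    rejection = np.bincount(labels, minlength=k).astype(float) / n_acc
    if np.any(rejection == 0.0):
        absent = [table.scenario_names[i] for i in np.flatnonzero(rejection == 0.0)]
        warnings.warn(
            f"scenarios absent from accepted set, PP floored at 0: {absent}",
            stacklevel=2,
        )
    present = np.unique(labels)
    if len(present) == 1:
        reg = np.zeros(k)
        reg[present[0]] = 1.0
        sel = int(present[0])
        lo = max(0.0, 1.0 - 3.0 / n_acc)  # rule-of-three style lower bound
        return ScenarioPosterior(
            table.scenario_names, rejection, reg, sel, lo, 1.0,
            tolerance, n_acc, "degenerate",
        )
    x = table.scaled()[idx] - table.scale_vector(observed)
    reg, ci, method = _multinomial_pp(x, labels, present, k)
    sel = int(np.argmax(reg))
    if ci is None:
        p = reg[sel]
        half = 1.96 * math.sqrt(max(p * (1 - p), 1e-12) / n_acc)
        lo, hi = max(0.0, p - half), min(1.0, p + half)
        method = method + "+binomial_ci"
    else:
        lo, hi = ci[sel]
        lo, hi = max(0.0, min(lo, reg[sel])), min(1.0, max(hi, reg[sel]))
    if np.sum(reg == reg[sel]) > 1:
        warnings.warn("tied posterior probabilities; lowest scenario index selected")
        sel = int(np.flatnonzero(reg == reg[sel])[0])
    return ScenarioPosterior(
        table.scenario_names, rejection, reg, sel, lo, hi, tolerance, n_acc, method
    )


def _multinomial_pp(
    x: np.ndarray, labels: np.ndarray, present: np.ndarray, k: int
) -> tuple[np.ndarray, list[tuple[float, float]] | None, str]:
    """Multinomial-logit PP at x=0 and per-class delta-method 95% CIs."""
    remap = {int(c): i for i, c in enumerate(present)}
    y = np.array([remap[int(l)] for l in labels])
    try:
        import statsmodels.api as sm

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            design = sm.add_constant(x, has_constant="add")
            fit = sm.MNLogit(y, design).fit(disp=0, maxiter=200)
            if not np.all(np.isfinite(fit.params)):
                raise RuntimeError("non-finite MNLogit parameters")
        n_classes = len(present)
        intercepts = np.concatenate([[0.0], fit.params[0, :]])
        expo = np.exp(intercepts - intercepts.max())
        probs_present = expo / expo.sum()
        # delta method: dp/db for intercept coefficients b_2..b_J
        cov = np.asarray(fit.cov_params())
        n_feat = design.shape[1]
        icov = np.zeros((n_classes - 1, n_classes - 1))
        for a in range(n_classes - 1):
            for b in range(n_classes - 1):
                icov[a, b] = cov[a * n_feat, b * n_feat]
        cis: list[tuple[float, float]] = []
        full = np.zeros(k)
        for i, c in enumerate(present):
            full[int(c)] = probs_present[i]
        for c in range(k):
            if c not in remap:
                cis.append((0.0, 0.0))
                continue
            i = remap[c]
            grad = np.empty(n_classes - 1)
            for j in range(1, n_classes):
                grad[j - 1] = probs_present[i] * ((1.0 if j == i else 0.0) - probs_present[j])
            var = float(grad @ icov @ grad)
            half = 1.96 * math.sqrt(max(var, 0.0))
            cis.append((full[int(c)] - half, full[int(c)] + half))
        return full, cis, "mnlogit-delta"
    except Exception:
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(max_iter=1000, C=1e6)
        clf.fit(x, y)
        probs_present = clf.predict_proba(np.zeros((1, x.shape[1])))[0]
        full = np.zeros(k)
        for i, c in enumerate(present):
            full[int(c)] = probs_present[i]
        return full, None, "sklearn-fallback"


# ---------------------------------------------------------------------------
# POD-based error rates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorRates:
    scenario_names: tuple[str, ...]
    confusion: np.ndarray  # rows: true scenario; cols: selected
    type1: np.ndarray  # P(not selected | true)
    type2: np.ndarray  # P(selected | some other true), averaged
    n_pods: int


def compute_error_rates(
    scenarios: Sequence[DemographicScenario],
    priors: PriorSet,
    table: ReferenceTable,
    config: SimulationConfig,
    rng: np.random.Generator,
    n_pods: int = 500,
    tolerance: float = 0.01,
) -> ErrorRates:
    """Type I / type II scenario-choice error from pseudo-observed datasets.

    ``n_pods`` pseudo-observed datasets are split evenly across scenarios;
    each is pushed through :func:`select_scenario` against ``table`` and the
    confusion matrix tabulated.  Type I for scenario s is the probability of
    not selecting s when s is true; type II is the probability of selecting s
    when another scenario is true (averaged over the others).
    """
    if n_pods < 100:
        raise ValueError("n_pods must be >= 100")
    k = len(scenarios)
    per = n_pods // k
    confusion = np.zeros((k, k))
    counts = np.zeros(k)
    for s_idx, scenario in enumerate(scenarios):
        for _ in range(per):
            draw = sample_prior(priors, rng)
            model = MutationModel(
                kappa=config.kappa, frequencies=config.frequencies,
                u=draw.get(config.mu_param, 1e-8),
            )
            ds = simulate_dataset(scenario, draw, model, config.L, rng)
            _, vec = abc_statistics(ds.alignment, ds.assignment)
            if not np.all(np.isfinite(vec)):
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                post = select_scenario(table, vec, tolerance)
            confusion[s_idx, post.selected] += 1
            counts[s_idx] += 1
    confusion /= counts[:, None]
    type1 = 1.0 - np.diag(confusion)
    type2 = np.array(
        [confusion[np.arange(k) != s, s].mean() for s in range(k)]
    )
    return ErrorRates(tuple(s.name for s in scenarios), confusion, type1, type2, n_pods)


# ---------------------------------------------------------------------------
# Parameter estimation (local-linear regression adjustment)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterPosterior:
    samples: dict[str, np.ndarray]
    point: dict[str, dict[str, float]]  # mean/median/mode per parameter
    interval: dict[str, tuple[float, float]]  # central 95%
    transforms: dict[str, str]
    n_accepted: int
    adjusted: bool


def _forward(x: np.ndarray, transform: str, lo: float, hi: float) -> np.ndarray:
    if transform == "log":
        return np.log(np.clip(x, 1e-300, None))
    if transform == "logit":
        p = np.clip((x - lo) / (hi - lo), 1e-12, 1 - 1e-12)
        return np.log(p / (1 - p))
    return x


def _backward(z: np.ndarray, transform: str, lo: float, hi: float) -> np.ndarray:
    if transform == "log":
        out = np.exp(z)
    elif transform == "logit":
        out = lo + (hi - lo) / (1.0 + np.exp(-z))
    else:
        out = z
    return np.clip(out, lo, hi)


def _mode_kde(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return float(x[0])
    kde = sps.gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def estimate_parameters(
    table: ReferenceTable,
    observed: np.ndarray,
    priors: PriorSet,
    scenario_index: int,
    tolerance: float = 0.01,
    adjust: bool = True,
) -> ParameterPosterior:
    """Posterior for the chosen scenario's parameters from the closest rows.

    Accepted draws are adjusted by weighted local-linear regression of each
    transformed parameter on the scaled statistic offsets (Epanechnikov
    weights in distance), then back-transformed and clipped to the prior
    support.  A singular design falls back to the unadjusted rejection
    sample with a warning.
    """
    mask = table.scenario_idx == scenario_index
    sub_stats = table.stats[mask]
    sub_params = [table.params[i] for i in np.flatnonzero(mask)]
    if len(sub_params) == 0:
        raise ValueError("no rows for the requested scenario")
    scaled = sub_stats / table.scales
    obs = table.scale_vector(observed)
    dist = np.sqrt(((scaled - obs) ** 2).sum(axis=1))
    n_accept = max(int(math.ceil(tolerance * table.n_rows)), 2)
    n_accept = min(n_accept, len(sub_params))
    order = np.argsort(dist, kind="stable")[:n_accept]
    d_acc = dist[order]
    d_max = d_acc.max() if d_acc.max() > 0 else 1.0
    w = 1.0 - (d_acc / d_max) ** 2
    w = np.clip(w, 1e-6, None)
    x = scaled[order] - obs

    names = list(sub_params[0])
    samples: dict[str, np.ndarray] = {}
    transforms: dict[str, str] = {}
    adjusted_flag = adjust
    for name in names:
        raw = np.array([sub_params[i][name] for i in order])
        prior = priors.priors.get(name)
        transform = prior.transform if prior is not None else "identity"
        lo, hi = prior.support if prior is not None else (-np.inf, np.inf)
        transforms[name] = transform
        z = _forward(raw, transform, lo, hi)
        if adjust and np.ptp(z) > 0:
            design = np.column_stack([np.ones(len(z)), x])
            wsq = np.sqrt(w)
            try:
                beta, *_ = np.linalg.lstsq(design * wsq[:, None], z * wsq, rcond=None)
                fitted = design @ beta
                z_adj = beta[0] + (z - fitted)
            except np.linalg.LinAlgError:
                warnings.warn(f"singular design for '{name}'; unadjusted sample used")
                z_adj = z
                adjusted_flag = False
        else:
            z_adj = z
        samples[name] = _backward(z_adj, transform, lo, hi)

    point = {}
    interval = {}
    for name, s in samples.items():
        point[name] = {
            "mean": float(np.mean(s)),
            "median": float(np.median(s)),
            "mode": _mode_kde(s),
        }
        interval[name] = (
            float(np.quantile(s, 0.025)),
            float(np.quantile(s, 0.975)),
        )
    return ParameterPosterior(samples, point, interval, transforms, n_accept, adjusted_flag)


# ---------------------------------------------------------------------------
# PCA model check
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PcaCheck:
    explained_variance_ratio: np.ndarray
    observed_coords: np.ndarray
    predictive_coords: np.ndarray
    reference_coords: np.ndarray
    observed_percentile: np.ndarray  # percentile of obs among predictive, per axis
    dropped_columns: tuple[int, ...]


def model_check_pca(
    table: ReferenceTable,
    observed: np.ndarray,
    predictive_stats: np.ndarray,
    n_components: int = 2,
) -> PcaCheck:
    """Project observed and posterior-predictive statistics into PC space.

    The PCA is fitted on the (MAD-scaled, centred) reference statistics;
    constant columns are dropped with notice.  The per-axis percentile of
    the observed point among the posterior-predictive projections is the
    model-check summary: values inside [2.5, 97.5] indicate the fitted
    scenario reproduces the observed data on that axis.
    """
    from sklearn.decomposition import PCA

    scaled = table.scaled()
    keep = np.ptp(scaled, axis=0) > 0
    dropped = tuple(int(i) for i in np.flatnonzero(~keep))
    if dropped:
        warnings.warn(f"constant statistic columns dropped from PCA: {dropped}")
    scaled = scaled[:, keep]
    n_components = min(n_components, scaled.shape[1])
    pca = PCA(n_components=n_components)
    ref_coords = pca.fit_transform(scaled)
    obs = (table.scale_vector(observed))[keep].reshape(1, -1)
    pred = (np.atleast_2d(predictive_stats) / table.scales)[:, keep]
    obs_coords = pca.transform(obs)[0]
    pred_coords = pca.transform(pred)
    pct = np.array(
        [
            100.0 * float(np.mean(pred_coords[:, a] <= obs_coords[a]))
            for a in range(n_components)
        ]
    )
    return PcaCheck(
        pca.explained_variance_ratio_,
        obs_coords,
        pred_coords,
        ref_coords,
        pct,
        dropped,
    )


def convert_generations_to_years(t: float, g: float = 2.0) -> float:
    """Generations → years at generation time g (default the conservative 2)."""
    if t < 0:
        raise ValueError("time must be non-negative")
    return t * g


# ---------------------------------------------------------------------------
# YAML prior files
# ---------------------------------------------------------------------------

def priors_from_dict(d: Mapping) -> PriorSet:
    """Build a :class:`PriorSet` from a plain mapping (e.g. parsed YAML).

    Structure::

        parameters:
          t1: {kind: uniform, low: 100, high: 1e6, transform: log}
          mu: {kind: truncated_gamma, mean: 2.0e-8, low: 1.6e-8, high: 2.9e-8}
        order: [[t1, t2], [t2, t3]]
        generation_time: 2
    """
    priors: dict[str, Prior] = {}
    for name, spec in d["parameters"].items():
        kind = spec.get("kind", "uniform")
        if kind == "uniform":
            priors[name] = Uniform(
                float(spec["low"]), float(spec["high"]),
                spec.get("transform", "identity"),
            )
        elif kind == "truncated_gamma":
            priors[name] = TruncatedGamma(
                float(spec["mean"]), float(spec["low"]), float(spec["high"]),
                float(spec.get("shape", 2.0)), spec.get("transform", "log"),
            )
        else:
            raise ValueError(f"unknown prior kind '{kind}' for '{name}'")
    order = tuple((a, b) for a, b in d.get("order", []))
    return PriorSet(priors, order, float(d.get("generation_time", 2.0)))


def load_priors(path) -> PriorSet:
    import yaml

    with open(path) as fh:
        return priors_from_dict(yaml.safe_load(fh))
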