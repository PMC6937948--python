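"""Diversity indices, neutrality tests, pairwise ΦST and hierarchical AMOVA.

The statistics here mirror what population geneticists compute from
multi-sample mtDNA alignments with Arlequin-style conventions:

* unbiased haplotype diversity Hd with Nei's sampling standard deviation,
* nucleotide diversity π and the mean number of pairwise differences k,
* Tajima's D and Fu's FS, with significance from neutral coalescent
  simulation (lower tail; FS conventionally called significant at p < 0.02,
  D at p < 0.05),
* pairwise ΦST from the matrix of pairwise sequence differences with a
  permutation test,
* three-level AMOVA (among groups / among populations within groups / within
  populations) with fixation indices F_CT, F_SC, F_ST and level-appropriate
  permutation schemes.

Distances are plain Hamming counts on comparable sites ("pairwise
differences"); no model correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from typing import Literal

import numpy as np
from scipy.special import logsumexp

from .popdata import (
    MISSING,
    HaplotypeTable,
    PopulationAssignment,
    SequenceAlignment,
    collapse_haplotypes,
    comparable_columns,
)

__all__ = [
    "SummaryStatistics",
    "PairwiseFstMatrix",
    "AmovaResult",
    "haplotype_diversity",
    "nucleotide_diversity",
    "segregating_sites",
    "tajimas_d",
    "fus_fs",
    "ewens_log_pmf",
    "neutrality_significance",
    "pairwise_difference_matrix",
    "pairwise_fst",
    "pairwise_fst_matrix",
    "amova",
    "summarize",
]

#: Default significance thresholds (stored, not baked into logic).
D_ALPHA = 0.05
FS_ALPHA = 0.02

NA = float("nan")


@dataclass(frozen=True)
class SummaryStatistics:
    """Per-population summary vector (the reporting unit and ABC features)."""

    n: int
    L: int
    S: int
    k: float
    pi: float
    sd_pi: float
    Hd: float
    sd_Hd: float
    K_obs: int
    D: float
    FS: float
    na_flags: frozenset[str] = field(default_factory=frozenset)

    def is_na(self, stat: str) -> bool:
        return stat in self.na_flags


@dataclass(frozen=True)
class PairwiseFstMatrix:
    labels: tuple[str, ...]
    phist: np.ndarray
    p_values: np.ndarray
    permutations: int


@dataclass(frozen=True)
class AmovaResult:
    """Three-level molecular variance decomposition.

    ``sigma2`` holds (σ²_a among groups, σ²_b among populations within
    groups, σ²_c within populations); ``percent`` the same as percentages of
    their sum.  ``n_distinct_group_permutations`` reports how many distinct
    reassignments of whole populations to groups exist — with few
    populations this bounds the achievable F_CT p-value from below.
    """

    ss: tuple[float, float, float]
    df: tuple[int, int, int]
    sigma2: tuple[float, float, float]
    percent: tuple[float, float, float]
    f_ct: float
    f_sc: float
    f_st: float
    p_ct: float
    p_sc: float
    p_st: float
    permutations: int
    n_distinct_group_permutations: int
    flags: frozenset[str] = field(default_factory=frozenset)


# ---------------------------------------------------------------------------
# Diversity indices
# ---------------------------------------------------------------------------

def haplotype_diversity(table: HaplotypeTable) -> tuple[float, float]:
    """Unbiased haplotype diversity and Nei's sampling standard deviation.

    Hd = n/(n−1) · (1 − Σ p_i²) and
    Var(Hd) = 2/(n(n−1)) · {2(n−2)[Σp_i³ − (Σp_i²)²] + Σp_i² − (Σp_i²)²}.
    Returns ``(nan, nan)`` for n < 2.
    """
    n = table.n
    if n < 2:
        return NA, NA
    p = np.asarray(table.counts, dtype=float) / n
    s2 = float((p**2).sum())
    s3 = float((p**3).sum())
    hd = n / (n - 1) * (1.0 - s2)
    var = 2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (s3 - s2**2) + s2 - s2**2)
    return hd, math.sqrt(max(var, 0.0))


def _pair_diffs(matrix: np.ndarray) -> np.ndarray:
    """Condensed vector of pairwise Hamming counts between rows."""
    n = matrix.shape[0]
    codes = matrix.view(np.uint32) if matrix.dtype == "U1" else matrix
    out = np.empty(n * (n - 1) // 2)
    idx = 0
    for i in range(n - 1):
        out[idx : idx + n - 1 - i] = (codes[i + 1 :] != codes[i]).sum(axis=1)
        idx += n - 1 - i
    return out


def nucleotide_diversity(
    aln: SequenceAlignment,
    policy: Literal["complete-deletion", "pairwise-ignore"] = "complete-deletion",
) -> tuple[float, float]:
    """Mean pairwise differences k and per-site nucleotide diversity π.

    Under complete deletion, columns with any missing/ambiguous symbol are
    dropped, k is the average Hamming distance over all C(n,2) pairs on the
    remaining sites, and π = k / L_effective.  Under pairwise-ignore each
    pair is compared on its own comparable sites and contributes its
    per-site proportion; π is the average proportion and k = π · L.
    """
    n = aln.n_samples
    if n < 2:
        raise ValueError("nucleotide diversity requires n >= 2")
    if policy == "complete-deletion":
        keep = comparable_columns(aln)
        if not keep.any():
            raise ValueError("no comparable sites under complete deletion")
        sub = np.ascontiguousarray(aln.matrix[:, keep])
        k = float(_pair_diffs(sub).mean())
        return k, k / int(keep.sum())
    miss = np.isin(aln.matrix, list(MISSING))
    props = []
    for i, j in combinations(range(n), 2):
        both = ~(miss[i] | miss[j])
        m = int(both.sum())
        if m == 0:
            raise ValueError(f"no comparable sites between rows {i} and {j}")
        props.append(float((aln.matrix[i, both] != aln.matrix[j, both]).sum()) / m)
    pi = float(np.mean(props))
    return pi * aln.n_sites, pi


def segregating_sites(
    aln: SequenceAlignment,
    policy: Literal["complete-deletion", "pairwise-ignore"] = "complete-deletion",
) -> tuple[int, int]:
    """Number of polymorphic columns S and the effective length L_eff."""
    if policy == "complete-deletion":
        keep = comparable_columns(aln)
        sub = aln.matrix[:, keep]
        if sub.shape[1] == 0:
            return 0, 0
        s = int((sub != sub[0]).any(axis=0).sum())
        return s, sub.shape[1]
    miss = np.isin(aln.matrix, list(MISSING))
    s = 0
    for col in range(aln.n_sites):
        states = set(aln.matrix[~miss[:, col], col])
        if len(states) > 1:
            s += 1
    return s, aln.n_sites


# ---------------------------------------------------------------------------
# Neutrality statistics
# ---------------------------------------------------------------------------

def tajimas_d(n: int, S: int, k: float) -> float:
    """Tajima's D from sample size, segregating sites, and mean pairwise k.

    Returns ``nan`` when S = 0 (the statistic is undefined, never 0/0).
    """
    if S == 0 or n < 2:
        return NA
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    denom = math.sqrt(e1 * S + e2 * S * (S - 1))
    if denom == 0.0:
        return NA
    return (k - S / a1) / denom


@lru_cache(maxsize=64)
def _log_stirling_first(n: int) -> tuple[float, ...]:
    """log of unsigned Stirling numbers of the first kind |s(n, k)|, k=0..n.

    Recurrence |s(m+1, k)| = |s(m, k−1)| + m·|s(m, k)|, in log space for
    overflow safety; n is capped at 1000.
    """
    if n > 1000:
        raise ValueError("n capped at 1000 for Stirling computation")
    prev = np.full(n + 1, -np.inf)
    prev[0] = 0.0  # |s(0,0)| = 1
    for m in range(1, n + 1):
        cur = np.full(n + 1, -np.inf)
        top = min(m, n)
        cur[1 : top + 1] = np.logaddexp(
            prev[0:top], (math.log(m - 1) if m > 1 else -np.inf) + prev[1 : top + 1]
        )
        prev = cur
    return tuple(prev)


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log P(K = j), j = 1..n, under the Ewens sampling formula.

    P(K = j) = |s(n, j)| θ^j / (θ(θ+1)···(θ+n−1)).
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    ls = np.asarray(_log_stirling_first(n)[1:])
    log_theta = math.log(theta)
    log_rising = sum(math.log(theta + i) for i in range(n))
    j = np.arange(1, n + 1)
    return ls + j * log_theta - log_rising


def fus_fs(n: int, k: float, K_obs: int) -> float:
    """Fu's FS: log-odds of observing at least K_obs haplotypes under Ewens.

    FS = ln(S′/(1−S′)) with S′ = P(K ≥ K_obs | θ = k, n).  Returns ``nan``
    when undefined (K_obs = 1 or k = 0) and signed infinity when S′ is
    numerically 0 or 1.
    """
    if K_obs <= 1 or k <= 0.0 or n < 2:
        return NA
    lp = ewens_log_pmf(n, k)
    log_sp = float(logsumexp(lp[K_obs - 1 :]))
    log_sp = min(log_sp, 0.0)
    sp = math.exp(log_sp)
    if sp >= 1.0:
        return math.inf
    if sp <= 0.0:
        return -math.inf
    # log(1-S') computed stably from the complementary tail
    log_one_minus = float(logsumexp(lp[: K_obs - 1])) if K_obs > 1 else -math.inf
    if not math.isfinite(log_one_minus):
        return math.inf
    return log_sp - log_one_minus


def neutrality_significance(
    stat: Literal["D", "FS"],
    observed: float,
    n: int,
    theta_hat: float,
    reps: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Lower-tail p-value of D or FS against the neutral coalescent null.

    Replicates are single-population constant-size coalescent genealogies
    with infinite-sites mutation at θ = ``theta_hat`` (the observed mean
    pairwise differences, the usual plug-in).  p is the fraction of
    replicates with statistic ≤ observed; replicates on which the statistic
    is undefined are redrawn.
    """
    from .coalsim import simulate_infinite_sites_stats

    if reps < 100:
        raise ValueError("reps must be >= 100")
    if not math.isfinite(observed):
        return NA
    rng = np.random.default_rng() if rng is None else rng
    count = 0
    done = 0
    redraws = 0
    while done < reps:
        S, k, K_obs = simulate_infinite_sites_stats(n, theta_hat, rng)
        value = tajimas_d(n, S, k) if stat == "D" else fus_fs(n, k, K_obs)
        if not math.isfinite(value):
            redraws += 1
            if redraws > 100 * reps:
                raise RuntimeError("null statistic undefined on almost all replicates")
            continue
        if value <= observed:
            count += 1
        done += 1
    return count / reps


# ---------------------------------------------------------------------------
# ΦST and AMOVA
# ---------------------------------------------------------------------------

def pairwise_difference_matrix(
    aln: SequenceAlignment,
    policy: Literal["complete-deletion", "pairwise-ignore"] = "complete-deletion",
) -> np.ndarray:
    """Full symmetric matrix of pairwise difference counts."""
    n = aln.n_samples
    if policy == "complete-deletion":
        keep = comparable_columns(aln)
        sub = np.ascontiguousarray(aln.matrix[:, keep])
    else:
        sub = aln.matrix
    d = np.zeros((n, n))
    codes = sub.view(np.uint32)
    if policy == "pairwise-ignore":
        miss = np.isin(sub, list(MISSING))
        for i in range(n):
            for j in range(i + 1, n):
                both = ~(miss[i] | miss[j])
                d[i, j] = d[j, i] = (codes[i, both] != codes[j, both]).sum()
    else:
        for i in range(n):
            diffs = (codes[i + 1 :] != codes[i]).sum(axis=1)
            d[i, i + 1 :] = diffs
            d[i + 1 :, i] = diffs
    return d


def _ssd_total(d2: np.ndarray, idx: np.ndarray) -> float:
    block = d2[np.ix_(idx, idx)]
    return float(block.sum()) / (2.0 * len(idx))


def _two_level_phist(d2: np.ndarray, groups: list[np.ndarray]) -> float:
    """ΦST from a two-level (populations / individuals) AMOVA.

    Returns ``nan`` when the total variance is zero.
    """
    n_total = sum(len(g) for g in groups)
    P = len(groups)
    all_idx = np.concatenate(groups)
    ssd_t = _ssd_total(d2, all_idx)
    ssd_wp = sum(_ssd_total(d2, g) for g in groups)
    ssd_ap = ssd_t - ssd_wp
    df_wp = n_total - P
    df_ap = P - 1
    if df_wp <= 0 or df_ap <= 0:
        return NA
    sigma_w = ssd_wp / df_wp
    n_c = (n_total - sum(len(g) ** 2 for g in groups) / n_total) / df_ap
    sigma_a = (ssd_ap / df_ap - sigma_w) / n_c
    tot = sigma_a + sigma_w
    if tot <= 0:
        return NA if tot == 0 and sigma_a == 0 else sigma_a / tot
    return sigma_a / tot


def pairwise_fst(
    aln: SequenceAlignment,
    assign: PopulationAssignment,
    pop_a: str,
    pop_b: str,
    permutations: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Pairwise ΦST between two populations with a permutation p-value.

    ΦST is the among-population variance fraction of a two-level AMOVA on
    the pairwise-difference matrix restricted to the two populations; the
    null is built by shuffling individuals between them.  p uses the
    standard (hits+1)/(perms+1) estimate with ties counted as ≥ observed.
    Returns ``(nan, nan)`` when total variance is zero.
    """
    rng = np.random.default_rng() if rng is None else rng
    samples_a = assign.samples_in_population(pop_a)
    samples_b = assign.samples_in_population(pop_b)
    sub = aln.subset(list(samples_a) + list(samples_b))
    d2 = pairwise_difference_matrix(sub)
    na, nb = len(samples_a), len(samples_b)
    idx_a = np.arange(na)
    idx_b = np.arange(na, na + nb)
    obs = _two_level_phist(d2, [idx_a, idx_b])
    if not math.isfinite(obs):
        return NA, NA
    hits = 0
    pool = np.arange(na + nb)
    for _ in range(permutations):
        perm = rng.permutation(pool)
        stat = _two_level_phist(d2, [perm[:na], perm[na:]])
        if math.isfinite(stat) and stat >= obs - 1e-12:
            hits += 1
    return obs, (hits + 1) / (permutations + 1)


def pairwise_fst_matrix(
    aln: SequenceAlignment,
    assign: PopulationAssignment,
    permutations: int = 1000,
    rng: np.random.Generator | None = None,
    level: Literal["population", "group"] = "population",
) -> PairwiseFstMatrix:
    """All pairwise ΦST values among populations (or groups) with p-values."""
    rng = np.random.default_rng() if rng is None else rng
    if level == "population":
        labels = assign.populations
        members = {p: assign.samples_in_population(p) for p in labels}
    else:
        labels = assign.groups
        members = {g: assign.samples_in_group(g) for g in labels}
    m = len(labels)
    phist = np.zeros((m, m))
    pvals = np.ones((m, m))
    flat = PopulationAssignment(
        {s: lab for lab in labels for s in members[lab]},
        {lab: lab for lab in labels},
    )
    for i in range(m):
        for j in range(i + 1, m):
            f, p = pairwise_fst(
                aln, flat, labels[i], labels[j], permutations=permutations, rng=rng
            )
            phist[i, j] = phist[j, i] = f
            pvals[i, j] = pvals[j, i] = p
    return PairwiseFstMatrix(labels, phist, pvals, permutations)


def _three_level_components(
    d2: np.ndarray,
    group_pops: list[list[np.ndarray]],
) -> tuple[tuple[float, float, float], tuple[int, int, int], tuple[float, float, float]]:
    """Sums of squares, degrees of freedom and variance components.

    ``group_pops[g]`` lists index arrays (individuals) of the populations in
    group g.  Standard moment estimators from the squared-distance AMOVA.
    """
    pops = [idx for g in group_pops for idx in g]
    N = sum(len(p) for p in pops)
    P = len(pops)
    G = len(group_pops)
    all_idx = np.concatenate(pops)
    ssd_total = _ssd_total(d2, all_idx)
    ssd_wp = sum(_ssd_total(d2, p) for p in pops)
    ssd_groups = 0.0
    for g in group_pops:
        gi = np.concatenate(g)
        ssd_groups += _ssd_total(d2, gi)
    ssd_ap_wg = ssd_groups - ssd_wp
    ssd_ag = ssd_total - ssd_groups
    df_ag, df_ap, df_wp = G - 1, P - G, N - P

    sigma_c = ssd_wp / df_wp if df_wp > 0 else 0.0
    # size coefficients (unequal sample sizes)
    sum_np2_over_ng = sum(
        sum(len(p) ** 2 for p in g) / sum(len(p) for p in g) for g in group_pops
    )
    sum_np2_over_N = sum(len(p) ** 2 for p in pops) / N
    sum_ng2_over_N = sum(sum(len(p) for p in g) ** 2 for g in group_pops) / N
    if df_ap > 0:
        n_prime = (N - sum_np2_over_ng) / df_ap
        sigma_b = (ssd_ap_wg / df_ap - sigma_c) / n_prime if n_prime > 0 else 0.0
    else:
        sigma_b = 0.0
    if df_ag > 0:
        n_dbl = (sum_np2_over_ng - sum_np2_over_N) / df_ag
        n_trpl = (N - sum_ng2_over_N) / df_ag
        msd_ag = ssd_ag / df_ag
        sigma_a = (msd_ag - sigma_c - n_dbl * sigma_b) / n_trpl if n_trpl > 0 else 0.0
    else:
        sigma_a = 0.0
    return (
        (ssd_ag, ssd_ap_wg, ssd_wp),
        (df_ag, df_ap, df_wp),
        (sigma_a, sigma_b, sigma_c),
    )


def _amova_indices(sig: tuple[float, float, float]) -> tuple[float, float, float]:
    a, b, c = sig
    tot = a + b + c
    f_ct = a / tot if tot != 0 else NA
    f_sc = b / (b + c) if (b + c) != 0 else NA
    f_st = (a + b) / tot if tot != 0 else NA
    return f_ct, f_sc, f_st


def _distinct_group_permutations(sizes: list[int]) -> int:
    """Distinct assignments of P labelled populations to groups of fixed sizes."""
    total = math.factorial(sum(sizes))
    for s in sizes:
        total //= math.factorial(s)
    return total


def amova(
    aln: SequenceAlignment,
    assign: PopulationAssignment,
    permutations: int = 1000,
    rng: np.random.Generator | None = None,
) -> AmovaResult:
    """Three-level AMOVA with permutation tests for F_CT, F_SC, F_ST.

    Permutation schemes follow the standard design: F_ST permutes individuals
    among populations across the whole dataset; F_SC permutes individuals
    among populations within their group; F_CT permutes whole populations
    among groups (group sizes in populations held fixed).
    """
    rng = np.random.default_rng() if rng is None else rng
    assign.validate_against(aln)
    d2 = pairwise_difference_matrix(aln)
    sample_index = {s: i for i, s in enumerate(aln.sample_ids)}

    groups = list(assign.groups)
    if len(groups) < 2:
        raise ValueError("three-level AMOVA needs at least 2 groups")
    group_pops: list[list[np.ndarray]] = []
    for g in groups:
        pops = []
        for p in assign.populations_in_group(g):
            pops.append(
                np.array([sample_index[s] for s in assign.samples_in_population(p)])
            )
        group_pops.append(pops)

    ss, df, sig = _three_level_components(d2, group_pops)
    f_ct, f_sc, f_st = _amova_indices(sig)
    tot = sum(sig)
    flags = set()
    if tot == 0:
        flags.add("zero_total_variance")
        percent = (0.0, 0.0, 0.0)
    else:
        percent = tuple(100.0 * s / tot for s in sig)  # type: ignore[assignment]
    for name, d in zip(("among_groups", "among_pops_within_groups", "within_pops"), df):
        if d <= 0:
            flags.add(f"no_df_{name}")

    pop_sizes_per_group = [len(g) for g in group_pops]
    n_distinct = _distinct_group_permutations(pop_sizes_per_group)

    hits_st = hits_sc = hits_ct = 0
    flat_pops = [p for g in group_pops for p in g]
    pop_lengths = [len(p) for p in flat_pops]
    group_of_pop = [gi for gi, g in enumerate(group_pops) for _ in g]
    all_idx = np.concatenate(flat_pops)

    for _ in range(permutations):
        # F_ST: individuals among populations, whole data
        perm = rng.permutation(all_idx)
        new_pops, pos = [], 0
        for ln in pop_lengths:
            new_pops.append(perm[pos : pos + ln])
            pos += ln
        gp = [[] for _ in groups]  # type: list[list[np.ndarray]]
        for pop, gi in zip(new_pops, group_of_pop):
            gp[gi].append(pop)
        _, _, s = _three_level_components(d2, gp)
        stat = _amova_indices(s)[2]
        if math.isfinite(f_st) and math.isfinite(stat) and stat >= f_st - 1e-12:
            hits_st += 1

        # F_SC: individuals among populations within each group
        gp2 = []
        for g in group_pops:
            gi_all = np.concatenate(g)
            perm_g = rng.permutation(gi_all)
            new_g, pos = [], 0
            for p in g:
                new_g.append(perm_g[pos : pos + len(p)])
                pos += len(p)
            gp2.append(new_g)
        _, _, s = _three_level_components(d2, gp2)
        stat = _amova_indices(s)[1]
        if math.isfinite(f_sc) and math.isfinite(stat) and stat >= f_sc - 1e-12:
            hits_sc += 1

        # F_CT: whole populations among groups
        order = rng.permutation(len(flat_pops))
        gp3, pos = [], 0
        for sz in pop_sizes_per_group:
            gp3.append([flat_pops[o] for o in order[pos : pos + sz]])
            pos += sz
        _, _, s = _three_level_components(d2, gp3)
        stat = _amova_indices(s)[0]
        if math.isfinite(f_ct) and math.isfinite(stat) and stat >= f_ct - 1e-12:
            hits_ct += 1

    def pval(hits: int, obs: float) -> float:
        return (hits + 1) / (permutations + 1) if math.isfinite(obs) else NA

    return AmovaResult(
        ss=ss,
        df=df,
        sigma2=sig,
        percent=percent,  # type: ignore[arg-type]
        f_ct=f_ct,
        f_sc=f_sc,
        f_st=f_st,
        p_ct=pval(hits_ct, f_ct),
        p_sc=pval(hits_sc, f_sc),
        p_st=pval(hits_st, f_st),
        permutations=permutations,
        n_distinct_group_permutations=n_distinct,
        flags=frozenset(flags),
    )


# ---------------------------------------------------------------------------
# Per-population summary
# ---------------------------------------------------------------------------

def summarize(
    aln: SequenceAlignment,
    policy: Literal["complete-deletion", "pairwise-ignore"] = "complete-deletion",
) -> SummaryStatistics:
    """Compute the full per-sample-set summary vector (the Table-2 row set).

    Statistics undefined for the input (single haplotype, S = 0, n < 2) are
    set to ``nan`` and recorded in ``na_flags``, mirroring the "n. a."
    reporting convention.
    """
    n = aln.n_samples
    flags: set[str] = set()
    S, L_eff = segregating_sites(aln, policy)
    if n < 2:
        return SummaryStatistics(
            n, L_eff, S, NA, NA, NA, NA, NA, 1, NA, NA,
            frozenset({"k", "pi", "Hd", "D", "FS"}),
        )
    k, pi = nucleotide_diversity(aln, policy)
    table = collapse_haplotypes(aln, policy)
    hd, sd_hd = haplotype_diversity(table)
    if table.k_obs == 1:
        flags |= {"Hd", "FS"}
    d = tajimas_d(n, S, k)
    if not math.isfinite(d):  # S = 0, or n <= 3 where the variance is zero
        flags |= {"D"}
    fs = fus_fs(n, k, table.k_obs)
    if math.isnan(fs):  # undefined (K_obs = 1 or k = 0); signed inf is kept
        flags |= {"FS"}
    # Nei's total variance of per-site diversity (drift + sampling terms).
    if L_eff > 0:
        var_pi = (n + 1) / (3.0 * (n - 1) * L_eff) * pi + (
            2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
        ) * pi * pi
        sd_pi = math.sqrt(max(var_pi, 0.0))
    else:
        sd_pi = NA
    return SummaryStatistics(
        n, L_eff, S, k, pi, sd_pi, hd, sd_hd, table.k_obs, d, fs, frozenset(flags)
    )
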