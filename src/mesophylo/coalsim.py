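"""Multi-population coalescent simulator with finite-sites HKY mutation.

The engine executes an event-list demographic model (population splits,
size changes, admixture pulses, all specified past-ward in generations) under
the standard continuous-time coalescent, then drops mutations on the
genealogy under an HKY substitution model via uniformization, yielding a
:class:`~mesophylo.popdata.SequenceAlignment`.

Scaling conventions (haploid mtDNA throughout)
----------------------------------------------
* Within a population of haploid effective size N the total coalescence rate
  with j active lineages is C(j,2)/(2N) per generation, so a pair coalesces
  after 2N generations on average.
* With per-site mutation rate u per generation, θ = 4Nu per site; a neutral
  sample then satisfies E[S] = θ_locus·a1(n) and E[k] = θ_locus with
  θ_locus = 4NuL.  This is the same timescale in which divergence times in
  units of 4N_AVE generations are expressed downstream.
* Rates quoted per year are converted to per generation with the generation
  time g (default 2 years) before entering the simulator.

No recombination (mtDNA) and no continuous migration; admixture events cover
pulse-like gene flow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import yaml

from .popdata import BASES, PopulationAssignment, SequenceAlignment

__all__ = [
    "Split",
    "SizeChange",
    "Admixture",
    "DemographicScenario",
    "MutationModel",
    "Genealogy",
    "SimulatedDataset",
    "ScenarioError",
    "simulate_genealogy",
    "mutate_hky",
    "simulate_dataset",
    "simulate_infinite_sites_stats",
    "load_scenario",
    "theta_from",
    "effective_size_from_theta",
]

Param = Union[float, str]


class ScenarioError(ValueError):
    """Malformed demographic scenario (unknown population, bad event order...)."""


@dataclass(frozen=True)
class Split:
    """Past-ward merge of ``children`` populations into ``ancestor`` at ``time``."""

    time: Param
    children: tuple[str, ...]
    ancestor: str
    ancestor_size: Param | None = None


@dataclass(frozen=True)
class SizeChange:
    time: Param
    population: str
    size: Param


@dataclass(frozen=True)
class Admixture:
    """At ``time`` (past-ward) each lineage in ``target`` moves to
    ``sources[0]`` with probability ``proportion``, else ``sources[1]``."""

    time: Param
    target: str
    sources: tuple[str, str]
    proportion: Param


Event = Union[Split, SizeChange, Admixture]


@dataclass(frozen=True)
class DemographicScenario:
    """Leaf populations, sizes, and an ordered past-ward event list.

    Numeric fields may be parameter names (strings) resolved against a draw
    with :meth:`resolve`; a fully numeric scenario validates structurally on
    construction via :meth:`validate`.
    """

    name: str
    samples: Mapping[str, int]
    sizes: Mapping[str, Param]
    events: tuple[Event, ...] = ()

    def resolve(self, params: Mapping[str, float]) -> "DemographicScenario":
        """Substitute parameter names with values from ``params``."""

        def val(x: Param) -> float:
            if isinstance(x, str):
                if x not in params:
                    raise ScenarioError(f"unresolved parameter '{x}'")
                return float(params[x])
            return float(x)

        events: list[Event] = []
        for ev in self.events:
            if isinstance(ev, Split):
                events.append(
                    replace(
                        ev,
                        time=val(ev.time),
                        ancestor_size=(
                            None if ev.ancestor_size is None else val(ev.ancestor_size)
                        ),
                    )
                )
            elif isinstance(ev, SizeChange):
                events.append(replace(ev, time=val(ev.time), size=val(ev.size)))
            else:
                events.append(
                    replace(ev, time=val(ev.time), proportion=val(ev.proportion))
                )
        sizes = {p: val(s) for p, s in self.sizes.items()}
        out = DemographicScenario(self.name, dict(self.samples), sizes, tuple(events))
        out.validate()
        return out

    def is_concrete(self) -> bool:
        if any(isinstance(s, str) for s in self.sizes.values()):
            return False
        for ev in self.events:
            vals = [ev.time]
            if isinstance(ev, Split) and ev.ancestor_size is not None:
                vals.append(ev.ancestor_size)
            if isinstance(ev, SizeChange):
                vals.append(ev.size)
            if isinstance(ev, Admixture):
                vals.append(ev.proportion)
            if any(isinstance(v, str) for v in vals):
                return False
        return True

    def validate(self) -> None:
        """Structural validation of a concrete scenario.

        Checks non-decreasing past-ward event times, that every referenced
        population exists at its event's time, and that exactly one
        population remains after the final event.
        """
        if not self.is_concrete():
            raise ScenarioError("scenario has unresolved parameters")
        if not self.samples:
            raise ScenarioError("scenario has no sampled populations")
        for p, n in self.samples.items():
            if n < 1:
                raise ScenarioError(f"population '{p}' has sample size {n} < 1")
            if p not in self.sizes:
                raise ScenarioError(f"no effective size for population '{p}'")
        for p, s in self.sizes.items():
            if float(s) <= 0:
                raise ScenarioError(f"non-positive size for population '{p}'")
        alive = set(self.samples)
        last_t = 0.0
        for ev in self.events:
            t = float(ev.time)  # type: ignore[arg-type]
            if t < last_t - 1e-12:
                raise ScenarioError(
                    f"event times must be non-decreasing past-ward "
                    f"(got {t} after {last_t})"
                )
            last_t = t
            if isinstance(ev, Split):
                for c in ev.children:
                    if c not in alive:
                        raise ScenarioError(
                            f"split at t={t} references population '{c}' "
                            f"not alive at that time"
                        )
                alive -= set(ev.children)
                alive.add(ev.ancestor)
            elif isinstance(ev, SizeChange):
                if ev.population not in alive:
                    raise ScenarioError(
                        f"size change at t={t} references dead population "
                        f"'{ev.population}'"
                    )
            else:
                r = float(ev.proportion)  # type: ignore[arg-type]
                if not (0.0 <= r <= 1.0):
                    raise ScenarioError(f"admixture proportion {r} outside [0, 1]")
                if ev.target not in alive:
                    raise ScenarioError(
                        f"admixture at t={t} references dead population "
                        f"'{ev.target}'"
                    )
                # sources may be populations that only exist past-ward of the
                # event (the target's ancestral continuation); they come alive
                # here and must have a declared size
                for p in ev.sources:
                    if p not in alive and p not in self.sizes:
                        raise ScenarioError(
                            f"admixture source '{p}' has no effective size"
                        )
                alive.discard(ev.target)
                alive.update(ev.sources)
        if len(alive) != 1:
            raise ScenarioError(
                f"after the final event {len(alive)} populations remain "
                f"({sorted(alive)}); exactly one is required"
            )


@dataclass(frozen=True)
class MutationModel:
    """HKY substitution model: κ, base frequencies, per-site rate u/generation."""

    kappa: float = 4.0
    frequencies: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    u: float = 1e-8

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.u < 0:
            raise ValueError("mutation rate must be non-negative")
        if abs(sum(self.frequencies) - 1.0) > 1e-8:
            raise ValueError("base frequencies must sum to 1")

    def rate_matrix(self) -> np.ndarray:
        """HKY generator Q (order A,C,G,T) scaled to mean rate u per site."""
        pi = np.asarray(self.frequencies)
        transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
        q = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                q[i, j] = pi[j] * (self.kappa if (i, j) in transitions else 1.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mean_rate = float(-(pi * np.diag(q)).sum())
        if mean_rate > 0 and self.u > 0:
            q *= self.u / mean_rate
        elif self.u == 0:
            q[:] = 0.0
        return q


@dataclass(frozen=True)
class Genealogy:
    """Binary coalescent tree: node i < n_leaves is a tip.

    ``parent[i]`` is −1 for the root; ``time`` is node age in generations
    (tips at 0).  ``leaf_population[i]`` names the sampled population of tip
    i; tips are ordered population-block-wise in scenario order.
    """

    n_leaves: int
    parent: np.ndarray
    time: np.ndarray
    leaf_population: tuple[str, ...]

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node (0 for the root)."""
        out = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        out[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return out

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())


@dataclass(frozen=True)
class SimulatedDataset:
    alignment: SequenceAlignment
    assignment: PopulationAssignment
    scenario_name: str
    params: dict[str, float]
    seed: int | None = None


def theta_from(n_eff: float, u: float) -> float:
    """θ = 4Nu per site (haploid N, pairwise coalescence over 2N generations)."""
    return 4.0 * n_eff * u


def effective_size_from_theta(theta: float, u: float) -> float:
    return theta / (4.0 * u)


# ---------------------------------------------------------------------------
# Genealogy simulation
# ---------------------------------------------------------------------------

def simulate_genealogy(
    scenario: DemographicScenario, rng: np.random.Generator
) -> Genealogy:
    """Simulate a coalescent genealogy under a concrete scenario.

    Within each population with j lineages and current size N, coalescences
    occur at rate C(j,2)/(2N) per generation; splits merge lineage pools;
    admixture assigns each lineage of the target independently to one of the
    two sources.  Returns a fully coalesced binary tree.
    """
    scenario.validate()
    pops = list(scenario.samples)
    n_total = int(sum(scenario.samples.values()))
    n_nodes = 2 * n_total - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    times = np.zeros(n_nodes)
    leaf_population: list[str] = []
    active: dict[str, list[int]] = {}
    node = 0
    for p in pops:
        ids = list(range(node, node + scenario.samples[p]))
        node += scenario.samples[p]
        active[p] = ids
        leaf_population.extend([p] * scenario.samples[p])
    next_internal = n_total
    sizes = {p: float(s) for p, s in scenario.sizes.items()}

    t = 0.0
    events = list(scenario.events) + [None]  # sentinel: open-ended final epoch
    for ev in events:
        t_end = math.inf if ev is None else float(ev.time)  # type: ignore[union-attr]
        while True:
            rates = {
                p: len(l) * (len(l) - 1) / 2.0 / (2.0 * sizes[p])
                for p, l in active.items()
                if len(l) >= 2
            }
            total_rate = sum(rates.values())
            if total_rate == 0.0:
                break
            wait = rng.exponential(1.0 / total_rate)
            if t + wait >= t_end:
                break
            t += wait
            r = rng.random() * total_rate
            acc = 0.0
            chosen = next(iter(rates))
            for p, rate in rates.items():
                acc += rate
                if r < acc:
                    chosen = p
                    break
            lineages = active[chosen]
            i, j = rng.choice(len(lineages), size=2, replace=False)
            a, b = lineages[int(i)], lineages[int(j)]
            parent[a] = parent[b] = next_internal
            times[next_internal] = t
            lineages[:] = [x for x in lineages if x not in (a, b)] + [next_internal]
            next_internal += 1
        if ev is None:
            break
        t = t_end
        if isinstance(ev, Split):
            pool: list[int] = []
            for c in ev.children:
                pool.extend(active.pop(c, []))
            active[ev.ancestor] = active.get(ev.ancestor, []) + pool
            if ev.ancestor_size is not None:
                sizes[ev.ancestor] = float(ev.ancestor_size)  # type: ignore[arg-type]
            elif ev.ancestor not in sizes:
                # default: ancestral size carries over from the first child
                sizes[ev.ancestor] = float(sizes[ev.children[0]])
        elif isinstance(ev, SizeChange):
            sizes[ev.population] = float(ev.size)  # type: ignore[arg-type]
        else:
            r_prop = float(ev.proportion)  # type: ignore[arg-type]
            src_a, src_b = ev.sources
            active.setdefault(src_a, [])
            active.setdefault(src_b, [])
            for lineage in active.pop(ev.target, []):
                dest = src_a if rng.random() < r_prop else src_b
                active[dest].append(lineage)

    remaining = [l for ls in active.values() for l in ls]
    if len(remaining) != 1 or next_internal != n_nodes:
        raise ScenarioError("genealogy failed to fully coalesce (internal error)")
    return Genealogy(n_total, parent, times, tuple(leaf_population))


# ---------------------------------------------------------------------------
# Mutation
# ---------------------------------------------------------------------------

def mutate_hky(
    genealogy: Genealogy,
    model: MutationModel,
    L: int,
    rng: np.random.Generator,
    sample_ids: Sequence[str] | None = None,
) -> SequenceAlignment:
    """Evolve an L-site sequence down the genealogy under HKY.

    The root sequence is drawn from the stationary frequencies; substitution
    events are placed along branches by uniformization of the HKY generator
    (a Poisson number of candidate events at the dominating rate, each
    applying the one-step jump matrix), which reproduces the exact
    finite-sites process including multiple hits.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    q = model.rate_matrix()
    lam = float(np.max(-np.diag(q)))
    n_nodes = genealogy.n_nodes
    root = int(np.flatnonzero(genealogy.parent < 0)[0])
    seqs = np.empty((n_nodes, L), dtype=np.int8)
    seqs[root] = rng.choice(4, size=L, p=np.asarray(model.frequencies))
    if lam > 0.0:
        b = np.eye(4) + q / lam
        cum_b = np.cumsum(b, axis=1)
        cum_b[:, -1] = 1.0
    order = np.argsort(-genealogy.time, kind="stable")  # root first
    blen = genealogy.branch_lengths()
    for node in order:
        node = int(node)
        if node == root:
            continue
        seq = seqs[genealogy.parent[node]].copy()
        if lam > 0.0:
            n_ev = rng.poisson(lam * blen[node] * L)
            if n_ev:
                sites = rng.integers(0, L, size=n_ev)
                draws = rng.random(n_ev)
                for s, d in zip(sites, draws):
                    seq[s] = np.searchsorted(cum_b[seq[s]], d, side="right")
        seqs[node] = seq
    base = np.array(BASES, dtype="U1")
    tips = base[seqs[: genealogy.n_leaves]]
    if sample_ids is None:
        counters: dict[str, int] = {}
        sample_ids = []
        for p in genealogy.leaf_population:
            counters[p] = counters.get(p, 0) + 1
            sample_ids.append(f"{p}_{counters[p]}")
    return SequenceAlignment(tuple(sample_ids), tips)


def simulate_dataset(
    scenario: DemographicScenario,
    params: Mapping[str, float],
    model: MutationModel,
    L: int,
    rng: np.random.Generator,
) -> SimulatedDataset:
    """One genealogy + mutation realisation of a (possibly templated) scenario."""
    concrete = scenario.resolve(params) if not scenario.is_concrete() else scenario
    gen = simulate_genealogy(concrete, rng)
    aln = mutate_hky(gen, model, L, rng)
    pop_of = {
        sid: pop for sid, pop in zip(aln.sample_ids, gen.leaf_population)
    }
    assign = PopulationAssignment(pop_of, {p: p for p in concrete.samples})
    return SimulatedDataset(aln, assign, scenario.name, dict(params))


# ---------------------------------------------------------------------------
# Fast neutral null (infinite sites) for neutrality-test significance
# ---------------------------------------------------------------------------

def simulate_infinite_sites_stats(
    n: int, theta: float, rng: np.random.Generator
) -> tuple[int, float, int]:
    """(S, k, K_obs) for one neutral constant-size coalescent replicate.

    Time is scaled so a lineage pair coalesces at rate 1; mutations fall on
    branches at rate θ/2 per unit time under the infinite-sites model, giving
    E[S] = θ·a1(n) and E[k] = θ.  Used as the simulation null for Tajima's D
    and Fu's FS significance.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    # Kingman topology with exponential epoch lengths.
    lineages = [1 << i for i in range(n)]  # leaf bitmasks
    s_total = 0
    k_sum = 0.0
    muts_per_leafset: list[tuple[int, int]] = []  # (bitmask, count)
    j = n
    while j > 1:
        epoch = rng.exponential(1.0 / (j * (j - 1) / 2.0))
        # each of the j branches carries Poisson(theta/2 * epoch) mutations
        if theta > 0:
            counts = rng.poisson(theta / 2.0 * epoch, size=j)
            for idx in np.flatnonzero(counts):
                muts_per_leafset.append((lineages[int(idx)], int(counts[int(idx)])))
                s_total += int(counts[int(idx)])
        a, b = rng.choice(j, size=2, replace=False)
        a, b = int(a), int(b)
        merged = lineages[a] | lineages[b]
        lineages = [x for t, x in enumerate(lineages) if t not in (a, b)]
        lineages.append(merged)
        j -= 1
    n_pairs = n * (n - 1) / 2.0
    hap_keys: dict[int, list[int]] = {i: [] for i in range(n)}
    for mut_id, (mask, count) in enumerate(muts_per_leafset):
        c = bin(mask).count("1")
        k_sum += count * c * (n - c)
        for leaf in range(n):
            if mask >> leaf & 1:
                hap_keys[leaf].append(mut_id * 10_000 + count)
    k = k_sum / n_pairs
    k_obs = len({tuple(v) for v in hap_keys.values()})
    return s_total, k, k_obs


# ---------------------------------------------------------------------------
# YAML scenario files
# ---------------------------------------------------------------------------

def scenario_from_dict(d: Mapping) -> DemographicScenario:
    events: list[Event] = []
    for ev in d.get("events", []):
        kind = ev["kind"]
        if kind == "split":
            events.append(
                Split(
                    ev["time"],
                    tuple(ev["children"]),
                    ev["ancestor"],
                    ev.get("ancestor_size"),
                )
            )
        elif kind == "size_change":
            events.append(SizeChange(ev["time"], ev["population"], ev["size"]))
        elif kind == "admixture":
            events.append(
                Admixture(
                    ev["time"], ev["target"], tuple(ev["sources"]), ev["proportion"]
                )
            )
        else:
            raise ScenarioError(f"unknown event kind '{kind}'")
    return DemographicScenario(
        d.get("name", "scenario"),
        dict(d["samples"]),
        dict(d["sizes"]),
        tuple(events),
    )


def load_scenario(path: str | Path) -> DemographicScenario:
    """Load a demographic scenario from a YAML file."""
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))
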