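"""Synthetic datasets emulating four co-distributed Mesoamerican bird taxa.

The built-in templates reproduce the sampling design of a comparative
mtDNA phylogeography study of montane birds (toucanets, bush-tanagers,
warblers and hummingbirds spanning the Sierra Madre del Sur and Central
America): 4 taxa, 2–6 geographic groups each, per-group sample sizes
(5,42,14,2 | 20,8,6,4,10,5 | 8,11,4,1 | 3,7,10,5,2) summing to 167
sequences, ~600–1100 bp mtDNA loci, and nested northward-colonisation
divergence scenarios with split times of 0.2–5.9 Myr.  Every generated
dataset carries a :class:`SyntheticTruth` record sufficient to regenerate
it bit-identically, so each pipeline stage can be tested against known
ground truth without any sequence download.

Effective sizes default to values yielding θ per site around 0.004
(matching the observed nucleotide-diversity magnitudes, 0.0004–0.0095);
they are a reconstruction, not an estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .coalsim import (
    DemographicScenario,
    MutationModel,
    Split,
    SizeChange,
    simulate_genealogy,
    mutate_hky,
)
from .popdata import PopulationAssignment, SequenceAlignment, write_alignment, write_popmap

__all__ = [
    "StudyTemplate",
    "SyntheticTruth",
    "TEMPLATES",
    "study_template",
    "generate_study",
    "generate_pairs",
]

#: Default generation time (years) used to turn template times in years
#: into generations.
GENERATION_TIME = 2.0

#: Default haploid effective size: with u = 4e-8 per site per generation
#: (2e-8 per year at g = 2) this gives θ = 4Nu = 0.004 per site.
DEFAULT_N = 25_000.0
DEFAULT_U = 4e-8


@dataclass(frozen=True)
class StudyTemplate:
    """Per-taxon group layout, sample sizes and default divergence scenario."""

    name: str
    groups: tuple[str, ...]
    sizes: tuple[int, ...]
    scenario: DemographicScenario
    L: int = 1000
    model: MutationModel = field(
        default_factory=lambda: MutationModel(kappa=6.0, u=DEFAULT_U)
    )


@dataclass(frozen=True)
class SyntheticTruth:
    """Everything needed to regenerate a synthetic dataset bit-identically."""

    template: str
    seed: int
    params: dict[str, float]
    pair_taus: tuple[float, ...] = ()


def _years(y: float) -> float:
    return y / GENERATION_TIME


def _template_aulacorhynchus() -> StudyTemplate:
    groups = ("SMS", "EMx-NCA", "CR-NP", "SP")
    sizes = (8, 11, 4, 1)
    scen = DemographicScenario(
        "aulacorhynchus-northward",
        dict(zip(groups, sizes)),
        {g: DEFAULT_N for g in groups},
        (
            Split(_years(1_328_000), ("SMS", "EMx-NCA"), "anc_mx", DEFAULT_N),
            Split(_years(2_860_000), ("anc_mx", "CR-NP"), "anc_n", DEFAULT_N),
            Split(_years(4_340_000), ("anc_n", "SP"), "root", DEFAULT_N),
        ),
    )
    return StudyTemplate("aulacorhynchus", groups, sizes, scen, L=1100)


def _template_chlorospingus() -> StudyTemplate:
    groups = ("SMO", "SMS", "TuxtlasMassif", "NChiapas", "NCA", "SCA")
    sizes = (20, 8, 6, 4, 10, 5)
    scen = DemographicScenario(
        "chlorospingus-northward",
        dict(zip(groups, sizes)),
        {g: DEFAULT_N for g in groups},
        (
            Split(_years(1_308_000), ("NCA", "SCA"), "anc_ca", DEFAULT_N),
            Split(_years(2_060_000), ("SMS", "SMO"), "anc_mxw", DEFAULT_N),
            Split(_years(2_840_000), ("anc_mxw", "TuxtlasMassif"), "anc_mxc", DEFAULT_N),
            Split(_years(3_900_000), ("anc_mxc", "NChiapas"), "anc_mx", DEFAULT_N),
            Split(_years(5_860_000), ("anc_mx", "anc_ca"), "root", DEFAULT_N),
        ),
    )
    return StudyTemplate("chlorospingus", groups, sizes, scen, L=900)


def _template_cardellina() -> StudyTemplate:
    groups = ("Cversicolor", "TMVB", "SMS", "SMOc")
    sizes = (5, 42, 14, 2)
    scen = DemographicScenario(
        "cardellina-northward",
        dict(zip(groups, sizes)),
        {g: DEFAULT_N for g in groups},
        (
            SizeChange(_years(40_200), "TMVB", DEFAULT_N * 2),
            Split(_years(260_000), ("TMVB", "SMS"), "anc_c", DEFAULT_N),
            Split(_years(426_000), ("anc_c", "SMOc"), "anc_mx", DEFAULT_N),
            Split(_years(1_304_000), ("anc_mx", "Cversicolor"), "root", DEFAULT_N),
        ),
    )
    return StudyTemplate("cardellina", groups, sizes, scen, L=700)


def _template_eupherusa() -> StudyTemplate:
    groups = ("Tridgwayi", "eximia", "poliocerca", "cyanophrys", "nigriventris")
    sizes = (3, 7, 10, 5, 2)
    scen = DemographicScenario(
        "eupherusa-with-thalurania",
        dict(zip(groups, sizes)),
        {g: DEFAULT_N for g in groups},
        (
            Split(_years(716_000), ("poliocerca", "cyanophrys"), "anc_sms", DEFAULT_N),
            Split(_years(1_346_000), ("eximia", "nigriventris"), "anc_emx", DEFAULT_N),
            Split(_years(1_804_000), ("anc_sms", "anc_emx"), "anc_eu", DEFAULT_N),
            Split(_years(2_780_000), ("anc_eu", "Tridgwayi"), "root", DEFAULT_N),
        ),
    )
    return StudyTemplate("eupherusa", groups, sizes, scen, L=600)


TEMPLATES = {
    "aulacorhynchus": _template_aulacorhynchus,
    "chlorospingus": _template_chlorospingus,
    "cardellina": _template_cardellina,
    "eupherusa": _template_eupherusa,
}


def study_template(name: str) -> StudyTemplate:
    try:
        return TEMPLATES[name]()
    except KeyError:
        raise KeyError(
            f"unknown template '{name}'; choose from {sorted(TEMPLATES)}"
        ) from None


def generate_study(
    template: StudyTemplate,
    seed: int,
    out_dir: str | Path | None = None,
) -> tuple[SequenceAlignment, PopulationAssignment, SyntheticTruth]:
    """Generate one synthetic taxon dataset with the template's group sizes.

    Returns the alignment, the population assignment (one population per
    group) and a truth record; with ``out_dir`` the FASTA, popmap TSV and a
    truth summary are also written.
    """
    rng = np.random.default_rng(seed)
    gen = simulate_genealogy(template.scenario, rng)
    aln = mutate_hky(gen, template.model, template.L, rng)
    pop_of = {s: p for s, p in zip(aln.sample_ids, gen.leaf_population)}
    assign = PopulationAssignment(pop_of, {g: g for g in template.groups})
    params = {
        f"t_{ev.ancestor}": float(ev.time)
        for ev in template.scenario.events
        if isinstance(ev, Split)
    }
    truth = SyntheticTruth(template.name, seed, params)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_alignment(aln, out / f"{template.name}.fasta")
        write_popmap(assign, out / f"{template.name}.popmap.tsv")
        with open(out / f"{template.name}.truth.tsv", "w") as fh:
            fh.write("key\tvalue\n")
            fh.write(f"template\t{truth.template}\n")
            fh.write(f"seed\t{truth.seed}\n")
            for k, v in truth.params.items():
                fh.write(f"{k}\t{v}\n")
    return aln, assign, truth


def generate_pairs(
    taus: Sequence[float],
    thetas: Sequence[float],
    L: int,
    seed: int,
    n_per_pop: int = 5,
    theta_ave: float | None = None,
    u: float = DEFAULT_U,
    kappa: float = 6.0,
    out_dir: str | Path | None = None,
) -> tuple[list[tuple[SequenceAlignment, SequenceAlignment]], SyntheticTruth]:
    """Independent two-population datasets at given divergence times.

    ``taus`` are divergence times in coalescent units of 4·N_AVE
    generations (N_AVE from ``theta_ave``, default the mean of ``thetas``);
    ``thetas`` are per-site θ of each pair's populations.  The co-divergence
    acceptance experiments are built on this generator.
    """
    if len(taus) != len(thetas):
        raise ValueError("taus and thetas must have equal length")
    rng = np.random.default_rng(seed)
    t_ave = float(np.mean(thetas)) if theta_ave is None else theta_ave
    pairs: list[tuple[SequenceAlignment, SequenceAlignment]] = []
    for i, (tau, theta) in enumerate(zip(taus, thetas)):
        n_eff = theta / (4.0 * u)
        t_gen = tau * t_ave / u
        scen = DemographicScenario(
            f"pair{i}",
            {"pop1": n_per_pop, "pop2": n_per_pop},
            {"pop1": n_eff, "pop2": n_eff},
            (Split(t_gen, ("pop1", "pop2"), "anc", n_eff),),
        )
        gen = simulate_genealogy(scen, rng)
        aln = mutate_hky(gen, MutationModel(kappa=kappa, u=u), L, rng)
        half = n_per_pop
        a1 = aln.subset(list(aln.sample_ids[:half]))
        a2 = aln.subset(list(aln.sample_ids[half:]))
        pairs.append((a1, a2))
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            write_alignment(a1, out / f"pair{i}_pop1.fasta")
            write_alignment(a2, out / f"pair{i}_pop2.fasta")
    truth = SyntheticTruth("pairs", seed, {f"theta_{i}": float(t) for i, t in enumerate(thetas)}, tuple(float(t) for t in taus))
    return pairs, truth
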