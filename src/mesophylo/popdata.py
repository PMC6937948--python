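"""Aligned-sequence data model, population maps, and haplotype collapsing.

Everything downstream (diversity statistics, AMOVA, the ABC modules) consumes
the three containers defined here:

* :class:`SequenceAlignment` — an n × L matrix of nucleotide symbols with
  stable sample identifiers and optional per-locus column blocks.
* :class:`PopulationAssignment` — the two-level sample → population → group
  hierarchy that AMOVA and the pairwise fixation indices operate on.  The
  number of groups K is always an *input* (e.g. from a prior clustering
  analysis), never inferred here.
* :class:`HaplotypeTable` — distinct haplotypes with multiplicities, the unit
  on which haplotype diversity and Fu's FS are defined.

Coordinates are 0-based half-open internally; user-facing reports are
1-based inclusive.  Sequences are used as given (curated alignments); no
reverse-complement detection is attempted.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceAlignment",
    "PopulationAssignment",
    "HaplotypeTable",
    "AlignmentError",
    "PopmapError",
    "read_alignment",
    "write_alignment",
    "read_popmap",
    "concatenate_loci",
    "collapse_haplotypes",
]

#: Unambiguous nucleotide states.
BASES = ("A", "C", "G", "T")

#: Symbols treated as missing data for haplotype identity and distances.
#: IUPAC ambiguity codes are deliberately included: resolving them would
#: invent alleles.
MISSING = frozenset("-?NRYSWKMBDHV")

_VALID = frozenset(BASES) | MISSING


class AlignmentError(ValueError):
    """Malformed alignment input (ragged lengths, duplicate ids, bad symbols)."""


class PopmapError(ValueError):
    """Malformed or incomplete population map."""


@dataclass(frozen=True)
class SequenceAlignment:
    """Matrix of aligned nucleotide symbols with named rows.

    Parameters
    ----------
    sample_ids
        Ordered, unique sequence labels (n of them).
    matrix
        ``(n, L)`` array of single-character unicode symbols, upper case.
    locus_bounds
        Optional ordered list of half-open ``(start, stop)`` column intervals
        labelling loci; must tile ``[0, L)`` without overlap when present.
    """

    sample_ids: tuple[str, ...]
    matrix: np.ndarray
    locus_bounds: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2:
            raise AlignmentError("sequence matrix must be 2-dimensional")
        if len(self.sample_ids) != self.matrix.shape[0]:
            raise AlignmentError(
                f"{len(self.sample_ids)} sample ids but {self.matrix.shape[0]} rows"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise AlignmentError(f"duplicate sample ids: {dupes}")
        bad = set(np.unique(self.matrix)) - _VALID
        if bad:
            raise AlignmentError(f"invalid symbols in alignment: {sorted(bad)}")
        if self.locus_bounds is not None:
            pos = 0
            for start, stop in self.locus_bounds:
                if start != pos or stop <= start:
                    raise AlignmentError(
                        f"locus_bounds must tile [0, {self.n_sites}) without "
                        f"overlap; offending interval ({start}, {stop})"
                    )
                pos = stop
            if pos != self.matrix.shape[1]:
                raise AlignmentError("locus_bounds do not cover the alignment")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def row(self, sample_id: str) -> np.ndarray:
        return self.matrix[self.sample_ids.index(sample_id)]

    def subset(self, sample_ids: Sequence[str]) -> "SequenceAlignment":
        """Rows restricted to ``sample_ids``, in the given order."""
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return SequenceAlignment(tuple(sample_ids), self.matrix[idx], self.locus_bounds)

    @classmethod
    def from_strings(
        cls,
        records: Iterable[tuple[str, str]],
        locus_bounds: Sequence[tuple[int, int]] | None = None,
    ) -> "SequenceAlignment":
        """Build from ``(id, sequence)`` pairs; symbols upper-cased, U→T."""
        ids: list[str] = []
        rows: list[np.ndarray] = []
        length: int | None = None
        for name, seq in records:
            seq = seq.upper().replace("U", "T")
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise AlignmentError(
                    f"length mismatch: record '{name}' has {len(seq)} columns, "
                    f"expected {length}"
                )
            ids.append(name)
            rows.append(np.frombuffer(seq.encode(), dtype="S1").astype("U1"))
        if not ids:
            raise AlignmentError("empty alignment")
        bounds = tuple(tuple(b) for b in locus_bounds) if locus_bounds else None
        return cls(tuple(ids), np.vstack(rows), bounds)

    def to_strings(self) -> list[tuple[str, str]]:
        return [
            (sid, "".join(row)) for sid, row in zip(self.sample_ids, self.matrix)
        ]


@dataclass(frozen=True)
class PopulationAssignment:
    """Two-level sample → population → group hierarchy.

    ``group_of`` must cover every population appearing in ``population_of``;
    K (the number of groups) is whatever the caller supplies.
    """

    population_of: dict[str, str]
    group_of: dict[str, str]
    coordinates: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.population_of.values()) - set(self.group_of)
        if missing:
            raise PopmapError(f"populations without a group: {sorted(missing)}")

    @property
    def populations(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for p in self.population_of.values():
            seen.setdefault(p)
        return tuple(seen)

    @property
    def groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(self.group_of[p])
        return tuple(seen)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def samples_in_population(self, population: str) -> tuple[str, ...]:
        return tuple(s for s, p in self.population_of.items() if p == population)

    def populations_in_group(self, group: str) -> tuple[str, ...]:
        return tuple(p for p in self.populations if self.group_of[p] == group)

    def samples_in_group(self, group: str) -> tuple[str, ...]:
        return tuple(
            s
            for s, p in self.population_of.items()
            if self.group_of[p] == group
        )

    def validate_against(self, aln: SequenceAlignment) -> None:
        """Raise :class:`PopmapError` listing alignment samples not assigned."""
        unassigned = [s for s in aln.sample_ids if s not in self.population_of]
        if unassigned:
            raise PopmapError(
                f"alignment samples missing from population map: {unassigned}"
            )


@dataclass(frozen=True)
class HaplotypeTable:
    """Distinct haplotypes with multiplicities.

    ``policy`` records how missing/ambiguous sites were treated when deciding
    haplotype identity, so the table is self-describing.
    """

    haplotypes: tuple[str, ...]
    counts: tuple[int, ...]
    policy: str

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.counts):
            raise ValueError("haplotype counts must be >= 1")
        if len(self.haplotypes) != len(self.counts):
            raise ValueError("haplotypes and counts differ in length")
        if len(set(self.haplotypes)) != len(self.haplotypes):
            raise ValueError("haplotypes not pairwise distinct")

    @property
    def n(self) -> int:
        return int(sum(self.counts))

    @property
    def k_obs(self) -> int:
        """Number of distinct haplotypes observed."""
        return len(self.haplotypes)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_alignment(path: str | Path | io.TextIOBase) -> SequenceAlignment:
    """Read a FASTA alignment.

    Record order is preserved, symbols are upper-cased and U is mapped to T.
    Ragged lengths raise :class:`AlignmentError` naming the offending record;
    duplicate ids raise as well.
    """
    handle = open(path) if isinstance(path, (str, Path)) else path
    try:
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]
    finally:
        if isinstance(path, (str, Path)):
            handle.close()
    return SequenceAlignment.from_strings(records)


def write_alignment(aln: SequenceAlignment, path: str | Path | io.TextIOBase) -> None:
    """Write FASTA; round trips through :func:`read_alignment` byte-stably."""
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in aln.to_strings()
    ]
    if isinstance(path, (str, Path)):
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta-2line")
    else:
        SeqIO.write(records, path, "fasta-2line")


def read_popmap(path: str | Path | io.TextIOBase) -> PopulationAssignment:
    """Read a population map TSV.

    Columns: ``sample_id``, ``population``, optional ``group`` (defaults to
    the population), optional ``lat`` and ``lon``.  A header line is accepted
    and detected by its first field being ``sample_id``.
    """
    handle = open(path) if isinstance(path, (str, Path)) else path
    try:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip()]
    finally:
        if isinstance(path, (str, Path)):
            handle.close()
    if lines and lines[0].split("\t")[0] == "sample_id":
        lines = lines[1:]
    population_of: dict[str, str] = {}
    group_of: dict[str, str] = {}
    coords: dict[str, tuple[float, float]] = {}
    for lineno, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if len(fields) < 2:
            raise PopmapError(f"line {lineno}: need at least sample_id and population")
        sample, pop = fields[0], fields[1]
        grp = fields[2] if len(fields) > 2 and fields[2] else pop
        if sample in population_of:
            if population_of[sample] != pop:
                raise PopmapError(
                    f"sample '{sample}' listed twice with conflicting populations "
                    f"('{population_of[sample]}' vs '{pop}')"
                )
            continue
        population_of[sample] = pop
        if pop in group_of and group_of[pop] != grp:
            raise PopmapError(
                f"population '{pop}' assigned to two groups "
                f"('{group_of[pop]}' vs '{grp}')"
            )
        group_of[pop] = grp
        if len(fields) >= 5:
            coords[sample] = (float(fields[3]), float(fields[4]))
    if not population_of:
        raise PopmapError("empty population map")
    return PopulationAssignment(population_of, group_of, coords)


def write_popmap(assign: PopulationAssignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpopulation\tgroup\n")
        for sample, pop in assign.population_of.items():
            fh.write(f"{sample}\t{pop}\t{assign.group_of[pop]}\n")


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def concatenate_loci(alignments: Sequence[SequenceAlignment]) -> SequenceAlignment:
    """Concatenate loci sharing identical sample-id sets into one region.

    Rows are matched by id (order follows the first input); ``locus_bounds``
    records each input block.  Non-identical sample sets raise with the
    asymmetric difference — there is no silent intersection.
    """
    if not alignments:
        raise AlignmentError("no alignments to concatenate")
    first = alignments[0]
    ref_ids = set(first.sample_ids)
    for i, aln in enumerate(alignments[1:], start=2):
        ids = set(aln.sample_ids)
        if ids != ref_ids:
            raise AlignmentError(
                f"sample sets differ between locus 1 and locus {i}: "
                f"only in first: {sorted(ref_ids - ids)}; "
                f"only in locus {i}: {sorted(ids - ref_ids)}"
            )
    blocks = [first.matrix]
    bounds: list[tuple[int, int]] = []
    pos = 0
    for aln in alignments:
        bounds.append((pos, pos + aln.n_sites))
        pos += aln.n_sites
    for aln in alignments[1:]:
        blocks.append(aln.subset(first.sample_ids).matrix)
    return SequenceAlignment(first.sample_ids, np.hstack(blocks), tuple(bounds))


# codepoint lookup for fast missing-symbol tests (all symbols are ASCII)
_MISS_LOOKUP = np.zeros(128, dtype=bool)
for _c in MISSING:
    _MISS_LOOKUP[ord(_c)] = True


def missing_mask(matrix: np.ndarray) -> np.ndarray:
    """Boolean mask of missing/ambiguous symbols (same shape as ``matrix``)."""
    return _MISS_LOOKUP[matrix.view(np.uint32)]


def comparable_columns(aln: SequenceAlignment) -> np.ndarray:
    """Boolean mask of columns free of gaps/missing/ambiguity in every row."""
    return ~missing_mask(aln.matrix).any(axis=0)


def collapse_haplotypes(
    aln: SequenceAlignment,
    policy: Literal["complete-deletion", "pairwise-ignore"] = "complete-deletion",
) -> HaplotypeTable:
    """Collapse an alignment into distinct haplotypes with counts.

    Under ``complete-deletion`` (the default, matching the usual treatment of
    sequence data with missing sites) every column containing any gap,
    ``?``/``N`` or IUPAC ambiguity symbol is removed before comparing rows.
    Under ``pairwise-ignore`` two rows are the same haplotype when they agree
    at every site where both are unambiguous; identity groups are formed by
    transitive closure of that relation.
    """
    if policy == "complete-deletion":
        keep = comparable_columns(aln)
        if not keep.any():
            raise AlignmentError("no comparable sites after complete deletion")
        rows = ["".join(r) for r in aln.matrix[:, keep]]
        order: dict[str, int] = {}
        counts: dict[str, int] = {}
        for r in rows:
            order.setdefault(r, len(order))
            counts[r] = counts.get(r, 0) + 1
        haps = sorted(counts, key=order.__getitem__)
        return HaplotypeTable(tuple(haps), tuple(counts[h] for h in haps), policy)
    if policy == "pairwise-ignore":
        n = aln.n_samples
        miss = np.isin(aln.matrix, list(MISSING))
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                both = ~(miss[i] | miss[j])
                if not both.any() or (aln.matrix[i, both] == aln.matrix[j, both]).all():
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
        groups: dict[int, list[int]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(i)
        reps = sorted(groups, key=lambda r: min(groups[r]))
        haps = tuple("".join(aln.matrix[r]) for r in reps)
        counts_t = tuple(len(groups[r]) for r in reps)
        return HaplotypeTable(haps, counts_t, policy)
    raise ValueError(f"unknown policy: {policy!r}")
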