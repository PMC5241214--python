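"""Core domain types shared across the package.

The central objects are:

* :class:`PopulationSite` — one biallelic-or-multiallelic record from a
  population VCF, carrying the alternate allele frequency spectrum.
* :class:`SwapSite` / :class:`SwapTable` — the positions where the base
  reference carries the population-minor allele and the majorized
  reference carries the major allele instead.
* :class:`Genome` — named nucleotide sequences with case preserved;
  majorization never changes lengths or names, only single bases.
* :class:`VariantCall` / :class:`CallSet` — filtered per-sample variant
  records keyed by (chromosome, position), tagged with the reference
  frame they are expressed in.
* :class:`ComparisonReport` — one row of the per-sample accounting table:
  totals, common/unique partitions, swap overlaps, and FP/FN percentages.

Coordinates: all positions on these types are 1-based (VCF convention);
0-based indexing happens only inside sequence-level code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Iterator, Mapping

NUCLEOTIDES = frozenset("ACGT")

BASE_FRAME = "base"
MAJOR_FRAME = "major"


class MajorefError(Exception):
    """Base class for data-level errors (CLI exit code 2)."""


class RecordError(MajorefError):
    """A single malformed input record (skippable in lenient mode)."""


class ReferenceMismatchError(MajorefError):
    """Genome or call REF disagrees with the swap table at a position."""


@dataclass(frozen=True)
class PopulationSite:
    """One population-VCF site with its alternate allele frequencies.

    ``alt_afs`` is parallel to ``alt_alleles``; every frequency lies in
    [0, 1] and ``pos`` is 1-based.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    alt_afs: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if len(self.alt_afs) != len(self.alt_alleles):
            raise ValueError(
                f"{self.chrom}:{self.pos}: {len(self.alt_alleles)} ALT alleles "
                f"but {len(self.alt_afs)} frequencies"
            )
        for af in self.alt_afs:
            if not (0.0 <= af <= 1.0) or math.isnan(af):
                raise ValueError(f"{self.chrom}:{self.pos}: AF {af!r} outside [0, 1]")

    @property
    def is_biallelic_snp(self) -> bool:
        return (
            len(self.alt_alleles) == 1
            and self.ref_allele.upper() in NUCLEOTIDES
            and self.alt_alleles[0].upper() in NUCLEOTIDES
        )


@dataclass(frozen=True, order=True)
class SwapSite:
    """A position where the base and majorized references differ.

    ``base_allele`` is the original reference base (the population-minor
    allele), ``major_allele`` the replacement, and ``major_af`` the major
    allele's population frequency, strictly above 0.5 for sites selected
    by the standard rule.  ``relaxed`` construction (used by table
    inversion) waives the >0.5 requirement.
    """

    chrom: str
    pos: int
    base_allele: str
    major_allele: str
    major_af: float

    def __post_init__(self) -> None:
        if self.base_allele == self.major_allele:
            raise ValueError(f"{self.chrom}:{self.pos}: swap alleles identical")
        for allele in (self.base_allele, self.major_allele):
            if allele not in NUCLEOTIDES:
                raise ValueError(
                    f"{self.chrom}:{self.pos}: allele {allele!r} is not a single "
                    "uppercase nucleotide"
                )
        if not (0.0 <= self.major_af <= 1.0):
            raise ValueError(f"{self.chrom}:{self.pos}: AF {self.major_af} outside [0, 1]")

    def inverted(self) -> "SwapSite":
        """Exchange the two alleles and complement the frequency."""
        return SwapSite(
            chrom=self.chrom,
            pos=self.pos,
            base_allele=self.major_allele,
            major_allele=self.base_allele,
            major_af=1.0 - self.major_af,
        )


class SwapTable:
    """An ordered, position-unique collection of :class:`SwapSite`.

    Sites are kept sorted by (chromosome, position); chromosome order
    follows ``chrom_order`` when given (e.g. the FASTA record order),
    lexicographic otherwise.  Lookup by (chrom, pos) is O(1).
    """

    def __init__(
        self,
        sites: Iterable[SwapSite] = (),
        chrom_order: Iterable[str] | None = None,
    ) -> None:
        self._by_pos: dict[tuple[str, int], SwapSite] = {}
        self._chrom_order: list[str] = list(chrom_order) if chrom_order else []
        for site in sites:
            self.add(site)

    def add(self, site: SwapSite) -> None:
        key = (site.chrom, site.pos)
        if key in self._by_pos:
            raise ValueError(f"duplicate swap site at {site.chrom}:{site.pos}")
        self._by_pos[key] = site
        if site.chrom not in self._chrom_order:
            self._chrom_order.append(site.chrom)

    def get(self, chrom: str, pos: int) -> SwapSite | None:
        return self._by_pos.get((chrom, pos))

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self._by_pos

    def __len__(self) -> int:
        return len(self._by_pos)

    def __iter__(self) -> Iterator[SwapSite]:
        rank = {c: i for i, c in enumerate(self._chrom_order)}
        return iter(
            sorted(self._by_pos.values(), key=lambda s: (rank.get(s.chrom, len(rank)), s.chrom, s.pos))
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SwapTable):
            return NotImplemented
        return list(self) == list(other)

    def __repr__(self) -> str:
        return f"SwapTable({len(self)} sites, {len(self._chrom_order)} chromosomes)"

    @property
    def chrom_order(self) -> tuple[str, ...]:
        return tuple(self._chrom_order)

    def positions(self) -> set[tuple[str, int]]:
        return set(self._by_pos)

    def inverted(self) -> "SwapTable":
        """Swap base/major alleles per site; frequencies become 1 - AF.

        The result is a relaxed table (frequencies may be <= 0.5) meant
        only for re-substitution, e.g. to undo a majorization.
        """
        out = SwapTable(chrom_order=self._chrom_order)
        for site in self._by_pos.values():
            out.add(site.inverted())
        return out


class Genome:
    """Named nucleotide sequences, case-preserving, insertion-ordered."""

    def __init__(self, sequences: Mapping[str, str]) -> None:
        self._seqs: dict[str, str] = dict(sequences)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._seqs)

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return self._seqs == other._seqs

    def __repr__(self) -> str:
        return f"Genome({len(self)} sequences, {sum(self.lengths().values())} bp)"

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}

    def base_at(self, chrom: str, pos: int) -> str:
        """Base at 1-based position ``pos`` (case as stored)."""
        return self._seqs[chrom][pos - 1]


@dataclass(frozen=True)
class VariantCall:
    """One per-sample variant record in a given reference frame.

    ``genotype`` holds allele indices (0 = REF); ``None`` entries mark
    missing calls and pass through frame translation unchanged.  ``qual``
    is phred-scaled; synthesized (inferred) hom-alt records carry
    ``qual = -1``, ``depth = 0`` and ``inferred = True``.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotype: tuple[int | None, ...]
    phased: bool = False
    qual: float | None = None
    depth: int | None = None
    sample_id: str = "sample"
    inferred: bool = False

    def __post_init__(self) -> None:
        if self.ref in self.alts:
            raise ValueError(f"{self.chrom}:{self.pos}: REF {self.ref} repeated in ALTs")
        n_alleles = 1 + len(self.alts)
        for idx in self.genotype:
            if idx is not None and not (0 <= idx < n_alleles):
                raise ValueError(
                    f"{self.chrom}:{self.pos}: genotype index {idx} out of range "
                    f"for {n_alleles} alleles"
                )

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref, *self.alts)

    def genotype_alleles(self) -> tuple[str | None, ...]:
        """Allele strings carried by the genotype (frame-invariant)."""
        return tuple(None if i is None else self.alleles[i] for i in self.genotype)

    def is_hom_ref(self) -> bool:
        return all(i == 0 or i is None for i in self.genotype)

    def with_(self, **kwargs) -> "VariantCall":
        return replace(self, **kwargs)


class CallSet:
    """Per-sample variant calls, unique per (chrom, pos), frame-tagged."""

    def __init__(
        self,
        calls: Iterable[VariantCall] = (),
        frame: str = BASE_FRAME,
        sample_id: str | None = None,
    ) -> None:
        if frame not in (BASE_FRAME, MAJOR_FRAME):
            raise ValueError(f"unknown frame {frame!r}")
        self.frame = frame
        self._by_pos: dict[tuple[str, int], VariantCall] = {}
        self.sample_id = sample_id
        for call in calls:
            self.add(call)

    def add(self, call: VariantCall) -> None:
        if self.sample_id is None:
            self.sample_id = call.sample_id
        elif call.sample_id != self.sample_id:
            raise ValueError(
                f"mixed samples in call set: {call.sample_id!r} vs {self.sample_id!r}"
            )
        if call.key in self._by_pos:
            raise ValueError(f"duplicate call at {call.chrom}:{call.pos}")
        self._by_pos[call.key] = call

    def get(self, chrom: str, pos: int) -> VariantCall | None:
        return self._by_pos.get((chrom, pos))

    def __len__(self) -> int:
        return len(self._by_pos)

    def __iter__(self) -> Iterator[VariantCall]:
        return iter(sorted(self._by_pos.values(), key=lambda c: (c.chrom, c.pos)))

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self._by_pos

    def __repr__(self) -> str:
        return f"CallSet({len(self)} calls, frame={self.frame!r}, sample={self.sample_id!r})"

    def positions(self) -> set[tuple[str, int]]:
        return set(self._by_pos)


def round_half_away(value: float, digits: int = 3) -> float:
    """Round with ties away from zero (the convention used for printed rates)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def exact_percent(numerator: int, denominator: int) -> float:
    """100 * numerator / denominator computed in decimal, returned as float."""
    if denominator == 0:
        raise ZeroDivisionError("zero denominator in percentage")
    return float(Decimal(100) * Decimal(numerator) / Decimal(denominator))


@dataclass
class ComparisonReport:
    """One row of the per-sample two-frame accounting table.

    Column semantics (matching the report TSV order): total calls in the
    base frame, total calls in the major frame, calls common to both
    (by position), unique to each, the overlap of each of those three
    partitions with the swap table, and the FP/FN percentages

    ``fp_percent = 100 * unique_base_in_swaps / total_base``
    ``fn_percent = 100 * unique_major_in_swaps / total_major``

    FP here means a base-frame call at a swap position that merely
    restates the population-major allele; FN means a major-frame-only
    call masked in the base frame by an individual homozygous for the
    base (minor) allele.  Percentages are ``None`` when a total is zero.
    """

    sample_id: str
    total_base: int
    total_major: int
    common: int
    unique_base: int
    unique_major: int
    common_in_swaps: int
    unique_base_in_swaps: int
    unique_major_in_swaps: int
    fp_percent: float | None = field(default=None)
    fn_percent: float | None = field(default=None)

    COLUMNS = (
        "sample_id",
        "total_base",
        "total_major",
        "common",
        "unique_base",
        "unique_major",
        "common_in_swaps",
        "unique_base_in_swaps",
        "unique_major_in_swaps",
        "fp_percent",
        "fn_percent",
    )

    def validate_partition(self) -> None:
        """Check the partition identities; raise on violation."""
        if self.common + self.unique_base != self.total_base:
            raise ValueError(
                f"{self.sample_id}: common + unique_base = "
                f"{self.common + self.unique_base} != total_base {self.total_base}"
            )
        if self.common + self.unique_major != self.total_major:
            raise ValueError(
                f"{self.sample_id}: common + unique_major = "
                f"{self.common + self.unique_major} != total_major {self.total_major}"
            )
        for part, whole in (
            (self.common_in_swaps, self.common),
            (self.unique_base_in_swaps, self.unique_base),
            (self.unique_major_in_swaps, self.unique_major),
        ):
            if part > whole:
                raise ValueError(f"{self.sample_id}: swap overlap {part} exceeds parent {whole}")

    def to_dict(self) -> dict:
        return {col: getattr(self, col) for col in self.COLUMNS}
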