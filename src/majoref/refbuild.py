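"""Build a coordinate-preserving major-allele reference.

The construction takes a base genome and a stream of population sites
with alternate allele frequencies, selects the biallelic SNP sites whose
alternate allele frequency is strictly above a threshold (0.5 by
default — i.e. the base reference carries the population-minor allele
there), and substitutes the major allele into the sequence at exactly
those positions.  Sequence lengths, record order and chromosome names
are never touched, so every coordinate on the majorized reference is
directly comparable with the base reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .models import (
    Genome,
    MajorefError,
    PopulationSite,
    ReferenceMismatchError,
    SwapSite,
    SwapTable,
)

logger = logging.getLogger(__name__)

DEFAULT_AF_THRESHOLD = 0.5

SWAP_TABLE_HEADER = "#chrom\tpos\tbase_allele\tmajor_allele\tmajor_af"


def select_swap_sites(
    sites: Iterable[PopulationSite],
    threshold: float = DEFAULT_AF_THRESHOLD,
    chrom_order: Sequence[str] | None = None,
) -> SwapTable:
    """Select swap sites: biallelic SNPs with alt AF strictly > ``threshold``.

    Multi-allelic records are discarded outright, even when one of their
    alternates exceeds the threshold.  Records whose REF or ALT is not a
    single A/C/G/T base (indels, MNPs, symbolic alleles) are excluded.
    All records sharing a duplicated (chrom, pos) are dropped and logged.
    The threshold comparison is strict, so a site at exactly the
    threshold keeps the base allele.
    """
    if not (0.0 <= threshold < 1.0):
        raise ValueError(f"threshold must lie in [0, 1), got {threshold}")

    seen: dict[tuple[str, int], PopulationSite | None] = {}
    duplicated: set[tuple[str, int]] = set()
    n_multi = n_non_snp = n_below = 0
    for site in sites:
        key = (site.chrom, site.pos)
        if key in seen:
            duplicated.add(key)
            continue
        seen[key] = site

    for key in duplicated:
        logger.warning("dropping all records at duplicated position %s:%d", *key)
        del seen[key]

    table = SwapTable(chrom_order=chrom_order)
    for (chrom, pos), site in seen.items():
        if len(site.alt_alleles) != 1:
            n_multi += 1
            continue
        if not site.is_biallelic_snp:
            n_non_snp += 1
            continue
        af = site.alt_afs[0]
        if af <= threshold:
            n_below += 1
            continue
        table.add(
            SwapSite(
                chrom=chrom,
                pos=pos,
                base_allele=site.ref_allele.upper(),
                major_allele=site.alt_alleles[0].upper(),
                major_af=af,
            )
        )
    logger.info(
        "selected %d swap sites (excluded: %d multi-allelic, %d non-SNP, "
        "%d at or below AF %.3g, %d at duplicated positions)",
        len(table), n_multi, n_non_snp, n_below, threshold, len(duplicated),
    )
    return table


def apply_swaps(genome: Genome, table: SwapTable, lenient: bool = False) -> Genome:
    """Substitute the major allele at every swap position of ``genome``.

    The returned genome differs from the input at exactly the applied
    swap positions; soft-mask case is preserved (a lowercase base is
    replaced by a lowercase major allele).  An ``N`` at a swap position
    is skipped with a warning.  A base that matches neither the expected
    allele nor ``N`` raises :class:`ReferenceMismatchError`, or is
    skipped when ``lenient`` is set.
    """
    by_chrom: dict[str, list[SwapSite]] = {}
    for site in table:
        by_chrom.setdefault(site.chrom, []).append(site)

    out: dict[str, str] = {}
    n_applied = n_skipped = 0
    for chrom in genome.names:
        seq = genome[chrom]
        sites = by_chrom.pop(chrom, None)
        if not sites:
            out[chrom] = seq
            continue
        buf = list(seq)
        for site in sites:
            if site.pos > len(seq):
                raise MajorefError(
                    f"swap position {chrom}:{site.pos} beyond chromosome "
                    f"length {len(seq)}"
                )
            current = buf[site.pos - 1]
            if current.upper() == "N":
                logger.warning("skipping swap at %s:%d: base is N", chrom, site.pos)
                n_skipped += 1
                continue
            if current.upper() != site.base_allele:
                msg = (
                    f"reference mismatch at {chrom}:{site.pos}: genome has "
                    f"{current!r}, swap table expects {site.base_allele!r}"
                )
                if lenient:
                    logger.warning("%s (skipped)", msg)
                    n_skipped += 1
                    continue
                raise ReferenceMismatchError(msg)
            replacement = site.major_allele
            if current.islower():
                replacement = replacement.lower()
            buf[site.pos - 1] = replacement
            n_applied += 1
        out[chrom] = "".join(buf)

    if by_chrom:
        missing = ", ".join(sorted(by_chrom))
        raise MajorefError(f"swap table references chromosomes absent from genome: {missing}")
    logger.info("applied %d swaps, skipped %d", n_applied, n_skipped)
    return Genome(out)


def invert_swap_table(table: SwapTable) -> SwapTable:
    """Exchange base/major alleles per site (AF becomes 1 - AF).

    The result re-substitutes the original alleles:
    ``apply_swaps(apply_swaps(g, T), invert_swap_table(T)) == g``.
    """
    return table.inverted()


def write_swap_table(table: SwapTable, path, extra_header: Sequence[str] = ()) -> None:
    """Write the swap table as TSV (1-based positions, AF at 6 decimals)."""
    with open(path, "w") as fh:
        for line in extra_header:
            fh.write(f"##{line.lstrip('#')}\n")
        fh.write(SWAP_TABLE_HEADER + "\n")
        for site in table:
            fh.write(
                f"{site.chrom}\t{site.pos}\t{site.base_allele}\t"
                f"{site.major_allele}\t{site.major_af:.6f}\n"
            )


def read_swap_table(path) -> SwapTable:
    """Read a swap-table TSV; malformed lines raise with their line number."""
    table = SwapTable()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise MajorefError(
                    f"{path}:{lineno}: expected 5 tab-separated fields, got {len(fields)}"
                )
            chrom, pos_s, base, major, af_s = fields
            try:
                site = SwapSite(
                    chrom=chrom,
                    pos=int(pos_s),
                    base_allele=base,
                    major_allele=major,
                    major_af=float(af_s),
                )
            except ValueError as exc:
                raise MajorefError(f"{path}:{lineno}: {exc}") from exc
            try:
                table.add(site)
            except ValueError as exc:
                raise MajorefError(f"{path}:{lineno}: {exc}") from exc
    return table


def write_swap_bed(table: SwapTable, path) -> None:
    """Write swap sites as BED (0-based half-open, one line per swap)."""
    with open(path, "w") as fh:
        for site in table:
            fh.write(
                f"{site.chrom}\t{site.pos - 1}\t{site.pos}\t"
                f"{site.base_allele}>{site.major_allele}\n"
            )


@dataclass
class ContigNameReport:
    """Result of comparing FASTA and VCF chromosome name sets.

    No renaming is ever applied; a mismatch is reported together with a
    suggestion when toggling a ``chr`` prefix would reconcile the sets.
    """

    fasta_only: frozenset[str]
    vcf_only: frozenset[str]
    shared: frozenset[str]
    suggestion: str | None = field(default=None)

    @property
    def consistent(self) -> bool:
        return not self.vcf_only


def check_contig_names(fasta_names: Iterable[str], vcf_names: Iterable[str]) -> ContigNameReport:
    fasta = set(fasta_names)
    vcf = set(vcf_names)
    suggestion = None
    if fasta and vcf and not (fasta & vcf):
        if {f"chr{n}" for n in vcf} <= fasta:
            suggestion = "VCF contigs match the FASTA after adding a 'chr' prefix"
        elif {n.removeprefix("chr") for n in vcf} <= fasta:
            suggestion = "VCF contigs match the FASTA after stripping the 'chr' prefix"
    return ContigNameReport(
        fasta_only=frozenset(fasta - vcf),
        vcf_only=frozenset(vcf - fasta),
        shared=frozenset(fasta & vcf),
        suggestion=suggestion,
    )
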