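"""FASTA and VCF input/output, backed by pysam.

Coordinates cross the 1-based/0-based boundary only here: domain
objects carry 1-based VCF-style positions, pysam records expose 0-based
starts, and the conversion happens at read/write time.

Provenance conventions written into every VCF this package produces:

* ``##majoref_frame=base|major`` — the reference frame the records are
  expressed in.
* INFO flag ``INFERRED_HOMALT`` — marks synthesized hom-alt records
  (projected from absence in the other frame, not from read evidence);
  such records carry QUAL ``.`` and DP 0 on disk and the sentinel
  ``qual = -1`` in memory.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import pysam

from .frame import INFERRED_DEPTH, INFERRED_QUAL
from .models import (
    BASE_FRAME,
    CallSet,
    MajorefError,
    Genome,
    PopulationSite,
    RecordError,
    VariantCall,
)

logger = logging.getLogger(__name__)

FRAME_HEADER_KEY = "majoref_frame"
INFERRED_FLAG = "INFERRED_HOMALT"
DEFAULT_LINE_WIDTH = 60


# ---------------------------------------------------------------------------
# FASTA

def read_genome_fasta(path) -> Genome:
    """Load a FASTA into memory, preserving record order and base case."""
    with pysam.FastaFile(str(path)) as fa:
        return Genome({name: fa.fetch(name) for name in fa.references})


def detect_fasta_line_width(path) -> int:
    """Width of the first sequence line (fallback 60 for empty files)."""
    with open(path) as fh:
        for line in fh:
            if line and not line.startswith(">"):
                stripped = line.rstrip("\n")
                if stripped:
                    return len(stripped)
    return DEFAULT_LINE_WIDTH


def write_genome_fasta(genome: Genome, path, line_width: int = DEFAULT_LINE_WIDTH) -> None:
    if line_width < 1:
        raise ValueError("line width must be positive")
    with open(path, "w") as fh:
        for name in genome.names:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# Population VCF (sites + allele frequencies)

def _site_afs(rec: pysam.VariantRecord, n_alts: int) -> tuple[float, ...]:
    """Alternate allele frequencies: INFO/AF, with AC/AN fallback."""
    info = rec.info
    if "AF" in info:
        raw = info["AF"]
        values = raw if isinstance(raw, tuple) else (raw,)
        # VCF floats are 32-bit in pysam; 6 decimals recovers the written text
        return tuple(round(float(v), 6) for v in values)
    if "AC" in info and "AN" in info:
        ac = info["AC"]
        ac = ac if isinstance(ac, tuple) else (ac,)
        an = int(info["AN"])
        if an <= 0:
            raise RecordError(f"{rec.chrom}:{rec.pos}: AN={an} is not positive")
        return tuple(int(c) / an for c in ac)
    raise RecordError(f"{rec.chrom}:{rec.pos}: no AF and no AC/AN in INFO")


def read_population_sites(path, strict: bool = False) -> Iterable[PopulationSite]:
    """Stream sites from a population VCF (plain or bgzip).

    Records with malformed frequencies (missing, non-numeric, outside
    [0, 1]) are skipped with a log message, or abort the run when
    ``strict`` is set.
    """
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            alts = tuple(rec.alts or ())
            try:
                afs = _site_afs(rec, len(alts))
                yield PopulationSite(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_alleles=alts,
                    alt_afs=afs,
                )
            except (RecordError, ValueError, TypeError) as exc:
                if strict:
                    raise RecordError(f"{rec.chrom}:{rec.pos}: {exc}") from exc
                logger.warning("skipping malformed record %s:%d: %s", rec.chrom, rec.pos, exc)


def _base_header(contigs: Mapping[str, int], extra_lines: Sequence[str] = ()) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.add_line(f"##contig=<ID={name},length={length}>")
    for line in extra_lines:
        header.add_line(line if line.startswith("##") else f"##{line}")
    return header


def write_population_vcf(
    sites: Iterable[PopulationSite],
    path,
    contigs: Mapping[str, int],
    extra_header: Sequence[str] = (),
) -> None:
    header = _base_header(contigs, extra_header)
    header.add_line(
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">'
    )
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for site in sites:
            rec = out.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                alleles=(site.ref_allele, *site.alt_alleles),
            )
            rec.info["AF"] = tuple(round(af, 6) for af in site.alt_afs)
            out.write(rec)


# ---------------------------------------------------------------------------
# Per-sample call sets

def callset_header(
    contigs: Mapping[str, int], frame: str, sample_id: str, extra_lines: Sequence[str] = ()
) -> pysam.VariantHeader:
    header = _base_header(contigs, extra_lines)
    header.add_line(f"##{FRAME_HEADER_KEY}={frame}")
    header.add_line(
        f'##INFO=<ID={INFERRED_FLAG},Number=0,Type=Flag,'
        'Description="Hom-alt record projected from absence in the other frame">'
    )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_samples([sample_id])
    return header


def write_callset_vcf(
    cs: CallSet,
    path,
    contigs: Mapping[str, int],
    extra_header: Sequence[str] = (),
) -> None:
    sample = cs.sample_id or "sample"
    header = callset_header(contigs, cs.frame, sample, extra_header)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in cs:
            rec = out.new_record(
                contig=call.chrom,
                start=call.pos - 1,
                alleles=(call.ref, *call.alts),
            )
            if call.inferred:
                rec.info[INFERRED_FLAG] = True
            else:
                rec.qual = call.qual
            fmt = rec.samples[sample]
            fmt["GT"] = tuple(call.genotype)
            fmt.phased = call.phased
            if call.depth is not None:
                fmt["DP"] = call.depth
            out.write(rec)


def read_frame_tag(header: pysam.VariantHeader) -> str | None:
    for line in str(header).splitlines():
        if line.startswith(f"##{FRAME_HEADER_KEY}="):
            return line.split("=", 1)[1].strip()
    return None


def read_callsets_vcf(path, frame: str | None = None) -> dict[str, CallSet]:
    """Read a (possibly multi-sample) VCF into one CallSet per sample.

    The frame comes from the ``##majoref_frame`` header unless
    overridden; a VCF with neither is assumed to be in the base frame.
    """
    with pysam.VariantFile(str(path)) as vf:
        tagged = read_frame_tag(vf.header)
        use_frame = frame or tagged or BASE_FRAME
        samples = list(vf.header.samples)
        if not samples:
            raise MajorefError(f"{path}: VCF has no sample columns")
        sets = {s: CallSet(frame=use_frame, sample_id=s) for s in samples}
        for rec in vf:
            alts = tuple(rec.alts or ())
            inferred = INFERRED_FLAG in rec.info
            for sample in samples:
                fmt = rec.samples[sample]
                gt = fmt.get("GT")
                if gt is None or all(g is None for g in gt):
                    continue
                depth = fmt.get("DP")
                call = VariantCall(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=alts,
                    genotype=tuple(gt),
                    phased=bool(getattr(fmt, "phased", False)),
                    qual=INFERRED_QUAL if inferred else rec.qual,
                    depth=INFERRED_DEPTH if inferred else depth,
                    sample_id=sample,
                    inferred=inferred,
                )
                sets[sample].add(call)
    return sets


def read_callset_vcf(path, sample_id: str | None = None, frame: str | None = None) -> CallSet:
    """Read a single sample's calls (the only sample unless named)."""
    sets = read_callsets_vcf(path, frame=frame)
    if sample_id is None:
        if len(sets) != 1:
            raise MajorefError(
                f"{path}: {len(sets)} samples present; specify which one"
            )
        return next(iter(sets.values()))
    if sample_id not in sets:
        raise MajorefError(f"{path}: sample {sample_id!r} not found")
    return sets[sample_id]


def read_bed_regions(path) -> list[tuple[str, int, int]]:
    """Read BED intervals (0-based half-open) for use as a callable mask."""
    regions = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise MajorefError(f"{path}:{lineno}: BED line has fewer than 3 fields")
            regions.append((fields[0], int(fields[1]), int(fields[2])))
    return regions
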