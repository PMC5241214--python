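"""Self-contained synthetic fixtures: genome, sites, individuals, calls.

Everything every other module consumes can be generated here from a
single seed: a toy multi-chromosome genome, biallelic SNP sites with a
controlled alternate-allele-frequency spectrum (sites with AF > 0.5 are
the intended swap set), Hardy–Weinberg diploid genotypes for a cohort
of individuals, and idealized per-frame variant calls.

The idealized caller emits a record wherever an individual's genotype
differs from homozygous-reference *in the requested frame* and says
nothing elsewhere — the variants-only convention.  It carries no
alignment or sequencing-error model: reference-frame masking is a pure
bookkeeping artifact of which allele is REF, and noiseless calls
exercise it exactly.  A per-site genotype-flip probability is available
as a noise hook but defaults to 0.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .models import (
    BASE_FRAME,
    CallSet,
    ComparisonReport,
    MAJOR_FRAME,
    MajorefError,
    Genome,
    PopulationSite,
    SwapTable,
    VariantCall,
    exact_percent,
)
from .refbuild import apply_swaps, select_swap_sites, write_swap_table
from .vcfio import write_callset_vcf, write_genome_fasta, write_population_vcf

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# rng stream tags, combined with the seed so every consumer is independent
_STREAM_REFERENCE = 0
_STREAM_SITES = 1
_STREAM_UNCALLABLE = 2
_STREAM_GENOTYPES = 3
_STREAM_NOISE = 4


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    ``af_distribution`` is ``("beta", a, b)``, ``("uniform",)`` or
    ``("fixed", (f1, f2, ...))`` (the fixed list is cycled over sites).
    The default Beta(0.5, 0.5) spectrum is U-shaped like a neutral site
    frequency spectrum and symmetric about 0.5, so about half the sites
    carry a population-major alternate allele and become swap sites.
    ``depth`` and ``qual`` are the constant evidence values stamped on
    idealized calls, chosen above the standard filter thresholds
    (DP >= 5, QUAL >= 30) so filtering is a pass-through unless a test
    perturbs them.
    """

    n_chroms: int = 2
    chrom_length: int = 100_000
    n_sites: int = 2_000
    af_distribution: tuple = ("beta", 0.5, 0.5)
    n_individuals: int = 20
    seed: int = 42
    uncallable_fraction: float = 0.0
    depth: int = 30
    qual: float = 60.0
    genotype_flip_prob: float = 0.0
    af_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.uncallable_fraction < 1.0):
            raise ValueError("uncallable_fraction must lie in [0, 1)")
        if self.n_sites > self.n_chroms * self.chrom_length:
            raise MajorefError(
                f"{self.n_sites} sites requested but genome has only "
                f"{self.n_chroms * self.chrom_length} positions"
            )

    def rng(self, *stream) -> np.random.Generator:
        return np.random.default_rng([self.seed, *stream])

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["af_distribution"] = list(d["af_distribution"])
        return d


@dataclass
class IndividualGenotypes:
    """One diploid individual's alternate-allele dosage per site.

    Genotypes are drawn independently per site as Binomial(2, alt AF) —
    Hardy–Weinberg proportions (1-f)^2, 2f(1-f), f^2.
    """

    sample_id: str
    index: int
    genotypes: np.ndarray  # dosage in {0, 1, 2}, aligned with the site list


def simulate_reference(cfg: SimConfig) -> Genome:
    """Uniform-random A/C/G/T chromosomes chr1..chrN, uppercase."""
    rng = cfg.rng(_STREAM_REFERENCE)
    seqs = {}
    for i in range(cfg.n_chroms):
        draws = rng.integers(0, 4, size=cfg.chrom_length)
        seqs[f"chr{i + 1}"] = _BASES[draws].tobytes().decode("ascii")
    return Genome(seqs)


def _draw_afs(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = cfg.af_distribution[0]
    if kind == "beta":
        _, a, b = cfg.af_distribution
        return rng.beta(a, b, size=n)
    if kind == "uniform":
        return rng.uniform(0.0, 1.0, size=n)
    if kind == "fixed":
        values = np.asarray(cfg.af_distribution[1], dtype=float)
        return np.resize(values, n)
    raise ValueError(f"unknown AF distribution {cfg.af_distribution!r}")


def simulate_population_sites(genome: Genome, cfg: SimConfig) -> list[PopulationSite]:
    """Distinct biallelic SNP sites with REF = the genome base.

    Positions are drawn without replacement uniformly over the genome;
    each site gets one random ALT different from REF and an AF from the
    configured spectrum.  Sites are returned sorted by chromosome (FASTA
    order) then position.
    """
    rng = cfg.rng(_STREAM_SITES)
    lengths = genome.lengths()
    total = sum(lengths.values())
    if cfg.n_sites > total:
        raise MajorefError(f"cannot place {cfg.n_sites} sites on a {total} bp genome")
    flat = rng.choice(total, size=cfg.n_sites, replace=False)
    flat.sort()
    bounds = np.cumsum([lengths[c] for c in genome.names])
    afs = _draw_afs(cfg, cfg.n_sites, rng)

    sites: list[PopulationSite] = []
    for flat_pos, af in zip(flat, afs):
        chrom_idx = int(np.searchsorted(bounds, flat_pos, side="right"))
        chrom = genome.names[chrom_idx]
        offset = int(flat_pos) - (int(bounds[chrom_idx - 1]) if chrom_idx else 0)
        pos = offset + 1
        ref = genome.base_at(chrom, pos).upper()
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        sites.append(
            PopulationSite(
                chrom=chrom,
                pos=pos,
                ref_allele=ref,
                alt_alleles=(alt,),
                # 6 decimals: the precision AFs carry in VCF text, so the
                # on-disk fixture selects exactly the same swap set
                alt_afs=(round(float(af), 6),),
            )
        )
    return sites


def simulate_individuals(
    sites: list[PopulationSite], cfg: SimConfig
) -> list[IndividualGenotypes]:
    """HWE cohort: per-site Binomial(2, AF), one seeded stream per individual."""
    afs = np.array([s.alt_afs[0] for s in sites])
    out = []
    for i in range(cfg.n_individuals):
        rng = cfg.rng(_STREAM_GENOTYPES, i)
        out.append(
            IndividualGenotypes(
                sample_id=f"ind{i + 1:03d}",
                index=i,
                genotypes=rng.binomial(2, afs),
            )
        )
    return out


def uncallable_mask(cfg: SimConfig, n_sites: int, individual_index: int) -> np.ndarray:
    """Per-individual boolean mask of sites that emit nothing in either frame."""
    rng = cfg.rng(_STREAM_UNCALLABLE, individual_index)
    return rng.random(n_sites) < cfg.uncallable_fraction


def effective_genotypes(
    individual: IndividualGenotypes, cfg: SimConfig
) -> np.ndarray:
    """Genotypes as observed by the caller: truth plus optional flip noise.

    Flips are drawn once per (individual, site) and shared by both
    frames, so frame comparisons see a single consistent observation.
    """
    g = individual.genotypes.copy()
    if cfg.genotype_flip_prob > 0:
        rng = cfg.rng(_STREAM_NOISE, individual.index)
        flip = rng.random(g.size) < cfg.genotype_flip_prob
        shift = rng.integers(1, 3, size=g.size)  # move to one of the 2 other dosages
        g[flip] = (g[flip] + shift[flip]) % 3
    return g


def idealized_caller(
    individual: IndividualGenotypes,
    sites: list[PopulationSite],
    frame: str,
    table: SwapTable,
    cfg: SimConfig,
) -> CallSet:
    """Variants-only calls for one individual in one reference frame.

    In the base frame a record appears wherever the alt dosage is > 0.
    In the major frame the REF at a swap site is the (population-major)
    alternate allele, so a record appears wherever the individual
    carries the base allele at all (dosage < 2); individuals homozygous
    for the major allele are hom-ref there and yield nothing — and
    symmetrically, hom-major individuals do yield (spurious-looking)
    records in the base frame.  Uncallable sites emit nothing in either
    frame.
    """
    if frame not in (BASE_FRAME, MAJOR_FRAME):
        raise ValueError(f"unknown frame {frame!r}")
    genotypes = effective_genotypes(individual, cfg)
    masked = uncallable_mask(cfg, len(sites), individual.index)
    calls = CallSet(frame=frame, sample_id=individual.sample_id)
    for site, dosage, uncallable in zip(sites, genotypes, masked):
        if uncallable:
            continue
        ref, alt = site.ref_allele, site.alt_alleles[0]
        swap = table.get(site.chrom, site.pos)
        if swap is not None and (swap.base_allele != ref.upper() or swap.major_allele != alt.upper()):
            raise MajorefError(
                f"{site.chrom}:{site.pos}: swap table alleles "
                f"{swap.base_allele}>{swap.major_allele} disagree with site {ref}>{alt}"
            )
        if frame == MAJOR_FRAME and swap is not None:
            rec_ref, rec_alt, alt_count = alt, ref, 2 - int(dosage)
        else:
            rec_ref, rec_alt, alt_count = ref, alt, int(dosage)
        if alt_count == 0:
            continue
        calls.add(
            VariantCall(
                chrom=site.chrom,
                pos=site.pos,
                ref=rec_ref,
                alts=(rec_alt,),
                genotype=(0, 1) if alt_count == 1 else (1, 1),
                phased=False,
                qual=cfg.qual,
                depth=cfg.depth,
                sample_id=individual.sample_id,
            )
        )
    return calls


def expected_report_from_genotypes(
    individual: IndividualGenotypes,
    sites: list[PopulationSite],
    table: SwapTable,
    cfg: SimConfig,
) -> ComparisonReport:
    """Direct recount of the accounting row from raw genotypes.

    This never builds call records or translates frames: it counts
    dosages site by site, which is an independent route to the same row
    the VCF → filter → intersect pipeline produces.  At a callable swap
    site with dosage g: both frames call iff g == 1, only the base frame
    iff g == 2 (the false positive), only the major frame iff g == 0
    (the masked false negative).  Non-swap sites call identically in
    both frames iff g > 0.
    """
    genotypes = effective_genotypes(individual, cfg)
    masked = uncallable_mask(cfg, len(sites), individual.index)
    swap_positions = table.positions()

    total_base = total_major = common = unique_base = unique_major = 0
    common_in_swaps = 0
    for site, g, uncallable in zip(sites, genotypes, masked):
        if uncallable:
            continue
        if (site.chrom, site.pos) in swap_positions:
            if g > 0:
                total_base += 1
            if g < 2:
                total_major += 1
            if g == 1:
                common += 1
                common_in_swaps += 1
            elif g == 2:
                unique_base += 1
            else:
                unique_major += 1
        elif g > 0:
            total_base += 1
            total_major += 1
            common += 1
    report = ComparisonReport(
        sample_id=individual.sample_id,
        total_base=total_base,
        total_major=total_major,
        common=common,
        unique_base=unique_base,
        unique_major=unique_major,
        common_in_swaps=common_in_swaps,
        unique_base_in_swaps=unique_base,
        unique_major_in_swaps=unique_major,
    )
    if total_base and total_major:
        report.fp_percent = exact_percent(report.unique_base_in_swaps, total_base)
        report.fn_percent = exact_percent(report.unique_major_in_swaps, total_major)
    return report


@dataclass
class Fixture:
    """In-memory view of a generated fixture plus the paths written."""

    cfg: SimConfig
    genome: Genome
    major_genome: Genome
    sites: list[PopulationSite]
    table: SwapTable
    individuals: list[IndividualGenotypes]
    paths: dict[str, object] = field(default_factory=dict)


def build_fixture(cfg: SimConfig) -> Fixture:
    """Generate all fixture objects in memory (no files)."""
    genome = simulate_reference(cfg)
    sites = simulate_population_sites(genome, cfg)
    table = select_swap_sites(sites, cfg.af_threshold, chrom_order=genome.names)
    major_genome = apply_swaps(genome, table)
    individuals = simulate_individuals(sites, cfg)
    return Fixture(
        cfg=cfg,
        genome=genome,
        major_genome=major_genome,
        sites=sites,
        table=table,
        individuals=individuals,
    )


def make_fixture(cfg: SimConfig, out_dir) -> Fixture:
    """Write a complete on-disk fixture; deterministic given the seed.

    Files: base and majorized FASTA, population VCF with AF, the swap
    table TSV, per-individual VCFs in both frames, and a manifest JSON
    recording the configuration and the expected accounting row per
    individual (recounted directly from genotypes).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fx = build_fixture(cfg)
    contigs = fx.genome.lengths()

    paths: dict[str, object] = {
        "base_fasta": out / "base.fa",
        "major_fasta": out / "major.fa",
        "population_vcf": out / "population.vcf",
        "swap_table": out / "swaps.tsv",
        "manifest": out / "manifest.json",
    }
    write_genome_fasta(fx.genome, paths["base_fasta"])
    write_genome_fasta(fx.major_genome, paths["major_fasta"])
    write_population_vcf(fx.sites, paths["population_vcf"], contigs)
    write_swap_table(fx.table, paths["swap_table"])

    expected = {}
    call_paths: dict[str, dict[str, Path]] = {}
    for ind in fx.individuals:
        per_frame = {}
        for frame in (BASE_FRAME, MAJOR_FRAME):
            cs = idealized_caller(ind, fx.sites, frame, fx.table, cfg)
            p = out / f"{ind.sample_id}.{frame}.vcf"
            write_callset_vcf(cs, p, contigs)
            per_frame[frame] = p
        call_paths[ind.sample_id] = per_frame
        expected[ind.sample_id] = expected_report_from_genotypes(
            ind, fx.sites, fx.table, cfg
        ).to_dict()

    manifest = {
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "n_sites": len(fx.sites),
        "n_swap_sites": len(fx.table),
        "contigs": contigs,
        "calls": {
            sid: {frame: str(p) for frame, p in frames.items()}
            for sid, frames in call_paths.items()
        },
        "expected_reports": expected,
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    fx.paths = {**paths, "calls": call_paths}
    return fx
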