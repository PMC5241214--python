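# Methods

## The reference-frame model

Two references, *base* and *major*, share every coordinate and differ
only at a set of **swap sites**: positions where the base reference
carries the population-minor allele of a biallelic SNP and the
majorized reference carries the major allele. Because coordinates are
preserved, a VCF record against either reference can be re-expressed
against the other by pure allele renumbering — no liftover, no
realignment.

For a swap site with base allele *b*, major allele *m*, and a source
record with REF = *m* and ALT list *A* (major→base direction; the other
direction is the mirror image):

* new REF = *b*; new ALT list = [*m*] followed by *A* with *b* removed,
  original order preserved;
* genotype indices are remapped through the allele *strings*, which are
  frame-invariant; phasing is kept verbatim;
* a remapped genotype that is homozygous index 0 is not a variant in
  the target frame and the record is dropped.

That last rule is the **hom-ref masking** phenomenon itself: a
variants-only caller emits nothing for hom-ref genotypes, so an
individual homozygous for the reference's minor allele is invisible in
the base frame (a false negative), while an individual homozygous for
the major allele produces a spurious base-frame record (a population-
level false positive). The round-trip theorem implemented and tested
here is exact: translation there-and-back is the identity on every
record *not* homozygous for the opposite frame's REF, and the dropped
records are exactly that homozygous subset. A blanket "round trip is
the identity" claim is impossible for variants-only call sets, since a
dropped hom-ref record carries no information to resurrect — hence the
opt-in `project_homref`, which synthesizes the missing hom-alt records
(GT 1/1, sentinel QUAL −1 / DP 0, INFO flag `INFERRED_HOMALT`) for
every swap site absent from the call set, restricted to a callable-
region BED when one is supplied. Without a mask, "absent" is assumed
to mean "hom-ref" at every swap site, which the log states loudly;
sentinel evidence values guarantee inferred records can never pass the
evidence filter, and filtering is applied before translation.

## Swap-site selection

From a population VCF: keep records that are biallelic (exactly one
ALT), SNPs (REF and ALT single A/C/G/T bases), with alternate allele
frequency **strictly** greater than the threshold (default 0.5, so a
50/50 tie keeps the base allele). Multi-allelic records are discarded
outright even when one ALT exceeds the threshold, and indels/MNPs are
excluded to preserve the coordinate frame. All records at a duplicated
(chrom, pos) are dropped and logged. The AF comes from INFO/AF, with
AC/AN as fallback; records with neither, or with frequencies outside
[0, 1], are skipped with a log message (strict mode aborts instead).
Allele frequencies are handled at 6-decimal precision — the precision
VCF text carries — so selection from a written file reproduces
selection from the in-memory site list bit-for-bit (VCF INFO floats are
32-bit; rounding on read recovers the written decimal).

Substitution preserves soft-masking (a lowercase base is replaced by a
lowercase major allele), skips `N` bases with a warning, and aborts on
a reference-base mismatch unless `--lenient` is set. Chromosome names
are never normalized: a FASTA/VCF name-set mismatch is reported with a
`chr`-prefix suggestion but no renaming, since silent renaming corrupts
coordinates.

## Accounting

Two filtered per-sample call sets (base frame, major frame) are
partitioned by (chrom, pos) into common / unique-to-base /
unique-to-major; each partition is intersected with the swap table;

    FP% = 100 · |unique_base ∩ swaps| / total_base
    FN% = 100 · |unique_major ∩ swaps| / total_major

Percentages are computed in exact decimal arithmetic and displayed at
3 decimals, ties rounded away from zero — the convention that
reproduces all published per-sample rows from their printed count
columns. Each rate requires its own positive denominator; a frame with
zero calls yields a null rate with a warning (a cohort of hom-major
individuals legitimately has `total_major = 0` with FP% = 100).
Matching is positional by default because the two frames share
coordinates and the published accounting is positional; an
allele-aware mode (`--allele-aware`) additionally requires the carried
allele multiset to agree.

Evidence filtering defaults to read depth ≥ 5 and variant quality
≥ 30, both inclusive, applied to each call set before intersection.

## Synthetic cohort

The generator emulates the study design at desk scale, fully
determined by one integer seed (independent substreams per consumer:
reference, sites, per-individual genotypes, per-individual callable
masks, noise):

| parameter | default | meaning |
|---|---|---|
| `n_chroms` × `chrom_length` | 2 × 100 kb | uniform-random A/C/G/T genome |
| `n_sites` | 2000 | distinct biallelic SNP positions, REF = genome base |
| `af_distribution` | Beta(0.5, 0.5) | alternate-AF spectrum; U-shaped like a neutral site-frequency spectrum and symmetric about 0.5, so ~half the sites become swap sites |
| `n_individuals` | 20 | diploid genotypes per site ~ Binomial(2, AF) (HWE) |
| `uncallable_fraction` | 0 | per-individual fraction of sites emitting nothing in either frame |
| `depth`, `qual` | 30, 60 | constants above the filter thresholds, so filtering is a pass-through unless perturbed |
| `genotype_flip_prob` | 0 | noise hook: per-site chance the observed genotype moves to another dosage, shared across frames |
| `seed` | 42 | determines everything |

The **idealized caller** emits a record exactly where the observed
genotype differs from hom-ref *in the requested frame* — no reads, no
alignment, no base-quality model. This is deliberate: the FP/FN
phenomenon being measured is purely a reference-frame bookkeeping
artifact, and noiseless calls exercise it exactly. Consequently,
passing tests demonstrate the correctness of the selection,
substitution, translation and accounting algebra — not robustness to
alignment error, mapping bias near divergent sites, or caller-specific
genotype-likelihood behavior, none of which are modeled. Real
call-set rates will also differ numerically because the synthetic AF
spectrum is symmetric, whereas the real human spectrum concentrates
swap sites near AF 1.

`make_fixture` writes the cohort to disk (FASTA both frames, population
VCF, swap TSV, per-individual per-frame VCFs) plus a manifest with the
expected accounting row per individual, recounted *directly from the
genotype dosages* without building call records — an independent route
used as the oracle in end-to-end tests.

## Numerical and design choices

* Coordinates are 1-based on all domain objects (VCF convention);
  0-based indexing exists only inside sequence code and BED output.
* Deterministic ordering everywhere: chromosomes in FASTA order, sites
  by position; selection is idempotent.
* Histogram bins are half-open [lo, hi) with the last bin closed; a
  value on an interior edge falls upward. Bin width must divide 1.
* The density table includes the trailing partial window; per-
  chromosome counts conserve the swap-site total.
* Table inversion (for round trips) exchanges the two alleles and maps
  AF → 1 − AF; the result intentionally relaxes the AF > 0.5 invariant.
* The histogram's `which` parameter exposes both the alternate-allele
  and base-allele (1 − alt) frequency, defaulting to the base-allele
  view for swap tables, whose mass is entirely below 0.5 by the strict
  selection rule.
* CLI exit codes: 0 success, 1 usage error, 2 data error; every output
  carries `##majoref_*` provenance headers echoing the parameters.

## Problem sizes used in the checks

Acceptance-style checks run at: 100 random (genome, table) pairs of
≤3 × 150 bp for substitution round trips; 20 seeds × 1000 records for
the selection oracle; 50 single-individual cohorts (60 sites each) for
frame round trips; the default 2 × 100 kb / 2000-site / 20-individual
cohort for end-to-end self-consistency and the masking identity; and
2000 individuals at one AF-0.6 site for HWE recovery against the exact
central 99% binomial interval around f² = 0.36. These sizes make the
Monte-Carlo properties sharp while keeping the whole suite fast.

## Known limitations

* SNP-only: indels, MNPs, CNVs and translocations are never majorized
  (they would break the shared coordinate frame).
* Variants-only semantics: without a gVCF or callable mask, hom-ref
  and uncallable are indistinguishable; `project_homref` makes the
  optimistic assumption explicit rather than solving it.
* Symbolic/structural ALT alleles at swap sites are rejected, not
  translated.
* No annotation liftover: databases built against the base reference
  are not rebuilt for the majorized one.
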