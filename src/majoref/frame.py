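"""Translate variant calls between the base and majorized reference frames.

Both references share coordinates; they differ only in which allele is
REF at swap sites.  Translating a record at a swap site therefore
renumbers alleles rather than moving them: the target frame's reference
allele becomes index 0, the source frame's reference allele becomes the
first ALT, and the remaining ALTs keep their order.  A record whose
remapped genotype is homozygous index 0 is not a variant in the target
frame — this is exactly the hom-ref masking a variants-only caller
performs, and such records vanish from the translated call set.

Because a variants-only call set cannot distinguish "homozygous
reference" from "uncallable", the converse direction (resurrecting the
calls the source frame masked) is opt-in: with ``project_homref`` every
swap site absent from the call set — optionally restricted to a callable
mask — yields a synthesized hom-alt record in the target frame, flagged
as inferred and carrying sentinel quality/depth so it can never pass an
evidence filter.
"""

from __future__ import annotations

import logging
from typing import Iterable

from .models import (
    BASE_FRAME,
    MAJOR_FRAME,
    CallSet,
    MajorefError,
    ReferenceMismatchError,
    SwapSite,
    SwapTable,
    VariantCall,
)

logger = logging.getLogger(__name__)

MAJOR_TO_BASE = "major2base"
BASE_TO_MAJOR = "base2major"

#: Marker returned by :func:`translate_record` for records that are
#: homozygous reference in the target frame (not a variant there).
NON_VARIANT = None

_SOURCE_FRAME = {MAJOR_TO_BASE: MAJOR_FRAME, BASE_TO_MAJOR: BASE_FRAME}
_TARGET_FRAME = {MAJOR_TO_BASE: BASE_FRAME, BASE_TO_MAJOR: MAJOR_FRAME}

INFERRED_QUAL = -1.0
INFERRED_DEPTH = 0


def _is_symbolic(allele: str) -> bool:
    return allele.startswith("<") or "[" in allele or "]" in allele or allele == "*"


def translate_record(
    call: VariantCall, table: SwapTable, direction: str
) -> VariantCall | None:
    """Re-express one call in the other reference frame.

    At a non-swap position the record is returned unchanged.  At a swap
    site the REF/ALT lists are rebuilt around the target frame's
    reference allele (previous REF first among the ALTs, remaining ALTs
    in original order), genotype indices are remapped over the allele
    *strings* (which are frame-invariant), and phasing is preserved.
    Returns :data:`NON_VARIANT` (``None``) when the remapped genotype is
    homozygous reference in the target frame.
    """
    if direction not in _SOURCE_FRAME:
        raise ValueError(f"unknown direction {direction!r}")
    site = table.get(call.chrom, call.pos)
    if site is None:
        return call

    if direction == MAJOR_TO_BASE:
        expected_ref, new_ref = site.major_allele, site.base_allele
    else:
        expected_ref, new_ref = site.base_allele, site.major_allele

    if call.ref.upper() != expected_ref:
        raise ReferenceMismatchError(
            f"{call.chrom}:{call.pos}: call REF {call.ref!r} does not match the "
            f"swap table's {expected_ref!r} for direction {direction}"
        )
    for alt in call.alts:
        if _is_symbolic(alt):
            raise MajorefError(
                f"{call.chrom}:{call.pos}: symbolic/structural ALT {alt!r} "
                "unsupported at a swap site"
            )

    new_alts = (call.ref,) + tuple(a for a in call.alts if a.upper() != new_ref)
    index_of = {allele.upper(): i for i, allele in enumerate((new_ref,) + new_alts)}
    old_alleles = call.alleles
    new_genotype = tuple(
        None if i is None else index_of[old_alleles[i].upper()] for i in call.genotype
    )
    if all(i == 0 or i is None for i in new_genotype):
        return NON_VARIANT
    return call.with_(ref=new_ref, alts=new_alts, genotype=new_genotype)


def synthesize_homalt(site: SwapSite, direction: str, sample_id: str) -> VariantCall:
    """Inferred hom-alt record for a swap site absent from the source frame.

    Absence in the major frame means the individual is (assumed)
    homozygous for the major allele, which in the base frame is a hom-alt
    variant REF=base ALT=major; the base→major direction is the mirror.
    Sentinel quality/depth mark the record as inferred, not evidence.
    """
    if direction == MAJOR_TO_BASE:
        ref, alt = site.base_allele, site.major_allele
    else:
        ref, alt = site.major_allele, site.base_allele
    return VariantCall(
        chrom=site.chrom,
        pos=site.pos,
        ref=ref,
        alts=(alt,),
        genotype=(1, 1),
        phased=False,
        qual=INFERRED_QUAL,
        depth=INFERRED_DEPTH,
        sample_id=sample_id,
        inferred=True,
    )


def translate_callset(
    cs: CallSet,
    table: SwapTable,
    direction: str,
    project_homref: bool = False,
    callable_mask: Iterable[tuple[str, int, int]] | None = None,
) -> CallSet:
    """Translate every record of ``cs``; optionally project masked hom-refs.

    ``callable_mask`` is a collection of BED-style (chrom, start, end)
    intervals (0-based half-open) restricting where absence of a call is
    interpreted as homozygous reference.  Without a mask every swap site
    is assumed callable, which is stated loudly in the log because it is
    an optimistic assumption for real variants-only call sets.
    """
    if cs.frame != _SOURCE_FRAME[direction]:
        raise MajorefError(
            f"call set is in frame {cs.frame!r} but direction {direction} "
            f"expects {_SOURCE_FRAME[direction]!r}"
        )
    out = CallSet(frame=_TARGET_FRAME[direction], sample_id=cs.sample_id)
    n_masked = 0
    for call in cs:
        translated = translate_record(call, table, direction)
        if translated is NON_VARIANT:
            n_masked += 1
            continue
        out.add(translated)
    if n_masked:
        logger.info(
            "%d records are homozygous reference in the %s frame and were dropped",
            n_masked, _TARGET_FRAME[direction],
        )

    if project_homref:
        if callable_mask is None:
            logger.warning(
                "project_homref with no callable mask: assuming every swap site "
                "is callable; absent calls are treated as homozygous reference"
            )
            callable_at = None
        else:
            callable_at = _mask_lookup(callable_mask)
        sample = cs.sample_id or "sample"
        for site in table:
            if (site.chrom, site.pos) in cs:
                continue
            if callable_at is not None and not callable_at(site.chrom, site.pos):
                continue
            synthesized = synthesize_homalt(site, direction, sample)
            if synthesized.key in out.positions():
                raise AssertionError(
                    f"synthesized record collides with a translated one at "
                    f"{site.chrom}:{site.pos}"
                )
            out.add(synthesized)
    return out


def _mask_lookup(intervals: Iterable[tuple[str, int, int]]):
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(chrom, []).append((int(start), int(end)))

    def callable_at(chrom: str, pos: int) -> bool:
        # pos is 1-based; intervals are 0-based half-open
        return any(start < pos <= end for start, end in by_chrom.get(chrom, ()))

    return callable_at


def filter_calls(
    cs: CallSet,
    min_depth: int = 5,
    min_qual: float = 30.0,
    lenient_missing: bool = False,
) -> CallSet:
    """Keep records with depth >= ``min_depth`` and qual >= ``min_qual``.

    Records missing either field fail the filter unless
    ``lenient_missing`` is set.  Defaults match the standard evidence
    filter (read depth at least 5, variant quality at least 30); both
    bounds are inclusive.
    """
    if min_depth < 0 or min_qual < 0:
        raise ValueError("filter thresholds must be nonnegative")
    out = CallSet(frame=cs.frame, sample_id=cs.sample_id)
    n_dropped = 0
    for call in cs:
        depth_ok = call.depth is not None and call.depth >= min_depth
        qual_ok = call.qual is not None and call.qual >= min_qual
        if call.depth is None and lenient_missing:
            depth_ok = True
        if call.qual is None and lenient_missing:
            qual_ok = True
        if depth_ok and qual_ok:
            out.add(call)
        else:
            n_dropped += 1
    logger.info(
        "filter (DP>=%d, QUAL>=%g): kept %d, dropped %d",
        min_depth, min_qual, len(out), n_dropped,
    )
    return out
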