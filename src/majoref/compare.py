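"""Two-frame call-set accounting: totals, partitions, swap overlap, FP/FN.

Given one individual's filtered call sets against the base reference and
against the majorized reference, partition the calls by position into
common / unique-to-base / unique-to-major, intersect each partition with
the swap table, and derive the false-positive and false-negative
percentages attributable to minor alleles in the base reference:

* FP% — base-frame calls unique to that frame at swap positions, as a
  percentage of all base-frame calls: these merely restate the
  population-major allele.
* FN% — major-frame calls unique to that frame at swap positions, as a
  percentage of all major-frame calls: these are masked in the base
  frame by individuals homozygous for the base (minor) allele.

Matching is positional by default — both frames share coordinates —
with an optional allele-aware mode that additionally requires the same
carried allele multiset.
"""

from __future__ import annotations

import json
import logging

import pandas as pd

from .models import (
    CallSet,
    ComparisonReport,
    MajorefError,
    SwapTable,
    exact_percent,
    round_half_away,
)

logger = logging.getLogger(__name__)

Position = tuple[str, int]


def intersect_by_position(
    cs_base: CallSet, cs_major: CallSet, allele_aware: bool = False
) -> tuple[set[Position], set[Position], set[Position]]:
    """Partition the two call sets' positions into (common, unique_base, unique_major).

    In allele-aware mode a shared position only counts as common when
    both records carry the same multiset of allele strings in their
    genotypes (allele strings are frame-invariant, so this is a fair
    cross-frame comparison).
    """
    if cs_base.sample_id != cs_major.sample_id:
        raise MajorefError(
            f"sample mismatch: {cs_base.sample_id!r} vs {cs_major.sample_id!r}"
        )
    pos_base = cs_base.positions()
    pos_major = cs_major.positions()
    common = pos_base & pos_major
    if allele_aware:
        concordant = set()
        for key in common:
            a = sorted(x for x in cs_base.get(*key).genotype_alleles() if x is not None)
            b = sorted(x for x in cs_major.get(*key).genotype_alleles() if x is not None)
            if a == b:
                concordant.add(key)
        common = concordant
    return common, pos_base - common, pos_major - common


def overlap_with_swaps(positions: set[Position], table: SwapTable) -> int:
    """Number of positions present in the swap table."""
    table_positions = table.positions()
    return sum(1 for key in positions if key in table_positions)


def compute_rates(report: ComparisonReport) -> ComparisonReport:
    """Fill in fp_percent / fn_percent from the count columns.

    Percentages are computed at full precision (decimal division);
    display rounding to 3 decimals with ties away from zero is applied
    by the serializers.  Each rate needs its own positive denominator;
    a rate with a zero total stays ``None`` with a warning, and both
    totals being zero raises.
    """
    if report.total_base == 0 and report.total_major == 0:
        raise MajorefError(
            f"{report.sample_id}: cannot compute rates with zero totals in both frames"
        )
    if report.total_base > 0:
        report.fp_percent = exact_percent(report.unique_base_in_swaps, report.total_base)
    else:
        logger.warning("%s: total_base is zero; fp_percent is null", report.sample_id)
    if report.total_major > 0:
        report.fn_percent = exact_percent(report.unique_major_in_swaps, report.total_major)
    else:
        logger.warning("%s: total_major is zero; fn_percent is null", report.sample_id)
    return report


def comparison_report(
    cs_base: CallSet,
    cs_major: CallSet,
    table: SwapTable,
    sample_id: str | None = None,
    allele_aware: bool = False,
) -> ComparisonReport:
    """Assemble the full per-sample accounting row.

    Inputs are expected to be already filtered (``filter_calls``) — the
    evidence filter precedes intersection.  When both totals are zero
    the percentages are left as ``None`` with a warning rather than
    raising, so empty samples still produce a (degenerate) row.
    """
    common, unique_base, unique_major = intersect_by_position(
        cs_base, cs_major, allele_aware=allele_aware
    )
    report = ComparisonReport(
        sample_id=sample_id or cs_base.sample_id or "sample",
        total_base=len(cs_base),
        total_major=len(cs_major),
        common=len(common),
        unique_base=len(unique_base),
        unique_major=len(unique_major),
        common_in_swaps=overlap_with_swaps(common, table),
        unique_base_in_swaps=overlap_with_swaps(unique_base, table),
        unique_major_in_swaps=overlap_with_swaps(unique_major, table),
    )
    if not allele_aware:
        report.validate_partition()
    try:
        compute_rates(report)
    except MajorefError as exc:
        logger.warning("%s; percentages reported as null", exc)
    return report


def venn_fractions(report: ComparisonReport) -> dict[str, float | None]:
    """Swap-overlap fractions of the partitions (pure arithmetic).

    Returns the fraction of common calls at swap positions, the swap
    fraction of each unique partition, and the fraction of all
    base-frame calls at swap positions.  Zero denominators yield None
    with a warning.
    """

    def frac(num: int, den: int, label: str) -> float | None:
        if den == 0:
            logger.warning("%s: zero denominator for %s; reporting null", report.sample_id, label)
            return None
        return num / den

    return {
        "common_swap_fraction": frac(report.common_in_swaps, report.common, "common"),
        "unique_base_swap_fraction": frac(
            report.unique_base_in_swaps, report.unique_base, "unique_base"
        ),
        "unique_major_swap_fraction": frac(
            report.unique_major_in_swaps, report.unique_major, "unique_major"
        ),
        "base_calls_swap_fraction": frac(
            report.common_in_swaps + report.unique_base_in_swaps,
            report.total_base,
            "total_base",
        ),
    }


def _display_row(report: ComparisonReport) -> dict:
    row = report.to_dict()
    for key in ("fp_percent", "fn_percent"):
        if row[key] is not None:
            row[key] = round_half_away(row[key], 3)
    return row


def reports_to_frame(reports: list[ComparisonReport]) -> pd.DataFrame:
    """Tabulate reports, one row per sample, in the canonical column order."""
    return pd.DataFrame([_display_row(r) for r in reports], columns=ComparisonReport.COLUMNS)


def write_report_tsv(reports: list[ComparisonReport], path, header_lines=()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"##{line.lstrip('#')}\n")
        frame = reports_to_frame(reports)
        for key in ("fp_percent", "fn_percent"):
            frame[key] = frame[key].map(lambda v: "NA" if pd.isna(v) else f"{v:.3f}")
        frame.to_csv(fh, sep="\t", index=False)


def write_report_json(reports: list[ComparisonReport], path) -> None:
    with open(path, "w") as fh:
        json.dump([_display_row(r) for r in reports], fh, indent=2)
        fh.write("\n")
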