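"""Published per-sample accounting rows, frozen as test inputs/expectations.

Column order: total_base, total_major, common, unique_base, unique_major,
common_in_swaps, unique_base_in_swaps, unique_major_in_swaps, then the
published FP and FN percentages (printed at 3 decimals).  The count
columns serve as inputs; the two percentage columns are the expected
output of the rate formula.

Row "S1" is known to violate the partition identity as printed
(common + unique_base exceeds total_base by 57); its rates still follow
the same formula from the printed counts.
"""

ROWS = {
    "T2": (3523566, 2706277, 2464798, 1058768, 241479, 528792, 1054623, 231312, "29.931", "8.547"),
    "T5": (3576580, 2739673, 2510844, 1065736, 228829, 533822, 1061286, 218090, "29.673", "7.960"),
    "T7": (3526146, 2703089, 2465770, 1060376, 237319, 531096, 1056067, 226438, "29.950", "8.377"),
    "T9": (3514195, 2688450, 2455194, 1059001, 233256, 525819, 1054619, 222620, "30.010", "8.281"),
    "T18": (3566071, 2727320, 2496670, 1069401, 230650, 533797, 1065220, 220366, "29.871", "8.080"),
    "S1": (3297701, 2448217, 2198875, 1098883, 249342, 417178, 1094338, 238850, "33.185", "9.756"),
    "S7": (2960779, 2149583, 1865248, 1095531, 284335, 304256, 1090309, 273521, "36.825", "12.724"),
    "S1_bwa": (3708065, 2837119, 2587491, 1120574, 249628, 467586, 1105687, 229644, "29.818", "8.094"),
    "S7_bwa": (3646224, 2782382, 2513539, 1132685, 268843, 432290, 1114869, 245991, "30.576", "8.841"),
}


def as_report(sample_id):
    from majoref import ComparisonReport

    tb, tm, c, ub, um, cs, ubs, ums, _, _ = ROWS[sample_id]
    return ComparisonReport(
        sample_id=sample_id,
        total_base=tb,
        total_major=tm,
        common=c,
        unique_base=ub,
        unique_major=um,
        common_in_swaps=cs,
        unique_base_in_swaps=ubs,
        unique_major_in_swaps=ums,
    )
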