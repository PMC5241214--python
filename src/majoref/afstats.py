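"""Allele-frequency histograms and swap-site density along chromosomes."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .models import MajorefError, PopulationSite, SwapSite, SwapTable

BASE_ALLELE_FREQ = "base_allele_freq"
ALT_ALLELE_FREQ = "alt_allele_freq"


@dataclass
class AFHistogram:
    """Counts of sites per allele-frequency bin.

    Bins are half-open [lo, hi) except the last, which is closed so a
    frequency of exactly 1.0 is counted.  A frequency exactly on an
    interior edge falls in the upper bin.
    """

    bin_edges: np.ndarray
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "count": self.counts,
            }
        )


@dataclass
class ChromDensity:
    """Swap-site counts in fixed-width windows along each chromosome.

    The trailing partial window is included; per-chromosome counts sum
    to that chromosome's swap-site total.
    """

    window_size: int
    counts: dict[str, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": chrom,
                "window_start": i * self.window_size,
                "window_size": self.window_size,
                "count": int(c),
            }
            for chrom, per_window in self.counts.items()
            for i, c in enumerate(per_window)
        ]
        return pd.DataFrame(rows, columns=["chrom", "window_start", "window_size", "count"])


def _frequencies(sites, which: str) -> np.ndarray:
    freqs = []
    for site in sites:
        if isinstance(site, SwapSite):
            alt_af = site.major_af
        elif isinstance(site, PopulationSite):
            if len(site.alt_afs) != 1:
                raise MajorefError(
                    f"{site.chrom}:{site.pos}: histogram requires biallelic sites; "
                    f"got {len(site.alt_afs)} ALT frequencies"
                )
            alt_af = site.alt_afs[0]
        else:
            raise TypeError(f"unsupported site type {type(site).__name__}")
        freqs.append(1.0 - alt_af if which == BASE_ALLELE_FREQ else alt_af)
    return np.asarray(freqs, dtype=float)


def af_histogram(
    sites: Iterable[PopulationSite] | SwapTable,
    which: str = BASE_ALLELE_FREQ,
    bin_width: float = 0.1,
) -> AFHistogram:
    """Histogram of allele frequencies over [0, 1].

    ``which`` selects the frequency plotted: the alternate allele's, or
    the base (reference) allele's, i.e. 1 - alt AF.  For a swap table
    the alternate allele is the major allele, so the base-allele
    frequency is the minor-allele frequency of the swapped-out base —
    always below 0.5 by the strict selection rule.  ``bin_width`` must
    divide 1 evenly.
    """
    if which not in (BASE_ALLELE_FREQ, ALT_ALLELE_FREQ):
        raise ValueError(f"unknown frequency choice {which!r}")
    n_bins = round(1.0 / bin_width)
    if n_bins < 1 or abs(n_bins * bin_width - 1.0) > 1e-9:
        raise MajorefError(f"bin width {bin_width} does not divide 1 evenly")
    freqs = _frequencies(sites, which)
    if freqs.size and (freqs.min() < 0 or freqs.max() > 1):
        raise MajorefError("frequencies outside [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(freqs, bins=edges)
    return AFHistogram(bin_edges=edges, counts=counts)


def swap_density(
    table: SwapTable,
    genome_lengths: Mapping[str, int],
    window_size: int = 1_000_000,
) -> ChromDensity:
    """Swap sites per fixed-width window, for every chromosome in ``genome_lengths``."""
    if window_size < 1:
        raise ValueError(f"window size must be >= 1, got {window_size}")
    counts: dict[str, np.ndarray] = {
        chrom: np.zeros(max(1, -(-length // window_size)), dtype=np.int64)
        for chrom, length in genome_lengths.items()
    }
    for site in table:
        if site.chrom not in counts:
            raise MajorefError(f"swap table chromosome {site.chrom!r} absent from lengths")
        counts[site.chrom][(site.pos - 1) // window_size] += 1
    return ChromDensity(window_size=window_size, counts=counts)
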