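"""Single-genotype low-heterozygosity (autozygosity) scan.

Windows of fixed size (1 Mb in the motivating analysis) are scored by the
number of heterozygous calls of one focal sample; windows below a
genome-wide percentile of that count distribution are flagged and runs of
adjacent flagged windows are merged into candidate autozygous regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from walnutkit.io_windows import (
    GenotypeMatrix,
    Window,
    count_snps_per_window,
    tile_windows,
)


@dataclass(frozen=True)
class LowHetRegion:
    chrom: str
    start: int
    end: int
    n_windows: int
    total_het_snps: int
    threshold: float


def low_het_threshold(window_counts, percentile: float = 10.0) -> float:
    """Empirical percentile (linear interpolation) of per-window SNP counts.

    Fractional thresholds (e.g. 377.5) arise naturally from the
    interpolation.  Counts from partial terminal windows should be excluded
    by the caller before estimation.
    """
    counts = np.asarray(window_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("cannot take a percentile of zero windows")
    if counts.size < 10:
        warnings.warn("fewer than 10 windows: percentile threshold is unstable")
    return float(np.percentile(counts, percentile))


def call_low_het_regions(
    windows: list[Window],
    window_counts,
    threshold: float,
) -> list[LowHetRegion]:
    """Flag windows with count strictly below ``threshold``; merge adjacent runs.

    "Adjacent" means sharing a boundary on the same chromosome; regions
    never span chromosomes.  Merging is order-independent and idempotent.
    """
    counts = np.asarray(window_counts)
    if counts.size != len(windows):
        raise ValueError("one count per window required")
    order = sorted(range(len(windows)), key=lambda i: (windows[i].chrom, windows[i].start))
    regions: list[LowHetRegion] = []
    cur: dict | None = None
    for i in order:
        w, c = windows[i], counts[i]
        flagged = c < threshold
        if flagged and cur is not None and w.chrom == cur["chrom"] and w.start == cur["end"]:
            cur["end"] = w.end
            cur["n"] += 1
            cur["tot"] += int(c)
        elif flagged:
            if cur is not None:
                regions.append(_close(cur, threshold))
            cur = {"chrom": w.chrom, "start": w.start, "end": w.end, "n": 1, "tot": int(c)}
        else:
            if cur is not None:
                regions.append(_close(cur, threshold))
                cur = None
    if cur is not None:
        regions.append(_close(cur, threshold))
    return regions


def _close(cur: dict, threshold: float) -> LowHetRegion:
    return LowHetRegion(
        cur["chrom"], cur["start"], cur["end"], cur["n"], cur["tot"], threshold
    )


def low_het_scan(
    mat: GenotypeMatrix,
    focal_sample: str | None = None,
    window_size: int = 1_000_000,
    percentile: float = 10.0,
) -> tuple[np.ndarray, list[Window], float, list[LowHetRegion]]:
    """End-to-end scan: tile, count heterozygous calls, threshold, merge.

    Partial terminal windows are excluded from threshold estimation but
    still flagged after rescaling their count by size/actual_length, which
    avoids spurious flags at chromosome ends.  Returns
    ``(counts, windows, threshold, regions)``.
    """
    if mat.chrom_lengths is None:
        raise ValueError("matrix lacks chromosome lengths")
    windows = tile_windows(mat.chrom_lengths, window_size)
    counts = count_snps_per_window(
        mat, windows, heterozygous_only=True, focal_sample=focal_sample
    )
    full = np.asarray([not w.partial for w in windows])
    threshold = low_het_threshold(counts[full], percentile)
    scaled = counts.astype(float)
    for i, w in enumerate(windows):
        if w.partial:
            scaled[i] = counts[i] * window_size / w.length
    regions = call_low_het_regions(windows, scaled, threshold)
    return counts, windows, threshold, regions


def regions_to_bed(regions: list[LowHetRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t"
                f"n_windows={r.n_windows};het_snps={r.total_het_snps}\n"
            )
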