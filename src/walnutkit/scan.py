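"""Genome-wide divergence scan: F_ST outliers, permutation FDR, sweeps.

The scan flags windows in the top quantile (default 5%) of the windowed
Weir–Cockerham F_ST distribution, estimates an empirical false-discovery
rate by permuting individual -> population labels genome-wide, classifies
outlier windows into candidate selective sweeps by the sign of per-group
Tajima's D, and intersects outlier windows with known trait-associated
loci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from walnutkit.io_windows import GenotypeMatrix, Window, assign_sites
from walnutkit.stats import wc_fst_components


@dataclass
class ScanConfig:
    window_size: int = 100_000
    outlier_quantile: float = 0.95
    n_permutations: int = 1000
    seed: int = 0
    min_snps: int | None = None  # optional per-window SNP mask (default off)

    def __post_init__(self) -> None:
        if not 0.0 < self.outlier_quantile < 1.0:
            raise ValueError("outlier_quantile must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass(frozen=True)
class OutlierCall:
    window: Window
    fst: float
    is_outlier: bool
    cutoff_used: float


@dataclass(frozen=True)
class TraitLocus:
    marker: str
    chrom: str
    position: int  # 1-based bp
    trait: str


def call_fst_outliers(
    windows: list[Window],
    window_fsts,
    quantile: float = 0.95,
) -> tuple[float, list[OutlierCall]]:
    """Flag windows at or above the empirical F_ST quantile.

    The cutoff is the linear-interpolation quantile of the defined window
    values; windows with undefined (NaN) F_ST are never flagged.  Fewer
    than 20 defined windows make the cutoff unstable (warning); none is an
    error.
    """
    fsts = np.asarray(window_fsts, dtype=float)
    defined = np.isfinite(fsts)
    if not defined.any():
        raise ValueError("no windows with defined F_ST")
    if defined.sum() < 20:
        warnings.warn("fewer than 20 defined windows: quantile cutoff unstable")
    cutoff = float(np.quantile(fsts[defined], quantile))
    if np.isclose(fsts[defined].min(), fsts[defined].max()):
        warnings.warn("all window F_ST values equal: every window is flagged")
    calls = [
        OutlierCall(w, float(f), bool(defined[i] and f >= cutoff), cutoff)
        for i, (w, f) in enumerate(zip(windows, fsts))
    ]
    return cutoff, calls


def _windowed_fst_matrix(
    calls: np.ndarray,
    windows: list[Window],
    idx1: np.ndarray,
    idx2: np.ndarray,
) -> np.ndarray:
    """Ratio-of-sums F_ST per window from per-site components (vectorized)."""
    a, b, c, defined = wc_fst_components(calls, idx1, idx2)
    num = np.where(defined, a, 0.0)
    den = np.where(defined, a + b + c, 0.0)
    cnum = np.concatenate([[0.0], np.cumsum(num)])
    cden = np.concatenate([[0.0], np.cumsum(den)])
    out = np.full(len(windows), np.nan)
    for i, w in enumerate(windows):
        d = cden[w.site_end] - cden[w.site_start]
        if d != 0:
            out[i] = (cnum[w.site_end] - cnum[w.site_start]) / d
    return out


def windowed_fst(
    mat: GenotypeMatrix,
    windows: list[Window],
    group1: str,
    group2: str,
) -> np.ndarray:
    windows = assign_sites(windows, mat)
    gidx = mat.group_indices()
    return _windowed_fst_matrix(mat.calls, windows, gidx[group1], gidx[group2])


def permutation_fdr(
    mat: GenotypeMatrix,
    windows: list[Window],
    group1: str,
    group2: str,
    observed_cutoff: float,
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict:
    """Empirical FDR of the outlier cutoff by genome-wide label permutation.

    Each permutation shuffles the individual -> population assignment
    across all samples (group sizes preserved; LD within individuals is
    left intact), recomputes windowed F_ST genome-wide and counts windows
    at or above ``observed_cutoff``.  The FDR estimate is the
    expected-null-count ratio: mean permuted count / observed count.
    Deterministic given ``seed``.
    """
    windows = assign_sites(windows, mat)
    gidx = mat.group_indices()
    idx1, idx2 = gidx[group1], gidx[group2]
    pooled = np.concatenate([idx1, idx2])
    n1 = idx1.size

    observed = _windowed_fst_matrix(mat.calls, windows, idx1, idx2)
    n_observed = int(np.nansum(observed >= observed_cutoff))

    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_permutations, dtype=np.int64)
    for k in range(n_permutations):
        perm = rng.permutation(pooled)
        f = _windowed_fst_matrix(mat.calls, windows, perm[:n1], perm[n1:])
        null_counts[k] = int(np.nansum(f >= observed_cutoff))
    mean_null = float(null_counts.mean())
    fdr = float("nan") if n_observed == 0 else min(1.0, mean_null / n_observed)
    if n_observed == 0:
        warnings.warn("zero observed outliers: FDR undefined")
    return {
        "fdr": fdr,
        "mean_null_count": mean_null,
        "n_observed": n_observed,
        "null_counts": null_counts,
    }


def classify_sweeps(stats_df: pd.DataFrame) -> pd.DataFrame:
    """Classify F_ST-outlier windows into candidate selective sweeps.

    Expects the :func:`walnutkit.stats.windowed_stats` two-group columns
    plus a boolean ``is_outlier`` column.  An outlier window is a sweep
    candidate in group 1 when its group-1 Tajima's D is negative, and/or in
    group 2 when group-2 D is negative; ROD (1 - pi_g1/pi_g2) is carried
    along.  Windows with missing group statistics are flagged
    ``unclassified``.
    """
    df = stats_df.loc[stats_df["is_outlier"]].copy()
    d1, d2 = df["g1_tajima_d"], df["g2_tajima_d"]
    df["sweep_g1"] = d1 < 0
    df["sweep_g2"] = d2 < 0
    df["unclassified"] = d1.isna() & d2.isna()
    df["direction"] = np.select(
        [
            df["unclassified"],
            df["sweep_g1"] & df["sweep_g2"],
            df["sweep_g1"],
            df["sweep_g2"],
        ],
        ["unclassified", "both", "group1", "group2"],
        default="none",
    )
    return df


def overlap_trait_loci(
    stats_df: pd.DataFrame,
    loci: list[TraitLocus],
) -> pd.DataFrame:
    """Assign trait-associated loci to the half-open windows containing them.

    Reports, per locus, the containing window's F_ST, ROD and group D
    values and whether that window is an outlier; loci on chromosomes
    absent from the scan are reported as unplaced.
    """
    rows = []
    for locus in loci:
        pos0 = locus.position - 1
        hit = stats_df[
            (stats_df["chrom"] == locus.chrom)
            & (stats_df["start"] <= pos0)
            & (pos0 < stats_df["end"])
        ]
        if hit.empty:
            rows.append(
                {
                    "marker": locus.marker,
                    "trait": locus.trait,
                    "chrom": locus.chrom,
                    "position": locus.position,
                    "placed": False,
                    "in_outlier_window": False,
                }
            )
            continue
        for _, w in hit.iterrows():
            rows.append(
                {
                    "marker": locus.marker,
                    "trait": locus.trait,
                    "chrom": locus.chrom,
                    "position": locus.position,
                    "placed": True,
                    "window_start": int(w["start"]),
                    "window_end": int(w["end"]),
                    "fst": w.get("fst", float("nan")),
                    "rod": w.get("rod", float("nan")),
                    "g1_tajima_d": w.get("g1_tajima_d", float("nan")),
                    "g2_tajima_d": w.get("g2_tajima_d", float("nan")),
                    "in_outlier_window": bool(w.get("is_outlier", False)),
                }
            )
    return pd.DataFrame(rows)
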