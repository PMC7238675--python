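"""Single-window population-genetic statistics from their defining formulas.

Implements nucleotide diversity (pi), Tajima's D, Weir–Cockerham F_ST
variance components with the ratio-of-sums ("weighted") windowed estimator,
and the reduction-of-diversity coefficient ROD = 1 - pi1/pi2.  All
estimators are computed directly from allele counts; no external popgen
tool is called.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from walnutkit.io_windows import MISSING, GenotypeMatrix, Window, assign_sites


# ---------------------------------------------------------------------------
# per-site building blocks


def site_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (n_diploids_called, alt_frequency, het_frequency).

    ``calls`` is a sites x samples dosage slice; frequency entries are NaN
    where no diploid is called.
    """
    calls = np.atleast_2d(calls)
    called = calls != MISSING
    n = called.sum(axis=1).astype(np.float64)
    alt = np.where(called, calls, 0).sum(axis=1).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
        h = np.where(n > 0, (calls == 1).sum(axis=1) / n, np.nan)
    return n, p, h


def site_pi_terms(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site mean pairwise difference 2c(k-c)/(k(k-1)) over chromosomes.

    ``k`` is the per-site count of non-missing chromosomes (2 x called
    diploids) and ``c`` the alt-allele count.  Returns ``(terms, skipped)``
    where sites with k < 2 contribute 0 and are flagged in ``skipped``.
    """
    calls = np.atleast_2d(calls)
    called = calls != MISSING
    k = 2.0 * called.sum(axis=1)
    c = np.where(called, calls, 0).sum(axis=1).astype(np.float64)
    skipped = k < 2
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(skipped, 0.0, 2.0 * c * (k - c) / (k * (k - 1.0)))
    return terms, skipped


def window_pi(mat: GenotypeMatrix, window: Window, sample_idx=None) -> float:
    """Nucleotide diversity per bp over a window.

    Monomorphic and unobserved positions contribute 0 to the numerator but
    the full window length is the denominator (windowed-pi convention).
    """
    (window,) = assign_sites([window], mat)
    calls = mat.calls[window.site_start : window.site_end]
    if sample_idx is not None:
        calls = calls[:, sample_idx]
    terms, _ = site_pi_terms(calls)
    return float(terms.sum() / window.length)


# ---------------------------------------------------------------------------
# Tajima's D


@dataclass(frozen=True)
class TajimaConstants:
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    """The 1989 normalizing constants for a sample of ``n`` chromosomes."""
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4 chromosomes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(a1, a2, b1, b2, c1, c2, e1, e2)


def tajima_d(n_chromosomes: int, S: int, pi_sum: float) -> float:
    """Tajima's D from sample size, segregating sites and mean pairwise diff.

    ``pi_sum`` is the mean number of pairwise differences summed over sites
    (not per bp).  Returns NaN when ``S`` = 0 (the statistic is undefined).
    """
    if S < 0:
        raise ValueError("S must be non-negative")
    k = tajima_constants(int(n_chromosomes))
    if S == 0:
        return float("nan")
    var = k.e1 * S + k.e2 * S * (S - 1.0)
    return float((pi_sum - S / k.a1) / np.sqrt(var))


# ---------------------------------------------------------------------------
# Weir–Cockerham F_ST


def wc_fst_components(
    calls: np.ndarray, idx1: np.ndarray, idx2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir–Cockerham (1984) variance components for 2 populations.

    Returns ``(a, b, c, defined)``: the among-population, among-individual
    and within-individual components and a mask of sites where both
    populations have at least one called diploid and the formulas are
    defined (at least 2 diploids in total).  Undefined sites carry NaN.
    """
    calls = np.atleast_2d(calls)
    r = 2.0
    n1, p1, h1 = site_counts(calls[:, idx1])
    n2, p2, h2 = site_counts(calls[:, idx2])
    defined = (n1 > 0) & (n2 > 0) & (n1 + n2 > 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        inner = pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0
        a = (nbar / nc) * (s2 - inner / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
    nan = np.where(defined, 0.0, np.nan)
    return a + nan, b + nan, c + nan, defined


def wc_fst_site(
    calls: np.ndarray, idx1: np.ndarray, idx2: np.ndarray
) -> tuple[float, float, float]:
    """Variance components (a, b, c) for a single site."""
    a, b, c, defined = wc_fst_components(np.atleast_2d(calls), idx1, idx2)
    if not defined[0]:
        return float("nan"), float("nan"), float("nan")
    return float(a[0]), float(b[0]), float(c[0])


def fst_from_components(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Ratio-of-sums estimate sum(a)/sum(a+b+c) over defined sites.

    Sites with undefined (NaN) components are excluded from both numerator
    and denominator.  Negative estimates are reported as computed.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    denom = (a[ok] + b[ok] + c[ok]).sum()
    if not ok.any() or denom == 0:
        return float("nan")
    return float(a[ok].sum() / denom)


def window_fst(
    mat: GenotypeMatrix, window: Window, idx1: np.ndarray, idx2: np.ndarray
) -> float:
    (window,) = assign_sites([window], mat)
    calls = mat.calls[window.site_start : window.site_end]
    a, b, c, _ = wc_fst_components(calls, idx1, idx2)
    return fst_from_components(a, b, c)


# ---------------------------------------------------------------------------
# ROD


def rod(pi_group1: float, pi_group2: float) -> float:
    """Reduction-of-diversity coefficient 1 - pi_group1/pi_group2.

    Group 1 is the putatively diversity-reduced group (the "Occidental"
    slot in the walnut analysis).  Undefined (NaN) when pi_group2 = 0 or
    either input is NaN.
    """
    if not np.isfinite(pi_group1) or not np.isfinite(pi_group2) or pi_group2 == 0:
        return float("nan")
    return float(1.0 - pi_group1 / pi_group2)


# ---------------------------------------------------------------------------
# windowed table


def _modal_chrom_count(k: np.ndarray) -> int:
    """Most frequent per-site chromosome count (ties -> largest)."""
    vals, counts = np.unique(k, return_counts=True)
    return int(vals[counts == counts.max()].max())


def windowed_stats(
    mat: GenotypeMatrix,
    windows: list[Window],
    group1: str | None = None,
    group2: str | None = None,
) -> pd.DataFrame:
    """Per-window pi, S, Tajima's D, F_ST and ROD as a tidy DataFrame.

    With ``group1``/``group2`` set (population labels in ``mat.groups``),
    per-group pi and D, the Weir–Cockerham windowed F_ST and
    ROD = 1 - pi_g1/pi_g2 are included.  Tajima's D uses
    n = 2 x samples when the window has no missing data and otherwise the
    per-window modal chromosome count (flagged in ``d_n_modal``).
    """
    windows = assign_sites(windows, mat)
    two_group = group1 is not None and group2 is not None
    if two_group:
        gidx = mat.group_indices()
        idx1, idx2 = gidx[group1], gidx[group2]

    rows = []
    for w in windows:
        calls = mat.calls[w.site_start : w.site_end]
        row: dict = {
            "chrom": w.chrom,
            "start": w.start,
            "end": w.end,
            "partial": w.partial,
            "n_snps": w.n_sites,
        }
        row.update(_pi_s_d(calls, w.length, prefix=""))
        if two_group:
            row.update(_pi_s_d(calls[:, idx1], w.length, prefix="g1_"))
            row.update(_pi_s_d(calls[:, idx2], w.length, prefix="g2_"))
            a, b, c, _ = wc_fst_components(calls, idx1, idx2)
            row["fst"] = fst_from_components(a, b, c)
            row["rod"] = rod(row["g1_pi"], row["g2_pi"])
        rows.append(row)
    return pd.DataFrame(rows)


def _pi_s_d(calls: np.ndarray, length: int, prefix: str) -> dict:
    terms, skipped = site_pi_terms(calls)
    seg = terms > 0
    S = int(seg.sum())
    out = {
        f"{prefix}pi": float(terms.sum() / length),
        f"{prefix}S": S,
    }
    if calls.shape[0] == 0 or S == 0:
        out[f"{prefix}tajima_d"] = float("nan")
        out[f"{prefix}d_n_modal"] = False
        return out
    called = calls != MISSING
    k = 2 * called.sum(axis=1)
    full = 2 * calls.shape[1]
    if (k == full).all():
        n = full
        modal = False
    else:
        n = _modal_chrom_count(k[~skipped]) if (~skipped).any() else 0
        modal = True
    if n < 4:
        out[f"{prefix}tajima_d"] = float("nan")
    else:
        out[f"{prefix}tajima_d"] = tajima_d(n, S, float(terms.sum()))
    out[f"{prefix}d_n_modal"] = modal
    return out
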