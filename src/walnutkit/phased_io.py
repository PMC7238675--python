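"""Wide-TSV serialisation of phased marker alleles.

Layout: one marker per row with columns ``marker``, ``chrom``, ``bp``,
then a ``<individual>_hapA`` / ``<individual>_hapB`` pair per individual
(hapA = maternal, hapB = paternal).  Missing alleles are the
:data:`walnutkit.synth.HAP_MISSING` sentinel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from walnutkit.synth import HAP_MISSING


def write_phased_tsv(phased: dict, marker_table: pd.DataFrame, path) -> None:
    """``phased`` maps individual -> chrom -> (2, n_markers) allele arrays;
    ``marker_table`` needs columns (marker, chrom or lg, bp) ordered to
    match the arrays chromosome by chromosome."""
    tab = marker_table.rename(columns={"lg": "chrom"})
    out = tab[["marker", "chrom", "bp"]].copy()
    for ind, per_chrom in phased.items():
        col_a, col_b = [], []
        for chrom in dict.fromkeys(tab["chrom"]):
            alle = per_chrom[chrom]
            col_a.extend(alle[0].tolist())
            col_b.extend(alle[1].tolist())
        out[f"{ind}_hapA"] = col_a
        out[f"{ind}_hapB"] = col_b
    out.to_csv(path, sep="\t", index=False)


def read_phased_tsv(path) -> tuple[dict, pd.DataFrame]:
    """Inverse of :func:`write_phased_tsv`.

    Returns ``(phased, marker_table)`` with the same in-memory layout the
    simulator produces.
    """
    df = pd.read_csv(path, sep="\t")
    marker_table = df[["marker", "chrom", "bp"]].copy()
    inds = sorted(
        {c[:-5] for c in df.columns if c.endswith("_hapA")}
    )
    chroms = list(dict.fromkeys(df["chrom"]))
    phased: dict = {}
    for ind in inds:
        phased[ind] = {}
        for chrom in chroms:
            sub = df[df["chrom"] == chrom]
            phased[ind][chrom] = np.vstack(
                [
                    sub[f"{ind}_hapA"].fillna(HAP_MISSING).to_numpy(dtype=np.int16),
                    sub[f"{ind}_hapB"].fillna(HAP_MISSING).to_numpy(dtype=np.int16),
                ]
            )
    return phased, marker_table
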