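"""Scaffold anchoring to a genetic map, AGP building, Marey-map rates.

Probe (marker) alignments to scaffolds are filtered (identity >= 98%,
probe coverage >= 95%, single hit), scaffolds are assigned to linkage
groups by the modal LG of their retained markers, ordered by mean marker
cM, oriented by the sign of the rank correlation between marker cM and
scaffold bp, and concatenated into AGP v2.1 pseudomolecules with
fixed-length 100,000-nt gaps.  Recombination rates are least-squares
Marey-map slopes (cM on Mb) in sliding windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class ProbeAlignment:
    probe: str
    target: str
    start: int
    end: int
    identity: float  # percent, 0..100
    coverage: float  # fraction of probe length, 0..1
    n_hits: int


@dataclass
class AnchoredScaffold:
    scaffold: str
    length: int
    lg: str
    orientation: str  # "+", "-", or "unknown" (laid out as "+")
    order_key: float  # mean cM of supporting markers
    n_markers: int
    lg_conflict: bool = False


def alignments_frame(alignments) -> pd.DataFrame:
    if isinstance(alignments, pd.DataFrame):
        return alignments
    return pd.DataFrame([a.__dict__ for a in alignments])


def filter_probe_alignments(
    alignments,
    min_identity: float = 98.0,
    min_coverage: float = 0.95,
    unique_only: bool = True,
) -> pd.DataFrame:
    """Retain alignments with identity >= 98, coverage >= 0.95, single hit.

    Boundary values pass: the rule filters OUT records below the
    thresholds.  Idempotent; the retained set is a subset of the input.
    """
    df = alignments_frame(alignments)
    keep = (df["identity"] >= min_identity) & (df["coverage"] >= min_coverage)
    if unique_only:
        keep &= df["n_hits"] == 1
    return df.loc[keep].reset_index(drop=True)


def assign_order_orient(
    retained: pd.DataFrame,
    genetic_map: pd.DataFrame,
    scaffold_lengths: dict[str, int],
    min_mode_fraction: float = 2 / 3,
) -> tuple[list[AnchoredScaffold], list[str]]:
    """Assign scaffolds to linkage groups, order and orient them.

    LG assignment is the modal LG of a scaffold's retained markers, and is
    accepted only when the mode holds more than ``min_mode_fraction`` of
    them (otherwise the scaffold is left unanchored with a conflict flag).
    Order within an LG is by mean marker cM.  Orientation is the sign of
    the Spearman rank correlation between marker cM and scaffold bp
    (positive "+", negative "-"); fewer than 2 distinct cM or bp positions
    give "unknown", laid out as "+".
    """
    merged = retained.merge(
        genetic_map[["marker", "lg", "cm"]],
        left_on="probe",
        right_on="marker",
        how="inner",
    )
    anchored: list[AnchoredScaffold] = []
    unanchored: list[str] = []
    for scaffold in scaffold_lengths:
        sub = merged[merged["target"] == scaffold]
        if sub.empty:
            unanchored.append(scaffold)
            continue
        mode = sub["lg"].mode().iloc[0]
        frac = (sub["lg"] == mode).mean()
        if sub["lg"].nunique() > 1 and frac <= min_mode_fraction:
            unanchored.append(scaffold)
            anchored.append(
                AnchoredScaffold(
                    scaffold, scaffold_lengths[scaffold], mode, "unknown",
                    float("nan"), len(sub), lg_conflict=True,
                )
            )
            continue
        sub = sub[sub["lg"] == mode]
        cm = sub["cm"].to_numpy(dtype=float)
        bp = sub["start"].to_numpy(dtype=float)
        if np.unique(cm).size < 2 or np.unique(bp).size < 2:
            orient = "unknown"
        else:
            rho = sps.spearmanr(bp, cm).statistic
            orient = "unknown" if rho == 0 or np.isnan(rho) else ("+" if rho > 0 else "-")
        anchored.append(
            AnchoredScaffold(
                scaffold, scaffold_lengths[scaffold], mode, orient,
                float(cm.mean()), len(sub),
            )
        )
    anchored = [a for a in anchored if not a.lg_conflict] + [
        a for a in anchored if a.lg_conflict
    ]
    return anchored, unanchored


class AGPLayout:
    """AGP v2.1 layout of pseudomolecules with exact coordinate lifting.

    Gap rows are fixed-length "N" gaps of type contig (the gap length is
    known by construction).  Scaffolds with unknown orientation are laid
    out as "+".
    """

    def __init__(self, rows: pd.DataFrame):
        self.rows = rows
        comp = rows[rows["component_type"] == "W"]
        self._by_scaffold = {
            r["component_id"]: r for _, r in comp.iterrows()
        }

    def objects(self) -> list[str]:
        return list(dict.fromkeys(self.rows["object"]))

    def object_length(self, obj: str) -> int:
        return int(self.rows.loc[self.rows["object"] == obj, "object_end"].max())

    def lift(self, scaffold: str, pos: int) -> tuple[str, int]:
        """Map a 1-based scaffold coordinate to its pseudomolecule coordinate."""
        r = self._by_scaffold[scaffold]
        length = int(r["component_end"])
        if not 1 <= pos <= length:
            raise ValueError(f"position {pos} outside {scaffold} (1..{length})")
        if r["orientation"] == "-":
            return r["object"], int(r["object_beg"]) - 1 + (length - pos + 1)
        return r["object"], int(r["object_beg"]) + pos - 1

    def drop(self, obj: str, pos: int) -> tuple[str, int]:
        """Inverse of :meth:`lift`; errors inside gap rows."""
        sub = self.rows[
            (self.rows["object"] == obj)
            & (self.rows["object_beg"] <= pos)
            & (pos <= self.rows["object_end"])
        ]
        if sub.empty:
            raise ValueError(f"position {pos} outside {obj}")
        r = sub.iloc[0]
        if r["component_type"] != "W":
            raise ValueError(f"position {pos} falls in a gap")
        off = pos - int(r["object_beg"]) + 1
        length = int(r["component_end"])
        if r["orientation"] == "-":
            return r["component_id"], length - off + 1
        return r["component_id"], off

    def to_agp(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##agp-version\t2.1\n")
            for _, r in self.rows.iterrows():
                if r["component_type"] == "W":
                    fields = [
                        r["object"], r["object_beg"], r["object_end"],
                        r["part_number"], "W", r["component_id"],
                        r["component_beg"], r["component_end"], r["orientation"],
                    ]
                else:
                    fields = [
                        r["object"], r["object_beg"], r["object_end"],
                        r["part_number"], "N", int(r["gap_length"]),
                        "contig", "yes", "align_genus",
                    ]
                fh.write("\t".join(str(x) for x in fields) + "\n")


def build_pseudomolecules(
    anchored: list[AnchoredScaffold],
    scaffold_lengths: dict[str, int],
    gap_bp: int = 100_000,
) -> AGPLayout:
    """Concatenate ordered scaffolds into pseudomolecules with fixed gaps.

    Pseudomolecule length is the sum of its scaffold lengths plus
    ``gap_bp`` x (k - 1) for k components; coordinates are 1-based
    inclusive per AGP convention.
    """
    placeable = [a for a in anchored if not a.lg_conflict]
    seen: set[str] = set()
    for a in placeable:
        if a.scaffold in seen:
            raise ValueError(f"duplicate scaffold assignment: {a.scaffold}")
        seen.add(a.scaffold)
    rows = []
    for lg in dict.fromkeys(a.lg for a in placeable):
        members = sorted(
            (a for a in placeable if a.lg == lg), key=lambda a: a.order_key
        )
        pos = 1
        part = 1
        for i, a in enumerate(members):
            if i > 0:
                rows.append(
                    {
                        "object": lg, "object_beg": pos,
                        "object_end": pos + gap_bp - 1, "part_number": part,
                        "component_type": "N", "gap_length": gap_bp,
                    }
                )
                pos += gap_bp
                part += 1
            L = scaffold_lengths[a.scaffold]
            rows.append(
                {
                    "object": lg, "object_beg": pos, "object_end": pos + L - 1,
                    "part_number": part, "component_type": "W",
                    "component_id": a.scaffold, "component_beg": 1,
                    "component_end": L,
                    "orientation": a.orientation if a.orientation in "+-" else "+",
                }
            )
            pos += L
            part += 1
    return AGPLayout(pd.DataFrame(rows))


def marey_recombination_rate(
    marker_table: pd.DataFrame,
    window: int = 10_000_000,
    step: int = 1_000_000,
    min_markers: int = 2,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-window recombination rate (cM/Mb) from a Marey map.

    ``marker_table`` needs columns (lg, bp, cm) with bp on the
    pseudomolecule.  The rate in a window is the least-squares slope of cM
    on Mb over the markers inside it; windows with fewer than
    ``min_markers`` or no bp spread are NaN.  Windows slide fully inside
    the chromosome (a 12-Mb chromosome gives starts at 0, 1 and 2 Mb).
    """
    rows = []
    for lg, sub in marker_table.groupby("lg", sort=False):
        bp = sub["bp"].to_numpy(dtype=float)
        cm = sub["cm"].to_numpy(dtype=float)
        srt = np.argsort(bp)
        bp, cm = bp[srt], cm[srt]
        if np.any(np.diff(cm) < 0):
            warnings.warn(f"non-monotone cM on {lg}; slopes still computed")
        length = (
            chrom_lengths[lg]
            if chrom_lengths is not None
            else int(bp.max())
        )
        starts = (
            range(0, max(length - window, 0) + 1, step)
            if length >= window
            else [0]
        )
        for s in starts:
            e = min(s + window, length)
            inside = (bp - 1 >= s) & (bp - 1 < e)
            n = int(inside.sum())
            if n < min_markers or np.unique(bp[inside]).size < 2:
                rate = float("nan")
            else:
                rate = float(np.polyfit(bp[inside] / 1e6, cm[inside], 1)[0])
            rows.append(
                {"lg": lg, "start": s, "end": e, "n_markers": n, "cm_per_mb": rate}
            )
    return pd.DataFrame(rows)
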