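"""Haplotype-block definition and pedigree inheritance tracing.

Blocks are map intervals with no recombination inside any of the
considered ancestral meioses, so within the pedigree each block travels as
a unit and can be matched exactly between generations.  The module
consumes PHASED marker data (from the gene-drop simulator or a
user-supplied phased source); it does not infer phase.

Haplotype convention: row 0 of an individual's phased array is the
maternal haplotype (inherited from the dam), row 1 the paternal one.
Missing alleles are coded :data:`HAP_MISSING` and ignored in matching; a
block with all markers missing is "unknown".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from walnutkit.synth import HAP_MISSING


class Pedigree:
    """Acyclic pedigree of individuals with optional (sire, dam) parents.

    ``entries`` maps individual -> (sire, dam), both ``None`` for founders.
    An individual with exactly one known parent is rejected.
    """

    def __init__(self, entries: dict[str, tuple[str | None, str | None]]):
        self.entries = dict(entries)
        for ind, (sire, dam) in self.entries.items():
            if (sire is None) != (dam is None):
                raise ValueError(
                    f"{ind}: both parents must be known or both unknown"
                )
            for p in (sire, dam):
                if p is not None and p not in self.entries:
                    raise ValueError(f"{ind}: parent {p} not in pedigree")
        self._order = self._toposort()

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        df = pd.read_csv(path)
        entries = {}
        for _, row in df.iterrows():
            sire = None if pd.isna(row["sire"]) else str(row["sire"])
            dam = None if pd.isna(row["dam"]) else str(row["dam"])
            entries[str(row["id"])] = (sire, dam)
        return cls(entries)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            [
                {"id": i, "sire": s or "", "dam": d or ""}
                for i, (s, d) in self.entries.items()
            ]
        ).to_csv(path, index=False)

    def _toposort(self) -> list[str]:
        order: list[str] = []
        state: dict[str, int] = {}

        def visit(ind: str, stack: tuple = ()):
            if state.get(ind) == 2:
                return
            if ind in stack:
                raise ValueError("pedigree contains a cycle")
            state[ind] = 1
            sire, dam = self.entries[ind]
            for p in (sire, dam):
                if p is not None:
                    visit(p, stack + (ind,))
            state[ind] = 2
            order.append(ind)

        for ind in self.entries:
            visit(ind)
        return order

    def topological_order(self) -> list[str]:
        """Individuals with parents always preceding children."""
        return list(self._order)

    def parents(self, ind: str) -> tuple[str | None, str | None]:
        return self.entries[ind]

    def founders(self) -> list[str]:
        return [i for i in self._order if self.entries[i] == (None, None)]

    def __contains__(self, ind: str) -> bool:
        return ind in self.entries

    def __iter__(self):
        return iter(self._order)


@dataclass(frozen=True)
class HaplotypeBlock:
    """Half-open map interval containing ``marker_idx`` rows of the map."""

    chrom: str
    start: int
    end: int
    marker_idx: tuple[int, ...]  # indices into the per-chrom marker arrays

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class BlockAssignment:
    """Per-individual, per-block phased alleles and inferred parental origin.

    ``maternal_origin``/``paternal_origin`` are the most distant ancestor
    haplotypes reached by unique matching, as ``"individual:h0"`` /
    ``"individual:h1"`` strings, or ``"unknown"`` when matching is
    uninformative (zero or multiple candidate haplotypes).
    """

    individual: str
    block: HaplotypeBlock
    maternal_alleles: np.ndarray
    paternal_alleles: np.ndarray
    maternal_origin: str = "unknown"
    paternal_origin: str = "unknown"
    maternal_chain: list[str] = field(default_factory=list)
    paternal_chain: list[str] = field(default_factory=list)


def define_blocks(
    recombination_positions,
    chrom: str,
    chrom_length: int,
    marker_bp: np.ndarray,
) -> list[HaplotypeBlock]:
    """Partition a chromosome into blocks at ancestral crossover positions.

    ``recombination_positions`` is an iterable of per-meiosis bp position
    arrays; boundaries are their sorted union (deduplicated), so two
    meioses with crossovers {3 Mb} and {3 Mb, 7 Mb} yield the same three
    blocks as one meiosis with {3 Mb, 7 Mb}.  Markers are assigned to
    blocks by 0-based position; a marker outside the chromosome is an
    error.
    """
    marker_bp = np.asarray(marker_bp, dtype=np.int64)
    if marker_bp.size and (
        marker_bp.min() < 1 or marker_bp.max() > chrom_length
    ):
        raise ValueError("marker position outside chromosome")
    cuts = sorted(
        {
            int(p)
            for mei in recombination_positions
            for p in np.atleast_1d(mei)
            if 0 < int(p) < chrom_length
        }
    )
    bounds = [0, *cuts, chrom_length]
    blocks = []
    pos0 = marker_bp - 1
    for s, e in zip(bounds[:-1], bounds[1:]):
        idx = np.nonzero((pos0 >= s) & (pos0 < e))[0]
        blocks.append(HaplotypeBlock(chrom, s, e, tuple(int(i) for i in idx)))
    return blocks


def _alleles_match(x: np.ndarray, y: np.ndarray) -> bool:
    """Exact agreement at all positions where both are non-missing."""
    ok = (x != HAP_MISSING) & (y != HAP_MISSING)
    if not ok.any():
        return False
    return bool(np.array_equal(x[ok], y[ok]))


def _informative(x: np.ndarray) -> bool:
    return bool((x != HAP_MISSING).any())


def _trace_one(
    ped: Pedigree,
    phased: dict,
    chrom: str,
    idx: np.ndarray,
    individual: str,
    hap: int,
) -> tuple[str, list[str]]:
    """Follow one haplotype of one block up the pedigree while unique."""
    chain: list[str] = [f"{individual}:h{hap}"]
    cur_ind, cur_hap = individual, hap
    while True:
        sire, dam = ped.parents(cur_ind)
        if sire is None:
            break  # founder reached
        # row 0 is maternal -> came from dam; row 1 -> sire
        parent = dam if cur_hap == 0 else sire
        if parent not in phased:
            break  # untyped ancestor: stop here
        alle = phased[cur_ind][chrom][cur_hap, idx]
        if not _informative(alle):
            return "unknown", chain
        cand = [
            h
            for h in (0, 1)
            if _alleles_match(alle, phased[parent][chrom][h, idx])
        ]
        if len(cand) != 1:
            return "unknown", chain
        cur_ind, cur_hap = parent, cand[0]
        chain.append(f"{cur_ind}:h{cur_hap}")
    return f"{cur_ind}:h{cur_hap}", chain


def trace_inheritance(
    pedigree: Pedigree,
    phased: dict,
    blocks: list[HaplotypeBlock],
    focal: str,
) -> list[BlockAssignment]:
    """Trace both focal haplotypes of every block up the pedigree.

    For each block and haplotype, the parental haplotype it matches
    (identical alleles at all non-missing block markers) is followed
    upward while the match is unique; the terminal ancestor haplotype is
    reported, or "unknown" when zero or several candidates match.
    """
    if focal not in pedigree:
        raise ValueError(f"{focal} not in pedigree")
    out = []
    for blk in blocks:
        idx = np.asarray(blk.marker_idx, dtype=np.intp)
        mat = phased[focal][blk.chrom][0, idx]
        pat = phased[focal][blk.chrom][1, idx]
        m_origin, m_chain = _trace_one(
            pedigree, phased, blk.chrom, idx, focal, 0
        )
        p_origin, p_chain = _trace_one(
            pedigree, phased, blk.chrom, idx, focal, 1
        )
        out.append(
            BlockAssignment(
                individual=focal,
                block=blk,
                maternal_alleles=mat,
                paternal_alleles=pat,
                maternal_origin=m_origin,
                paternal_origin=p_origin,
                maternal_chain=m_chain,
                paternal_chain=p_chain,
            )
        )
    return out


def ancestor_identity(
    assignments: list[BlockAssignment],
    phased: dict,
    ancestor: str,
    pedigree: Pedigree | None = None,
) -> pd.DataFrame:
    """Per-chromosome count and summed bp of blocks allele-identical to an ancestor.

    A block is matched when either focal haplotype is identical (at all
    mutually non-missing block markers) to either of the ancestor's
    haplotypes.  Blocks with no informative comparison never match.
    """
    if pedigree is not None and ancestor not in pedigree:
        raise ValueError(f"ancestor {ancestor} not in pedigree")
    if ancestor not in phased:
        raise ValueError(f"ancestor {ancestor} has no phased data")
    rows: dict[str, dict] = {}
    for asg in assignments:
        blk = asg.block
        idx = np.asarray(blk.marker_idx, dtype=np.intp)
        anc = phased[ancestor][blk.chrom]
        matched = any(
            _alleles_match(foc, anc[h, idx])
            for foc in (asg.maternal_alleles, asg.paternal_alleles)
            for h in (0, 1)
        )
        row = rows.setdefault(
            blk.chrom,
            {"chrom": blk.chrom, "n_blocks": 0, "matched_blocks": 0, "matched_bp": 0},
        )
        row["n_blocks"] += 1
        if matched:
            row["matched_blocks"] += 1
            row["matched_bp"] += blk.length
    return pd.DataFrame(list(rows.values()))


def blocks_from_truth(truth, genetic_map, chrom_lengths) -> dict[str, list[HaplotypeBlock]]:
    """Blocks per chromosome from ALL simulated crossovers (cM -> bp by
    linear interpolation on the marker map), guaranteeing no recombination
    strictly inside any block of the simulation."""
    per_chrom_cuts: dict[str, list[float]] = {lg: [] for lg in chrom_lengths}
    for meioses in truth.crossovers.values():
        for m in meioses:
            lg = m["lg"]
            sub = genetic_map[genetic_map["lg"] == lg]
            cm = sub["cm"].to_numpy()
            bp = sub["bp"].to_numpy().astype(float)
            for x in m["positions_cm"]:
                per_chrom_cuts[lg].append(float(np.interp(x, cm, bp)))
    out = {}
    for lg, length in chrom_lengths.items():
        bp = genetic_map.loc[genetic_map["lg"] == lg, "bp"].to_numpy()
        out[lg] = define_blocks(
            [np.asarray(per_chrom_cuts[lg])], lg, length, bp
        )
    return out
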