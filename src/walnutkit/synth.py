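"""Synthetic inputs with the statistical structure the analyses assume.

Three generators, each returning ground truth for recovery tests:

* a two-population diploid sample under the Balding–Nichols model with
  optional planted "sweep" windows (low diversity, rare-allele-skewed
  spectrum, elevated F_ST in one population);
* a multi-generation pedigree gene-drop with Haldane (no-interference)
  recombination along a cM map, emitting phased marker alleles;
* a toy scaffold/marker/alignment fixture for genetic-map anchoring, with
  controllable decoy alignments.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; with a fixed seed every output is
byte-identical across runs.  Stream order within each generator is
documented in its docstring.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from walnutkit.io_windows import GenotypeMatrix, write_groups, write_vcf

HAP_MISSING = -9


# ---------------------------------------------------------------------------
# two-population Balding–Nichols simulation


@dataclass
class TwoPopSimConfig:
    """Configuration for the two-population genotype simulation.

    Defaults mirror the walnut founder panel: 11 Western (EU/USA) and 12
    Eastern (Asian) diploids with genome-wide differentiation F = 0.15.
    ``sweep_windows`` are half-open 0-based bp intervals in which the
    ``sweep_pop`` allele frequency is pushed near fixation with probability
    ``sweep_prob``.
    """

    n_pop1: int = 11
    n_pop2: int = 12
    n_sites: int = 10_000
    chrom_length: int = 10_000_000
    chrom: str = "Chr1"
    divergence_F: float = 0.15
    sweep_windows: tuple[tuple[int, int], ...] = ()
    sweep_pop: str = "pop1"
    sweep_prob: float = 0.9
    pop1_label: str = "pop1"
    pop2_label: str = "pop2"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pop1 < 2 or self.n_pop2 < 2:
            raise ValueError("each population needs at least 2 diploids")
        if not 0.0 <= self.divergence_F < 1.0:
            raise ValueError("divergence_F must be in [0, 1)")
        for s, e in self.sweep_windows:
            if not (0 <= s < e <= self.chrom_length):
                raise ValueError("sweep windows must lie within [0, chrom_length)")
        if self.sweep_pop not in (self.pop1_label, self.pop2_label, "pop1", "pop2"):
            raise ValueError("sweep_pop must name one of the two populations")


@dataclass
class SimTruth:
    """Ground truth of a simulation run, JSON-serialisable."""

    kind: str
    params: dict = field(default_factory=dict)
    ancestral_freq: np.ndarray | None = None
    pop_freqs: dict | None = None
    sweep_windows: list | None = None
    sweep_pop: str | None = None
    # pedigree gene-drop
    crossovers: dict | None = None  # (individual, which_parent, chrom) -> cM list
    origins: dict | None = None  # individual -> chrom -> (2, n_markers) founder-hap ids
    founder_haplotypes: list | None = None
    # anchoring fixture
    scaffold_order: dict | None = None
    scaffold_orientation: dict | None = None
    decoy_probes: list | None = None

    def to_json(self, path) -> None:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, dict):
                return {str(k): conv(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            if isinstance(x, (np.integer, np.floating)):
                return x.item()
            return x

        payload = {k: conv(v) for k, v in self.__dict__.items() if v is not None}
        with open(path, "w") as fh:
            json.dump(payload, fh)


def simulate_two_population(config: TwoPopSimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw a two-population diploid genotype matrix under Balding–Nichols.

    Per site the ancestral frequency is p ~ Uniform(0.05, 0.95); each
    population's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) for F > 0 and
    p itself for F = 0; genotypes are Binomial(2, p_k) under
    Hardy–Weinberg.  Inside a sweep window the sweep population's frequency
    is replaced, with probability ``sweep_prob``, by a draw near fixation
    (Uniform(0, 0.02) or Uniform(0.98, 1), the side chosen by rounding p),
    which yields reduced pi, an excess of rare alleles (negative Tajima's
    D) and elevated F_ST in those windows.

    RNG stream order: positions, ancestral freqs, pop-1 freqs, pop-2
    freqs, sweep replacement mask, sweep replacement values, pop-1
    genotypes, pop-2 genotypes.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    if cfg.n_sites == 0:
        warnings.warn("n_sites=0: emitting an empty matrix")
    n_sites = cfg.n_sites
    positions = np.sort(
        rng.choice(np.arange(1, cfg.chrom_length + 1), size=n_sites, replace=False)
    )
    p = rng.uniform(0.05, 0.95, size=n_sites)
    F = cfg.divergence_F
    if F > 0:
        alpha, beta = p * (1 - F) / F, (1 - p) * (1 - F) / F
        pk1 = rng.beta(alpha, beta)
        pk2 = rng.beta(alpha, beta)
    else:
        pk1 = p.copy()
        pk2 = p.copy()

    sweep_is_pop1 = cfg.sweep_pop in (cfg.pop1_label, "pop1")
    if cfg.sweep_windows and n_sites:
        pos0 = positions - 1
        in_sweep = np.zeros(n_sites, dtype=bool)
        for s, e in cfg.sweep_windows:
            in_sweep |= (pos0 >= s) & (pos0 < e)
        replace = in_sweep & (rng.uniform(size=n_sites) < cfg.sweep_prob)
        low = rng.uniform(0.0, 0.02, size=n_sites)
        high = rng.uniform(0.98, 1.0, size=n_sites)
        swept = np.where(p < 0.5, low, high)
        target = pk1 if sweep_is_pop1 else pk2
        target[replace] = swept[replace]

    g1 = rng.binomial(2, pk1[:, None], size=(n_sites, cfg.n_pop1)).astype(np.int8)
    g2 = rng.binomial(2, pk2[:, None], size=(n_sites, cfg.n_pop2)).astype(np.int8)

    samples = [f"{cfg.pop1_label}_{i+1:02d}" for i in range(cfg.n_pop1)] + [
        f"{cfg.pop2_label}_{i+1:02d}" for i in range(cfg.n_pop2)
    ]
    groups = {
        s: (cfg.pop1_label if i < cfg.n_pop1 else cfg.pop2_label)
        for i, s in enumerate(samples)
    }
    mat = GenotypeMatrix(
        chroms=np.asarray([cfg.chrom] * n_sites, dtype=object),
        positions=positions,
        calls=np.hstack([g1, g2]),
        samples=samples,
        groups=groups,
        chrom_lengths={cfg.chrom: cfg.chrom_length},
    )
    truth = SimTruth(
        kind="two_population",
        params={
            "divergence_F": F,
            "n_pop1": cfg.n_pop1,
            "n_pop2": cfg.n_pop2,
            "seed": cfg.seed,
            "chrom_length": cfg.chrom_length,
        },
        ancestral_freq=p,
        pop_freqs={cfg.pop1_label: pk1, cfg.pop2_label: pk2},
        sweep_windows=[list(w) for w in cfg.sweep_windows],
        sweep_pop=cfg.sweep_pop if cfg.sweep_windows else None,
    )
    return mat, truth


def simulate_two_population_vcf(
    config: TwoPopSimConfig,
    vcf_path,
    groups_path=None,
    truth_path=None,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Run :func:`simulate_two_population` and write VCF/groups/truth files."""
    mat, truth = simulate_two_population(config)
    write_vcf(mat, vcf_path)
    if groups_path is not None:
        write_groups(mat.groups, groups_path)
    if truth_path is not None:
        truth.to_json(truth_path)
    return mat, truth


# ---------------------------------------------------------------------------
# genetic maps


def uniform_genetic_map(
    chrom_lengths: dict[str, int],
    markers_per_mb: float = 50.0,
    cm_per_mb: float = 2.6,
    seed: int = 0,
) -> pd.DataFrame:
    """Markers uniformly placed on each chromosome with a linear Marey map.

    Returns a genetic-map table (marker, lg, cm, bp); ``cm_per_mb``
    defaults to a walnut-like genome-wide recombination rate.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, length in chrom_lengths.items():
        n = max(2, int(round(markers_per_mb * length / 1e6)))
        bp = np.sort(rng.choice(np.arange(1, length + 1), size=n, replace=False))
        for i, b in enumerate(bp):
            rows.append(
                {
                    "marker": f"{chrom}_M{i+1:05d}",
                    "lg": chrom,
                    "cm": b / 1e6 * cm_per_mb,
                    "bp": int(b),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pedigree gene-drop


def _check_map_monotone(genetic_map: pd.DataFrame) -> None:
    for lg, sub in genetic_map.groupby("lg", sort=False):
        cm = sub["cm"].to_numpy()
        if np.any(np.diff(cm) < 0):
            raise ValueError(f"genetic map cM not monotone on {lg}")


def simulate_pedigree_genotypes(
    pedigree,
    genetic_map: pd.DataFrame,
    seed: int = 0,
    founder_alleles: str = "unique",
    error_rate: float = 0.0,
) -> tuple[dict, SimTruth]:
    """Gene-drop phased marker alleles through a pedigree.

    Each founder receives two uniquely labelled haplotypes.  Every meiosis
    draws a crossover count ~ Poisson(map length in Morgans) with
    crossover positions uniform on the cM axis (Haldane model, no
    interference); the transmitted haplotype is the resulting mosaic of the
    parent's two haplotypes, starting from a randomly chosen one.

    ``founder_alleles``:
      * ``"unique"`` — every founder haplotype carries its own integer
        label at every marker (fully informative; exact tracing possible);
      * ``"biallelic"`` — founder haplotype alleles are Bernoulli(0.5) 0/1
        draws per marker (SNP-like; heterozygosity reflects IBD).

    ``error_rate`` flips each emitted biallelic allele independently
    (a simple genotyping-error model; ignored for ``"unique"``).

    Returns ``(phased, truth)`` where ``phased`` maps individual ->
    chrom -> (2, n_markers) allele array (row 0 = maternal, row 1 =
    paternal haplotype) and ``truth`` stores founder-haplotype origin
    arrays of identical shape plus per-meiosis crossover positions.

    RNG stream order: founder biallelic alleles (if any), then per
    individual in pedigree order, per (maternal, paternal) transmission,
    per chromosome in map order: crossover count, crossover positions,
    starting haplotype; finally error flips.
    """
    from walnutkit.haploblocks import Pedigree

    ped = pedigree if isinstance(pedigree, Pedigree) else Pedigree(pedigree)
    _check_map_monotone(genetic_map)
    rng = np.random.default_rng(seed)

    chroms = list(dict.fromkeys(genetic_map["lg"]))
    marker_cm = {
        lg: genetic_map.loc[genetic_map["lg"] == lg, "cm"].to_numpy() for lg in chroms
    }
    n_markers = {lg: marker_cm[lg].size for lg in chroms}

    founders = ped.founders()
    hap_label = {}
    for i, f in enumerate(founders):
        hap_label[(f, 0)] = 2 * i
        hap_label[(f, 1)] = 2 * i + 1

    founder_allele = {}
    if founder_alleles == "biallelic":
        for f in founders:
            for h in (0, 1):
                founder_allele[(f, h)] = {
                    lg: rng.integers(0, 2, size=n_markers[lg]).astype(np.int16)
                    for lg in chroms
                }
    elif founder_alleles != "unique":
        raise ValueError("founder_alleles must be 'unique' or 'biallelic'")

    # origin arrays: founder-haplotype id per marker
    origins: dict[str, dict[str, np.ndarray]] = {}
    crossovers: dict[str, list] = {}

    def meiosis(parent: str, child: str, which: str) -> dict[str, np.ndarray]:
        """Transmit one recombinant haplotype from ``parent``."""
        out = {}
        for lg in chroms:
            cm = marker_cm[lg]
            length_cm = float(cm[-1]) if cm.size else 0.0
            n_xo = rng.poisson(length_cm / 100.0)
            xo = np.sort(rng.uniform(0.0, length_cm, size=n_xo))
            start = int(rng.integers(0, 2))
            crossovers.setdefault(child, []).append(
                {"parent": parent, "which": which, "lg": lg,
                 "positions_cm": xo.tolist(), "start_hap": start}
            )
            sel = (start + np.searchsorted(xo, cm, side="right")) % 2
            par = origins[parent][lg]
            out[lg] = np.where(sel == 0, par[0], par[1])
        return out

    for ind in ped.topological_order():
        sire, dam = ped.parents(ind)
        if sire is None and dam is None:
            origins[ind] = {
                lg: np.vstack(
                    [
                        np.full(n_markers[lg], hap_label[(ind, 0)], dtype=np.int32),
                        np.full(n_markers[lg], hap_label[(ind, 1)], dtype=np.int32),
                    ]
                )
                for lg in chroms
            }
            continue
        maternal = meiosis(dam, ind, "maternal")
        paternal = meiosis(sire, ind, "paternal")
        origins[ind] = {
            lg: np.vstack([maternal[lg], paternal[lg]]) for lg in chroms
        }

    # emit alleles from origins
    label_to_founderhap = {v: k for k, v in hap_label.items()}
    phased: dict[str, dict[str, np.ndarray]] = {}
    for ind in origins:
        phased[ind] = {}
        for lg in chroms:
            org = origins[ind][lg]
            if founder_alleles == "unique":
                phased[ind][lg] = org.astype(np.int16)
            else:
                alle = np.empty_like(org, dtype=np.int16)
                for lab, fh in label_to_founderhap.items():
                    mask = org == lab
                    if mask.any():
                        src = founder_allele[fh][lg]
                        for row in (0, 1):
                            alle[row, mask[row]] = src[mask[row]]
                phased[ind][lg] = alle
    if founder_alleles == "biallelic" and error_rate > 0:
        for ind in phased:
            for lg in chroms:
                flips = rng.uniform(size=phased[ind][lg].shape) < error_rate
                phased[ind][lg] = np.where(
                    flips, 1 - phased[ind][lg], phased[ind][lg]
                ).astype(np.int16)

    truth = SimTruth(
        kind="pedigree_gene_drop",
        params={"seed": seed, "founder_alleles": founder_alleles,
                "error_rate": error_rate},
        crossovers=crossovers,
        origins=origins,
        founder_haplotypes=[f"{f}:h{h}" for (f, h) in hap_label],
    )
    return phased, truth


def phased_to_matrix(
    phased_individual: dict[str, np.ndarray],
    genetic_map: pd.DataFrame,
    sample: str,
    chrom_lengths: dict[str, int],
) -> GenotypeMatrix:
    """Collapse one individual's phased biallelic alleles to a dosage matrix."""
    chroms, positions, calls = [], [], []
    for lg in dict.fromkeys(genetic_map["lg"]):
        sub = genetic_map[genetic_map["lg"] == lg]
        alle = phased_individual[lg]
        dos = (alle[0] + alle[1]).astype(np.int8)
        chroms.extend([lg] * len(sub))
        positions.extend(sub["bp"].tolist())
        calls.append(dos)
    return GenotypeMatrix(
        chroms=np.asarray(chroms, dtype=object),
        positions=np.asarray(positions, dtype=np.int64),
        calls=np.concatenate(calls)[:, None],
        samples=[sample],
        chrom_lengths=chrom_lengths,
    )


def ibd_segments(
    truth: SimTruth, genetic_map: pd.DataFrame, individual: str,
    chrom_lengths: dict[str, int],
) -> dict[str, list[tuple[int, int]]]:
    """True autozygous (both haplotypes same founder haplotype) bp segments.

    Segment boundaries are placed at midpoints between the flanking markers
    (chromosome ends for terminal runs); marker-free chromsomes yield no
    segments.
    """
    out: dict[str, list[tuple[int, int]]] = {}
    for lg in dict.fromkeys(genetic_map["lg"]):
        bp = genetic_map.loc[genetic_map["lg"] == lg, "bp"].to_numpy()
        org = truth.origins[individual][lg]
        auto = org[0] == org[1]
        segs = []
        i = 0
        n = auto.size
        while i < n:
            if not auto[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and auto[j + 1]:
                j += 1
            start = 0 if i == 0 else int((bp[i - 1] + bp[i]) // 2)
            end = (
                chrom_lengths[lg]
                if j == n - 1
                else int((bp[j] + bp[j + 1]) // 2)
            )
            segs.append((start, end))
            i = j + 1
        out[lg] = segs
    return out


# ---------------------------------------------------------------------------
# anchoring fixture


@dataclass
class AnchorTruth:
    """Generating order/orientation and decoy labels of an anchoring fixture."""

    order: dict[str, list[str]]  # lg -> scaffold ids in true order
    orientation: dict[str, str]  # scaffold -> "+" or "-"
    decoy_probes: list[str]


def simulate_anchoring_fixture(
    n_scaffolds: int = 6,
    markers_per_scaffold: int = 8,
    decoy_fraction: float = 0.0,
    seed: int = 0,
    n_lgs: int = 1,
    cm_per_mb: float = 2.6,
) -> tuple[dict[str, int], pd.DataFrame, pd.DataFrame, AnchorTruth]:
    """Scaffolds with mapped probes plus alignment records and ground truth.

    Scaffold lengths are Uniform(0.5, 2) Mb; scaffolds are dealt round-robin
    to linkage groups, shuffled within each, and given random orientations.
    Marker cM positions follow a linear Marey map along the true layout.
    Clean alignments have identity in [99, 100], coverage in [0.98, 1] and a
    single hit; a ``decoy_fraction`` of probes is corrupted into one of the
    three rejectable classes (identity < 98, coverage < 0.95, or a
    duplicated multi-hit alignment), recorded in the truth.

    RNG stream order: scaffold lengths, per-LG order shuffles, orientations,
    per-scaffold marker positions, clean identities/coverages, decoy
    selection and corruption draws.
    """
    if n_scaffolds < 1 or markers_per_scaffold < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    scaffolds = [f"Scaffold_{i+1:03d}" for i in range(n_scaffolds)]
    lengths = {
        s: int(rng.uniform(0.5e6, 2e6)) for s in scaffolds
    }
    lgs = [f"LG{i+1:02d}" for i in range(n_lgs)]
    order: dict[str, list[str]] = {lg: [] for lg in lgs}
    for i, s in enumerate(scaffolds):
        order[lgs[i % n_lgs]].append(s)
    for lg in lgs:
        perm = rng.permutation(len(order[lg]))
        order[lg] = [order[lg][i] for i in perm]
    orientation = {s: ("+" if rng.uniform() < 0.5 else "-") for s in scaffolds}

    map_rows, aln_rows = [], []
    for lg in lgs:
        offset = 0.0
        for s in order[lg]:
            L = lengths[s]
            bp = np.sort(
                rng.choice(np.arange(1, L + 1), size=markers_per_scaffold, replace=False)
            )
            for i, b in enumerate(bp):
                global_pos = offset + (b if orientation[s] == "+" else L - b + 1)
                probe = f"{s}_P{i+1:03d}"
                map_rows.append(
                    {
                        "marker": probe,
                        "lg": lg,
                        "cm": global_pos / 1e6 * cm_per_mb,
                    }
                )
                aln_rows.append(
                    {
                        "probe": probe,
                        "target": s,
                        "start": int(b),
                        "end": int(b) + 70,
                        "identity": float(rng.uniform(99.0, 100.0)),
                        "coverage": float(rng.uniform(0.98, 1.0)),
                        "n_hits": 1,
                    }
                )
            offset += L
    alignments = pd.DataFrame(aln_rows)
    genetic_map = pd.DataFrame(map_rows)

    decoys: list[str] = []
    if decoy_fraction > 0:
        n_decoy = int(round(decoy_fraction * len(alignments)))
        decoy_idx = rng.choice(len(alignments), size=n_decoy, replace=False)
        extra_rows = []
        for di in decoy_idx:
            probe = alignments.at[di, "probe"]
            decoys.append(probe)
            mode = rng.integers(0, 3)
            if mode == 0:
                alignments.at[di, "identity"] = float(rng.uniform(80.0, 97.9))
            elif mode == 1:
                alignments.at[di, "coverage"] = float(rng.uniform(0.5, 0.949))
            else:
                alignments.at[di, "n_hits"] = 2
                other = scaffolds[int(rng.integers(0, n_scaffolds))]
                extra_rows.append(
                    {
                        "probe": probe,
                        "target": other,
                        "start": int(rng.integers(1, lengths[other])),
                        "end": int(rng.integers(1, lengths[other])) + 70,
                        "identity": float(rng.uniform(99.0, 100.0)),
                        "coverage": float(rng.uniform(0.98, 1.0)),
                        "n_hits": 2,
                    }
                )
        if extra_rows:
            alignments = pd.concat(
                [alignments, pd.DataFrame(extra_rows)], ignore_index=True
            )

    truth = AnchorTruth(order=order, orientation=orientation, decoy_probes=decoys)
    return lengths, genetic_map, alignments, truth
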