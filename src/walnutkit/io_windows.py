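"""Genotype I/O, variant filtering, and genome window tiling.

Internally all coordinates are 0-based half-open (BED convention); VCF
positions are converted on ingest and converted back on output.  Genotypes
are stored as allele dosages (0, 1, 2; -1 for missing) in a sites x samples
matrix that may span several chromosomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Biallelic diploid dosage matrix with sample -> population labels.

    Attributes
    ----------
    chroms : np.ndarray
        Per-site chromosome identifier (object dtype), grouped so that all
        sites of a chromosome are contiguous.
    positions : np.ndarray
        1-based bp positions, strictly increasing within each chromosome.
    calls : np.ndarray
        ``(n_sites, n_samples)`` int8 dosages in {0, 1, 2, -1}.
    samples : list of str
        Ordered sample identifiers (columns of ``calls``).
    groups : dict or None
        Sample -> population label; ``None`` for single-individual use.
    chrom_lengths : dict or None
        Chromosome -> length in bp, when known (e.g. from VCF contig lines).
    dropped_records : int
        Count of non-biallelic-SNP records skipped on ingest.
    """

    chroms: np.ndarray
    positions: np.ndarray
    calls: np.ndarray
    samples: list[str]
    groups: dict[str, str] | None = None
    chrom_lengths: dict[str, int] | None = None
    dropped_records: int = 0
    skipped_sites: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.chroms = np.asarray(self.chroms, dtype=object)
        if self.calls.ndim != 2 or self.calls.shape[0] != self.positions.size:
            raise ValueError("calls must be (n_sites, n_samples)")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2, -1}")
        for ch in self.chrom_order():
            pos = self.positions[self.chroms == ch]
            if pos.size > 1 and not (np.diff(pos) > 0).all():
                raise ValueError(f"positions not strictly increasing on {ch}")

    @property
    def n_sites(self) -> int:
        return self.positions.size

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def chrom_order(self) -> list[str]:
        seen: dict[str, None] = {}
        for ch in self.chroms:
            seen.setdefault(ch, None)
        return list(seen)

    def group_indices(self) -> dict[str, np.ndarray]:
        """Column indices per population label, in label-sorted order."""
        if self.groups is None:
            raise ValueError("matrix has no sample->population labels")
        out: dict[str, list[int]] = {}
        for j, s in enumerate(self.samples):
            if s in self.groups:
                out.setdefault(self.groups[s], []).append(j)
        return {g: np.asarray(ix, dtype=np.intp) for g, ix in sorted(out.items())}

    def take_sites(self, mask_or_index: np.ndarray) -> "GenotypeMatrix":
        return replace(
            self,
            chroms=self.chroms[mask_or_index],
            positions=self.positions[mask_or_index],
            calls=self.calls[mask_or_index],
        )

    def sample_column(self, sample: str) -> np.ndarray:
        return self.calls[:, self.samples.index(sample)]


@dataclass(frozen=True)
class Window:
    """Half-open genomic interval with the index range of contained sites."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    partial: bool = False
    site_start: int = 0  # row range [site_start, site_end) in the matrix
    site_end: int = 0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("window start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_sites(self) -> int:
        return self.site_end - self.site_start

    def contains(self, chrom: str, pos0: int) -> bool:
        return chrom == self.chrom and self.start <= pos0 < self.end


def read_groups(path) -> dict[str, str]:
    """Two-column whitespace/tab table: sample, population label."""
    groups: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, pop = line.split()[:2]
            groups[sample] = pop
    return groups


def read_vcf(path, groups_path=None) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic records and indels are dropped (counted in
    ``dropped_records``).  Dosage is derived from GT regardless of the
    phasing separator; any missing allele makes the call missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chrom_lengths: dict[str, int] = {}
    try:
        for name, ln in zip(vcf.seqnames, vcf.seqlens):
            chrom_lengths[name] = int(ln)
    except AttributeError:  # header without contig lengths
        pass

    chroms: list[str] = []
    positions: list[int] = []
    rows: list[np.ndarray] = []
    dropped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            dropped += 1
            continue
        # gts012=True: 0/1/2 dosage, 3 = missing
        g = rec.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        chroms.append(rec.CHROM)
        positions.append(rec.POS)
        rows.append(g)
    vcf.close()

    groups = read_groups(groups_path) if groups_path is not None else None
    if groups is not None:
        absent = sorted(set(groups) - set(samples))
        if absent:
            raise ValueError(f"samples in groups file absent from VCF: {absent}")

    if not rows:
        warnings.warn("VCF contained no biallelic SNP records")
        calls = np.empty((0, len(samples)), dtype=np.int8)
    else:
        calls = np.vstack(rows)
    return GenotypeMatrix(
        chroms=np.asarray(chroms, dtype=object),
        positions=np.asarray(positions, dtype=np.int64),
        calls=calls,
        samples=samples,
        groups=groups,
        chrom_lengths=chrom_lengths or None,
        dropped_records=dropped,
    )


def write_vcf(mat: GenotypeMatrix, path, phased: bool = False) -> None:
    """Write the matrix as a minimal VCF v4.2 with GT-only FORMAT."""
    sep = "|" if phased else "/"
    gt_strings = {0: f"0{sep}0", 1: f"0{sep}1", 2: f"1{sep}1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if mat.chrom_lengths:
            for ch, ln in mat.chrom_lengths.items():
                fh.write(f"##contig=<ID={ch},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(mat.samples)
            + "\n"
        )
        for i in range(mat.n_sites):
            gts = "\t".join(gt_strings[int(d)] for d in mat.calls[i])
            fh.write(
                f"{mat.chroms[i]}\t{mat.positions[i]}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_groups(groups: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sample, pop in groups.items():
            fh.write(f"{sample}\t{pop}\n")


def filter_variants(
    mat: GenotypeMatrix,
    maf_min: float = 0.10,
    max_missing_fraction: float = 0.0,
) -> GenotypeMatrix:
    """Retain sites by missingness and minor-allele frequency.

    A site is kept when its missing-call fraction is <= ``max_missing_fraction``
    and its minor-allele frequency, computed over non-missing calls, is
    strictly greater than ``maf_min`` (a MAF exactly at the threshold is
    removed).  Site order is preserved; the operation is idempotent.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if mat.n_sites == 0:
        return mat
    missing = mat.calls == MISSING
    n_missing = missing.sum(axis=1)
    with np.errstate(invalid="ignore"):
        n_called = mat.n_samples - n_missing
        alt = np.where(missing, 0, mat.calls).sum(axis=1)
        freq = np.divide(
            alt, 2.0 * n_called, out=np.zeros(mat.n_sites), where=n_called > 0
        )
    maf = np.minimum(freq, 1.0 - freq)
    keep = (n_missing <= max_missing_fraction * mat.n_samples) & (n_called > 0)
    keep &= maf > maf_min
    return mat.take_sites(keep)


def tile_windows(
    chrom_lengths: dict[str, int],
    size: int,
    step: int | None = None,
) -> list[Window]:
    """Tile (step == size) or slide (step < size) windows over chromosomes.

    Tiling covers ``[0, chrom_length)`` and emits a flagged final partial
    window.  Sliding emits only windows fully inside the chromosome (a
    12-Mb chromosome with 10-Mb windows at 1-Mb step yields starts at 0, 1
    and 2 Mb); a chromosome shorter than one window yields a single partial
    window so no sequence is silently dropped.
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    step = size if step is None else step
    if not 0 < step <= size:
        raise ValueError("require 0 < step <= size")
    windows: list[Window] = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            continue
        if step == size:
            for start in range(0, length, size):
                end = min(start + size, length)
                windows.append(Window(chrom, start, end, partial=end - start < size))
        else:
            if length < size:
                windows.append(Window(chrom, 0, length, partial=True))
                continue
            for start in range(0, length - size + 1, step):
                windows.append(Window(chrom, start, start + size, partial=False))
    return windows


def assign_sites(windows: list[Window], mat: GenotypeMatrix) -> list[Window]:
    """Attach to each window the matrix row range of sites it contains.

    1-based positions are converted to 0-based before the half-open interval
    test, so a site at 1-based position 100,000 falls in ``[0, 100000)``.
    """
    offsets: dict[str, tuple[int, np.ndarray]] = {}
    idx = 0
    for ch in mat.chrom_order():
        pos = mat.positions[mat.chroms == ch]
        offsets[ch] = (idx, pos - 1)  # 0-based
        idx += pos.size
    out: list[Window] = []
    for w in windows:
        if w.chrom not in offsets:
            out.append(replace_sites(w, 0, 0))
            continue
        off, pos0 = offsets[w.chrom]
        lo = int(np.searchsorted(pos0, w.start, side="left"))
        hi = int(np.searchsorted(pos0, w.end, side="left"))
        out.append(replace_sites(w, off + lo, off + hi))
    return out


def replace_sites(w: Window, site_start: int, site_end: int) -> Window:
    return Window(w.chrom, w.start, w.end, w.partial, site_start, site_end)


def count_snps_per_window(
    mat: GenotypeMatrix,
    windows: list[Window],
    heterozygous_only: bool = False,
    focal_sample: str | None = None,
) -> np.ndarray:
    """Per-window SNP counts, optionally heterozygous calls of one sample.

    ``heterozygous_only`` counts sites where the focal sample has dosage 1
    (the self-heterozygosity scan of a single genotype); with more than one
    sample in the matrix a ``focal_sample`` must then be named.
    """
    windows = assign_sites(windows, mat)
    if not heterozygous_only:
        return np.asarray([w.n_sites for w in windows], dtype=np.int64)
    if focal_sample is None:
        if mat.n_samples != 1:
            raise ValueError(
                "heterozygous_only with >1 sample requires focal_sample"
            )
        focal_sample = mat.samples[0]
    col = mat.sample_column(focal_sample)
    het = (col == 1).astype(np.int64)
    cum = np.concatenate([[0], np.cumsum(het)])
    return np.asarray(
        [cum[w.site_end] - cum[w.site_start] for w in windows], dtype=np.int64
    )
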