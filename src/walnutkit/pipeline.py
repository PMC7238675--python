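"""End-to-end orchestration from a config mapping, with a run manifest.

Every number in the emitted report comes from one library operation; the
pipeline only sequences stages, writes their tables and logs counts.
Stages run when their inputs are configured: ``scan`` (VCF + groups),
``autozygosity`` (VCF + focal sample), ``anchor`` (alignments + map +
scaffold lengths).  Any stage failure aborts with the stage name and
cause; partial outputs are kept alongside a ``.partial`` marker file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import walnutkit
from walnutkit.autozygosity import low_het_scan, regions_to_bed
from walnutkit.io_windows import filter_variants, read_vcf, tile_windows
from walnutkit.map_anchor import (
    assign_order_orient,
    build_pseudomolecules,
    filter_probe_alignments,
    marey_recombination_rate,
)
from walnutkit.scan import (
    TraitLocus,
    call_fst_outliers,
    classify_sweeps,
    overlap_trait_loci,
    permutation_fdr,
)
from walnutkit.stats import windowed_stats

log = logging.getLogger("walnutkit")


@dataclass
class RunConfig:
    """Paths and parameters of a pipeline run (see the example YAML)."""

    out_dir: str = "walnutkit_out"
    vcf: str | None = None
    groups: str | None = None
    group1: str | None = None  # the diversity-reduced slot of ROD
    group2: str | None = None
    focal_sample: str | None = None
    trait_loci: str | None = None  # TSV: marker, chrom, position, trait
    alignments: str | None = None
    genetic_map: str | None = None
    scaffold_lengths: str | None = None
    scan_window_size: int = 100_000
    density_window_size: int = 1_000_000
    marey_window: int = 10_000_000
    marey_step: int = 1_000_000
    maf_min: float = 0.10
    max_missing_fraction: float = 0.0
    outlier_quantile: float = 0.95
    low_het_percentile: float = 10.0
    n_permutations: int = 1000
    gap_bp: int = 100_000
    seed: int = 0
    counters: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _require(cfg: RunConfig, *names: str) -> None:
    for name in names:
        value = getattr(cfg, name)
        if value is None:
            raise ValueError(f"missing required config entry: {name}")
        if name in {"vcf", "groups", "trait_loci", "alignments",
                    "genetic_map", "scaffold_lengths"} and not Path(value).exists():
            raise FileNotFoundError(f"config entry {name} points to missing file: {value}")


def stage_scan(cfg: RunConfig, out: Path) -> dict:
    _require(cfg, "vcf", "groups", "group1", "group2")
    mat = read_vcf(cfg.vcf, groups_path=cfg.groups)
    n_raw = mat.n_sites
    mat = filter_variants(mat, cfg.maf_min, cfg.max_missing_fraction)
    windows = tile_windows(mat.chrom_lengths, cfg.scan_window_size)
    df = windowed_stats(mat, windows, cfg.group1, cfg.group2)
    cutoff, calls = call_fst_outliers(
        windows, df["fst"].to_numpy(), cfg.outlier_quantile
    )
    df["is_outlier"] = [c.is_outlier for c in calls]
    df["fst_cutoff"] = cutoff
    fdr = permutation_fdr(
        mat, windows, cfg.group1, cfg.group2, cutoff,
        n_permutations=cfg.n_permutations, seed=cfg.seed,
    )
    sweeps = classify_sweeps(df)
    df.to_csv(out / "window_stats.tsv", sep="\t", index=False)
    sweeps.to_csv(out / "sweep_candidates.tsv", sep="\t", index=False)
    info = {
        "sites_read": n_raw,
        "sites_after_filter": mat.n_sites,
        "dropped_records": mat.dropped_records,
        "n_windows": len(windows),
        "n_outliers": int(df["is_outlier"].sum()),
        "fst_cutoff": cutoff,
        "permutation_fdr": fdr["fdr"],
        "mean_null_outliers": fdr["mean_null_count"],
    }
    if cfg.trait_loci:
        loci = [
            TraitLocus(str(r["marker"]), str(r["chrom"]), int(r["position"]),
                       str(r["trait"]))
            for _, r in pd.read_csv(cfg.trait_loci, sep="\t").iterrows()
        ]
        hits = overlap_trait_loci(df, loci)
        hits.to_csv(out / "trait_locus_overlap.tsv", sep="\t", index=False)
        info["trait_loci_in_outliers"] = int(hits["in_outlier_window"].sum())
    return info


def stage_autozygosity(cfg: RunConfig, out: Path) -> dict:
    _require(cfg, "vcf")
    mat = read_vcf(cfg.vcf)
    counts, windows, threshold, regions = low_het_scan(
        mat,
        focal_sample=cfg.focal_sample,
        window_size=cfg.density_window_size,
        percentile=cfg.low_het_percentile,
    )
    pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "het_snps": counts,
        }
    ).to_csv(out / "het_density.tsv", sep="\t", index=False)
    regions_to_bed(regions, out / "low_het_regions.bed")
    return {
        "n_windows": len(windows),
        "threshold": threshold,
        "n_regions": len(regions),
        "n_flagged_windows": int(sum(r.n_windows for r in regions)),
    }


def stage_anchor(cfg: RunConfig, out: Path) -> dict:
    _require(cfg, "alignments", "genetic_map", "scaffold_lengths")
    aln = pd.read_csv(cfg.alignments, sep="\t")
    gmap = pd.read_csv(cfg.genetic_map, sep="\t")
    lens_df = pd.read_csv(
        cfg.scaffold_lengths, sep="\t", header=None, names=["scaffold", "length"]
    )
    lengths = dict(zip(lens_df["scaffold"], lens_df["length"].astype(int)))
    retained = filter_probe_alignments(aln)
    anchored, unanchored = assign_order_orient(retained, gmap, lengths)
    layout = build_pseudomolecules(anchored, lengths, gap_bp=cfg.gap_bp)
    layout.to_agp(out / "pseudomolecules.agp")
    pd.DataFrame([a.__dict__ for a in anchored]).to_csv(
        out / "anchoring.tsv", sep="\t", index=False
    )
    info = {
        "alignments_in": len(aln),
        "alignments_retained": len(retained),
        "scaffolds_anchored": sum(1 for a in anchored if not a.lg_conflict),
        "scaffolds_unanchored": len(unanchored),
    }
    if "bp" in gmap.columns:
        lifted = []
        retained_map = retained.merge(gmap, left_on="probe", right_on="marker")
        placed = {a.scaffold for a in anchored if not a.lg_conflict}
        for _, r in retained_map.iterrows():
            if r["target"] not in placed:
                continue
            obj, pos = layout.lift(r["target"], int(r["start"]))
            lifted.append({"lg": obj, "bp": pos, "cm": r["cm"]})
        if lifted:
            marey = marey_recombination_rate(
                pd.DataFrame(lifted),
                window=cfg.marey_window,
                step=cfg.marey_step,
            )
            marey.to_csv(out / "marey_rates.tsv", sep="\t", index=False)
            info["mean_cm_per_mb"] = float(np.nanmean(marey["cm_per_mb"]))
    return info


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all configured stages; return (and write) the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / ".partial"
    marker.touch()
    manifest: dict = {
        "walnutkit_version": walnutkit.__version__,
        "seed": cfg.seed,
        "stages": {},
    }
    stages = []
    if cfg.vcf and cfg.groups:
        stages.append(("scan", stage_scan))
    if cfg.vcf and cfg.focal_sample:
        stages.append(("autozygosity", stage_autozygosity))
    if cfg.alignments:
        stages.append(("anchor", stage_anchor))
    if not stages:
        raise ValueError("no stage has its inputs configured")
    for name, fn in stages:
        log.info("stage %s starting", name)
        try:
            manifest["stages"][name] = fn(cfg, out)
        except Exception as exc:
            raise RuntimeError(f"stage {name} failed: {exc}") from exc
        log.info("stage %s done: %s", name, manifest["stages"][name])
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    marker.unlink()
    return manifest
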