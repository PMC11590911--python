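"""End-to-end pipeline: QC -> pairwise LD -> decay summaries -> reports.

`run_pipeline` reads a PED/MAP panel (plus population map and optional
duplicate-sample PED for concordance), applies the QC cascade, estimates
pairwise syntenic LD per population, and writes the full set of result tables
with a JSON manifest.  Outputs are deterministic for a given configuration:
reruns produce byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .concordance import concordance_report
from .decay import (
    DistanceBins,
    adjacent_snp_summary,
    bin_by_distance,
    decay_curve,
    pairwise_syntenic_ld,
    per_chromosome_summary,
    point_distance_summary,
)
from .errors import SnpldError, UndefinedStatisticError
from .panel import GenotypePanel
from .plink_io import read_ped_map, write_table
from .qc import DEFAULT_MAF_EDGES, QCThresholds, apply_qc, maf_histogram, monomorphic_overlap

log = logging.getLogger("snpld")


@dataclass
class PipelineConfig:
    """Inputs, thresholds and options for one pipeline run."""

    ped: str
    map: str
    popmap: str
    out_dir: str
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    bins: DistanceBins = field(default_factory=DistanceBins)
    statistic: str = "r2_corrected"
    max_distance_bp: int = 1_000_000
    populations: list[str] | None = None  # None = all populations in the panel
    duplicates_ped: str | None = None     # PED of re-genotyped samples (same MAP)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        thr_keys = {"hwe_p_min", "maf_min", "call_rate_min", "hwe_method", "autosomes"}
        thr = {k: raw.pop(k) for k in list(raw) if k in thr_keys}
        if "autosomes" in thr:
            thr["autosomes"] = frozenset(str(c) for c in thr["autosomes"])
        cfg = cls(**raw)
        if thr:
            cfg.thresholds = QCThresholds(**thr)
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the output manifest (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    log.info("reading panel: %s / %s", config.ped, config.map)
    panel = read_ped_map(config.ped, config.map, config.popmap)
    pops = config.populations or panel.populations

    # --- QC on the pooled panel
    retained, report = apply_qc(panel, config.thresholds)
    report.to_tsv(out / "qc_report.tsv")
    outputs["qc_report"] = "qc_report.tsv"
    log.info("QC: %d -> %d loci", report.n_input, report.n_retained)
    if retained.n_loci == 0:
        log.warning("no loci retained after QC; downstream tables will be empty")

    # --- MAF spectra per population
    maf_rows = []
    for pop in pops:
        counts = maf_histogram(retained, pop) if retained.n_loci else []
        for k, c in enumerate(counts):
            maf_rows.append((pop, f"{DEFAULT_MAF_EDGES[k]:.6g}-{DEFAULT_MAF_EDGES[k+1]:.6g}", int(c)))
    write_table(maf_rows, out / "maf_histogram.tsv", columns=("population", "maf_bin", "n_loci"))
    outputs["maf_histogram"] = "maf_histogram.tsv"

    # --- monomorphic overlap: each population vs all others jointly
    overlap_rows = []
    for pop in pops:
        others = [p for p in pops if p != pop]
        if not others or retained.n_loci == 0:
            continue
        try:
            frac = monomorphic_overlap(retained, pop, others)
        except UndefinedStatisticError:
            frac = None
        overlap_rows.append((pop, "+".join(others), frac))
    write_table(overlap_rows, out / "monomorphic_overlap.tsv",
                columns=("population", "other_populations", "overlap_fraction"))
    outputs["monomorphic_overlap"] = "monomorphic_overlap.tsv"

    # --- pairwise LD and decay summaries per population
    bin_rows, point_rows, chrom_rows, adj_rows, curve_rows = [], [], [], [], []
    for pop in pops:
        log.info("pairwise syntenic LD: %s", pop)
        est, skipped = pairwise_syntenic_ld(
            retained, pop, max_distance_bp=config.max_distance_bp
        )
        est_out = est.copy()
        pair_file = f"ld_pairs_{pop}.tsv"
        write_table(
            est_out.itertuples(index=False), out / pair_file, columns=list(est.columns)
        )
        outputs[f"ld_pairs_{pop}"] = pair_file

        for s in bin_by_distance(est, config.bins, config.statistic, population=pop):
            bin_rows.append((pop, s.bin, s.mean, s.sd, s.n_pairs))
        for s in point_distance_summary(est, statistic="r2", population=pop):
            point_rows.append((pop, s.bin, s.mean, s.sd, s.n_pairs))
        for stat in ("D", "Dprime", "r2"):
            for rec in per_chromosome_summary(est, statistic=stat).itertuples(index=False):
                chrom_rows.append((pop, stat, rec.chrom, rec.mean, rec.sd, rec.n_pairs))
        means, _sk = adjacent_snp_summary(retained, pop)
        for chrom, m in means.items():
            adj_rows.append((pop, chrom, m))
        for rec in decay_curve(est, statistic=config.statistic).itertuples(index=False):
            curve_rows.append((pop, rec.distance_mid_bp, rec.mean, rec.n_pairs))

    write_table(bin_rows, out / "bin_summary.tsv",
                columns=("population", "bin", f"mean_{config.statistic}", "sd", "n_pairs"))
    outputs["bin_summary"] = "bin_summary.tsv"
    write_table(point_rows, out / "point_summary.tsv",
                columns=("population", "window", "mean_r2", "sd", "n_pairs"))
    outputs["point_summary"] = "point_summary.tsv"
    write_table(chrom_rows, out / "per_chromosome.tsv",
                columns=("population", "statistic", "chrom", "mean", "sd", "n_pairs"))
    outputs["per_chromosome"] = "per_chromosome.tsv"
    write_table(adj_rows, out / "adjacent_snp.tsv",
                columns=("population", "chrom", "mean_r2"))
    outputs["adjacent_snp"] = "adjacent_snp.tsv"
    write_table(curve_rows, out / "decay_curve.tsv",
                columns=("population", "distance_mid_bp", f"mean_{config.statistic}", "n_pairs"))
    outputs["decay_curve"] = "decay_curve.tsv"

    # --- concordance of re-genotyped samples, if provided
    if config.duplicates_ped:
        dup_panel = read_ped_map(config.duplicates_ped, config.map, config.popmap)
        pairs = _match_duplicate_pairs(dup_panel, panel)
        rows = concordance_report(dup_panel, panel, pairs)
        write_table(rows, out / "concordance.tsv",
                    columns=("sample", "Po", "Pc", "Q", "n_loci_used"))
        outputs["concordance"] = "concordance.tsv"

    manifest = {
        "snpld_version": __version__,
        "seed": config.seed,
        "parameters": {
            "hwe_p_min": config.thresholds.hwe_p_min,
            "maf_min": config.thresholds.maf_min,
            "call_rate_min": config.thresholds.call_rate_min,
            "hwe_method": config.thresholds.hwe_method,
            "statistic": config.statistic,
            "max_distance_bp": config.max_distance_bp,
            "bins": [list(e) for e in config.bins.edges],
            "populations": pops,
        },
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _match_duplicate_pairs(dup_panel: GenotypePanel, panel: GenotypePanel):
    """Pair duplicate ids (``<sample>_dup``) with their originals; otherwise
    require identical ids in both panels."""
    pairs = []
    originals = set(panel.sample_ids)
    for s in dup_panel.sample_ids:
        base = s[:-4] if s.endswith("_dup") else s
        if base not in originals:
            raise SnpldError(f"duplicate sample {s!r} has no original in the main panel")
        pairs.append((s, base))
    return pairs
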