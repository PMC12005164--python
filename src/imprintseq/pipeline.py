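"""End-to-end orchestration: simulate -> normalize -> test -> imprint ->
group -> conserve -> cluster -> tissue -> report.

The pipeline runs the full analysis on a synthetic experiment (or on count
tables supplied through the same readers), writes every stage's table to
the output directory, and produces a single JSON report of headline
tallies. All thresholds are recorded in the report so every number is
traceable to a stage output file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import allele_stats, conservation, dynamics, grouping, imprinting, synthetic, tissue
from .io_tables import (
    collapse_alleles,
    rpm_normalize,
    write_counts,
    write_expression,
    write_pangene_table,
    write_tissue_atlas,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-experiment analysis run."""

    seed: int
    out_dir: str = "imprintseq_run"
    sim: synthetic.SimConfig | None = None
    thresholds: imprinting.ImprintThresholds = field(
        default_factory=imprinting.ImprintThresholds
    )
    expr_min: float = 1.0
    strong_min: float = 5.0
    baseline_dap: int = 11
    k_clusters: int = 9
    min_genotypes: int = 4
    syntelog_dropout: float = 0.05
    panel_dap: int = 14

    def __post_init__(self) -> None:
        if self.sim is None:
            self.sim = synthetic.SimConfig(
                genotype_pairs=(
                    ("B73", "W22"),
                    ("B73", "Ky21"),
                    ("B73", "NC358"),
                    ("B73", "CML333"),
                    ("B73", "M162W"),
                    ("B73", "B97"),
                    ("B73", "Oh43"),
                    ("B73", "Ki11"),
                ),
                seed=self.seed,
            )
        elif self.sim.seed is None:
            self.sim = dataclasses.replace(self.sim, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", None)
        thr_raw = raw.pop("thresholds", None)
        if seed is not None:
            raw["seed"] = seed
        cfg = cls(**raw)
        if sim_raw:
            sim_raw.setdefault("seed", cfg.seed)
            if "genotype_pairs" in sim_raw:
                sim_raw["genotype_pairs"] = tuple(
                    tuple(p) for p in sim_raw["genotype_pairs"]
                )
            if "dap_set" in sim_raw:
                sim_raw["dap_set"] = tuple(sim_raw["dap_set"])
            cfg.sim = synthetic.SimConfig(**sim_raw)
        if thr_raw:
            cfg.thresholds = imprinting.ImprintThresholds(**thr_raw)
        return cfg


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj) if isinstance(obj, set)] if isinstance(
            obj, set
        ) else [_jsonable(v) for v in obj]
    return obj


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Run every stage on a simulated experiment and write the report bundle."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = cfg.sim
    assert sim is not None
    thr = cfg.thresholds
    report: dict[str, Any] = {
        "seed": cfg.seed,
        "thresholds": dataclasses.asdict(thr),
        "filters": {"expr_min": cfg.expr_min, "strong_min": cfg.strong_min},
    }

    # --- stage: simulate ---------------------------------------------------
    log.info("simulating %d genes, %d genotype pairs", sim.n_total(), len(sim.genotype_pairs))
    truth = synthetic.generate_truth(sim)
    panel, _ = synthetic.simulate_panel(sim, truth)
    ref, ref_alt = sim.reference_pair
    acm = panel[ref_alt]
    synthetic.write_truth(truth, out / "truth.tsv")
    write_counts(acm, out / "counts.tsv", out / "meta.tsv")

    syn = synthetic.simulate_syntelogs(
        truth, sim.alt_genotypes, dropout_rate=cfg.syntelog_dropout, seed=cfg.seed
    )
    write_pangene_table(syn, out / "syntelogs.tsv")
    atlas = synthetic.simulate_tissue_atlas(truth, sim, noise_sd=0.1)
    write_tissue_atlas(atlas, out / "atlas.tsv")

    # --- stage: normalize --------------------------------------------------
    expr = rpm_normalize(acm)
    write_expression(expr, out / "rpm.tsv")

    # --- stage: imprinting test + calls ------------------------------------
    de = allele_stats.imprint_tests(acm, spec=thr.test_spec())
    calls, summary = imprinting.imprint_profile(expr, de, thr, cfg.expr_min)
    calls.reset_index().to_csv(out / "imprint_calls.tsv", sep="\t", index=False)
    summary.to_csv(out / "imprint_summary.tsv", sep="\t")
    by_dap = (
        calls[calls["status"].isin([imprinting.STATUS_MEG, imprinting.STATUS_PEG])]
        .reset_index()
        .groupby(["dap", "status"])
        .size()
    )
    report["imprinted_counts_per_dap"] = {
        f"{dap}DAP_{status}": int(n) for (dap, status), n in by_dap.items()
    }

    # --- stage: temporal grouping ------------------------------------------
    assignments = grouping.assign_groups(calls, cfg.expr_min, cfg.strong_min)
    assignments.to_csv(out / "groups.tsv", sep="\t")
    gsum = grouping.group_summary(assignments)
    gsum.to_csv(out / "group_summary.tsv", sep="\t", index=False)
    report["group_sizes"] = {
        (
            f"{row['direction']}_group{row['group']}"
            if row["group"] in "1234"
            else f"{row['direction']}_{row['group']}"
        ): int(row["count"])
        for _, row in gsum.iterrows()
    }
    bias_tab = grouping.bias_consistency_counts(calls, thr)
    bias_tab.to_csv(out / "bias_consistency.tsv", sep="\t", index=False)

    # --- stage: DE vs earliest time point ----------------------------------
    mapping: dict[str, str] = {f"{ref}:{t.gene_id}": t.gene_id for t in truth}
    for rec in syn.for_genotype(ref_alt).itertuples():
        mapping[f"{ref_alt}:{rec.alt_gene_id}"] = rec.b73_gene_id
    gene_level = collapse_alleles(acm, mapping)
    bw_cols = gene_level.samples_where(maternal=ref)
    bw = gene_level.subset_samples(bw_cols)
    de_base = allele_stats.de_vs_baseline(bw, baseline_dap=cfg.baseline_dap)
    de_base.results.reset_index().to_csv(out / "de_vs_baseline.tsv", sep="\t", index=False)
    de_base.overlap.to_csv(out / "de_overlap.tsv", sep="\t")
    report["de_overlap"] = {
        f"{direction}_{col}": int(de_base.overlap.loc[direction, col])
        for direction in de_base.overlap.index
        for col in de_base.overlap.columns
    }

    # --- stage: clustering --------------------------------------------------
    gene_expr = rpm_normalize(gene_level)
    traj_bw, _ = dynamics.max_normalize(gene_expr, maternal=ref)
    model = dynamics.fit_kmeans(traj_bw, k=cfg.k_clusters, seed=cfg.seed)
    model.assignments.rename("cluster").to_csv(out / "clusters.tsv", sep="\t")
    model.centroids.to_csv(out / "cluster_centroids.tsv", sep="\t")
    traj_wb, _ = dynamics.max_normalize(gene_expr, maternal=ref_alt)
    transferred = dynamics.transfer_clusters(model, traj_wb)
    transferred.rename("cluster").to_csv(out / "clusters_reciprocal.tsv", sep="\t")
    report["cluster_sizes"] = {
        str(c): int(n) for c, n in model.assignments.value_counts().sort_index().items()
    }

    # --- stage: conservation -------------------------------------------------
    table = conservation.build_genotype_table(
        panel, syn, thr, dap=cfg.panel_dap, expr_min=cfg.expr_min
    )
    table.to_csv(out / "genotype_table.tsv", sep="\t", index=False)
    # reference direction/groups come from the time-series reference alleles
    ref_assign = assignments[assignments.index.str.startswith(f"{ref}:")].copy()
    ref_assign.index = [g.split(":", 1)[1] for g in ref_assign.index]
    directions = ref_assign.loc[
        ref_assign["direction"].isin([imprinting.STATUS_MEG, imprinting.STATUS_PEG]),
        "direction",
    ]
    scores = conservation.conservation_scores(table, directions, thr)
    scores.to_csv(out / "conservation.tsv", sep="\t")
    by_group = conservation.conservation_by_group(scores, ref_assign, cfg.min_genotypes)
    by_group.to_csv(out / "conservation_by_group.tsv", sep="\t", index=False)
    report["conservation_mean_by_group"] = {
        f"{row['direction']}_group{row['group']}": round(float(row["mean"]), 4)
        for _, row in by_group.iterrows()
        if row["group"] in "1234"
    }
    pcounts = conservation.panel_counts(table, thr)
    pcounts.to_csv(out / "panel_counts.tsv", sep="\t")

    # --- stage: tissue -------------------------------------------------------
    tissue_calls = tissue.classify_tissue(atlas)
    tissue_calls.to_csv(out / "tissue_calls.tsv", sep="\t")
    degs, universe = synthetic.simulate_mdr1_degs(truth, seed=cfg.seed)
    crosstab = tissue.crosstab_groups_tissue(ref_assign, tissue_calls, degs, universe)
    crosstab.to_csv(out / "tissue_crosstab.tsv", sep="\t", index=False)
    report["tissue_class_counts"] = {
        str(k): int(v) for k, v in tissue_calls["tissue_class"].value_counts().items()
    }

    report_path = out / "report.json"
    report_path.write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n")
    log.info("report written to %s", report_path)
    return report
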