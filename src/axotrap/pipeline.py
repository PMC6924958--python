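"""End-to-end orchestration.

``run_all`` ties every stage into one reproducible run: simulate (or
load) counts, QC, the twelve DGE comparisons, the stringent filter and
translatome classification, the learning-effect analyses, transcript
contribution scores, and colocalization on synthetic or supplied
images.  All randomness flows from a single seed; identical config and
seed give a byte-identical summary JSON.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .comparisons import run_comparisons
from .dge import CountMatrix
from .effects import (direction_concordance, effect_correlation,
                      expression_by_group, top_abundance_union)
from .filtering import apply_filter, classify_translatome
from .qc import qc_summary
from .simulate import ImageSpec, SimConfig, generate_counts, generate_image_pair, \
    generate_transcript_table
from .transcripts import contribution_scores, divergent_transcripts, score_correlation
from .coloc import costes_threshold, manders

__version__ = "0.1.0"

__all__ = ["RunConfig", "run_all", "__version__"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either file paths (counts + sample sheet) or a simulation block
    must be present.  All thresholds of the analysis are surfaced here
    with their standard defaults: FDR level alpha = 0.05, transcript
    divergence threshold 0.3, top-abundance n_top = 50, regression-line
    significance 1e-5.
    """

    counts_path: str | None = None
    sample_sheet_path: str | None = None
    transcript_table_path: str | None = None
    out_dir: str = "axotrap_out"
    alpha: float = 0.05
    strict_enrichment_confirm: bool = True
    divergence_threshold: float = 0.3
    n_top: int = 50
    min_p_for_line: float = 1e-5
    seed: int = 0
    simulate: SimConfig | None = None
    simulate_images: ImageSpec | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        sim_img = raw.pop("simulate_images", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = SimConfig(**sim)
        if sim_img is not None:
            cfg.simulate_images = ImageSpec(**sim_img)
        return cfg


def _log(msg: str) -> None:
    print(f"[axotrap] {msg}", file=sys.stderr)


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run report.

    Output files go under ``config.out_dir``; the deterministic summary
    lands in ``summary.json``.  A failed stage is recorded in the
    report with its diagnostic and re-raised as RuntimeError by the
    CLI wrapper.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                result = fn()
                report["stages"][name] = {"status": "ok"}
                _log(f"{name}: ok ({time.time() - t0:.1f}s)")
                return result
            except Exception as exc:  # noqa: BLE001 - recorded and re-raised
                report["stages"][name] = {"status": "failed", "error": str(exc)}
                _log(f"{name}: FAILED ({exc})")
                raise
        return deco

    # --- counts -----------------------------------------------------------
    truth = None
    if config.counts_path and config.sample_sheet_path:
        @stage("load_counts")
        def cm():
            return io.read_count_matrix(config.counts_path, config.sample_sheet_path)
    elif config.simulate is not None:
        @stage("simulate_counts")
        def cm():
            sim_cfg = config.simulate
            result, t = generate_counts(sim_cfg)
            io.write_count_matrix(result, out / "counts.tsv", out / "sample_sheet.csv")
            t.to_csv(out / "ground_truth.tsv", sep="\t")
            return result
    else:
        report["stages"]["load_counts"] = {
            "status": "failed",
            "error": "neither counts paths nor a simulation block provided",
        }
        raise ValueError("config must provide counts paths or a simulation block")

    # --- QC ---------------------------------------------------------------
    @stage("qc")
    def qc():
        q = qc_summary(cm)
        q["replicate_correlations"].to_csv(out / "qc_replicate_correlations.tsv",
                                           sep="\t", index=False)
        q["pca"].to_csv(out / "qc_pca.tsv", sep="\t", index_label="sample_id")
        return q
    report["qc"] = {
        "median_replicate_correlation": float(qc["replicate_correlations"]["r"].median()),
        "explained_variance_ratio": qc["explained_variance_ratio"],
    }

    # --- DGE comparisons --------------------------------------------------
    @stage("comparisons")
    def cs():
        result = run_comparisons(cm, alpha=config.alpha)
        for name, table in result.tables.items():
            io.write_dge_table(table, out / f"dge_{name}.tsv")
        return result

    # --- filter + classification -----------------------------------------
    @stage("classify")
    def classification():
        decisions = apply_filter(cs, alpha=config.alpha,
                                 strict_enrichment_confirm=config.strict_enrichment_confirm)
        decisions.to_csv(out / "filter_decisions.tsv", sep="\t", index=False)
        c = classify_translatome(decisions)
        c.table.to_csv(out / "classification.tsv", sep="\t", index_label="gene_id")
        return c
    report["translatome"] = classification.summary

    # --- learning effects -------------------------------------------------
    @stage("effects")
    def eff():
        axon = cs["trap_trained_vs_control_axon"]
        cortex = cs["trap_trained_vs_control_cortex"]
        conc = direction_concordance(axon, cortex, alpha=config.alpha)
        result = {"concordance": conc.to_dict()}
        both = axon.index[((axon["padj"] < config.alpha).fillna(False))
                          & ((cortex["padj"] < config.alpha).fillna(False))]
        if len(both) >= 3:
            result["effect_correlation_both_regulated"] = effect_correlation(
                axon, cortex, subset=both, min_p_for_line=config.min_p_for_line)
        else:
            result["effect_correlation_both_regulated"] = {
                "omitted": True, "note": "fewer than 3 genes regulated in both areas"}
        groups = expression_by_group(cm, axon, cortex, alpha=config.alpha)
        groups["groups"].to_csv(out / "expression_by_group.tsv", sep="\t")
        result["expression_anova"] = {
            k: groups["anova"][k] for k in ("F", "df", "p", "eta_squared")}
        from .dge import size_factors
        sf = size_factors(cm.counts)
        norm = cm.counts / sf
        vectors = {}
        for comp in ("axon", "cortex"):
            for cond in ("control", "trained"):
                samples = cm.samples_in(fraction="trap", compartment=comp, condition=cond)
                vectors[f"{comp}_{cond}"] = norm[samples].mean(axis=1)
        tops = top_abundance_union(vectors, n_top=config.n_top)
        result["top_abundance_union_size"] = tops["union_size"]
        return result
    report["effects"] = eff

    # --- transcript contributions ----------------------------------------
    if config.transcript_table_path or config.simulate is not None:
        @stage("transcripts")
        def tx():
            if config.transcript_table_path:
                table = io.read_transcript_table(config.transcript_table_path)
            else:
                table, _ = generate_transcript_table(config.simulate)
                io.write_transcript_table(table, out / "transcript_table.tsv")
            scores = contribution_scores(table)
            scores.to_csv(out / "contribution_scores.tsv", sep="\t", index=False)
            corr = score_correlation(scores)
            div = divergent_transcripts(scores, threshold=config.divergence_threshold)
            div.to_csv(out / "divergent_transcripts.tsv", sep="\t", index=False)
            return {
                "n_transcripts": int(len(scores)),
                "n_valid": int(scores["valid"].sum()),
                "score_correlation": corr,
                "n_divergent_genes": int(len(div)),
            }
        report["transcripts"] = tx
    else:
        report["stages"]["transcripts"] = {"status": "skipped"}

    # --- colocalization ---------------------------------------------------
    if config.simulate_images is not None:
        @stage("coloc")
        def coloc():
            from .coloc import ImagePair, subtract_background
            pair, _ = generate_image_pair(config.simulate_images)
            io.write_image(pair.ch1, out / "coloc_ch1.tif")
            io.write_image(pair.ch2, out / "coloc_ch2.tif")
            bg = config.simulate_images.background_mean
            pair = ImagePair(subtract_background(pair.ch1, bg),
                             subtract_background(pair.ch2, bg),
                             roi_masks=pair.roi_masks, background_subtracted=True)
            rois = list(pair.roi_masks) or [None]
            results = {}
            for roi in rois:
                t1, t2, slope, intercept = costes_threshold(pair, roi)
                m1, m2 = manders(pair, t1, t2, roi)
                results[roi or "full"] = {
                    "t1": t1, "t2": t2, "slope": slope, "intercept": intercept,
                    "M1": m1, "M2": m2,
                }
            return results
        report["coloc"] = coloc
    else:
        report["stages"]["coloc"] = {"status": "skipped"}

    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    _log(f"report written to {summary_path}")
    return report
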