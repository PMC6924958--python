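"""Stringent translatome filtering and classification.

Three rules are applied to each of the four TRAP comparisons,
per gene:

1. the gene must be differentially expressed (padj < alpha) between
   the TRAPed samples;
2. it is excluded if the corresponding tissue-transcriptome comparison
   shows the same effect (padj < alpha with the same sign) — a
   significant opposite-sign transcriptome change does not exclude;
3. it is excluded if the sample on the enriched (upregulated) side is
   not itself enriched over its tissue transcriptome (padj < alpha and
   log2FC > 0 in the TRAP-over-transcriptome comparison of that
   design cell).

A surviving gene is *axonal* if it is learning-regulated in axons,
enriched in axons vs cortex in either condition, or both; cortex flags
are symmetric.  The classification partitions the gene universe into
axonal_only / shared / cortex_only / none.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .comparisons import CELL_MAP, TRAP_COMPARISONS, TWIN_MAP, ComparisonSet
from .dge import CONDITIONS

__all__ = [
    "FilterDecisions",
    "TranslatomeClassification",
    "apply_filter",
    "classify_translatome",
    "background_overlap_audit",
    "round_pct",
]

AUDIT_CODES = ("pass", "not_de", "transcriptome_mirror", "not_trap_enriched", "untested")


def round_pct(fraction: float) -> int:
    """Percentage rounded half-away-from-zero to an integer."""
    x = fraction * 100.0
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


def _enriched_cell(comparison: str, direction: int) -> tuple[str, str]:
    """Design cell (compartment, condition) on the upregulated side."""
    parts = comparison.split("_")
    if "axon_vs_cortex" in comparison:
        cond = parts[-1]
        return ("axon" if direction > 0 else "cortex", cond)
    comp = parts[-1]
    return (comp, "trained" if direction > 0 else "control")


def apply_filter(
    cs: ComparisonSet,
    alpha: float | None = None,
    strict_enrichment_confirm: bool = True,
) -> pd.DataFrame:
    """Evaluate the three filter rules per gene x TRAP comparison.

    Returns a long DataFrame with one row per (gene_id, comparison) and
    columns de, direction (+1/-1/0), transcriptome_mirror,
    enrichment_confirmed, survives, audit_code.  With
    ``strict_enrichment_confirm`` (default) rule 3 is applied to all
    four TRAP comparisons; otherwise only to the axon-vs-cortex
    enrichment comparisons (rule 3 then holds vacuously for the
    learning comparisons).
    """
    if alpha is None:
        alpha = cs.alpha
    frames = []
    genes = cs.gene_ids
    for comp_name in TRAP_COMPARISONS:
        trap = cs[comp_name]
        twin = cs[TWIN_MAP[comp_name]]
        tested = trap["tested"].to_numpy(bool)
        padj = trap["padj"].to_numpy(float)
        lfc = trap["log2fc"].to_numpy(float)
        de = tested & (padj < alpha)
        direction = np.where(de, np.sign(lfc), 0.0).astype(int)

        twin_tested = twin["tested"].to_numpy(bool)
        twin_sig = twin_tested & (twin["padj"].to_numpy(float) < alpha)
        same_sign = np.sign(twin["log2fc"].to_numpy(float)) == np.sign(lfc)
        mirror = de & twin_sig & same_sign

        rule3_applies = strict_enrichment_confirm or "axon_vs_cortex" in comp_name
        confirmed = np.ones(len(genes), dtype=bool)
        required_untested = ~tested | (de & ~twin_tested)
        if rule3_applies:
            for d in (1, -1):
                cell = _enriched_cell(comp_name, d)
                ip = cs[cs.cell_map[cell]]
                ip_ok = (
                    ip["tested"].to_numpy(bool)
                    & (ip["padj"].to_numpy(float) < alpha)
                    & (ip["log2fc"].to_numpy(float) > 0)
                )
                sel = de & (direction == d)
                confirmed[sel] = ip_ok[sel]
                # the IP comparison is only *required* for genes reaching rule 3
                required_untested |= sel & ~mirror & ~ip["tested"].to_numpy(bool)

        survives = de & ~mirror & confirmed & ~required_untested
        audit = np.where(
            required_untested, "untested",
            np.where(~de, "not_de",
                     np.where(mirror, "transcriptome_mirror",
                              np.where(~confirmed, "not_trap_enriched", "pass"))),
        )
        frames.append(pd.DataFrame({
            "gene_id": genes,
            "comparison": comp_name,
            "de": de & ~required_untested,
            "direction": direction,
            "transcriptome_mirror": mirror,
            "enrichment_confirmed": confirmed,
            "survives": survives,
            "audit_code": audit,
        }))
    out = pd.concat(frames, ignore_index=True)
    return out


CLASSIFICATION_COLUMNS = [
    "axon_regulated_dir",
    "axon_enriched_control",
    "axon_enriched_trained",
    "cortex_regulated_dir",
    "cortex_enriched_control",
    "cortex_enriched_trained",
    "label",
]


@dataclass
class TranslatomeClassification:
    """Per-gene filter outcome flags, the final label, and summary counts."""

    table: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def genes_with_label(self, label: str) -> pd.Index:
        return self.table.index[self.table["label"] == label]

    @property
    def axonal(self) -> pd.Index:
        return self.table.index[self.table["label"].isin(["axonal_only", "shared"])]

    @property
    def cortical(self) -> pd.Index:
        return self.table.index[self.table["label"].isin(["cortex_only", "shared"])]

    @property
    def translatome(self) -> pd.Index:
        return self.table.index[self.table["label"] != "none"]


def summarize_classification(table: pd.DataFrame) -> dict:
    """Count fields and composition percentages from a classification table.

    Composition follows the partition: translatome genes regulated by
    learning in either area; of the remainder, those enriched only in
    cortex, only in axons, or (rarely) in both.
    """
    labels = table["label"]
    n_axonal_only = int((labels == "axonal_only").sum())
    n_shared = int((labels == "shared").sum())
    n_cortex_only = int((labels == "cortex_only").sum())
    n_axonal = n_axonal_only + n_shared
    n_translatome = n_axonal + n_cortex_only

    in_translatome = labels != "none"
    regulated = (table["axon_regulated_dir"] != 0) | (table["cortex_regulated_dir"] != 0)
    axon_enr = table["axon_enriched_control"] | table["axon_enriched_trained"]
    cortex_enr = table["cortex_enriched_control"] | table["cortex_enriched_trained"]
    n_regulated = int((in_translatome & regulated).sum())
    rem = in_translatome & ~regulated
    n_axon_enr_only = int((rem & axon_enr & ~cortex_enr).sum())
    n_cortex_enr_only = int((rem & cortex_enr & ~axon_enr).sum())
    n_enr_both = int((rem & cortex_enr & axon_enr).sum())

    def pct(k):
        return round_pct(k / n_translatome) if n_translatome else 0

    return {
        "n_genes": int(len(table)),
        "n_axonal": n_axonal,
        "n_axonal_only": n_axonal_only,
        "n_shared": n_shared,
        "n_cortex_only": n_cortex_only,
        "n_translatome": n_translatome,
        "shared_of_translatome_pct": pct(n_shared),
        "axonal_of_translatome_pct": pct(n_axonal),
        "n_regulated": n_regulated,
        "n_axon_enriched_only": n_axon_enr_only,
        "n_cortex_enriched_only": n_cortex_enr_only,
        "n_enriched_both_areas": n_enr_both,
        "regulated_pct": pct(n_regulated),
        "axon_enriched_only_pct": pct(n_axon_enr_only),
        "cortex_enriched_only_pct": pct(n_cortex_enr_only),
    }


def classify_translatome(decisions: pd.DataFrame) -> TranslatomeClassification:
    """Fold per-comparison filter decisions into per-gene labels.

    A gene is axonal if it survives the axon learning comparison or
    survives an axon-vs-cortex comparison on the axon side (direction
    > 0); cortical flags are symmetric (cortex side = direction < 0 in
    axon-vs-cortex, or surviving the cortex learning comparison).
    Labels: shared (both), axonal_only, cortex_only, none.
    """
    genes = decisions.loc[decisions["comparison"] == TRAP_COMPARISONS[0], "gene_id"]
    genes = pd.Index(genes, name="gene_id")
    wide = {c: decisions[decisions["comparison"] == c].set_index("gene_id")
            for c in TRAP_COMPARISONS}

    def surv(comp):
        return wide[comp]["survives"].reindex(genes).fillna(False).to_numpy(bool)

    def sdir(comp):
        return wide[comp]["direction"].reindex(genes).fillna(0).to_numpy(int)

    axon_learning = "trap_trained_vs_control_axon"
    cortex_learning = "trap_trained_vs_control_cortex"
    out = pd.DataFrame(index=genes)
    out["axon_regulated_dir"] = np.where(surv(axon_learning), sdir(axon_learning), 0)
    out["cortex_regulated_dir"] = np.where(surv(cortex_learning), sdir(cortex_learning), 0)
    for cond in CONDITIONS:
        comp = f"trap_axon_vs_cortex_{cond}"
        out[f"axon_enriched_{cond}"] = surv(comp) & (sdir(comp) > 0)
        out[f"cortex_enriched_{cond}"] = surv(comp) & (sdir(comp) < 0)

    axonal = (
        (out["axon_regulated_dir"] != 0)
        | out["axon_enriched_control"] | out["axon_enriched_trained"]
    )
    cortical = (
        (out["cortex_regulated_dir"] != 0)
        | out["cortex_enriched_control"] | out["cortex_enriched_trained"]
    )
    out["label"] = np.select(
        [axonal & cortical, axonal, cortical],
        ["shared", "axonal_only", "cortex_only"],
        default="none",
    )
    out = out[CLASSIFICATION_COLUMNS]
    return TranslatomeClassification(table=out, summary=summarize_classification(out))


def background_overlap_audit(
    class_main: TranslatomeClassification,
    class_control: TranslatomeClassification,
) -> dict:
    """Compare a main classification with a background-control run.

    Reports, per run, the axonal/cortical overlap fraction under both
    candidate denominators (the whole translatome — the union of the
    axonal and cortical sets — and the axonal set alone), plus the
    cross-run intersections of the learning-regulated and axonal sets.
    """
    if not class_main.table.index.equals(class_control.table.index):
        raise ValueError("classifications cover different gene universes")

    def per_run(c: TranslatomeClassification) -> dict:
        s = c.summary
        n_shared, n_trans, n_ax = s["n_shared"], s["n_translatome"], s["n_axonal"]
        return {
            "n_axonal": n_ax,
            "n_cortical": s["n_shared"] + s["n_cortex_only"],
            "n_shared": n_shared,
            "n_translatome": n_trans,
            "overlap_of_translatome": n_shared / n_trans if n_trans else np.nan,
            "overlap_of_translatome_pct": round_pct(n_shared / n_trans) if n_trans else None,
            "overlap_of_axonal": n_shared / n_ax if n_ax else np.nan,
        }

    def regulated(c, col):
        return set(c.table.index[c.table[col] != 0])

    report = {"main": per_run(class_main), "control": per_run(class_control)}
    for col, key in (("axon_regulated_dir", "axon_regulated"),
                     ("cortex_regulated_dir", "cortex_regulated")):
        a, b = regulated(class_main, col), regulated(class_control, col)
        report[f"{key}_intersection"] = sorted(a & b)
        report[f"n_{key}_main"] = len(a)
        report[f"n_{key}_control"] = len(b)
    ax_a, ax_b = set(class_main.axonal), set(class_control.axonal)
    report["axonal_intersection_size"] = len(ax_a & ax_b)
    return report
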