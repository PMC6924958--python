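"""Transcript-level contribution scores.

For a gene regulated by learning, each transcript's contribution score
is C = Delta FPKM(transcript) / Delta FPKM(gene) per area, where the
gene-level Delta FPKM is the sum of its transcripts' (so valid scores
sum to one per gene and area; scores can fall outside [0, 1] when
transcripts move in opposite directions).  Divergent genes are those
whose per-transcript scores differ between axons and cortex by more
than a threshold (default 0.3 — more than 30% of the learning effect
on different transcripts).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .dge import COMPARTMENTS

__all__ = [
    "contribution_scores",
    "score_correlation",
    "divergent_transcripts",
    "TRANSCRIPT_COLUMNS",
]

TRANSCRIPT_COLUMNS = [
    "gene_id", "transcript_id",
    "fpkm_axon_control", "fpkm_axon_trained",
    "fpkm_cortex_control", "fpkm_cortex_trained",
]

MIN_GENE_DELTA = 1e-6


def _validate_table(tt: pd.DataFrame) -> pd.DataFrame:
    missing = set(TRANSCRIPT_COLUMNS) - set(tt.columns)
    if missing:
        raise ValueError(f"transcript table missing columns: {sorted(missing)}")
    if tt.duplicated(subset=["gene_id", "transcript_id"]).any():
        dup = tt[tt.duplicated(subset=["gene_id", "transcript_id"])]
        raise ValueError(f"duplicate (gene, transcript) keys: "
                         f"{dup[['gene_id', 'transcript_id']].values.tolist()[:5]}")
    fpkm_cols = TRANSCRIPT_COLUMNS[2:]
    if (tt[fpkm_cols].to_numpy(float) < 0).any():
        raise ValueError("FPKM values must be non-negative")
    return tt


def contribution_scores(
    tt: pd.DataFrame, min_gene_delta: float = MIN_GENE_DELTA
) -> pd.DataFrame:
    """Per-transcript contribution scores per area.

    Returns one row per (gene_id, transcript_id) with columns c_axon,
    c_cortex, divergence (|c_axon - c_cortex|), and valid.  A gene is
    invalid in an area when |gene Delta FPKM| < min_gene_delta there
    (no score is emitted: columns are NaN); ``valid`` requires both
    areas.
    """
    tt = _validate_table(tt)
    out = tt[["gene_id", "transcript_id"]].copy()
    valid_all = np.ones(len(tt), dtype=bool)
    for area in COMPARTMENTS:
        delta_t = (tt[f"fpkm_{area}_trained"] - tt[f"fpkm_{area}_control"]).to_numpy(float)
        delta_gene = pd.Series(delta_t).groupby(tt["gene_id"].to_numpy()).transform("sum").to_numpy()
        ok = np.abs(delta_gene) >= min_gene_delta
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.where(ok, delta_t / delta_gene, np.nan)
        out[f"c_{area}"] = c
        valid_all &= ok
    out["divergence"] = np.abs(out["c_axon"] - out["c_cortex"])
    out["valid"] = valid_all
    return out


def score_correlation(
    scores: pd.DataFrame,
    direction_classes: dict[str, list] | None = None,
    min_pairs: int = 3,
) -> dict:
    """Pearson correlation of (c_axon, c_cortex) pairs per direction class.

    ``direction_classes`` maps a class name (e.g. ``axon_up_cortex_down``)
    to the gene ids in that class; with None a single class over all
    valid transcripts is used.  Classes with fewer than ``min_pairs``
    valid pairs are omitted with a note.
    """
    valid = scores[scores["valid"]]
    if direction_classes is None:
        direction_classes = {"all": list(valid["gene_id"].unique())}
    out: dict = {}
    for name, genes in direction_classes.items():
        sub = valid[valid["gene_id"].isin(set(genes))]
        x = sub["c_axon"].to_numpy(float)
        y = sub["c_cortex"].to_numpy(float)
        if len(x) < min_pairs or np.ptp(x) == 0 or np.ptp(y) == 0:
            out[name] = {"omitted": True,
                         "note": f"fewer than {min_pairs} valid pairs or degenerate scores"}
            continue
        r, p = stats.pearsonr(x, y)
        out[name] = {"omitted": False, "r": float(r), "p": float(p), "n": int(len(x))}
    return out


def divergent_transcripts(scores: pd.DataFrame, threshold: float = 0.3) -> pd.DataFrame:
    """Genes with a transcript whose area scores differ by > threshold.

    Returns one row per flagged gene (gene_id, max divergence, the
    transcript attaining it), sorted by divergence descending.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    valid = scores[scores["valid"]].dropna(subset=["divergence"])
    if valid.empty:
        return pd.DataFrame(columns=["gene_id", "divergence", "transcript_id"])
    idx = valid.groupby("gene_id")["divergence"].idxmax()
    per_gene = valid.loc[idx, ["gene_id", "divergence", "transcript_id"]]
    flagged = per_gene[per_gene["divergence"] > threshold]
    return flagged.sort_values("divergence", ascending=False).reset_index(drop=True)
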