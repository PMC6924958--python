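"""Gene-level learning analyses.

Direction concordance of learning effects between axons and cortex,
effect-size correlation, expression summaries by regulation group with
one-way ANOVA and Bonferroni post hocs, the most-abundant-gene union,
and generic gene-list overlap against published reference sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .dge import COMPARTMENTS, CountMatrix, size_factors
from .filtering import round_pct

__all__ = [
    "ConcordanceReport",
    "direction_concordance",
    "effect_correlation",
    "expression_by_group",
    "top_abundance_union",
    "gene_list_overlap",
    "one_way_anova",
]


@dataclass
class ConcordanceReport:
    """Counts of learning-regulated genes by area and direction agreement."""

    n_regulated_total: int
    n_both_areas: int
    n_axon_only: int
    n_cortex_only: int
    n_opposite_direction: int
    n_same_direction: int
    exception_genes: list[str]

    def __post_init__(self) -> None:
        assert self.n_both_areas == self.n_opposite_direction + self.n_same_direction
        assert self.n_regulated_total == (
            self.n_both_areas + self.n_axon_only + self.n_cortex_only
        )

    @property
    def both_areas_pct(self) -> int:
        if self.n_regulated_total == 0:
            return 0
        return round_pct(self.n_both_areas / self.n_regulated_total)

    def to_dict(self) -> dict:
        return {
            "n_regulated_total": self.n_regulated_total,
            "n_both_areas": self.n_both_areas,
            "n_axon_only": self.n_axon_only,
            "n_cortex_only": self.n_cortex_only,
            "n_opposite_direction": self.n_opposite_direction,
            "n_same_direction": self.n_same_direction,
            "both_areas_pct": self.both_areas_pct,
            "exception_genes": list(self.exception_genes),
        }


def direction_concordance(
    axon_dge: pd.DataFrame, cortex_dge: pd.DataFrame, alpha: float = 0.05
) -> ConcordanceReport:
    """Classify genes regulated in >= 1 area by where and how they agree.

    The exceptions list holds genes significant in both areas with the
    same sign of log2 fold change (the near-universal pattern in this
    design is opposite-direction regulation).
    """
    if not axon_dge.index.equals(cortex_dge.index):
        raise ValueError("DGE tables cover different gene universes")
    sig_a = (axon_dge["padj"] < alpha).fillna(False).to_numpy(bool)
    sig_c = (cortex_dge["padj"] < alpha).fillna(False).to_numpy(bool)
    sign_a = np.sign(axon_dge["log2fc"].to_numpy(float))
    sign_c = np.sign(cortex_dge["log2fc"].to_numpy(float))
    both = sig_a & sig_c
    same = both & (sign_a == sign_c)
    return ConcordanceReport(
        n_regulated_total=int((sig_a | sig_c).sum()),
        n_both_areas=int(both.sum()),
        n_axon_only=int((sig_a & ~sig_c).sum()),
        n_cortex_only=int((sig_c & ~sig_a).sum()),
        n_opposite_direction=int((both & ~same).sum()),
        n_same_direction=int(same.sum()),
        exception_genes=list(axon_dge.index[same]),
    )


def effect_correlation(
    axon_dge: pd.DataFrame,
    cortex_dge: pd.DataFrame,
    subset=None,
    min_p_for_line: float = 1e-5,
) -> dict:
    """Pearson correlation of log2 fold changes between areas.

    The OLS regression line is reported only when the correlation is
    significant at ``min_p_for_line`` (default 1e-5), mirroring the
    practice of drawing lines only for strongly significant fits.
    """
    if subset is None:
        subset = axon_dge.index
    subset = pd.Index(subset)
    if len(subset) < 3:
        raise ValueError("subset must contain at least 3 genes")
    x = axon_dge.loc[subset, "log2fc"].to_numpy(float)
    y = cortex_dge.loc[subset, "log2fc"].to_numpy(float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("fewer than 3 finite log2fc pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    out = {"r": float(r), "p": float(p), "n": int(len(x)),
           "slope": None, "intercept": None}
    if p < min_p_for_line:
        slope, intercept = np.polyfit(x, y, 1)
        out["slope"], out["intercept"] = float(slope), float(intercept)
    return out


def one_way_anova(groups: dict[str, np.ndarray]) -> dict:
    """One-way ANOVA via the sum-of-squares decomposition, with eta^2."""
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    arrays = {k: v for k, v in arrays.items() if v.size > 0}
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least 2 non-empty groups")
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 values")
    allv = np.concatenate(list(arrays.values()))
    grand = allv.mean()
    ss_total = ((allv - grand) ** 2).sum()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in arrays.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in arrays.values())
    df_b = len(arrays) - 1
    df_w = allv.size - len(arrays)
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    f = ms_b / ms_w if ms_w > 0 else (0.0 if ms_b == 0 else np.inf)
    p = float(stats.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    eta2 = ss_between / ss_total if ss_total > 0 else 0.0
    return {"F": float(f), "df": (int(df_b), int(df_w)), "p": p,
            "eta_squared": float(eta2),
            "ss_between": float(ss_between), "ss_within": float(ss_within),
            "ss_total": float(ss_total)}


def _bonferroni_pairwise(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    names = [k for k, v in groups.items() if len(v) >= 2]
    pairs = list(combinations(names, 2))
    out = {}
    for a, b in pairs:
        _, p = stats.ttest_ind(groups[a], groups[b])
        out[(a, b)] = float(min(1.0, p * len(pairs)))
    return out


def expression_by_group(
    cm: CountMatrix,
    axon_dge: pd.DataFrame,
    cortex_dge: pd.DataFrame,
    alpha: float = 0.05,
    exclude_gene_sets: dict[str, set] | None = None,
) -> dict:
    """Mean expression of genes binned by learning-regulation group.

    Genes are binned per area as up / down / ns by the area's learning
    DGE table; a gene's expression value is log10(x+1) of its mean
    size-factor-normalized count over that area's TRAP samples.  Bins
    are compared by one-way ANOVA with Bonferroni-adjusted pairwise
    t-tests.  ``exclude_gene_sets`` removes named gene sets before
    binning (to check robustness of the group means).  Empty bins are
    reported with n = 0 and omitted from the ANOVA.
    """
    sf = size_factors(cm.counts)
    norm = cm.counts / sf
    excluded: set = set()
    for s in (exclude_gene_sets or {}).values():
        excluded |= set(s)
    keep = ~cm.gene_ids.isin(excluded)

    dge = {"axon": axon_dge, "cortex": cortex_dge}
    groups: dict[str, np.ndarray] = {}
    summary_rows = []
    for area in COMPARTMENTS:
        samples = cm.samples_in(fraction="trap", compartment=area)
        expr = np.log10(norm[samples].mean(axis=1).to_numpy(float) + 1.0)
        t = dge[area]
        sig = (t["padj"] < alpha).fillna(False).to_numpy(bool)
        sign = np.sign(t["log2fc"].to_numpy(float))
        bins = {
            "up": sig & (sign > 0),
            "down": sig & (sign < 0),
            "ns": ~sig,
        }
        for cls, mask in bins.items():
            key = f"{area}_{cls}"
            vals = expr[mask & keep]
            groups[key] = vals
            summary_rows.append({
                "group": key, "n": int(vals.size),
                "mean": float(vals.mean()) if vals.size else np.nan,
                "sem": float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan,
            })
    anova_groups = {k: v for k, v in groups.items() if v.size >= 2}
    anova = one_way_anova(anova_groups)
    pairwise = _bonferroni_pairwise(anova_groups)
    return {
        "groups": pd.DataFrame(summary_rows).set_index("group"),
        "anova": anova,
        "bonferroni_pairwise": {f"{a}|{b}": p for (a, b), p in pairwise.items()},
    }


def top_abundance_union(expression: dict[str, pd.Series], n_top: int) -> dict:
    """Union of the n_top most-abundant genes in each expression vector.

    Ties are broken by gene_id position in the vector's index
    (first-come), and the per-vector top lists are reported so the
    tie-break is auditable.
    """
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    per_vector = {}
    union: set = set()
    for name, vec in expression.items():
        if n_top > len(vec):
            raise ValueError(f"n_top exceeds universe size for {name!r}")
        order = np.lexsort((np.arange(len(vec)), -vec.to_numpy(float)))
        top = list(vec.index[order[:n_top]])
        per_vector[name] = top
        union |= set(top)
    return {"union": sorted(union), "union_size": len(union), "per_vector": per_vector}


def gene_list_overlap(query_set, reference_lists: dict[str, set]) -> dict:
    """Overlap of a query gene set with named reference lists.

    Reports each pairwise intersection size and the fraction of the
    query covered by the union of all reference lists.
    """
    query = set(query_set)
    if not query:
        raise ValueError("query set is empty")
    per_list = {}
    union: set = set()
    for name, ref in reference_lists.items():
        ref = set(ref)
        per_list[name] = len(query & ref)
        union |= ref
    n_cov = len(query & union)
    coverage = n_cov / len(query)
    return {
        "n_query": len(query),
        "per_list": per_list,
        "n_in_union": n_cov,
        "union_coverage": coverage,
        "union_coverage_pct": round_pct(coverage),
    }
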