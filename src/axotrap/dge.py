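"""Negative-binomial two-group differential expression.

A transparent, self-contained DGE stage: median-of-ratios size factors,
gene-wise method-of-moments dispersion, a Wald test on the log2 fold
change, and Benjamini-Hochberg adjustment.  The model is NB with
``var = mu + alpha * mu**2``, the same parameterization the synthetic
count generator uses.  No fold-change shrinkage, dispersion trend
fitting, or independent filtering is applied: the scientific content of
the pipeline lives in the downstream filtering logic, and a small test
surface keeps every step auditable.  Externally produced DGE tables
(at least ``gene_id, log2fc, padj``) are accepted anywhere a result
table is consumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "FRACTIONS",
    "COMPARTMENTS",
    "CONDITIONS",
    "size_factors",
    "estimate_dispersion",
    "bh_adjust",
    "test_dge",
]

FRACTIONS = ("trap", "transcriptome")
COMPARTMENTS = ("axon", "cortex")
CONDITIONS = ("control", "trained")

DISPERSION_FLOOR = 1e-8

#: Columns of a DGE result table.
DGE_COLUMNS = ["base_mean", "log2fc", "lfc_se", "wald_stat", "pvalue", "padj", "tested"]


@dataclass
class CountMatrix:
    """Gene x sample integer counts plus the 2x2x2 design sheet.

    ``counts`` is a genes-by-samples DataFrame of non-negative integers.
    ``sample_sheet`` is indexed by sample_id with columns ``fraction``
    (trap / transcriptome), ``compartment`` (axon / cortex),
    ``condition`` (control / trained) and ``replicate``.
    """

    counts: pd.DataFrame
    sample_sheet: pd.DataFrame

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            raise ValueError("gene_ids must be unique")
        if counts.columns.has_duplicates:
            raise ValueError("sample_ids must be unique")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            self.counts = counts = counts.round().astype(np.int64)
            arr = counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        sheet = self.sample_sheet
        missing = set(counts.columns) - set(sheet.index)
        if missing:
            raise ValueError(f"samples absent from sample sheet: {sorted(missing)}")
        for col, allowed in (
            ("fraction", FRACTIONS),
            ("compartment", COMPARTMENTS),
            ("condition", CONDITIONS),
        ):
            if col not in sheet.columns:
                raise ValueError(f"sample sheet missing column {col!r}")
            bad = set(sheet[col]) - set(allowed)
            if bad:
                raise ValueError(f"invalid {col} values: {sorted(bad)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def group_of(self, sample_id: str) -> tuple[str, str, str]:
        row = self.sample_sheet.loc[sample_id]
        return (row["fraction"], row["compartment"], row["condition"])

    def samples_in(self, fraction=None, compartment=None, condition=None) -> list[str]:
        """Sample ids matching the given design-cell coordinates."""
        sheet = self.sample_sheet.loc[list(self.counts.columns)]
        mask = pd.Series(True, index=sheet.index)
        if fraction is not None:
            mask &= sheet["fraction"] == fraction
        if compartment is not None:
            mask &= sheet["compartment"] == compartment
        if condition is not None:
            mask &= sheet["condition"] == condition
        return list(sheet.index[mask])

    def groups(self) -> dict[tuple[str, str, str], list[str]]:
        """Map each of the (up to 8) design cells to its sample ids."""
        out: dict[tuple[str, str, str], list[str]] = {}
        for s in self.counts.columns:
            out.setdefault(self.group_of(s), []).append(s)
        return out


def size_factors(counts: pd.DataFrame | CountMatrix) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample.

    For each gene with a positive geometric mean across samples, the
    ratio count / geometric-mean is formed; a sample's factor is the
    median of its ratios.  Scale-equivariant: multiplying one column by
    c multiplies its factor by c.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    arr = counts.to_numpy(dtype=float)
    zero_samples = np.where((arr == 0).all(axis=0))[0]
    if zero_samples.size:
        names = [str(counts.columns[i]) for i in zero_samples]
        raise ValueError(f"sample(s) with all-zero counts: {names}")
    with np.errstate(divide="ignore"):
        logs = np.log(arr)
    finite = np.isfinite(logs).all(axis=1)
    if not finite.any():
        raise ValueError("no gene has nonzero counts in every sample; "
                         "size factors are undefined")
    log_geomean = logs[finite].mean(axis=1)
    log_ratios = logs[finite] - log_geomean[:, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame,
    groups: list[list[str]],
    sf: pd.Series | None = None,
) -> pd.Series:
    """Gene-wise NB dispersion alpha by pooled method of moments.

    On size-factor-normalized counts, alpha_g = max(floor,
    (pooled within-group variance - mean) / mean^2), with the pooled
    variance combining within-group sums of squares across ``groups``
    and the mean taken over all involved samples.  floor = 1e-8.
    """
    involved = [s for g in groups for s in g]
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs >= 2 replicates to estimate dispersion")
    if sf is None:
        sf = size_factors(counts[involved])
    norm = counts[involved].to_numpy(dtype=float) / sf.loc[involved].to_numpy()
    norm_df = pd.DataFrame(norm, index=counts.index, columns=involved)
    ss = np.zeros(len(counts))
    df_total = 0
    for g in groups:
        sub = norm_df[g].to_numpy()
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df_total += len(g) - 1
    pooled_var = ss / df_total
    mean = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - mean) / mean**2
    alpha = np.where(np.isfinite(alpha), alpha, DISPERSION_FLOOR)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)
    return pd.Series(alpha, index=counts.index, name="dispersion")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, in input order.

    adj_(i) = min_{j>=i} ( p_(j) * m / j ), capped at 1, over the m
    non-missing entries; NaNs pass through untouched.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    vals = p[mask]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = vals.size
    if m == 0:
        return out
    order = np.argsort(vals, kind="stable")
    ranked = vals[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[mask] = restored
    return out


def _group_mean_variance(mu: np.ndarray, alpha: np.ndarray, sf_group: np.ndarray) -> np.ndarray:
    # Var of the mean of normalized counts: each normalized count k_s/sf_s has
    # variance mu/sf_s + alpha*mu^2 under NB(mean sf_s*mu, alpha).
    n = sf_group.size
    per_sample = mu[:, None] / sf_group[None, :] + alpha[:, None] * (mu[:, None] ** 2)
    return per_sample.sum(axis=1) / n**2


#: Prior degrees of freedom for dispersion moderation in ``test_dge``.
DISPERSION_PRIOR_DF = 10.0


def test_dge(
    counts: pd.DataFrame | CountMatrix,
    group_a_samples: list[str],
    group_b_samples: list[str],
    alpha_fdr: float = 0.05,
    sf: pd.Series | None = None,
    prior_df: float = DISPERSION_PRIOR_DF,
) -> pd.DataFrame:
    """NB Wald test of group B over group A with a moderated SE.

    Gene-wise method-of-moments dispersions are shrunk toward the
    median dispersion across genes with prior weight ``prior_df``
    (empirical-Bayes moderation, no trend fitting), and the Wald
    statistic log2fc / lfc_se is referred to a t distribution with
    residual-plus-prior degrees of freedom — the moderated-t inference
    that keeps raw p-values uniform under the null at small replicate
    numbers, where a plug-in dispersion with a normal reference is
    anticonservative.

    Returns a DataFrame indexed by gene_id with columns base_mean,
    log2fc (B over A), lfc_se, wald_stat, pvalue, padj (BH over tested
    genes) and tested.  Genes with zero counts in all involved samples
    are flagged untested and carry no p-values.  When either group mean
    is zero a 0.5 pseudo-count enters both group means so the fold
    change (and its variance floor) stays finite.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    a = list(group_a_samples)
    b = list(group_b_samples)
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    if set(a) & set(b):
        raise ValueError(f"groups overlap: {sorted(set(a) & set(b))}")
    involved = a + b
    missing = set(involved) - set(counts.columns)
    if missing:
        raise ValueError(f"unknown samples: {sorted(missing)}")
    if sf is None:
        sf = size_factors(counts[involved])
    sf = sf.loc[involved]
    alpha_raw = estimate_dispersion(counts, [a, b], sf=sf).to_numpy()

    raw = counts[involved].to_numpy(dtype=float)
    norm = raw / sf.to_numpy()
    norm_df = pd.DataFrame(norm, index=counts.index, columns=involved)
    mu_a = norm_df[a].mean(axis=1).to_numpy()
    mu_b = norm_df[b].mean(axis=1).to_numpy()
    base_mean = norm.mean(axis=1)
    tested = raw.sum(axis=1) > 0

    resid_df = len(a) + len(b) - 2
    prior = float(np.median(alpha_raw[tested])) if tested.any() else DISPERSION_FLOOR
    alpha_disp = (resid_df * alpha_raw + prior_df * prior) / (resid_df + prior_df)

    needs_pseudo = (mu_a == 0) | (mu_b == 0)
    m_a = np.where(needs_pseudo, mu_a + 0.5, mu_a)
    m_b = np.where(needs_pseudo, mu_b + 0.5, mu_b)

    log2fc = np.log2(m_b) - np.log2(m_a)
    var_a = _group_mean_variance(m_a, alpha_disp, sf.loc[a].to_numpy())
    var_b = _group_mean_variance(m_b, alpha_disp, sf.loc[b].to_numpy())
    ln2 = np.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(var_a / m_a**2 + var_b / m_b**2) / ln2
    se = np.maximum(se, 1e-12)
    wald = log2fc / se
    pvalue = 2.0 * stats.t.sf(np.abs(wald), resid_df + prior_df)

    result = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "lfc_se": se,
            "wald_stat": wald,
            "pvalue": pvalue,
            "padj": np.nan,
            "tested": tested,
        },
        index=counts.index,
    )
    result.index.name = "gene_id"
    untested_cols = ["log2fc", "lfc_se", "wald_stat", "pvalue", "padj"]
    result.loc[~tested, untested_cols] = np.nan
    result.loc[tested, "padj"] = bh_adjust(result.loc[tested, "pvalue"].to_numpy())
    return result
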