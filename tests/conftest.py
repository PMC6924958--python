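import numpy as np
import pandas as pd
import pytest

from axotrap import ComparisonSet, CountMatrix, SimConfig, generate_counts
from axotrap.comparisons import COMPARISON_NAMES


@pytest.fixture(scope="session")
def small_sim():
    """A small 8-group simulation with planted effects, shared across tests."""
    cfg = SimConfig(n_genes=800, n_replicates=4, seed=11)
    cm, truth = generate_counts(cfg)
    return cfg, cm, truth


def make_comparison_set(genes, entries, alpha=0.05):
    """Build a ComparisonSet from sparse hand-set (log2fc, padj) entries.

    ``entries`` maps comparison name -> {gene: (log2fc, padj)}; genes
    not mentioned default to log2fc 0, padj 1, tested.  padj None marks
    a gene untested in that comparison.
    """
    genes = pd.Index(genes, name="gene_id")
    tables = {}
    for name in COMPARISON_NAMES:
        t = pd.DataFrame(
            {
                "base_mean": 100.0,
                "log2fc": 0.0,
                "lfc_se": 0.1,
                "wald_stat": 0.0,
                "pvalue": 1.0,
                "padj": 1.0,
                "tested": True,
            },
            index=genes,
        )
        for gene, (lfc, padj) in entries.get(name, {}).items():
            if padj is None:
                t.loc[gene, ["log2fc", "pvalue", "padj"]] = np.nan
                t.loc[gene, "tested"] = False
            else:
                t.loc[gene, "log2fc"] = lfc
                t.loc[gene, "pvalue"] = padj
                t.loc[gene, "padj"] = padj
        tables[name] = t
    return ComparisonSet(tables=tables, alpha=alpha)


def make_count_matrix(counts, fractions, compartments, conditions):
    """CountMatrix from an array plus per-sample design coordinates."""
    counts = pd.DataFrame(np.asarray(counts))
    counts.index = [f"g{i}" for i in range(counts.shape[0])]
    counts.columns = [f"s{i}" for i in range(counts.shape[1])]
    sheet = pd.DataFrame(
        {
            "fraction": fractions,
            "compartment": compartments,
            "condition": conditions,
            "replicate": range(1, counts.shape[1] + 1),
        },
        index=counts.columns,
    )
    return CountMatrix(counts, sheet)
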