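"""Quality control: replicate correlations and PCA of the samples."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .dge import CountMatrix, size_factors

__all__ = ["qc_summary"]


def qc_summary(cm: CountMatrix) -> dict:
    """Replicate correlations and PCA coordinates on log-normalized counts.

    Pearson correlation of log2(normalized + 1) expression between every
    replicate pair within each of the design groups, and the first two
    principal components (gene-centered) per sample.
    """
    if cm.counts.shape[1] < 2:
        raise ValueError("QC needs at least 2 samples")
    sf = size_factors(cm.counts)
    logn = np.log2(cm.counts / sf + 1.0)

    rows = []
    for group, samples in cm.groups().items():
        for a, b in combinations(samples, 2):
            r = float(np.corrcoef(logn[a], logn[b])[0, 1])
            rows.append({"group": "_".join(group), "sample_a": a, "sample_b": b, "r": r})
    rep_corr = pd.DataFrame(rows, columns=["group", "sample_a", "sample_b", "r"])

    from sklearn.decomposition import PCA
    X = logn.to_numpy(float).T  # samples x genes
    n_comp = min(2, X.shape[0] - 1) or 1
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(X)
    if coords.shape[1] < 2:
        coords = np.column_stack([coords, np.zeros(len(coords))])
        var = np.append(pca.explained_variance_ratio_, 0.0)
    else:
        var = pca.explained_variance_ratio_[:2]
    pca_df = pd.DataFrame(coords[:, :2], index=logn.columns, columns=["pc1", "pc2"])
    return {
        "replicate_correlations": rep_corr,
        "pca": pca_df,
        "explained_variance_ratio": [float(v) for v in var[:2]],
    }
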