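"""PCA, hierarchical clustering, TUS and QC-dispersion diagnostics.

These are the instruments used throughout the workflow to judge data
quality and the effect of signal selection: clustering of pooled-QC
injections near the centre of the PCA score plot indicates instrument
stability, and the fraction of variance captured by the first principal
component after selection quantifies how strongly the retained signals
follow the cell count.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .core import FeatureMatrix, ValidationError, align


def pca(matrix: FeatureMatrix):
    """Principal component analysis with samples as observations.

    Expects the log10 + range-scaled matrix (no further standardization is
    applied).  Returns ``(scores, loadings, explained)`` where ``scores`` is
    samples x components, ``loadings`` is signals x components and
    ``explained`` are variance fractions summing to 1.  Sign convention: the
    largest-magnitude loading of each component is positive.
    """
    if matrix.k < 1 or matrix.n_samples < 2:
        raise ValidationError("PCA needs >= 1 signal and >= 2 samples")
    X = matrix.abundance.to_numpy(dtype=float).T  # samples x signals
    if np.isnan(X).any():
        raise ValidationError("missing values present; impute before PCA")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((S ** 2).sum())
    explained = (S ** 2) / total if total > 0 else np.zeros_like(S)
    # deterministic sign: largest |loading| positive per component
    for c in range(Vt.shape[0]):
        j = int(np.abs(Vt[c]).argmax())
        if Vt[c, j] < 0:
            Vt[c] = -Vt[c]
            U[:, c] = -U[:, c]
    comp_names = [f"PC{i + 1}" for i in range(len(S))]
    scores = pd.DataFrame(U * S, index=matrix.sample_ids, columns=comp_names)
    loadings = pd.DataFrame(Vt.T, index=matrix.signal_ids, columns=comp_names)
    return scores, loadings, explained


def hclust(matrix: FeatureMatrix):
    """Agglomerative clustering of samples (Euclidean, complete linkage).

    Returns ``(linkage_matrix, labels, leaf_order)``; ties broken
    deterministically by sample order.
    """
    if matrix.n_samples < 2:
        raise ValidationError("need at least 2 samples to cluster")
    X = matrix.abundance.to_numpy(dtype=float).T
    if np.isnan(X).any():
        raise ValidationError("missing values present; impute before HC")
    Z = linkage(X, method="complete", metric="euclidean")
    order = leaves_list(Z).tolist()
    return Z, matrix.sample_ids.tolist(), order


def tus_per_sample(matrix: FeatureMatrix) -> pd.Series:
    """Total useful signal: per-sample sum of retained-signal abundances."""
    return matrix.abundance.fillna(0.0).sum(axis=0).rename("tus")


def qc_cluster_check(scores: pd.DataFrame, samples: pd.DataFrame,
                     threshold: float = 0.5):
    """QC tightness in the first two PCA components.

    Ratio of the QC samples' mean distance to the QC centroid over all
    samples' mean distance to the overall centroid; passes iff the ratio is
    at most ``threshold``.  Returns ``(passed, ratio)``.
    """
    qc_ids = samples.index[samples["role"] == "qc"]
    qc_ids = qc_ids.intersection(scores.index)
    if len(qc_ids) < 2:
        raise ValidationError("need at least 2 QC samples in the scores")
    pcs = scores.iloc[:, : min(2, scores.shape[1])].to_numpy(dtype=float)
    qc = scores.loc[qc_ids].iloc[:, : pcs.shape[1]].to_numpy(dtype=float)

    def dispersion(points: np.ndarray) -> float:
        centroid = points.mean(axis=0, keepdims=True)
        return float(np.linalg.norm(points - centroid, axis=1).mean())

    overall = dispersion(pcs)
    if overall == 0:
        return True, 0.0
    ratio = dispersion(qc) / overall
    return ratio <= threshold, ratio
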