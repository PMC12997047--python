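"""Batch/drift corrections and normalization strategies.

Two QC-anchored corrections (inter-batch median rescaling and SVR-based
injection-order drift correction), the three post-selection normalizations
compared on the T-cell model (cell count, total useful signal, per-signal
median), and the log10 + range-scaling transform applied before PCA and
hierarchical clustering.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .core import FeatureMatrix, ValidationError, align
from .qa import qc_cv

log = logging.getLogger("lipocurve")


def interbatch_qc_median(matrix: FeatureMatrix, samples: pd.DataFrame):
    """Rescale each batch so per-signal QC medians agree across batches.

    For signal i in batch b: ``x -> x * m_i / m_ib`` with ``m_ib`` the median
    over batch-b QCs and ``m_i`` the median over all QCs.  Signals whose
    batch QC median is zero (or undefined) are left uncorrected in that
    batch and flagged.  A single batch is an identity transform.
    """
    samples = align(matrix, samples)
    batches = samples["batch"].unique().tolist()
    if len(batches) < 2:
        return matrix.copy(), []
    qc = samples[samples["role"] == "qc"]
    for b in batches:
        if (qc["batch"] == b).sum() == 0:
            raise ValidationError(f"batch {b!r} has no QC samples")
    m_all = matrix.abundance[list(qc.index)].median(axis=1)
    out = matrix.abundance.copy()
    flagged: set[str] = set()
    for b in batches:
        qc_b = qc.index[qc["batch"] == b]
        m_b = matrix.abundance[list(qc_b)].median(axis=1)
        factor = m_all / m_b
        bad = (m_b == 0) | m_b.isna() | m_all.isna()
        factor = factor.where(~bad, 1.0)
        flagged |= set(matrix.signal_ids[bad])
        cols = samples.index[samples["batch"] == b]
        out[list(cols)] = out[list(cols)].mul(factor, axis=0)
    if flagged:
        log.warning("inter-batch correction skipped for %d signal(s) with "
                    "zero/undefined batch QC median", len(flagged))
    return matrix.with_abundance(out), sorted(flagged)


def qc_drift_correct(matrix: FeatureMatrix, samples: pd.DataFrame,
                     epsilon: float = 0.05, c: float = 1.0,
                     gamma: float | str = "scale"):
    """QC-anchored smooth drift correction along injection order.

    Per signal, a support-vector regression (RBF kernel, epsilon-insensitive
    loss) of QC abundance on injection order is fitted; every sample is
    divided by the fitted curve evaluated at its own injection order, then
    rescaled to the signal's QC median.  Guard: if the correction increases
    a signal's QC CV (or the fitted curve is nonpositive anywhere), that
    signal is reverted to its input values.

    Returns ``(matrix, reverted_ids)``.
    """
    samples = align(matrix, samples)
    qc = samples[samples["role"] == "qc"]
    if len(qc) < 5:
        raise ValidationError("need at least 5 QC injections for drift fitting")
    t_qc = qc["injection_order"].to_numpy(dtype=float)
    if np.unique(t_qc).size < 2:
        raise ValidationError("QCs sit at a single injection position")
    t_all = samples["injection_order"].to_numpy(dtype=float)
    lo, span = t_all.min(), max(t_all.max() - t_all.min(), 1.0)
    tq = ((t_qc - lo) / span).reshape(-1, 1)
    ta = ((t_all - lo) / span).reshape(-1, 1)

    pre_cv = qc_cv(matrix, samples)
    out = matrix.abundance.copy()
    reverted = []
    for sig in matrix.signal_ids:
        v = matrix.abundance.loc[sig, qc.index].to_numpy(dtype=float)
        ok = ~np.isnan(v)
        if ok.sum() < 5 or np.nanmedian(v) <= 0:
            reverted.append(sig)
            continue
        med = float(np.nanmedian(v))
        model = SVR(kernel="rbf", C=c, epsilon=epsilon, gamma=gamma)
        model.fit(tq[ok], v[ok] / med)
        curve = model.predict(ta)
        if (curve <= 0).any():
            reverted.append(sig)
            continue
        factor = pd.Series(curve, index=samples.index)
        out.loc[sig] = matrix.abundance.loc[sig] / factor
    corrected = matrix.with_abundance(out)
    post_cv = qc_cv(corrected, samples)
    worse = (post_cv > pre_cv).fillna(False)
    for sig in matrix.signal_ids[worse]:
        out.loc[sig] = matrix.abundance.loc[sig]
        reverted.append(sig)
    return matrix.with_abundance(out), sorted(set(map(str, reverted)))


def normalize_by_cell_count(matrix: FeatureMatrix, samples: pd.DataFrame):
    """Divide each sample's abundances by its cell count (``x_ij / c_j``)."""
    samples = align(matrix, samples)
    counts = samples["cell_count"]
    if counts.isna().any() or (counts <= 0).any():
        bad = samples.index[counts.isna() | (counts <= 0)].tolist()
        raise ValidationError(
            f"sample(s) without a positive cell count: {bad}"
        )
    return matrix.with_abundance(matrix.abundance.div(counts, axis=1))


def normalize_by_tus(matrix: FeatureMatrix) -> FeatureMatrix:
    """Divide each sample by its total useful signal (column sum over
    retained signals; missing values contribute 0)."""
    tus = matrix.abundance.fillna(0.0).sum(axis=0)
    if (tus <= 0).any():
        bad = matrix.sample_ids[tus <= 0].tolist()
        raise ValidationError(f"sample(s) with nonpositive TUS: {bad}")
    return matrix.with_abundance(matrix.abundance.div(tus, axis=1))


def normalize_by_median(matrix: FeatureMatrix):
    """Divide each signal by its median abundance across all samples.

    Signals with a zero median are flagged and left unnormalized.
    Returns ``(matrix, flagged_ids)``.
    """
    med = matrix.abundance.median(axis=1)
    flagged = matrix.signal_ids[(med == 0) | med.isna()].tolist()
    divisor = med.where(~((med == 0) | med.isna()), 1.0)
    if flagged:
        log.warning("median normalization skipped for %d signal(s) with "
                    "zero median", len(flagged))
    return matrix.with_abundance(matrix.abundance.div(divisor, axis=0)), flagged


def log10_range_scale(matrix: FeatureMatrix) -> FeatureMatrix:
    """Per-signal log10 transform followed by range scaling.

    ``y = log10(x)``; then ``z = (y - mean(y)) / (max(y) - min(y))`` per
    signal.  Zeros are replaced by half the signal's minimum positive value
    before the log (zeros are rare after QA and log(0) is undefined);
    constant signals (zero range) map to all zeros.  Missing values
    propagate — impute before PCA/HC.
    """
    X = matrix.abundance
    vals = X.to_numpy(dtype=float)
    if (vals[~np.isnan(vals)] < 0).any():
        raise ValidationError("negative abundances cannot be log-scaled")
    out = vals.copy()
    zero_rows = (out == 0).any(axis=1)
    for i in np.where(zero_rows)[0]:
        row = out[i]
        positive = row[(row > 0) & ~np.isnan(row)]
        if positive.size == 0:
            raise ValidationError(
                f"signal {X.index[i]!r} has no positive abundance"
            )
        row[row == 0] = positive.min() / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.log10(out)
    mean = np.nanmean(y, axis=1, keepdims=True)
    rng = np.nanmax(y, axis=1, keepdims=True) - np.nanmin(y, axis=1, keepdims=True)
    z = np.where(rng > 0, (y - mean) / np.where(rng > 0, rng, 1.0), 0.0)
    z = np.where(np.isnan(y), np.nan, z)
    return matrix.with_abundance(
        pd.DataFrame(z, index=X.index, columns=X.columns),
        allow_negative=True,
    )
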