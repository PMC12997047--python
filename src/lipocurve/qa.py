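"""Quality-assurance cascade for untargeted feature matrices.

Four stages, applied in this order: blank exceedance, QC detection rate,
k-NN imputation of the remaining missing values, and a QC coefficient-of-
variation cut.  Each stage is a pure function returning a new matrix; the
cascade emits a :class:`~lipocurve.core.QAReport` whose attrition always
balances (``k_in - removals = k_out``).

The CV filter deliberately runs *after* imputation and is computed on QC
injections only: QCs are repeated injections of one pool, so their spread
measures instrument precision, not biology.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import FeatureMatrix, QAReport, ValidationError, align
from .io import WorkflowConfig


def _condition_groups(samples: pd.DataFrame) -> list[pd.Index]:
    """Biological conditions for the blank rule: one group per distinct curve
    cell count, plus one per (timepoint x group) cell of the experiment."""
    groups: list[pd.Index] = []
    curve = samples[samples["role"] == "curve"]
    for count in sorted(curve["cell_count"].dropna().unique()):
        groups.append(curve.index[curve["cell_count"] == count])
    exp = samples[samples["role"] == "experimental"]
    if len(exp):
        for (_, _), cell in exp.groupby(["timepoint", "group"], sort=True):
            groups.append(cell.index)
    return groups


def filter_by_blank(matrix: FeatureMatrix, samples: pd.DataFrame,
                    rule: str = "any_condition"):
    """Keep signals whose condition means exceed the blank mean.

    ``rule='all_conditions'`` requires every condition mean to exceed the
    blank mean (a condition with no detections cannot exceed it);
    ``'any_condition'`` requires at least one defined condition mean to.
    Signals absent from all blanks (undefined blank mean) are kept.
    Missing values are ignored when averaging.
    """
    if rule not in ("any_condition", "all_conditions"):
        raise ValidationError(f"unknown blank rule {rule!r}")
    samples = align(matrix, samples)
    blank_ids = samples.index[samples["role"] == "blank"]
    if len(blank_ids) == 0:
        raise ValidationError(
            "no blank samples; skip the blank stage explicitly if none exist"
        )
    conditions = _condition_groups(samples)
    if not conditions:
        raise ValidationError("no curve or experimental conditions found")

    blank_mean = matrix.abundance[list(blank_ids)].mean(axis=1)
    cond_means = pd.DataFrame(
        {i: matrix.abundance[list(ids)].mean(axis=1)
         for i, ids in enumerate(conditions)}
    )
    exceeds = cond_means.gt(blank_mean, axis=0)  # NaN comparisons are False
    if rule == "any_condition":
        keep = exceeds.any(axis=1)
    else:
        keep = exceeds.all(axis=1)
    keep = keep | blank_mean.isna()  # undefined blank mean: kept
    removed = matrix.signal_ids[~keep].tolist()
    return matrix.subset_signals(matrix.signal_ids[keep]), removed


def filter_by_qc_presence(matrix: FeatureMatrix, samples: pd.DataFrame,
                          min_frac: float = 0.75):
    """Keep signals detected in at least ``min_frac`` of QC injections
    (boundary inclusive)."""
    samples = align(matrix, samples)
    qc_ids = samples.index[samples["role"] == "qc"]
    if len(qc_ids) < 2:
        raise ValidationError("need at least 2 QC samples")
    frac = matrix.abundance[list(qc_ids)].notna().sum(axis=1) / len(qc_ids)
    keep = frac >= min_frac
    removed = matrix.signal_ids[~keep].tolist()
    return matrix.subset_signals(matrix.signal_ids[keep]), removed


def impute_knn(matrix: FeatureMatrix, k: int = 5) -> FeatureMatrix:
    """k-nearest-neighbour imputation of missing abundances.

    Sample-to-sample distances are Euclidean on per-signal standardized
    log10 abundances, over the signals observed in both samples.  A missing
    (signal, sample) entry becomes the median (in log space, then
    back-transformed) over the k nearest samples in which that signal was
    observed.  Observed entries are never altered.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    X = matrix.abundance
    if X.shape[1] < k + 1:
        raise ValidationError(f"need at least k+1={k + 1} samples")
    obs = X.notna().to_numpy()
    if (~obs).sum() == 0:
        return matrix.copy()
    if (~obs.any(axis=1)).any():
        bad = matrix.signal_ids[~obs.any(axis=1)].tolist()
        raise ValidationError(
            f"signal(s) missing in all samples (filter first): {bad}"
        )

    # distance space: standardized log10; zeros are excluded from distances
    # (log-undefined) but are kept as observed values
    vals = X.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logv = np.where(vals > 0, np.log10(np.where(vals > 0, vals, 1.0)), np.nan)
    mu = np.nanmean(logv, axis=1, keepdims=True)
    sd = np.nanstd(logv, axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (logv - mu) / sd

    n = X.shape[1]
    zobs = ~np.isnan(z)
    dist = np.full((n, n), np.nan)
    for j in range(n):
        shared = zobs[:, [j]] & zobs  # k x n
        diff = np.where(shared, z - z[:, [j]], 0.0)
        with np.errstate(invalid="ignore"):
            d = np.sqrt((diff ** 2).sum(axis=0))
        d[shared.sum(axis=0) == 0] = np.nan
        dist[j] = d
    np.fill_diagonal(dist, np.nan)
    if np.isnan(dist).all(axis=1).any():
        j = int(np.isnan(dist).all(axis=1).argmax())
        raise ValidationError(
            f"sample {X.columns[j]!r} shares no observed signals with any other"
        )

    out = vals.copy()
    miss_i, miss_j = np.where(~obs)
    for i, j in zip(miss_i, miss_j):
        candidates = np.where(obs[i] & ~np.isnan(dist[j]))[0]
        if candidates.size == 0:
            raise ValidationError(
                f"no neighbour observes signal {X.index[i]!r} "
                f"for sample {X.columns[j]!r}"
            )
        order = candidates[np.argsort(dist[j, candidates], kind="stable")]
        neighbours = order[:k]
        logged = np.log10(vals[i, neighbours])
        out[i, j] = 10.0 ** np.median(logged)
    return matrix.with_abundance(
        pd.DataFrame(out, index=X.index, columns=X.columns)
    )


def qc_cv(matrix: FeatureMatrix, samples: pd.DataFrame) -> pd.Series:
    """Per-signal coefficient of variation (sample sd / mean) over QCs."""
    samples = align(matrix, samples)
    qc_ids = samples.index[samples["role"] == "qc"]
    if len(qc_ids) < 2:
        raise ValidationError("need at least 2 QC samples")
    qc = matrix.abundance[list(qc_ids)]
    mean = qc.mean(axis=1)
    sd = qc.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    cv[mean == 0] = np.nan  # undefined
    return cv.rename("qc_cv")


def filter_by_cv(matrix: FeatureMatrix, samples: pd.DataFrame,
                 cv_max: float = 0.30):
    """Discard signals with QC CV strictly greater than ``cv_max``
    (boundary CV == cv_max is kept); undefined CV (zero mean) is removed."""
    cv = qc_cv(matrix, samples)
    keep = cv <= cv_max  # NaN compares False: undefined CV removed
    removed = matrix.signal_ids[~keep].tolist()
    return matrix.subset_signals(matrix.signal_ids[keep]), removed, cv


def run_qa(matrix: FeatureMatrix, samples: pd.DataFrame,
           cfg: WorkflowConfig | None = None):
    """Full QA cascade: blank -> QC presence -> k-NN imputation -> CV.

    Returns ``(filtered_matrix, report)`` with a balanced
    :class:`~lipocurve.core.QAReport`.
    """
    cfg = cfg or WorkflowConfig()
    samples = align(matrix, samples)
    k_in = matrix.k
    m1, removed_blank = filter_by_blank(matrix, samples, cfg.blank_rule)
    m2, removed_qc = filter_by_qc_presence(m1, samples, cfg.qc_presence_min)
    n_missing = m2.n_missing()
    m3 = impute_knn(m2, cfg.knn_k) if n_missing else m2
    m4, removed_cv, cv = filter_by_cv(m3, samples, cfg.cv_max)
    report = QAReport(
        k_in=k_in,
        removed_blank=len(removed_blank),
        removed_qc_presence=len(removed_qc),
        removed_cv=len(removed_cv),
        n_imputed=n_missing,
        k_out=m4.k,
        qc_cv=cv,
        removed_ids={
            "blank": removed_blank,
            "qc_presence": removed_qc,
            "cv": removed_cv,
        },
    )
    report.validate()
    return m4, report
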