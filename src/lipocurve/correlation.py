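"""Interval-wise Spearman selection of cell-derived chemical signals.

The method's core idea: a calibration curve of known, increasing cell counts
is analyzed alongside the experimental samples, and a chemical signal is
called *cell-derived* when its abundance correlates positively and strongly
with the cell count (rho >= 0.7, two-sided p < 0.05, unadjusted — the step
is a conservative filter, not inferential testing).  Correlations are
computed over every contiguous window of at least three distinct cell counts,
and the widest window is used for downstream selection by default.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import FeatureMatrix, SelectionResult, ValidationError, align
from .io import WorkflowConfig


def enumerate_intervals(counts: Sequence[int], min_counts: int = 3
                        ) -> list[tuple[int, int]]:
    """All contiguous windows of the sorted distinct counts with at least
    ``min_counts`` counts, ordered by low endpoint then width."""
    counts = list(counts)
    if any(b <= a for a, b in zip(counts, counts[1:])):
        raise ValidationError("counts must be sorted and strictly increasing")
    if len(counts) < min_counts:
        raise ValidationError(
            f"need at least {min_counts} distinct counts, got {len(counts)}"
        )
    return [
        (counts[i], counts[j])
        for i in range(len(counts))
        for j in range(i + min_counts - 1, len(counts))
    ]


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with a t-distribution p-value.

    rho is the Pearson correlation of mid-ranks (average ranks on ties); the
    two-sided p comes from ``t = rho * sqrt((n-2) / (1-rho^2))`` on ``n-2``
    degrees of freedom, with ``p = 0`` at ``|rho| = 1``.  A constant ``y``
    gives ``(nan, 1.0)`` — such a signal is never selected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValidationError("need at least 3 paired observations")
    if np.unique(x).size < 2:
        raise ValidationError("x must not be constant")
    if np.unique(y).size < 2:
        return math.nan, 1.0
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _snap(float(np.corrcoef(rx, ry)[0, 1]))
    return rho, _t_pvalue(rho, n)


def _snap(rho: float) -> float:
    """Clamp float noise: rank correlations this close to +-1 are exact
    (the nearest attainable non-unit value is O(1/n^3) away)."""
    if abs(rho) > 1.0 - 1e-12:
        return math.copysign(1.0, rho)
    return rho


def _t_pvalue(rho: float, n: int, one_sided: bool = False) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    if one_sided:
        return float(sps.t.sf(t, n - 2))
    return float(2.0 * sps.t.sf(abs(t), n - 2))


def select_correlated(matrix: FeatureMatrix, samples: pd.DataFrame,
                      interval: tuple[int, int], rho_min: float = 0.7,
                      alpha: float = 0.05, one_sided: bool = False,
                      inclusive: bool = True) -> SelectionResult:
    """Spearman selection of one cell-count interval.

    Uses every curve sample (replicates included) whose cell count lies in
    ``[low, high]``; a signal is selected iff ``rho >= rho_min`` (strict with
    ``inclusive=False``) and ``p < alpha``.  No multiplicity adjustment.
    """
    samples = align(matrix, samples)
    low, high = interval
    curve = samples[(samples["role"] == "curve")
                    & (samples["cell_count"] >= low)
                    & (samples["cell_count"] <= high)]
    counts = curve["cell_count"].to_numpy(dtype=float)
    if np.unique(counts).size < 3:
        raise ValidationError(
            f"interval {interval} covers fewer than 3 distinct cell counts"
        )
    sub = matrix.abundance[list(curve.index)]
    vals = sub.to_numpy(dtype=float)
    n = counts.size

    if np.isnan(vals).any():
        rows = [spearman_pair(counts, vals[i], one_sided)
                for i in range(vals.shape[0])]
        rho = np.array([r[0] for r in rows])
        p = np.array([r[1] for r in rows])
    else:
        rx = sps.rankdata(counts)
        ry = sps.rankdata(vals, axis=1)
        rxc = rx - rx.mean()
        ryc = ry - ry.mean(axis=1, keepdims=True)
        denom = np.sqrt((rxc ** 2).sum() * (ryc ** 2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = (ryc @ rxc) / denom
        rho[denom == 0] = np.nan
        near_one = np.abs(rho) > 1.0 - 1e-12
        rho[near_one] = np.sign(rho[near_one])
        p = np.array([1.0 if math.isnan(r) else _t_pvalue(r, n, one_sided)
                      for r in rho])

    if inclusive:
        passes_rho = rho >= rho_min
    else:
        passes_rho = rho > rho_min
    selected = np.where(np.isnan(rho), False, passes_rho & (p < alpha))
    table = pd.DataFrame(
        {"rho": rho, "p": p, "selected": selected},
        index=matrix.signal_ids,
    )
    result = SelectionResult(interval=(int(low), int(high)), table=table,
                             n_samples=n)
    result.validate(rho_min, alpha)
    return result


def spearman_pair(x: np.ndarray, y: np.ndarray, one_sided: bool = False
                  ) -> tuple[float, float]:
    """Pairwise-complete Spearman for one signal (drops missing pairs)."""
    ok = ~np.isnan(y)
    if np.unique(x[ok]).size < 3:
        return math.nan, 1.0
    if np.unique(y[ok]).size < 2:
        return math.nan, 1.0
    rx = sps.rankdata(x[ok])
    ry = sps.rankdata(y[ok])
    rho = float(np.corrcoef(rx, ry)[0, 1])
    return rho, _t_pvalue(rho, int(ok.sum()), one_sided)


def interval_correlation_map(matrix: FeatureMatrix, samples: pd.DataFrame,
                             cfg: WorkflowConfig | None = None
                             ) -> list[SelectionResult]:
    """Selection over every enumerable interval (chord-diagram edge list)."""
    cfg = cfg or WorkflowConfig()
    samples = align(matrix, samples)
    curve_counts = sorted(
        samples.loc[samples["role"] == "curve", "cell_count"].dropna().unique()
    )
    intervals = enumerate_intervals(
        [int(c) for c in curve_counts], cfg.min_interval_counts
    )
    return [
        select_correlated(
            matrix, samples, interval,
            rho_min=cfg.rho_min, alpha=cfg.corr_alpha,
            one_sided=cfg.one_sided_corr,
            inclusive=cfg.rho_boundary_inclusive,
        )
        for interval in intervals
    ]


def widest_interval(samples: pd.DataFrame) -> tuple[int, int]:
    counts = sorted(
        samples.loc[samples["role"] == "curve", "cell_count"].dropna().unique()
    )
    if len(counts) < 3:
        raise ValidationError("need at least 3 distinct curve cell counts")
    return int(counts[0]), int(counts[-1])
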