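"""Assumption-gated factorial testing of the paired experiment.

Each chemical signal is tested for a time effect (acute vs baseline, a
2-level within-subject factor), a group effect (between-subject) and their
interaction.  Signals whose residuals pass Shapiro-Wilk normality and whose
group x time cells pass Levene's homoscedasticity test (median-centred) go
through a two-way mixed ANOVA; the rest go through the aligned-rank-transform
(ART) ANOVA, a nonparametric factorial alternative that preserves
interaction testing.  P-values are Benjamini-Hochberg adjusted per effect
across signals, and a signal is significant for an effect iff raw p < 0.05
and adjusted p < 0.2 (exploratory dual threshold).

Because the within factor has exactly two levels, the mixed ANOVA reduces
exactly to per-subject summaries: with d_s = y_acute - y_baseline and
m_s = (y_acute + y_baseline)/2,

* the time effect is the F-test of the (unweighted) grand mean of d,
* the interaction is the one-way ANOVA of d across groups,
* the group effect is the one-way ANOVA of m across groups,

all against the pooled within-group error of the respective summary.  In the
one-group case the time F equals the squared paired t statistic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import (
    DifferentialResult,
    FeatureMatrix,
    ValidationError,
    align,
)
from .io import WorkflowConfig

EFFECTS = ("time", "group", "interaction")


def _paired_summaries(y: np.ndarray, design: pd.DataFrame):
    """Per-subject differences d (acute - baseline), means m, and groups."""
    y = np.asarray(y, dtype=float)
    if len(y) != len(design):
        raise ValidationError("y and design lengths differ")
    subj = design["subject"].to_numpy()
    tp = design["timepoint"].to_numpy()
    subjects, sidx = np.unique(subj, return_inverse=True)
    n = subjects.size
    is_a = tp == "acute"
    is_b = tp == "baseline"
    if not (is_a | is_b).all():
        raise ValidationError("timepoint must be acute or baseline")
    ca = np.zeros(n, dtype=int)
    cb = np.zeros(n, dtype=int)
    np.add.at(ca, sidx[is_a], 1)
    np.add.at(cb, sidx[is_b], 1)
    bad = (ca != 1) | (cb != 1)
    if bad.any():
        raise ValidationError(
            f"subject(s) not paired across both timepoints: "
            f"{subjects[bad].tolist()}"
        )
    ya = np.empty(n)
    yb = np.empty(n)
    ya[sidx[is_a]] = y[is_a]
    yb[sidx[is_b]] = y[is_b]
    g = np.empty(n, dtype=object)
    g[sidx] = design["group"].to_numpy()
    return ya - yb, (ya + yb) / 2.0, g


def _oneway(values: np.ndarray, groups: np.ndarray):
    """One-way ANOVA F with degenerate handling.

    Returns ``(F, p, df1, df2, mse)``; with a single group the between-group
    test is undefined and reported as ``(nan, 1.0)``.
    """
    labels = pd.unique(groups)
    G = len(labels)
    N = len(values)
    means = np.array([values[groups == lab].mean() for lab in labels])
    ns = np.array([(groups == lab).sum() for lab in labels])
    sse = sum(((values[groups == lab] - mu) ** 2).sum()
              for lab, mu in zip(labels, means))
    df2 = N - G
    mse = sse / df2 if df2 > 0 else math.nan
    if G == 1:
        return math.nan, 1.0, 0, df2, mse
    grand = values.mean()
    ssb = float((ns * (means - grand) ** 2).sum())
    df1 = G - 1
    if df2 <= 0:
        raise ValidationError("a group x time cell has too few subjects")
    if mse == 0:
        if ssb == 0:
            return 0.0, 1.0, df1, df2, mse
        return math.inf, 0.0, df1, df2, mse
    F = (ssb / df1) / mse
    return float(F), float(sps.f.sf(F, df1, df2)), df1, df2, mse


def _intercept_f(values: np.ndarray, groups: np.ndarray):
    """F-test of the unweighted grand mean of ``values`` against the pooled
    within-group error (the 2-level within-factor main effect)."""
    labels = pd.unique(groups)
    G = len(labels)
    N = len(values)
    df2 = N - G
    if df2 <= 0:
        raise ValidationError("need at least 2 subjects in some group")
    means = np.array([values[groups == lab].mean() for lab in labels])
    ns = np.array([(groups == lab).sum() for lab in labels])
    sse = sum(((values[groups == lab] - mu) ** 2).sum()
              for lab, mu in zip(labels, means))
    mse = sse / df2
    est = means.mean()  # unweighted grand mean
    var_est = mse / (G * G) * (1.0 / ns).sum()
    if var_est == 0:
        if est == 0:
            return 0.0, 1.0, 1, df2
        return math.inf, 0.0, 1, df2
    F = est * est / var_est
    return float(F), float(sps.f.sf(F, 1, df2)), 1, df2


def mixed_anova(y, design: pd.DataFrame) -> dict:
    """Two-way mixed ANOVA via the exact 2-level-within reduction.

    ``design`` needs columns ``subject``, ``timepoint`` (acute/baseline) and
    ``group``; every subject must appear at both timepoints.
    """
    d, m, g = _paired_summaries(np.asarray(y, dtype=float), design)
    f_time, p_time, _, _ = _intercept_f(d, g)
    f_int, p_int, *_ = _oneway(d, g)
    f_group, p_group, *_ = _oneway(m, g)
    return {
        "F_time": f_time, "p_time": p_time,
        "F_group": f_group, "p_group": p_group,
        "F_interaction": f_int, "p_interaction": p_int,
    }


def _cell_effect_components(y: np.ndarray, design: pd.DataFrame):
    """Unweighted cell-means decomposition over group x time cells."""
    cells = (design["group"].astype(str) + "|"
             + design["timepoint"].astype(str)).to_numpy()
    groups = pd.unique(design["group"])
    times = pd.unique(design["timepoint"])
    mu = {}
    for g in groups:
        for t in times:
            sel = cells == f"{g}|{t}"
            if sel.sum() < 1:
                raise ValidationError(f"empty group x time cell ({g}, {t})")
            mu[(g, t)] = y[sel].mean()
    # means by margin, unweighted over cells
    grand = np.mean([mu[(g, t)] for g in groups for t in times])
    a_t = {t: np.mean([mu[(g, t)] for g in groups]) - grand for t in times}
    b_g = {g: np.mean([mu[(g, t)] for t in times]) - grand for g in groups}
    gamma = {(g, t): mu[(g, t)] - grand - a_t[t] - b_g[g]
             for g in groups for t in times}
    cell_mu = {f"{g}|{t}": mu[(g, t)] for g in groups for t in times}
    resid = y - np.array([cell_mu[c] for c in cells])
    comp = {
        "time": np.array([a_t[t] for t in design["timepoint"]]),
        "group": np.array([b_g[g] for g in design["group"]]),
        "interaction": np.array(
            [gamma[(g, t)] for g, t in zip(design["group"],
                                           design["timepoint"])]
        ),
    }
    return resid, comp


def art_anova(y, design: pd.DataFrame) -> dict:
    """Aligned-rank-transform factorial ANOVA.

    For each effect, the data are aligned by removing the cell-means
    estimates of every *other* effect (keeping that effect's own component
    plus the residual), mid-ranked, and submitted to the mixed-ANOVA F-test;
    only the aligned-for effect's statistic is retained.  All-tied aligned
    values yield ``F = 0, p = 1``.
    """
    y = np.asarray(y, dtype=float)
    resid, comp = _cell_effect_components(y, design)
    out = {}
    for effect in EFFECTS:
        aligned = resid + comp[effect]
        if np.allclose(aligned, aligned[0], rtol=0.0, atol=1e-12):
            out[f"F_{effect}"] = 0.0
            out[f"p_{effect}"] = 1.0
            continue
        ranks = sps.rankdata(aligned)
        res = mixed_anova(ranks, design)
        out[f"F_{effect}"] = res[f"F_{effect}"]
        out[f"p_{effect}"] = res[f"p_{effect}"]
    return out


def assumption_gate(y, design: pd.DataFrame, alpha: float = 0.05) -> str:
    """Route one signal to ``mixed_anova`` or ``art_anova``.

    Shapiro-Wilk on the residuals of the group x time cell-means model, and
    median-centred Levene across the cells; both must be non-significant at
    ``alpha`` for the parametric route.  ``alpha = 0`` disables the gate.
    """
    y = np.asarray(y, dtype=float)
    cells = design["group"].astype(str) + "|" + design["timepoint"].astype(str)
    cell_values = [y[(cells == lab).to_numpy()] for lab in cells.unique()]
    if any(len(v) < 2 for v in cell_values):
        raise ValidationError("each group x time cell needs >= 2 observations")
    if alpha == 0:
        return "mixed_anova"
    resid, _ = _cell_effect_components(y, design)
    if np.allclose(resid, resid[0]):
        return "art_anova"  # degenerate residuals: Shapiro undefined
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p_shapiro = float(sps.shapiro(resid).pvalue)
        p_levene = float(sps.levene(*cell_values, center="median").pvalue)
    if p_shapiro >= alpha and p_levene >= alpha:
        return "mixed_anova"
    return "art_anova"


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return np.maximum(out, p)  # guard rounding: step-up is never below p


def _experimental_design(samples: pd.DataFrame) -> pd.DataFrame:
    exp = samples[samples["role"] == "experimental"]
    if exp.empty:
        raise ValidationError("no experimental samples")
    design = pd.DataFrame(
        {
            "subject": exp["subject_id"],
            "timepoint": exp["timepoint"],
            "group": exp["group"],
        },
        index=exp.index,
    )
    paired = design.groupby("subject")["timepoint"].nunique() == 2
    unpaired = paired.index[~paired].tolist()
    if unpaired:
        warnings.warn(f"dropping unpaired subject(s): {unpaired}", stacklevel=2)
        design = design[~design["subject"].isin(unpaired)]
    return design


def run_differential(matrix: FeatureMatrix, samples: pd.DataFrame,
                     cfg: WorkflowConfig | None = None) -> DifferentialResult:
    """Assumption-gated per-signal testing with per-effect BH adjustment.

    Run on all QA-passing signals (the *standard* approach) or on the
    correlation-selected subset (subset the matrix first).
    """
    cfg = cfg or WorkflowConfig()
    samples = align(matrix, samples)
    design = _experimental_design(samples)
    sub = matrix.abundance[list(design.index)]
    if sub.isna().to_numpy().any():
        raise ValidationError("missing values among experimental samples; "
                              "impute before differential testing")
    routes, pvals = [], {e: [] for e in EFFECTS}
    for sig in matrix.signal_ids:
        y = sub.loc[sig].to_numpy(dtype=float)
        route = assumption_gate(y, design, cfg.assumption_alpha)
        res = mixed_anova(y, design) if route == "mixed_anova" \
            else art_anova(y, design)
        routes.append(route)
        for e in EFFECTS:
            p = res[f"p_{e}"]
            pvals[e].append(1.0 if (p is None or math.isnan(p)) else p)

    table = pd.DataFrame({"route": routes}, index=matrix.signal_ids)
    if cfg.bh_pooled:
        pooled = np.concatenate([np.asarray(pvals[e]) for e in EFFECTS])
        adj = bh_adjust(pooled).reshape(len(EFFECTS), -1)
        padj = {e: adj[i] for i, e in enumerate(EFFECTS)}
    else:
        padj = {e: bh_adjust(pvals[e]) for e in EFFECTS}
    for e in EFFECTS:
        table[f"p_{e}"] = pvals[e]
        table[f"padj_{e}"] = padj[e]
        table[f"sig_{e}"] = (table[f"p_{e}"] < cfg.sig_p) \
            & (table[f"padj_{e}"] < cfg.sig_padj)
    result = DifferentialResult(table, sig_p=cfg.sig_p, sig_padj=cfg.sig_padj)
    result.validate()
    return result


@dataclass
class VennPartition:
    """Per-effect partition of significant signals between the standard and
    correlation-based approaches."""

    partitions: dict

    def counts(self) -> pd.DataFrame:
        rows = [
            {
                "effect": effect,
                "shared": len(part["shared"]),
                "standard_only": len(part["standard_only"]),
                "correlation_only": len(part["correlation_only"]),
            }
            for effect, part in self.partitions.items()
        ]
        return pd.DataFrame(rows).set_index("effect")

    def __getitem__(self, effect: str) -> dict:
        return self.partitions[effect]


def compare_approaches(result_standard: DifferentialResult,
                       result_correlated: DifferentialResult,
                       selected_ids) -> VennPartition:
    """Venn partition {shared, standard-only, correlation-only} per effect.

    ``result_standard`` covers all QA signals, ``result_correlated`` the
    correlation-selected subset of the same matrix.
    """
    std_ids = set(result_standard.table.index)
    cor_ids = set(result_correlated.table.index)
    if not cor_ids <= std_ids:
        raise ValidationError("correlation-approach signals are not a subset "
                              "of the standard-approach signals")
    if set(selected_ids) != cor_ids:
        raise ValidationError("selection does not match the "
                              "correlation-approach result")
    partitions = {}
    keys = list(EFFECTS) + ["any"]
    for effect in keys:
        if effect == "any":
            sig_std = set(result_standard.any_significant_ids())
            sig_cor = set(result_correlated.any_significant_ids())
        else:
            sig_std = set(result_standard.significant_ids(effect))
            sig_cor = set(result_correlated.significant_ids(effect))
        partitions[effect] = {
            "shared": sorted(sig_std & sig_cor),
            "standard_only": sorted(sig_std - sig_cor),
            "correlation_only": sorted(sig_cor - sig_std),
        }
    return VennPartition(partitions)
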