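"""Reading and writing feature tables, sample metadata, configs and stage outputs.

All interchange is comma-separated UTF-8 text with a decimal point.  Missing
abundances are empty fields, never ``0``; zeros in the input are kept as true
measured zeros.  Writes are deterministic: rows are ordered by signal_id and,
where applicable, by interval.
"""

from __future__ import annotations

import io as _stdio
import logging
import warnings
from dataclasses import dataclass, asdict, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    POLARITIES,
    FeatureMatrix,
    FormatError,
    SampleInfo,
    ValidationError,
    frame_to_samples,
    samples_to_frame,
)

log = logging.getLogger("lipocurve")

_FEATURE_META_COLS = ["signal_id", "mz", "rt", "polarity"]


@dataclass
class WorkflowConfig:
    """Thresholds of the whole workflow, with the study's defaults.

    qc_presence_min
        Minimum fraction of QC injections in which a signal must be detected
        (boundary inclusive: 3 of 4 QCs passes at 0.75).
    cv_max
        Maximum coefficient of variation (sd/mean over QC injections); signals
        with CV strictly greater are discarded.
    knn_k
        Neighbours used for k-NN imputation of missing values.
    rho_min, corr_alpha
        Spearman selection thresholds: keep a signal iff rho >= rho_min and
        p < corr_alpha (two-sided by default; no multiplicity adjustment).
    min_interval_counts
        Minimum number of distinct cell counts per correlation interval.
    sig_p, sig_padj
        Dual significance thresholds of the differential stage (raw p and
        Benjamini-Hochberg adjusted p).
    assumption_alpha
        Level of the Shapiro-Wilk / Levene gate that routes each signal to the
        parametric mixed ANOVA or the aligned-rank-transform ANOVA.
    blank_rule
        'any_condition' keeps a signal when at least one condition mean
        exceeds the blank mean; 'all_conditions' requires every condition to.
    """

    qc_presence_min: float = 0.75
    cv_max: float = 0.30
    knn_k: int = 5
    rho_min: float = 0.7
    corr_alpha: float = 0.05
    min_interval_counts: int = 3
    sig_p: float = 0.05
    sig_padj: float = 0.2
    assumption_alpha: float = 0.05
    blank_rule: str = "any_condition"
    seed: int = 0
    # correlation options
    one_sided_corr: bool = False
    rho_boundary_inclusive: bool = True
    # BH pooling across effects (default: per-effect vectors)
    bh_pooled: bool = False
    # QC-based SVR drift correction hyperparameters
    svr_epsilon: float = 0.05
    svr_c: float = 1.0
    svr_gamma: float | str = "scale"
    # QC clustering diagnostic
    qc_dispersion_max: float = 0.5

    def __post_init__(self) -> None:
        for name in ("qc_presence_min", "cv_max"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValidationError(f"{name} must be in (0, 1], got {v}")
        for name in ("rho_min", "corr_alpha", "sig_p", "sig_padj",
                     "assumption_alpha"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")
        if self.knn_k < 1:
            raise ValidationError("knn_k must be >= 1")
        if self.min_interval_counts < 3:
            raise ValidationError("min_interval_counts must be >= 3")
        if self.blank_rule not in ("any_condition", "all_conditions"):
            raise ValidationError(
                f"blank_rule must be any_condition/all_conditions, got "
                f"{self.blank_rule!r}"
            )


def load_config(path: str | Path) -> WorkflowConfig:
    """Read a flat key:value YAML config; unknown keys are rejected."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dc_fields(WorkflowConfig)}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"unknown config key(s): {sorted(unknown)}")
    return WorkflowConfig(**raw)


def save_config(cfg: WorkflowConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# feature table / metadata
# ---------------------------------------------------------------------------

def read_feature_table(path: str | Path, polarity: str | None = None) -> FeatureMatrix:
    """Read a signal-by-sample abundance table.

    Expected columns: ``signal_id, mz, rt, polarity`` followed by one column
    per sample.  Empty abundance fields become NaN (missing).  If ``polarity``
    is given, rows of the other polarity are rejected.
    """
    df = pd.read_csv(path, dtype={"signal_id": str})
    missing_meta = [c for c in _FEATURE_META_COLS if c not in df.columns]
    if missing_meta:
        raise FormatError(f"feature table missing column(s): {missing_meta}")
    if df["signal_id"].duplicated().any():
        dups = df.loc[df["signal_id"].duplicated(), "signal_id"].tolist()
        raise FormatError(f"duplicate signal_id(s): {dups}")
    bad_pol = ~df["polarity"].isin(POLARITIES)
    if bad_pol.any():
        raise ValidationError(
            f"unknown polarity value(s): {sorted(df.loc[bad_pol, 'polarity'].unique())}"
        )
    if polarity is not None:
        if polarity not in POLARITIES:
            raise ValidationError(f"unknown polarity {polarity!r}")
        df = df[df["polarity"] == polarity]
    df = df.set_index("signal_id")
    signals = df[["mz", "rt", "polarity"]]
    abundance = df.drop(columns=["mz", "rt", "polarity"]).astype(float)
    if (abundance.to_numpy() < 0).any():
        raise ValidationError("negative abundance in feature table")
    return FeatureMatrix(abundance, signals)


def write_feature_table(matrix: FeatureMatrix, path: str | Path) -> None:
    out = pd.concat([matrix.signals, matrix.abundance], axis=1)
    out = out.sort_index()
    out.index.name = "signal_id"
    out.to_csv(path)


def read_metadata(path: str | Path) -> list[SampleInfo]:
    """Read the per-sample design table and validate cross-field invariants.

    Experimental subjects present at only one timepoint are kept but flagged
    with a warning (unpaired samples are dropped later by the differential
    stage).
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "subject_id": str,
                                  "batch": str})
    if df.empty:
        warnings.warn("metadata file is empty", stacklevel=2)
        return []
    required = {"sample_id", "role", "injection_order"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"metadata missing column(s): {sorted(missing)}")
    for col in ("cell_count", "batch", "subject_id", "timepoint", "group"):
        if col not in df.columns:
            df[col] = None
    df["batch"] = df["batch"].fillna("B1")
    samples = frame_to_samples(df.set_index("sample_id"))
    _check_pairing(samples)
    frame = samples_to_frame(samples)
    for pol_frame in (frame,):  # one polarity per file
        orders = pol_frame["injection_order"]
        if orders.duplicated().any():
            raise ValidationError("injection_order values must be unique")
    curve_counts = frame.loc[frame["role"] == "curve", "cell_count"].dropna()
    if len(curve_counts) and curve_counts.nunique() < 3:
        warnings.warn(
            "fewer than 3 distinct curve cell counts; correlation analysis "
            "will not be possible",
            stacklevel=2,
        )
    return samples


def _check_pairing(samples: list[SampleInfo]) -> None:
    seen: dict[str, set] = {}
    for s in samples:
        if s.role == "experimental":
            seen.setdefault(s.subject_id, set()).add(s.timepoint)
    for subject, tps in seen.items():
        if len(tps) < 2:
            warnings.warn(
                f"subject {subject!r} present at only one timepoint; "
                "flagged unpaired",
                stacklevel=3,
            )


def write_metadata(samples: list[SampleInfo], path: str | Path) -> None:
    samples_to_frame(samples).to_csv(path)


# ---------------------------------------------------------------------------
# stage outputs
# ---------------------------------------------------------------------------

def write_qa_report(report, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "qa_report.csv"
    report.to_frame().to_csv(path, index=False)
    if report.qc_cv is not None:
        cv = report.qc_cv.rename("qc_cv").sort_index()
        cv.index.name = "signal_id"
        cv.to_csv(out_dir / "qa_qc_cv.csv")
    return path


def write_selection_table(results, out_dir: str | Path) -> Path:
    """Write per-signal selection rows for one or many intervals."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not isinstance(results, (list, tuple)):
        results = [results]
    rows = []
    for res in results:
        t = res.table.copy()
        t.insert(0, "low_count", res.interval[0])
        t.insert(1, "high_count", res.interval[1])
        t.index.name = "signal_id"
        rows.append(t.reset_index())
    table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["signal_id", "low_count", "high_count", "rho", "p", "selected"]
    )
    table = table.sort_values(["low_count", "high_count", "signal_id"])
    path = out_dir / "selection.csv"
    table.to_csv(path, index=False)
    return path


def write_interval_edges(results, out_dir: str | Path) -> Path:
    """Chord-diagram edge list: one row per interval with its selection count."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "low_count": res.interval[0],
            "high_count": res.interval[1],
            "n_selected": res.n_selected,
        }
        for res in results
    ]
    edges = pd.DataFrame(rows, columns=["low_count", "high_count", "n_selected"])
    edges = edges.sort_values(["low_count", "high_count"])
    path = out_dir / "interval_edges.csv"
    edges.to_csv(path, index=False)
    return path


def write_differential_table(result, out_dir: str | Path,
                             name: str = "differential.csv") -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t = result.table.sort_index()
    t.index.name = "signal_id"
    path = out_dir / name
    t.to_csv(path)
    return path


def write_pca_outputs(scores: pd.DataFrame, loadings: pd.DataFrame,
                      explained: np.ndarray, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scores.to_csv(out_dir / "pca_scores.csv")
    loadings.sort_index().to_csv(out_dir / "pca_loadings.csv")
    pd.DataFrame(
        {"component": [f"PC{i + 1}" for i in range(len(explained))],
         "explained_variance_fraction": explained}
    ).to_csv(out_dir / "pca_explained_variance.csv", index=False)


def write_linkage(linkage: np.ndarray, labels: list[str],
                  out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame(
        linkage, columns=["left", "right", "height", "n_members"]
    )
    path = out_dir / "hc_linkage.csv"
    table.to_csv(path, index_label="merge")
    with open(out_dir / "hc_labels.csv", "w", encoding="utf-8") as fh:
        fh.write("leaf,sample_id\n")
        for i, lab in enumerate(labels):
            fh.write(f"{i},{lab}\n")
    return path


def write_stage_outputs(result, out_dir: str | Path) -> None:
    """Dispatch a stage result to its writer by type."""
    from .core import DifferentialResult, QAReport, SelectionResult

    if isinstance(result, QAReport):
        write_qa_report(result, out_dir)
    elif isinstance(result, SelectionResult):
        write_selection_table(result, out_dir)
    elif isinstance(result, (list, tuple)) and result and isinstance(
            result[0], SelectionResult):
        write_selection_table(result, out_dir)
        write_interval_edges(result, out_dir)
    elif isinstance(result, DifferentialResult):
        write_differential_table(result, out_dir)
    else:
        raise TypeError(f"no writer for {type(result).__name__}")


def log_attrition(stage: str, k_in: int, k_out: int) -> None:
    log.info("%s: k_in=%d k_out=%d removed=%d", stage, k_in, k_out, k_in - k_out)
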