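"""Shared domain types for the cell-curve lipidomics workflow.

Untargeted LC-MS cell lipidomics produces a matrix of chemical-signal
abundances (one row per deconvoluted feature: neutral mass + retention time)
over a set of injections that mixes experimental samples with quality-control
pools, blanks, media injections and a cell-count calibration curve.  The
types here carry that structure between the pipeline stages; every stage is a
pure transformation returning a new matrix plus a report, never mutating its
input.

Missing values (non-detections) are encoded as NaN in the abundance matrix,
distinct from true zeros: a zero is a measured low abundance, a NaN means the
feature-extraction software found no peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

POLARITIES = frozenset({"positive", "negative"})
ROLES = frozenset({"blank", "qc", "media", "curve", "experimental"})
TIMEPOINTS = frozenset({"acute", "baseline"})

#: Columns of a sample-metadata frame, in canonical order.
SAMPLE_COLUMNS = (
    "role",
    "cell_count",
    "batch",
    "injection_order",
    "subject_id",
    "timepoint",
    "group",
)


class ValidationError(ValueError):
    """Input violates a domain invariant."""


class FormatError(ValidationError):
    """Input file is structurally malformed."""


@dataclass(frozen=True)
class ChemicalSignal:
    """One detected LC-MS feature: an (m/z, retention time) entity."""

    signal_id: str
    mz: float
    rt: float
    polarity: str

    def __post_init__(self) -> None:
        if not self.signal_id:
            raise ValidationError("signal_id must be non-empty")
        if not self.mz > 0:
            raise ValidationError(f"mz must be positive, got {self.mz}")
        if self.rt < 0:
            raise ValidationError(f"rt must be nonnegative, got {self.rt}")
        if self.polarity not in POLARITIES:
            raise ValidationError(
                f"polarity must be one of {sorted(POLARITIES)}, got {self.polarity!r}"
            )


@dataclass(frozen=True)
class SampleInfo:
    """Design metadata for one injection.

    ``cell_count`` is required for calibration-curve samples; ``subject_id``,
    ``timepoint`` and ``group`` are required for experimental samples (the
    paired acute/baseline x between-subject-group design).
    """

    sample_id: str
    role: str
    injection_order: int
    batch: str = "B1"
    cell_count: int | None = None
    subject_id: str | None = None
    timepoint: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if self.role not in ROLES:
            raise ValidationError(
                f"role must be one of {sorted(ROLES)}, got {self.role!r}"
            )
        if self.injection_order < 1:
            raise ValidationError("injection_order must be a positive integer")
        if self.role == "curve":
            if self.cell_count is None:
                raise ValidationError(
                    f"curve sample {self.sample_id!r} requires cell_count"
                )
            if self.cell_count < 0:
                raise ValidationError("cell_count must be nonnegative")
        if self.role == "experimental":
            if not self.subject_id:
                raise ValidationError(
                    f"experimental sample {self.sample_id!r} requires subject_id"
                )
            if self.timepoint not in TIMEPOINTS:
                raise ValidationError(
                    f"experimental sample {self.sample_id!r} requires timepoint "
                    f"in {sorted(TIMEPOINTS)}"
                )
            if not self.group:
                raise ValidationError(
                    f"experimental sample {self.sample_id!r} requires group"
                )


def samples_to_frame(samples: Iterable[SampleInfo]) -> pd.DataFrame:
    """Tabulate SampleInfo records into a frame indexed by sample_id."""
    records = list(samples)
    frame = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in records],
            "role": [s.role for s in records],
            "cell_count": [s.cell_count for s in records],
            "batch": [s.batch for s in records],
            "injection_order": [s.injection_order for s in records],
            "subject_id": [s.subject_id for s in records],
            "timepoint": [s.timepoint for s in records],
            "group": [s.group for s in records],
        }
    ).set_index("sample_id")
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].tolist()
        raise FormatError(f"duplicate sample_id(s): {dups}")
    return frame


def frame_to_samples(frame: pd.DataFrame) -> list[SampleInfo]:
    """Inverse of :func:`samples_to_frame` (validates each row)."""
    out = []
    for sample_id, row in frame.iterrows():
        cc = row.get("cell_count")
        out.append(
            SampleInfo(
                sample_id=str(sample_id),
                role=row["role"],
                injection_order=int(row["injection_order"]),
                batch=str(row.get("batch", "B1")),
                cell_count=None if pd.isna(cc) else int(cc),
                subject_id=_opt(row.get("subject_id")),
                timepoint=_opt(row.get("timepoint")),
                group=_opt(row.get("group")),
            )
        )
    return out


def _opt(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or pd.isna(value):
        return None
    value = str(value)
    return value if value else None


class FeatureMatrix:
    """Nonnegative abundance matrix, chemical signals x samples.

    ``abundance`` is a float DataFrame indexed by signal_id with one column
    per sample_id; NaN marks a missing (non-detected) value.  ``signals`` is
    a frame indexed by signal_id with columns ``mz``, ``rt``, ``polarity``.
    """

    def __init__(self, abundance: pd.DataFrame, signals: pd.DataFrame | None = None,
                 allow_negative: bool = False):
        abundance = abundance.astype(float)
        if abundance.index.has_duplicates:
            dups = abundance.index[abundance.index.duplicated()].tolist()
            raise FormatError(f"duplicate signal_id(s): {dups}")
        if abundance.columns.has_duplicates:
            dups = abundance.columns[abundance.columns.duplicated()].tolist()
            raise FormatError(f"duplicate sample column(s): {dups}")
        if not allow_negative and (abundance.to_numpy() < 0).any():
            raise ValidationError("abundances must be nonnegative")
        self.allow_negative = allow_negative
        if signals is None:
            signals = pd.DataFrame(
                {"mz": np.nan, "rt": np.nan, "polarity": "positive"},
                index=abundance.index,
            )
        else:
            signals = signals.copy()
            if not signals.index.equals(abundance.index):
                signals = signals.reindex(abundance.index)
                if signals.isna().all(axis=1).any():
                    raise ValidationError("signal table does not cover all matrix rows")
        self.abundance = abundance
        self.signals = signals

    # -- basic queries -------------------------------------------------
    @property
    def k(self) -> int:
        """Number of chemical signals."""
        return self.abundance.shape[0]

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[1]

    @property
    def signal_ids(self) -> pd.Index:
        return self.abundance.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.abundance.columns

    def n_missing(self) -> int:
        return int(self.abundance.isna().to_numpy().sum())

    # -- pure transformations ------------------------------------------
    def subset_signals(self, ids: Sequence[str]) -> "FeatureMatrix":
        ids = pd.Index(ids)
        missing = ids.difference(self.abundance.index)
        if len(missing):
            raise ValidationError(f"unknown signal_id(s): {missing.tolist()}")
        return FeatureMatrix(self.abundance.loc[ids], self.signals.loc[ids],
                             allow_negative=self.allow_negative)

    def subset_samples(self, ids: Sequence[str]) -> "FeatureMatrix":
        ids = pd.Index(ids)
        missing = ids.difference(self.abundance.columns)
        if len(missing):
            raise ValidationError(f"unknown sample_id(s): {missing.tolist()}")
        return FeatureMatrix(self.abundance[list(ids)], self.signals,
                             allow_negative=self.allow_negative)

    def with_abundance(self, abundance: pd.DataFrame,
                       allow_negative: bool | None = None) -> "FeatureMatrix":
        """New matrix sharing this one's signal table."""
        if allow_negative is None:
            allow_negative = self.allow_negative
        return FeatureMatrix(abundance, self.signals.reindex(abundance.index),
                             allow_negative=allow_negative)

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.abundance.copy(), self.signals.copy(),
                             allow_negative=self.allow_negative)

    def equals(self, other: "FeatureMatrix") -> bool:
        return self.abundance.equals(other.abundance)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"FeatureMatrix(k={self.k}, n_samples={self.n_samples}, "
            f"missing={self.n_missing()})"
        )


def align(matrix: FeatureMatrix, samples: pd.DataFrame) -> pd.DataFrame:
    """Check that metadata covers every matrix column and return it in
    matrix column order.  Raises on samples present in one but not the other.
    """
    missing = matrix.sample_ids.difference(samples.index)
    if len(missing):
        raise ValidationError(
            f"metadata missing for sample(s): {sorted(missing.tolist())}"
        )
    extra = samples.index.difference(matrix.sample_ids)
    if len(extra):
        raise ValidationError(
            f"metadata names sample(s) absent from the feature table: "
            f"{sorted(extra.tolist())}"
        )
    return samples.loc[matrix.sample_ids]


@dataclass
class QAReport:
    """Signal attrition across the QA cascade.

    Invariant: ``k_in - removed_blank - removed_qc_presence - removed_cv ==
    k_out`` (checked by :meth:`validate`).
    """

    k_in: int
    removed_blank: int = 0
    removed_qc_presence: int = 0
    removed_cv: int = 0
    n_imputed: int = 0
    k_out: int = 0
    qc_cv: pd.Series | None = None
    removed_ids: dict = field(default_factory=dict)

    def validate(self) -> None:
        total = self.removed_blank + self.removed_qc_presence + self.removed_cv
        if self.k_in - total != self.k_out:
            raise ValidationError(
                f"attrition does not balance: {self.k_in} - {total} != {self.k_out}"
            )
        if self.qc_cv is not None and (self.qc_cv.dropna() < 0).any():
            raise ValidationError("CV must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": ["input", "blank", "qc_presence", "imputation", "cv", "output"],
                "removed": [0, self.removed_blank, self.removed_qc_presence, 0,
                            self.removed_cv, 0],
                "imputed": [0, 0, 0, self.n_imputed, 0, 0],
                "k": [self.k_in,
                      self.k_in - self.removed_blank,
                      self.k_in - self.removed_blank - self.removed_qc_presence,
                      self.k_in - self.removed_blank - self.removed_qc_presence,
                      self.k_out,
                      self.k_out],
            }
        )


@dataclass
class SelectionResult:
    """Spearman selection over one cell-count interval.

    ``table`` is indexed by signal_id with columns ``rho``, ``p``,
    ``selected``; rho is NaN where undefined (constant abundance), in which
    case the signal is never selected.
    """

    interval: tuple[int, int]
    table: pd.DataFrame
    n_samples: int = 0

    @property
    def selected_ids(self) -> list[str]:
        return self.table.index[self.table["selected"]].tolist()

    @property
    def n_selected(self) -> int:
        return int(self.table["selected"].sum())

    def validate(self, rho_min: float, alpha: float) -> None:
        t = self.table
        bad = t["selected"] & ~((t["rho"] >= rho_min) & (t["p"] < alpha))
        if bad.any():
            raise ValidationError("selected flag inconsistent with thresholds")
        if (t["selected"] & t["rho"].isna()).any():
            raise ValidationError("undefined rho must not be selected")


@dataclass
class DifferentialResult:
    """Per-signal factorial test results.

    ``table`` is indexed by signal_id with columns ``route`` (mixed_anova or
    art_anova) and, per effect in {time, group, interaction}: ``p_<effect>``,
    ``padj_<effect>``, ``sig_<effect>``.
    """

    table: pd.DataFrame
    sig_p: float = 0.05
    sig_padj: float = 0.2

    EFFECTS = ("time", "group", "interaction")

    def significant_ids(self, effect: str = "time") -> list[str]:
        return self.table.index[self.table[f"sig_{effect}"]].tolist()

    def any_significant_ids(self) -> list[str]:
        mask = np.zeros(len(self.table), dtype=bool)
        for e in self.EFFECTS:
            mask |= self.table[f"sig_{e}"].to_numpy()
        return self.table.index[mask].tolist()

    def validate(self) -> None:
        for e in self.EFFECTS:
            p = self.table[f"p_{e}"]
            padj = self.table[f"padj_{e}"]
            if ((padj < p) & p.notna()).any():
                raise ValidationError(f"padj < p for effect {e}")
            expect = (p < self.sig_p) & (padj < self.sig_padj)
            if not (self.table[f"sig_{e}"] == expect.fillna(False)).all():
                raise ValidationError(f"sig flag inconsistent for effect {e}")


@dataclass
class SimTruth:
    """Ground truth for a simulated dataset.

    ``signals`` is indexed by signal_id with columns ``origin`` (cell,
    background or media), ``beta`` (abundance per cell; >0 for cell-derived
    signals, NaN otherwise), ``affected`` (True where a time effect was
    planted) and ``artifact`` (True for background signals carrying a
    spurious treatment artifact).
    """

    signals: pd.DataFrame
    planted_time_fc: float = 1.0
    noise_cv: float = 0.0

    def ids(self, origin: str) -> list[str]:
        return self.signals.index[self.signals["origin"] == origin].tolist()

    @property
    def cell_ids(self) -> list[str]:
        return self.ids("cell")

    @property
    def affected_ids(self) -> list[str]:
        return self.signals.index[self.signals["affected"]].tolist()

    def validate(self) -> None:
        if not self.signals["origin"].isin(["cell", "background", "media"]).all():
            raise ValidationError("origin must be cell/background/media")
        cell = self.signals["origin"] == "cell"
        if not (self.signals.loc[cell, "beta"] > 0).all():
            raise ValidationError("cell signals must have beta > 0")
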