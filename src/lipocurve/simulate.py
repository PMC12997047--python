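"""Synthetic LC-MS cell-lipidomics data with known ground truth.

The generator emulates the two study designs the workflow targets:

* a T-lymphocyte (CD3+) calibration curve — 6 cell counts (50k, 100k, 250k,
  500k, 750k, 1M) with 5 biological replicates each, analyzed in increasing
  count order with pooled QCs interleaved, blanks, media injections, and a
  mid-worklist batch break;
* a dermal-endothelial (HMVEC-d) experiment — a 4-count curve (25k..100k)
  injected in triplicate at the beginning, middle and end of the worklist,
  alongside paired acute/baseline experimental samples from three
  between-subject groups.

Cell-derived signal i in sample j with c_j cells has abundance
``beta_i * c_j * eps_ij`` where eps is multiplicative lognormal noise with a
given coefficient of variation; background signals have count-independent
means, media signals appear only in media and experimental samples, blanks
carry background at a reduced level, QC columns are the pooled mean of all
non-blank samples under the same noise, and the whole worklist is subject to
optional exponential injection-order drift and a per-batch scale factor.
Abundances below the detection limit are censored to missing (MNAR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import FeatureMatrix, SimTruth, ValidationError, samples_to_frame, SampleInfo


def lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean 1 and sd/mean = cv (exactly 1 if cv=0)."""
    if cv < 0:
        raise ValidationError("noise cv must be nonnegative")
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


@dataclass
class SimConfig:
    """Parameters of the simulated designs (defaults = the CD3+ curve)."""

    counts: tuple = (50_000, 100_000, 250_000, 500_000, 750_000, 1_000_000)
    reps_per_count: int = 5
    n_cell_signals: int = 70
    n_background_signals: int = 1000
    n_media_signals: int = 150
    noise_cv: float = 0.10
    drift_slope: float = 0.0          # fractional drift per injection
    n_batches: int = 2                # mid-worklist break by default
    batch_scale: float = 1.3          # multiplicative step between batches
    lod: float = 2000.0               # detection limit (abundance units)
    n_subjects_per_group: int = 8
    planted_time_fc: float = 3.0      # acute/baseline fold change
    frac_affected: float = 0.1        # fraction of cell signals with the effect
    seed: int = 0
    # worklist composition
    n_blanks: int = 3
    n_media_samples: int = 3
    n_qc: int | None = None           # None: one QC per ~5 injections
    blank_level: float = 0.5          # background level in blanks
    subject_cv: float = 0.2           # between-subject lognormal CV
    experimental_cells: int = 50_000  # cells plated per experimental well
    n_background_artifact: int = 0    # background signals with a spurious
    background_artifact_fc: float = 1.0  # acute-stage artifact fold change
    groups: tuple = ("IgE", "COX", "MRGPRX2")

    @property
    def n_counts(self) -> int:
        return len(self.counts)

    def __post_init__(self) -> None:
        counts = tuple(self.counts)
        if any(b <= a for a, b in zip(counts, counts[1:])):
            raise ValidationError("counts must be strictly increasing")
        if not 0 <= self.frac_affected < 1:
            raise ValidationError("frac_affected must be in [0, 1)")
        if self.planted_time_fc <= 0 or self.background_artifact_fc <= 0:
            raise ValidationError("fold changes must be positive")
        if self.reps_per_count < 1 or self.n_batches < 1:
            raise ValidationError("reps_per_count and n_batches must be >= 1")

    @classmethod
    def cd3_curve(cls, **overrides) -> "SimConfig":
        """The 6-count x 5-replicate T-cell calibration design."""
        return cls(**overrides)

    @classmethod
    def hmvec_experiment(cls, **overrides) -> "SimConfig":
        """The 4-count x 3-replicate endothelial curve plus the paired
        acute/baseline, three-group experimental design."""
        defaults = dict(
            counts=(25_000, 50_000, 75_000, 100_000),
            reps_per_count=3,
            n_cell_signals=200,
            n_background_signals=300,
            n_media_signals=60,
        )
        defaults.update(overrides)
        return cls(**defaults)


# ---------------------------------------------------------------------------
# signal panels
# ---------------------------------------------------------------------------

_BG_MEAN_LOG = math.log(2.0e5)


def _signal_panel(cfg: SimConfig, rng: np.random.Generator):
    """Draw per-signal parameters and the signal metadata table."""
    n_cell, n_bg, n_media = (
        cfg.n_cell_signals, cfg.n_background_signals, cfg.n_media_signals,
    )
    ids = (
        [f"cell_{i + 1:04d}" for i in range(n_cell)]
        + [f"bg_{i + 1:04d}" for i in range(n_bg)]
        + [f"media_{i + 1:04d}" for i in range(n_media)]
    )
    origin = ["cell"] * n_cell + ["background"] * n_bg + ["media"] * n_media
    beta = rng.lognormal(mean=0.0, sigma=1.0, size=n_cell)  # abundance/cell
    bg_mean = rng.lognormal(mean=_BG_MEAN_LOG, sigma=1.2, size=n_bg)
    media_mean = rng.lognormal(mean=_BG_MEAN_LOG, sigma=1.0, size=n_media)
    truth = pd.DataFrame(
        {
            "origin": origin,
            "beta": np.concatenate([beta, np.full(n_bg + n_media, np.nan)]),
            "affected": False,
            "artifact": False,
        },
        index=pd.Index(ids, name="signal_id"),
    )
    signals = pd.DataFrame(
        {
            "mz": np.round(rng.uniform(150.0, 1200.0, len(ids)), 4),
            "rt": np.round(rng.uniform(0.5, 19.0, len(ids)), 3),
            "polarity": "positive",
        },
        index=truth.index,
    )
    return truth, signals, beta, bg_mean, media_mean


def _mean_block(cfg, truth, beta, bg_mean, media_mean, sample_rows):
    """Noise-free expected abundance for a list of sample descriptors.

    Each descriptor is a dict with at least ``role`` and optionally
    ``cell_count``/``fc`` (per-sample multiplicative factor on cell signals)
    and ``bg_fc`` (factor on background signals).  Structural absences
    (cells in blanks, media signals in curve samples, ...) are NaN.
    """
    k = len(truth)
    n = len(sample_rows)
    mean = np.full((k, n), np.nan)
    is_cell = (truth["origin"] == "cell").to_numpy()
    is_bg = (truth["origin"] == "background").to_numpy()
    is_media = (truth["origin"] == "media").to_numpy()
    for j, row in enumerate(sample_rows):
        role = row["role"]
        if role == "blank":
            mean[is_bg, j] = bg_mean * cfg.blank_level
        elif role == "curve":
            mean[is_cell, j] = beta * row["cell_count"]
            mean[is_bg, j] = bg_mean
        elif role == "media":
            mean[is_bg, j] = bg_mean
            mean[is_media, j] = media_mean
        elif role == "experimental":
            mean[is_cell, j] = beta * row["cell_fc"]
            mean[is_bg, j] = bg_mean * row.get("bg_fc", 1.0)
            mean[is_media, j] = media_mean
        else:  # pragma: no cover
            raise ValidationError(f"unknown simulated role {role!r}")
    return mean


def _assemble(cfg, rng, truth, signals, mean, sample_rows):
    """Noise, QC pooling, drift/batch, and detection-limit censoring."""
    k, n = mean.shape
    abundance = mean * lognormal_noise(rng, cfg.noise_cv, (k, n))
    columns = [row["sample_id"] for row in sample_rows]
    ab = pd.DataFrame(abundance, index=truth.index, columns=columns)
    base = pd.DataFrame(
        {
            "sample_id": columns,
            "role": [r["role"] for r in sample_rows],
            "cell_count": [r.get("cell_count") for r in sample_rows],
            "injection_order": np.arange(1, n + 1),
            "subject_id": [r.get("subject_id") for r in sample_rows],
            "timepoint": [r.get("timepoint") for r in sample_rows],
            "group": [r.get("group") for r in sample_rows],
        }
    ).set_index("sample_id")
    base["batch"] = "B1"

    matrix = FeatureMatrix(ab.clip(lower=0), signals)
    n_qc = cfg.n_qc if cfg.n_qc is not None else max(2, round(n / 5))
    matrix, samples = make_qc_pool(matrix, base, n_qc,
                                   noise_cv=cfg.noise_cv, rng=rng)

    # contiguous batches over the final injection order
    order = samples["injection_order"].to_numpy()
    edges = np.array_split(np.argsort(order), cfg.n_batches)
    batch = np.empty(len(samples), dtype=object)
    for b, idx in enumerate(edges):
        batch[idx] = f"B{b + 1}"
    samples["batch"] = batch

    drift = np.exp(cfg.drift_slope * order)
    scale = np.array(
        [cfg.batch_scale ** int(bl[1:]) / cfg.batch_scale for bl in batch]
    )
    factors = pd.Series(drift * scale, index=samples.index)
    ab = matrix.abundance.mul(factors, axis=1)
    ab = ab.where(~(ab < cfg.lod))  # left-censor below the detection limit
    matrix = FeatureMatrix(ab, signals)
    samples = samples[
        ["role", "cell_count", "batch", "injection_order",
         "subject_id", "timepoint", "group"]
    ]
    return matrix, samples


def _curve_rows(cfg, rng, prefix: str = "curve"):
    rows = [
        {"sample_id": f"blank_{i + 1}", "role": "blank"}
        for i in range(cfg.n_blanks)
    ]
    for count in cfg.counts:  # increasing count order, replicates shuffled
        reps = rng.permutation(cfg.reps_per_count) + 1
        for rep in reps:
            rows.append(
                {
                    "sample_id": f"{prefix}_{count}_r{rep}",
                    "role": "curve",
                    "cell_count": int(count),
                }
            )
    rows += [
        {"sample_id": f"media_{i + 1}", "role": "media"}
        for i in range(cfg.n_media_samples)
    ]
    return rows


def simulate_cell_curve(cfg: SimConfig):
    """Simulate a cell-count calibration worklist.

    Returns ``(matrix, samples, truth)``: the feature matrix including QC
    columns, the sample-metadata frame, and the ground truth.
    """
    if len(set(cfg.counts)) < 3:
        raise ValidationError(
            "need at least 3 distinct cell counts for correlation analysis"
        )
    rng = np.random.default_rng(cfg.seed)
    truth_frame, signals, beta, bg_mean, media_mean = _signal_panel(cfg, rng)
    rows = _curve_rows(cfg, rng)
    mean = _mean_block(cfg, truth_frame, beta, bg_mean, media_mean, rows)
    matrix, samples = _assemble(cfg, rng, truth_frame, signals, mean, rows)
    truth = SimTruth(truth_frame, planted_time_fc=1.0, noise_cv=cfg.noise_cv)
    truth.validate()
    return matrix, samples, truth


def simulate_experiment(cfg: SimConfig):
    """Simulate the paired acute/baseline x between-group experiment with its
    companion calibration curve.

    A ``frac_affected`` subset of cell-derived signals is multiplied by
    ``planted_time_fc`` in acute samples; each subject carries a lognormal
    random effect shared by its two samples.  Optionally,
    ``n_background_artifact`` background signals carry a spurious
    ``background_artifact_fc`` at the acute stage (a handling artifact
    confounded with timepoint, used to probe the standard-vs-correlation
    approach comparison).
    """
    if cfg.n_subjects_per_group < 2:
        raise ValidationError("need >= 2 subjects per group")
    rng = np.random.default_rng(cfg.seed)
    truth_frame, signals, beta, bg_mean, media_mean = _signal_panel(cfg, rng)

    n_affected = round(cfg.frac_affected * cfg.n_cell_signals)
    if cfg.frac_affected > 0 and n_affected < 1:
        import warnings

        warnings.warn("frac_affected rounds to zero affected signals "
                      "(null experiment)", stacklevel=2)
    cell_ids = truth_frame.index[truth_frame["origin"] == "cell"]
    affected = rng.choice(cell_ids, size=n_affected, replace=False)
    truth_frame.loc[affected, "affected"] = True
    if cfg.n_background_artifact:
        bg_ids = truth_frame.index[truth_frame["origin"] == "background"]
        artifact = rng.choice(bg_ids, size=cfg.n_background_artifact,
                              replace=False)
        truth_frame.loc[artifact, "artifact"] = True
    is_affected = truth_frame.loc[cell_ids, "affected"].to_numpy()
    is_artifact = truth_frame.loc[
        truth_frame["origin"] == "background", "artifact"
    ].to_numpy()

    # subjects and their paired samples, in randomized run order
    subj_effect = {}
    exp_rows = []
    for group in cfg.groups:
        for s in range(cfg.n_subjects_per_group):
            sid = f"{group}_S{s + 1:02d}"
            subj_effect[sid] = lognormal_noise(rng, cfg.subject_cv, None)
            for tp in ("baseline", "acute"):
                cell_fc = np.full(cfg.n_cell_signals,
                                  cfg.experimental_cells * subj_effect[sid])
                if tp == "acute":
                    cell_fc = cell_fc * np.where(
                        is_affected, cfg.planted_time_fc, 1.0
                    )
                bg_fc = np.where(
                    is_artifact, cfg.background_artifact_fc, 1.0
                ) if tp == "acute" else 1.0
                exp_rows.append(
                    {
                        "sample_id": f"{sid}_{tp}",
                        "role": "experimental",
                        "subject_id": sid,
                        "timepoint": tp,
                        "group": group,
                        "cell_fc": cell_fc,
                        "bg_fc": bg_fc,
                    }
                )
    exp_rows = [exp_rows[i] for i in rng.permutation(len(exp_rows))]

    # curve triplicates at beginning / middle / end of the worklist
    blanks = [{"sample_id": f"blank_{i + 1}", "role": "blank"}
              for i in range(cfg.n_blanks)]
    series = []
    for rep in range(1, cfg.reps_per_count + 1):
        series.append([
            {"sample_id": f"curve_{c}_r{rep}", "role": "curve",
             "cell_count": int(c)}
            for c in cfg.counts
        ])
    media = [{"sample_id": f"media_{i + 1}", "role": "media"}
             for i in range(cfg.n_media_samples)]
    chunks = np.array_split(exp_rows, max(1, len(series) - 1))
    rows = list(blanks)
    for i, block in enumerate(series):
        rows.extend(block)
        if i < len(chunks):
            rows.extend(chunks[i])
    rows.extend(media)

    mean = _mean_block(cfg, truth_frame, beta, bg_mean, media_mean, rows)
    matrix, samples = _assemble(cfg, rng, truth_frame, signals, mean, rows)
    truth = SimTruth(truth_frame, planted_time_fc=cfg.planted_time_fc,
                     noise_cv=cfg.noise_cv)
    truth.validate()
    return matrix, samples, truth


def make_qc_pool(matrix: FeatureMatrix, samples: pd.DataFrame, n_qc: int,
                 noise_cv: float = 0.0, rng: np.random.Generator | None = None):
    """Append pooled-QC columns, evenly interleaved in injection order.

    Each QC column is the per-signal mean over all non-blank samples (missing
    treated as 0: pooling equal volumes dilutes an absent analyte) perturbed
    by lognormal noise.  All samples are renumbered to consecutive injection
    orders with one QC after every ~n/n_qc injections, so consecutive QC
    orders are at most ``ceil(n/n_qc) + 1`` apart.

    Returns ``(matrix_with_qcs, samples_with_qcs)``.
    """
    if n_qc < 2:
        raise ValidationError("need at least 2 QC injections")
    pooled_cols = samples.index[samples["role"] != "blank"]
    if len(pooled_cols) == 0:
        raise ValidationError("no non-blank samples to pool")
    if rng is None:
        rng = np.random.default_rng(0)
    pool_mean = matrix.abundance[list(pooled_cols)].fillna(0.0).mean(axis=1)

    eps = lognormal_noise(rng, noise_cv, (matrix.k, n_qc))
    qc = pd.DataFrame(
        pool_mean.to_numpy()[:, None] * eps,
        index=matrix.signal_ids,
        columns=[f"QC_{i + 1}" for i in range(n_qc)],
    )
    ab = pd.concat([matrix.abundance, qc], axis=1)

    existing = samples.sort_values("injection_order")
    chunks = np.array_split(np.arange(len(existing)), n_qc)
    ordered: list[str] = []
    for i, chunk in enumerate(chunks):
        ordered.extend(existing.index[chunk])
        ordered.append(f"QC_{i + 1}")
    out = samples.reindex(existing.index).copy()
    qc_meta = pd.DataFrame(
        {"role": "qc", "cell_count": None, "batch": "B1",
         "injection_order": 0, "subject_id": None, "timepoint": None,
         "group": None},
        index=pd.Index([f"QC_{i + 1}" for i in range(n_qc)], name="sample_id"),
    )
    out = pd.concat([out.astype(object), qc_meta.astype(object)])
    out = out.loc[ordered]
    out["injection_order"] = np.arange(1, len(out) + 1)
    return FeatureMatrix(ab[ordered], matrix.signals), out


def truth_to_csv(truth: SimTruth, path) -> None:
    truth.signals.sort_index().to_csv(path)
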