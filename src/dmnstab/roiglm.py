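"""Event-related GLM on ROI time series: deactivation estimates.

Each subject's 10 default-mode ROIs are summarized as an ROI-by-volume
matrix. Risky-decision ("pump"), cash-out, and explosion events are
convolved with a canonical double-gamma hemodynamic response function and
entered as condition regressors; a pump-number parametric modulator
(mean-centered within the pump condition) controls for balloon size;
discrete-cosine drift regressors implement a 128 s high-pass; optional
nuisance columns (6 motion parameters + white-matter and CSF signals) are
appended. Jittered inter-trial periods are unmodeled and serve as the
implicit baseline. Volumes with frame displacement above 2 mm, and volumes
already marked missing, are censored (rows dropped from both series and
design). The per-ROI ordinary-least-squares beta of the pump condition is
the "deactivation" estimate: negative values mean the ROI is suppressed
below baseline during risk decisions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .config import (
    HIGHPASS_CUTOFF_S,
    MOTION_CENSOR_MM,
    N_ROIS,
    ROI_NAMES,
    TR_SECONDS,
)

EVENT_TYPES = ("pump", "cash_out", "explosion")


# ---------------------------------------------------------------------------
# time-series container and on-disk schemas
# ---------------------------------------------------------------------------


@dataclass
class ROITimeSeries:
    """A 10 x T ROI activation matrix with a missing-volume mask.

    ``values[r, t]`` is NaN wherever ``missing_mask[t]`` is set; all
    unmasked values are finite.
    """

    values: np.ndarray  # (10, T)
    missing_mask: np.ndarray  # (T,) bool
    tr_seconds: float = TR_SECONDS
    roi_names: tuple[str, ...] = ROI_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.roi_names):
            raise ValueError(
                f"values must be ({len(self.roi_names)}, T); got {self.values.shape}"
            )
        if self.missing_mask.shape != (self.values.shape[1],):
            raise ValueError("missing_mask length must equal T")
        if self.n_volumes < 20:
            raise ValueError("need at least 20 volumes")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        # enforce the NaN convention both ways
        self.values[:, self.missing_mask] = np.nan
        if not np.all(np.isfinite(self.values[:, ~self.missing_mask])):
            raise ValueError("unmasked values must be finite")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[1]

    def with_missing(self, volumes: np.ndarray | list[int] | set[int]) -> "ROITimeSeries":
        """Return a copy with additional volumes marked missing."""
        idx = np.asarray(sorted(volumes), dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_volumes):
            raise ValueError("missing volume index out of range")
        mask = self.missing_mask.copy()
        mask[idx] = True
        values = self.values.copy()
        values[:, mask] = np.nan
        return ROITimeSeries(values, mask, self.tr_seconds, self.roi_names)


def write_series_csv(ts: ROITimeSeries, path) -> None:
    """One row per volume, header = ROI names, empty cell = missing."""
    df = pd.DataFrame(ts.values.T, columns=list(ts.roi_names))
    df.to_csv(path, index=False, float_format="%.10g", na_rep="")


def read_series_csv(path, tr_seconds: float = TR_SECONDS) -> ROITimeSeries:
    df = pd.read_csv(path)
    values = df.to_numpy(dtype=float).T
    mask = np.any(np.isnan(values), axis=0)
    return ROITimeSeries(values, mask, tr_seconds, tuple(df.columns))


def write_events_tsv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_events_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"onset", "duration", "type", "pump_number"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# hemodynamic response and design construction
# ---------------------------------------------------------------------------

HRF_LENGTH_S = 40.0


def _double_gamma_raw(t: np.ndarray) -> np.ndarray:
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]

    def gpdf(x: np.ndarray, shape: float) -> np.ndarray:
        return np.exp((shape - 1) * np.log(x) - x - gammaln(shape))

    out[pos] = gpdf(tp, 6.0) - gpdf(tp, 16.0) / 6.0
    return out


#: true peak of the double-gamma response (grid-independent normalizer)
_HRF_PEAK = float(_double_gamma_raw(np.arange(0.0, 32.0, 1e-3)).max())


def double_gamma_hrf(t: np.ndarray) -> np.ndarray:
    """Canonical double-gamma HRF (SPM defaults: response delay 6 s,
    undershoot 16 s, response/undershoot ratio 6; maximum near 5 s).

    Normalized by the response's true peak, so a condition beta is on the
    scale of the underlying response amplitude regardless of sampling.
    """
    t = np.asarray(t, dtype=float)
    return _double_gamma_raw(t) / _HRF_PEAK


def convolve_events(
    onsets: np.ndarray,
    weights: np.ndarray,
    n_volumes: int,
    tr_seconds: float = TR_SECONDS,
    oversample: int = 16,
) -> np.ndarray:
    """HRF-convolved stick regressor sampled at volume acquisition times.

    Events are placed on a microtime grid (``tr / oversample``), convolved
    with the canonical HRF, and sampled at t = 0, TR, 2 TR, ...
    """
    onsets = np.asarray(onsets, dtype=float)
    weights = np.asarray(weights, dtype=float)
    dt = tr_seconds / oversample
    n_grid = n_volumes * oversample
    if np.any(onsets < 0) or np.any(onsets >= n_volumes * tr_seconds):
        raise ValueError("event onset outside the acquired series")
    grid = np.zeros(n_grid)
    idx = np.minimum(np.round(onsets / dt).astype(int), n_grid - 1)
    np.add.at(grid, idx, weights)
    hrf = double_gamma_hrf(np.arange(0, HRF_LENGTH_S + dt, dt))
    col = np.convolve(grid, hrf)[:n_grid]
    return col[::oversample]


def dct_drift_basis(
    n_volumes: int,
    tr_seconds: float = TR_SECONDS,
    cutoff_s: float = HIGHPASS_CUTOFF_S,
) -> np.ndarray:
    """Discrete-cosine high-pass drift columns (periods longer than cutoff)."""
    duration = n_volumes * tr_seconds
    order = int(np.floor(2.0 * duration / cutoff_s)) + 1
    t = np.arange(n_volumes)
    cols = [
        np.cos(np.pi * k * (2 * t + 1) / (2 * n_volumes)) for k in range(1, order + 1)
    ]
    if not cols:
        return np.empty((n_volumes, 0))
    return np.column_stack(cols)


@dataclass
class GLMDesign:
    """A T x K design matrix with labeled columns."""

    matrix: np.ndarray
    labels: list[str] = field(default_factory=list)

    def column(self, label: str) -> np.ndarray:
        return self.matrix[:, self.labels.index(label)]

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]


def build_glm_design(
    events: pd.DataFrame,
    n_volumes: int,
    tr_seconds: float = TR_SECONDS,
    nuisance: np.ndarray | None = None,
    cutoff_s: float = HIGHPASS_CUTOFF_S,
    oversample: int = 16,
) -> GLMDesign:
    """Build the event-related design: conditions, pump PM, drift, nuisance.

    The pump parametric modulator is the pump-number-weighted copy of the
    pump regressor with weights mean-centered within the pump condition
    (no further orthogonalization). Conditions with no events are dropped
    with a warning.
    """
    cols: list[np.ndarray] = []
    labels: list[str] = []
    for cond in EVENT_TYPES:
        sel = events[events["type"] == cond]
        if len(sel) == 0:
            warnings.warn(f"condition {cond!r} has no events; column dropped")
            continue
        onsets = sel["onset"].to_numpy(dtype=float)
        cols.append(
            convolve_events(onsets, np.ones(len(sel)), n_volumes, tr_seconds, oversample)
        )
        labels.append(cond)
        if cond == "pump":
            pm = sel["pump_number"].to_numpy(dtype=float)
            pm = pm - pm.mean()
            cols.append(convolve_events(onsets, pm, n_volumes, tr_seconds, oversample))
            labels.append("pump_pm")
    drift = dct_drift_basis(n_volumes, tr_seconds, cutoff_s)
    for k in range(drift.shape[1]):
        cols.append(drift[:, k])
        labels.append(f"drift_{k + 1}")
    cols.append(np.ones(n_volumes))
    labels.append("intercept")
    if nuisance is not None:
        nuisance = np.asarray(nuisance, dtype=float)
        if nuisance.shape[0] != n_volumes:
            raise ValueError("nuisance regressors must have one row per volume")
        for k in range(nuisance.shape[1]):
            cols.append(nuisance[:, k])
            labels.append(f"nuisance_{k + 1}")
    matrix = np.column_stack(cols)
    # a condition with a single event yields an all-zero (centered) PM
    # column; drop degenerate columns rather than failing on rank
    nonzero = np.ptp(matrix, axis=0) > 0
    nonzero[labels.index("intercept")] = True
    for lbl, keep in zip(labels, nonzero):
        if not keep:
            warnings.warn(f"column {lbl!r} is constant; dropped")
    matrix = matrix[:, nonzero]
    labels = [lbl for lbl, keep in zip(labels, nonzero) if keep]
    if np.linalg.matrix_rank(matrix) < matrix.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return GLMDesign(matrix, labels)


# ---------------------------------------------------------------------------
# motion censoring and estimation
# ---------------------------------------------------------------------------


def censor_frames(
    motion_mm: np.ndarray, threshold_mm: float = MOTION_CENSOR_MM
) -> tuple[np.ndarray, float]:
    """Flag volumes whose frame displacement exceeds the threshold.

    Returns the boolean censor mask and the censored fraction.
    """
    motion_mm = np.asarray(motion_mm, dtype=float)
    if np.any(motion_mm < 0):
        raise ValueError("displacements must be non-negative")
    mask = motion_mm > threshold_mm
    return mask, float(mask.mean())


@dataclass
class DeactivationResult:
    """Per-ROI pump-condition betas with their OLS standard errors."""

    pump_betas: np.ndarray  # (10,)
    pump_se: np.ndarray  # (10,)
    betas: pd.DataFrame  # all coefficients, ROIs x columns
    n_used: int
    censored_fraction: float

    def to_frame(self, roi_names: tuple[str, ...] = ROI_NAMES) -> pd.DataFrame:
        return pd.DataFrame(
            {"pump_beta": self.pump_betas, "pump_se": self.pump_se},
            index=list(roi_names),
        )


def estimate_deactivation(
    ts: ROITimeSeries,
    design: GLMDesign,
    censor_mask: np.ndarray | None = None,
) -> DeactivationResult:
    """OLS fit of the design to each ROI; returns the pump-condition betas.

    Censored volumes (series missing mask plus any motion censor mask) are
    dropped from both the series and the design before estimation, which
    is exactly equivalent to deleting those rows.
    """
    if design.n_volumes != ts.n_volumes:
        raise ValueError("design and series must cover the same volumes")
    drop = ts.missing_mask.copy()
    if censor_mask is not None:
        censor_mask = np.asarray(censor_mask, dtype=bool)
        if censor_mask.shape != (ts.n_volumes,):
            raise ValueError("censor mask length must equal T")
        drop |= censor_mask
    keep = ~drop
    x = design.matrix[keep]
    y = ts.values[:, keep].T  # (n_used, 10)
    n_used, k = x.shape
    if n_used <= k:
        raise ValueError("fewer usable volumes than design columns")
    if np.linalg.matrix_rank(x) < k:
        raise ValueError("design rank deficient after censoring")
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    dof = n_used - k
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(x.T @ x)
    if "pump" not in design.labels:
        raise ValueError("design has no pump condition column")
    j = design.labels.index("pump")
    pump_betas = beta[j]
    pump_se = np.sqrt(sigma2 * xtx_inv[j, j])
    betas = pd.DataFrame(beta.T, index=list(ts.roi_names), columns=design.labels)
    return DeactivationResult(
        pump_betas=pump_betas,
        pump_se=pump_se,
        betas=betas,
        n_used=n_used,
        censored_fraction=float(drop.mean()),
    )


def deactivation_table(
    results: dict[str, DeactivationResult], roi_names: tuple[str, ...] = ROI_NAMES
) -> pd.DataFrame:
    """Stack per-subject pump betas into a subjects x ROIs table."""
    rows = {sid: res.pump_betas for sid, res in results.items()}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(roi_names))


assert len(ROI_NAMES) == N_ROIS
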