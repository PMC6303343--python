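"""Synthetic BART studies with known ground truth.

Generates everything the downstream stages consume: per-subject balloon
trial histories (24 balloons, explosion points 4-10 in one fixed
pseudo-random order shared by all subjects), self-paced event timings with
0.5-4.0 s uniform jitter, 10-ROI time series driven by a unified-SEM
(contemporaneous + lag-1) network process with group and individual
parameters, NaN-censored outcome volumes, and an HRF-shaped deactivation
signal injected at pump events. A single coupling knob ties each subject's
true network stability (mean autoregressive coefficient) to their true
feedback-learning slopes, so the end-to-end association the analysis tests
for exists in the generator by construction and its recovery can be
measured.

Behavioral mechanics: each trial draws a latent intended pump count from
the trial-level linear model (subject intercept and slope deviations plus
Gaussian noise), rounded and floored at one. The balloon pops at its
explosion point, so observed pumps = min(intended, explosion point) and an
explosion occurs exactly when the intent reaches that point. The
current-outcome fixed effect is therefore not a generative dial here (the
outcome is mechanically determined); `simulate_learning_rows` provides an
uncensored draw directly from the trial-level equation for validating the
mixed-model fitter, where every fixed effect acts generatively.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import (
    EXPLOSION_MAX,
    EXPLOSION_MIN,
    JITTER_MAX_S,
    JITTER_MIN_S,
    N_BALLOONS,
    N_ROIS,
    ROI_NAMES,
    TR_SECONDS,
    TruthConfig,
)
from .roiglm import ROITimeSeries, convolve_events, write_events_tsv, write_series_csv

#: Dedicated seed for the fixed pseudo-random explosion-point order. The
#: study's actual sequence is unpublished; this one is generated once and
#: shared by every subject and every run.
EXPLOSION_ORDER_SEED = 19

#: Relative strength of the injected pump response in each ROI (the
#: per-subject amplitude multiplies this profile), loosely mimicking
#: stronger deactivation in midline hubs than in hippocampus.
DEACT_ROI_WEIGHTS = (1.0, 1.0, 0.85, 0.8, 0.7, 0.7, 0.6, 0.6, 0.9, 0.85)

#: Volumes discarded before the retained series starts.
DEFAULT_BURN_IN = 100

#: Washout appended after the last event when sizing a scan, seconds.
_WASHOUT_S = 16.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BARTTrial:
    balloon_index: int
    pumps: int
    outcome: str  # "cash_out" | "explosion"
    explosion_point: int

    def __post_init__(self) -> None:
        if not 0 <= self.balloon_index < N_BALLOONS:
            raise ValueError("balloon_index out of range")
        if self.pumps < 1:
            raise ValueError("pumps must be positive")
        if not EXPLOSION_MIN <= self.explosion_point <= EXPLOSION_MAX:
            raise ValueError("explosion_point outside 4-10")
        if self.pumps > self.explosion_point:
            raise ValueError("pumps cannot exceed the explosion point")
        exploded = self.pumps == self.explosion_point
        if (self.outcome == "explosion") != exploded:
            raise ValueError("outcome inconsistent with pumps vs explosion point")
        if self.outcome not in ("cash_out", "explosion"):
            raise ValueError(f"unknown outcome {self.outcome!r}")


@dataclass
class BARTSession:
    """One subject's 24-trial history plus the event timing table."""

    subject_id: str
    trials: list[BARTTrial]
    event_timings: pd.DataFrame  # onset, duration, type, pump_number

    def __post_init__(self) -> None:
        if len(self.trials) != N_BALLOONS:
            raise ValueError(f"expected {N_BALLOONS} trials")
        idx = [t.balloon_index for t in self.trials]
        if idx != sorted(set(idx)):
            raise ValueError("balloon_index must be strictly increasing")

    @property
    def pump_counts(self) -> np.ndarray:
        return np.array([t.pumps for t in self.trials], dtype=int)


@dataclass
class SubjectTruth:
    """Per-subject generative parameters of a coupled study."""

    subject_id: str
    u0: float
    u3: float  # valence-slope deviation
    u4: float  # value-slope deviation
    ar_mean: float
    phi_diag: np.ndarray  # (10,)
    deact_amp: float


@dataclass
class StudyBundle:
    """A complete synthetic study: behavior, time series, ground truth."""

    truth: TruthConfig
    seed: int
    sessions: list[BARTSession]
    series: dict[str, ROITimeSeries]
    subjects: pd.DataFrame  # per-subject true parameters
    subject_truths: list[SubjectTruth] = field(default_factory=list)
    a_template: np.ndarray | None = None


def subject_label(j: int) -> str:
    return f"S{j + 1:03d}"


# ---------------------------------------------------------------------------
# behavioral simulation
# ---------------------------------------------------------------------------


def explosion_sequence(
    n_balloons: int = N_BALLOONS, seed: int = EXPLOSION_ORDER_SEED
) -> np.ndarray:
    """The fixed pseudo-random order of explosion points (4-10, repeated)."""
    base = np.arange(EXPLOSION_MIN, EXPLOSION_MAX + 1)
    reps = int(np.ceil(n_balloons / base.size))
    seq = np.tile(base, reps)
    rng = np.random.default_rng(seed)
    return rng.permutation(seq)[:n_balloons]


def _check_truth(truth: TruthConfig) -> None:
    for name in ("tau00", "tau33", "tau44", "sigma2"):
        if getattr(truth, name) < 0:
            raise ValueError(f"{name} must be non-negative")


def simulate_bart_behavior(
    truth: TruthConfig,
    n_subjects: int,
    seed: int,
    subject_effects: pd.DataFrame | None = None,
    explosion_points: np.ndarray | None = None,
) -> list[BARTSession]:
    """Simulate per-subject balloon histories and self-paced event timings.

    ``subject_effects`` may supply the random effects (columns u0, u3, u4)
    instead of drawing them; coupled studies use this to plant the
    stability-learning association.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    _check_truth(truth)
    rng = np.random.default_rng(seed)
    g0, g1, _g2, g3, g4 = truth.gamma
    sigma = float(np.sqrt(truth.sigma2))
    if explosion_points is None:
        explosion_points = explosion_sequence()
    n_balloons = len(explosion_points)
    if subject_effects is None:
        u0 = rng.normal(0.0, np.sqrt(truth.tau00), n_subjects)
        u3 = rng.normal(0.0, np.sqrt(truth.tau33), n_subjects)
        u4 = rng.normal(0.0, np.sqrt(truth.tau44), n_subjects)
    else:
        u0 = subject_effects["u0"].to_numpy(float)
        u3 = subject_effects["u3"].to_numpy(float)
        u4 = subject_effects["u4"].to_numpy(float)
        if len(u0) != n_subjects:
            raise ValueError("subject_effects rows must match n_subjects")

    sessions: list[BARTSession] = []
    z75 = norm.ppf(0.75)
    for j in range(n_subjects):
        # generative "high value" threshold: the 75th percentile of the
        # subject's latent intended-pump distribution
        thr = g0 + u0[j] + z75 * sigma
        eps = rng.normal(0.0, sigma, n_balloons)
        prev_val = 0.0
        prev_value = 0.0
        trials: list[BARTTrial] = []
        events: list[tuple[float, float, str, int]] = []
        n_events = 0
        for i, ep in enumerate(explosion_points):
            ep = int(ep)
            lp = g0 + u0[j] + g1 * i + (g3 + u3[j]) * prev_val + (g4 + u4[j]) * prev_value
            intended = int(np.floor(lp + eps[i] + 0.5))
            intended = max(intended, 1)
            if intended >= ep:
                pumps, outcome = ep, "explosion"
            else:
                pumps, outcome = intended, "cash_out"
            trials.append(BARTTrial(i, pumps, outcome, ep))
            for k in range(1, pumps + 1):
                events.append((0.0, 0.0, "pump", k))
            events.append((0.0, 0.0, outcome, pumps))
            n_events += pumps + 1
            prev_val = 1.0 if outcome == "cash_out" else 0.0
            prev_value = 1.0 if pumps > thr else 0.0
        jitter = rng.uniform(JITTER_MIN_S, JITTER_MAX_S, n_events)
        onsets = np.cumsum(jitter)
        timing = pd.DataFrame(
            {
                "onset": onsets,
                "duration": 0.0,
                "type": [e[2] for e in events],
                "pump_number": [e[3] for e in events],
            }
        )
        sessions.append(BARTSession(subject_label(j), trials, timing))
    return sessions


def simulate_learning_rows(
    gamma: tuple[float, float, float, float, float],
    tau00: float,
    tau33: float,
    tau44: float,
    sigma2: float,
    n_subjects: int,
    n_trials: int = N_BALLOONS,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw design rows exogenously and the response from the trial-level
    equation itself (no balloon censoring).

    Used to validate the mixed-model fitter: every fixed effect, including
    the current-outcome term, acts generatively here. Returns (rows,
    true_effects) where rows has the LearningDesignRow schema plus the
    ``pumps`` response and true_effects holds each subject's u0/u3/u4.
    """
    for v in (tau00, tau33, tau44, sigma2):
        if v < 0:
            raise ValueError("variances must be non-negative")
    rng = np.random.default_rng(seed)
    g0, g1, g2, g3, g4 = gamma
    n_rows = n_trials - 1
    u0 = rng.normal(0, np.sqrt(tau00), n_subjects)
    u3 = rng.normal(0, np.sqrt(tau33), n_subjects)
    u4 = rng.normal(0, np.sqrt(tau44), n_subjects)
    frames = []
    for j in range(n_subjects):
        tn = np.arange(1, n_trials)
        co = rng.binomial(1, 0.3, n_rows).astype(float)
        pv = rng.binomial(1, 0.65, n_rows).astype(float)
        pval = rng.binomial(1, 0.25, n_rows).astype(float)
        y = (
            g0
            + u0[j]
            + g1 * tn
            + g2 * co
            + (g3 + u3[j]) * pv
            + (g4 + u4[j]) * pval
            + rng.normal(0, np.sqrt(sigma2), n_rows)
        )
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": subject_label(j),
                    "pumps": y,
                    "trial_number": tn,
                    "current_outcome": co,
                    "prev_valence": pv,
                    "prev_value": pval,
                }
            )
        )
    truth = pd.DataFrame(
        {"subject_id": [subject_label(j) for j in range(n_subjects)],
         "u0": u0, "u3": u3, "u4": u4}
    )
    return pd.concat(frames, ignore_index=True), truth


# ---------------------------------------------------------------------------
# network time-series simulation
# ---------------------------------------------------------------------------


def check_stationary(a: np.ndarray, phi: np.ndarray) -> None:
    """Raise unless (I - A) is invertible and the VAR companion is stable."""
    p = a.shape[0]
    i_a = np.eye(p) - a
    if np.linalg.cond(i_a) > 1e8:
        raise ValueError("(I - A) is singular or near-singular")
    companion = np.linalg.solve(i_a, phi)
    rho = np.max(np.abs(np.linalg.eigvals(companion)))
    if rho >= 1.0:
        raise ValueError(f"non-stationary model: spectral radius {rho:.3f} >= 1")


def simulate_network_timeseries(
    a: np.ndarray,
    phi: np.ndarray,
    zeta_var: np.ndarray | float,
    n_volumes: int,
    burn_in: int = DEFAULT_BURN_IN,
    missing_pattern=None,
    seed: int | np.random.Generator = 0,
    tr_seconds: float = TR_SECONDS,
    roi_names: tuple[str, ...] = ROI_NAMES,
) -> ROITimeSeries:
    """Simulate η(t) = (I - A)⁻¹(Φ η(t-1) + ζ(t)), ζ ~ N(0, diag).

    The first ``burn_in`` volumes are discarded; volumes listed in
    ``missing_pattern`` are then replaced by NaN (temporal order kept).
    """
    a = np.asarray(a, dtype=float)
    phi = np.asarray(phi, dtype=float)
    p = a.shape[0]
    zeta = np.broadcast_to(np.asarray(zeta_var, dtype=float), (p,))
    if np.any(zeta <= 0):
        raise ValueError("innovation variances must be positive")
    check_stationary(a, phi)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = np.linalg.inv(np.eye(p) - a)
    b = m @ phi
    total = n_volumes + burn_in
    shocks = rng.normal(0.0, np.sqrt(zeta), size=(total, p)) @ m.T
    eta = np.zeros((total, p))
    prev = np.zeros(p)
    for t in range(total):
        prev = b @ prev + shocks[t]
        eta[t] = prev
    values = eta[burn_in:].T.copy()
    mask = np.zeros(n_volumes, dtype=bool)
    ts = ROITimeSeries(values, mask, tr_seconds, roi_names)
    if missing_pattern is not None:
        ts = ts.with_missing(np.asarray(sorted(missing_pattern), dtype=int))
    return ts


def contemporaneous_template(
    edges: tuple[tuple[str, str, float], ...], roi_names: tuple[str, ...] = ROI_NAMES
) -> np.ndarray:
    """Build the group contemporaneous matrix A from (source, target, w)."""
    p = len(roi_names)
    a = np.zeros((p, p))
    index = {name: i for i, name in enumerate(roi_names)}
    for src, dst, w in edges:
        a[index[dst], index[src]] = w
    np.fill_diagonal(a, 0.0)
    return a


# ---------------------------------------------------------------------------
# coupled study
# ---------------------------------------------------------------------------


def outcome_volumes(events: pd.DataFrame, tr_seconds: float = TR_SECONDS) -> np.ndarray:
    """Volume indices acquired during cash-out / explosion events."""
    sel = events[events["type"].isin(["cash_out", "explosion"])]
    return np.unique((sel["onset"].to_numpy(float) // tr_seconds).astype(int))


def make_coupled_study(
    truth: TruthConfig,
    n_subjects: int,
    t_range: tuple[int, int],
    seed: int,
    tr_seconds: float = TR_SECONDS,
    burn_in: int = DEFAULT_BURN_IN,
) -> StudyBundle:
    """Generate a full study with a planted stability-learning coupling.

    Per subject: a mean AR coefficient is drawn around the group value;
    the true valence/value slope deviations are
    ``coupling_b * z(AR) + N(0, slope_noise_sd²)`` where z(AR) is the AR
    deviation standardized by its generative SD; the deactivation
    amplitude is drawn independently of the AR process (so the two
    feature sets are uncorrelated in truth). Pump events carry an
    HRF-shaped response scaled by that amplitude, added onto the uSEM
    series; outcome volumes are NaN-censored.
    """
    if not t_range or len(t_range) != 2 or t_range[0] > t_range[1]:
        raise ValueError("t_range must be (min, max) with min <= max")
    _check_truth(truth)
    rng = np.random.default_rng(seed)
    ar_mean = rng.normal(truth.ar_mean, truth.ar_between_sd, n_subjects)
    ar_mean = np.clip(ar_mean, 0.05, 0.90)
    z = (ar_mean - truth.ar_mean) / truth.ar_between_sd
    u3 = truth.coupling_b * z + rng.normal(0, truth.slope_noise_sd, n_subjects)
    u4 = truth.coupling_b * z + rng.normal(0, truth.slope_noise_sd, n_subjects)
    u0 = rng.normal(0, np.sqrt(truth.tau00), n_subjects)
    deact_amp = rng.normal(truth.deact_amp_mean, truth.deact_amp_sd, n_subjects)

    effects = pd.DataFrame({"u0": u0, "u3": u3, "u4": u4})
    behav_seed = int(rng.integers(0, 2**31 - 1))
    sessions = simulate_bart_behavior(
        truth, n_subjects, behav_seed, subject_effects=effects
    )

    a_template = contemporaneous_template(truth.group_contemporaneous)
    weights = np.asarray(DEACT_ROI_WEIGHTS)
    series: dict[str, ROITimeSeries] = {}
    subject_truths: list[SubjectTruth] = []
    t_lo, t_hi = int(t_range[0]), int(t_range[1])
    scan_draws = rng.integers(t_lo, t_hi + 1, n_subjects)
    for j, session in enumerate(sessions):
        events = session.event_timings
        t_needed = int(np.ceil((events["onset"].max() + _WASHOUT_S) / tr_seconds))
        n_vol = max(t_needed, int(scan_draws[j]))
        phi_diag = np.clip(
            ar_mean[j] + rng.normal(0, truth.ar_within_sd, N_ROIS), 0.02, 0.95
        )
        ts = simulate_network_timeseries(
            a_template,
            np.diag(phi_diag),
            truth.zeta_var,
            n_vol,
            burn_in=burn_in,
            seed=rng,
            tr_seconds=tr_seconds,
        )
        pumps = events[events["type"] == "pump"]
        signal = convolve_events(
            pumps["onset"].to_numpy(float), np.ones(len(pumps)), n_vol, tr_seconds
        )
        ts.values += np.outer(deact_amp[j] * weights, signal)
        ts = ts.with_missing(outcome_volumes(events, tr_seconds))
        series[session.subject_id] = ts
        subject_truths.append(
            SubjectTruth(
                subject_id=session.subject_id,
                u0=float(u0[j]),
                u3=float(u3[j]),
                u4=float(u4[j]),
                ar_mean=float(ar_mean[j]),
                phi_diag=phi_diag,
                deact_amp=float(deact_amp[j]),
            )
        )
    subjects = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subject_truths],
            "ar_mean": ar_mean,
            "u0": u0,
            "u3": u3,
            "u4": u4,
            "deact_amp": deact_amp,
        }
    )
    return StudyBundle(
        truth=truth,
        seed=seed,
        sessions=sessions,
        series=series,
        subjects=subjects,
        subject_truths=subject_truths,
        a_template=a_template,
    )


# ---------------------------------------------------------------------------
# on-disk study layout
# ---------------------------------------------------------------------------


def trials_table(sessions: list[BARTSession]) -> pd.DataFrame:
    rows = [
        {
            "subject": s.subject_id,
            "balloon": t.balloon_index,
            "pumps": t.pumps,
            "outcome": t.outcome,
            "explosion_point": t.explosion_point,
        }
        for s in sessions
        for t in s.trials
    ]
    return pd.DataFrame(rows)


def write_study(bundle: StudyBundle, out_dir) -> None:
    """Write trial table, per-subject event/series files, and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials_table(bundle.sessions).to_csv(out / "trials.csv", index=False)
    for session in bundle.sessions:
        write_events_tsv(session.event_timings, out / f"events_{session.subject_id}.tsv")
    for sid, ts in bundle.series.items():
        write_series_csv(ts, out / f"series_{sid}.csv")
    truth = {
        "seed": bundle.seed,
        "gamma": list(bundle.truth.gamma),
        "tau00": bundle.truth.tau00,
        "tau33": bundle.truth.tau33,
        "tau44": bundle.truth.tau44,
        "sigma2": bundle.truth.sigma2,
        "coupling_b": bundle.truth.coupling_b,
        "subjects": bundle.subjects.to_dict(orient="records"),
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
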