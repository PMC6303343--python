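"""Trial-level feedback-learning model and empirical-Bayes indices.

The trial-level design codes, for every balloon after the first, the
current outcome (cash-out = 0, explosion = 1), the previous outcome's
valence, and whether the previous balloon was "high value" for that
subject (final pumps strictly above the subject's own 75th percentile).
The printed coding of previous valence in the source analysis plan is
internally inconsistent (both levels zero), so this package codes
previous cash-out = 1 and previous explosion = 0: a positive valence
slope then reads "more pumps after positive feedback", matching the
construct the indices are meant to capture.

The linear mixed model has fixed effects (intercept, trial number,
current outcome, previous valence, previous value), a random intercept
u0j ~ N(0, tau00), and independent random previous-valence and
previous-value slopes (diagonal random-effects covariance; 24 trials per
subject cannot identify an unstructured 3x3). Estimation is (restricted)
maximum likelihood with the relative variance components profiled out of
a scale parameter, as in standard mixed-model software; per-subject
empirical-Bayes slopes are the closed-form BLUPs at the estimated
variance components, i.e. precision-weighted compromises between each
subject's own slope and the fixed effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .config import VALUE_PERCENTILE
from .synth import BARTSession

FIXED_EFFECTS = ["intercept", "trial_number", "current_outcome", "prev_valence", "prev_value"]
RANDOM_EFFECTS = ["intercept", "prev_valence", "prev_value"]

_VAR_FLOOR = 1e-8
_BOUNDARY_TOL = 1e-6


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


def value_threshold(pump_counts: np.ndarray, percentile: float = VALUE_PERCENTILE) -> float:
    """A subject's high-value cutoff: the 75th percentile of their pumps."""
    return float(np.percentile(np.asarray(pump_counts, dtype=float), percentile))


def build_design(session: BARTSession, percentile: float = VALUE_PERCENTILE) -> pd.DataFrame:
    """Design rows for one subject; the first trial emits no row."""
    if len(session.trials) < 2:
        raise ValueError("need at least 2 trials to form a design row")
    thr = value_threshold(session.pump_counts, percentile)
    rows = []
    for t in range(1, len(session.trials)):
        cur = session.trials[t]
        prev = session.trials[t - 1]
        rows.append(
            {
                "subject_id": session.subject_id,
                "pumps": cur.pumps,
                "trial_number": cur.balloon_index,
                "current_outcome": 1.0 if cur.outcome == "explosion" else 0.0,
                # cash-out = 1 so a positive slope means more pumps after
                # positive feedback (see module docstring)
                "prev_valence": 1.0 if prev.outcome == "cash_out" else 0.0,
                "prev_value": 1.0 if prev.pumps > thr else 0.0,
            }
        )
    return pd.DataFrame(rows)


def build_design_table(
    sessions: list[BARTSession], percentile: float = VALUE_PERCENTILE
) -> pd.DataFrame:
    return pd.concat([build_design(s, percentile) for s in sessions], ignore_index=True)


def design_from_trials(trials: pd.DataFrame, percentile: float = VALUE_PERCENTILE) -> pd.DataFrame:
    """Build the design straight from a trial-table CSV (synth schema)."""
    frames = []
    for sid, grp in trials.groupby("subject", sort=True):
        grp = grp.sort_values("balloon")
        pumps = grp["pumps"].to_numpy(int)
        outcome = grp["outcome"].to_numpy()
        if len(grp) < 2:
            raise ValueError(f"subject {sid}: need at least 2 trials")
        bad = set(outcome) - {"cash_out", "explosion"}
        if bad:
            raise ValueError(f"subject {sid}: undefined outcome values {sorted(bad)}")
        thr = value_threshold(pumps, percentile)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "pumps": pumps[1:].astype(float),
                    "trial_number": grp["balloon"].to_numpy(int)[1:],
                    "current_outcome": (outcome[1:] == "explosion").astype(float),
                    "prev_valence": (outcome[:-1] == "cash_out").astype(float),
                    "prev_value": (pumps[:-1] > thr).astype(float),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# mixed-model fit
# ---------------------------------------------------------------------------


@dataclass
class LearningFit:
    """Fitted trial-level mixed model."""

    gamma_hat: pd.Series  # five fixed effects
    gamma_se: pd.Series
    tau00_hat: float
    tau33_hat: float
    tau44_hat: float
    sigma2_hat: float
    loglik: float
    reml: bool
    converged: bool
    n_iter: int
    boundary: dict[str, bool]
    random_effects: pd.DataFrame  # subject_id, u0, u3, u4 (BLUPs)
    eb_valence: pd.Series  # gamma3 + u3 per subject
    eb_value: pd.Series  # gamma4 + u4 per subject
    n_obs: int
    n_subjects: int


class _Suffstats:
    """Per-subject sufficient statistics for the profiled likelihood."""

    def __init__(self, rows: pd.DataFrame):
        subjects = sorted(rows["subject_id"].unique())
        if len(subjects) < 2:
            raise ValueError("need at least 2 subjects")
        ztz, ztx, zty, xtx, xty, yty, ns = [], [], [], [], [], [], []
        for sid in subjects:
            grp = rows[rows["subject_id"] == sid]
            if len(grp) < 2:
                raise ValueError(f"subject {sid}: need at least 2 rows")
            x = np.column_stack(
                [
                    np.ones(len(grp)),
                    grp["trial_number"].to_numpy(float),
                    grp["current_outcome"].to_numpy(float),
                    grp["prev_valence"].to_numpy(float),
                    grp["prev_value"].to_numpy(float),
                ]
            )
            z = x[:, [0, 3, 4]]
            y = grp["pumps"].to_numpy(float)
            ztz.append(z.T @ z)
            ztx.append(z.T @ x)
            zty.append(z.T @ y)
            xtx.append(x.T @ x)
            xty.append(x.T @ y)
            yty.append(y @ y)
            ns.append(len(grp))
        self.subjects = subjects
        self.ztz = np.array(ztz)  # (S, 3, 3)
        self.ztx = np.array(ztx)  # (S, 3, 5)
        self.zty = np.array(zty)  # (S, 3)
        self.xtx_sum = np.sum(xtx, axis=0)  # (5, 5)
        self.xty_sum = np.sum(xty, axis=0)  # (5,)
        self.yty_sum = float(np.sum(yty))
        self.ns = np.array(ns)
        self.n_total = int(self.ns.sum())
        if np.linalg.matrix_rank(self.xtx_sum) < 5:
            raise ValueError("design matrix is rank deficient")

    def gls_parts(self, theta: np.ndarray):
        """GLS building blocks at relative variances theta = tau/sigma2.

        With Vtilde_j = I + Z diag(theta) Z', everything reduces to the
        3x3 matrix C_j = I + W Z'Z W (W = sqrt(theta)) via Woodbury.
        """
        w = np.sqrt(np.maximum(theta, 0.0))
        k = w[None, :, None] * self.ztz * w[None, None, :]  # (S,3,3)
        c = np.eye(3)[None] + k
        # logdet |Vtilde_j| = logdet C_j
        sign, logdet = np.linalg.slogdet(c)
        wztx = w[None, :, None] * self.ztx
        wzty = w[None, :] * self.zty
        ci_wztx = np.linalg.solve(c, wztx)  # (S,3,5)
        ci_wzty = np.linalg.solve(c, wzty[..., None])[..., 0]  # (S,3)
        xvx = self.xtx_sum - np.einsum("sik,sil->kl", wztx, ci_wztx)
        xvy = self.xty_sum - np.einsum("sik,si->k", wztx, ci_wzty)
        yvy = self.yty_sum - float(np.einsum("si,si->", wzty, ci_wzty))
        return w, c, logdet.sum(), xvx, xvy, yvy


def _criterion(theta: np.ndarray, ss: _Suffstats, reml: bool) -> float:
    _, _, logdet, xvx, xvy, yvy = ss.gls_parts(theta)
    try:
        gamma = np.linalg.solve(xvx, xvy)
    except np.linalg.LinAlgError:
        return np.inf
    rss = yvy - 2 * gamma @ xvy + gamma @ xvx @ gamma
    rss = max(rss, 1e-12)
    n, p = ss.n_total, 5
    if reml:
        sign, ld_xvx = np.linalg.slogdet(xvx)
        if sign <= 0:
            return np.inf
        return logdet + ld_xvx + (n - p) * np.log(rss / (n - p))
    return logdet + n * np.log(rss / n)


def _blups(ss: "_Suffstats", gamma: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Closed-form BLUPs u_j = D Z' V^-1 (y_j - X_j gamma) at relative
    variances theta = tau/sigma2; with V = sigma2 (I + Z Theta Z') this is
    Theta [s - Z'Z W C^-1 W s] where s = Z'(y - X gamma)."""
    w, c, _, _, _, _ = ss.gls_parts(theta)
    s = ss.zty - np.einsum("sik,k->si", ss.ztx, gamma)
    ci_ws = np.linalg.solve(c, (w[None, :] * s)[..., None])[..., 0]
    return theta[None, :] * (s - np.einsum("sij,sj->si", ss.ztz, w[None, :] * ci_ws))


def empirical_bayes_slopes(
    rows: pd.DataFrame,
    gamma: np.ndarray,
    sigma2: float,
    tau00: float,
    tau33: float,
    tau44: float,
) -> pd.DataFrame:
    """BLUP random-effect deviations at the given variance components.

    Exposed so EB behavior can be examined at imposed (not estimated)
    components, e.g. in the no-pooling limit.
    """
    ss = _Suffstats(rows)
    theta = np.array([tau00, tau33, tau44]) / sigma2
    u = _blups(ss, np.asarray(gamma, dtype=float), theta)
    return pd.DataFrame(
        {"subject_id": ss.subjects, "u0": u[:, 0], "u3": u[:, 1], "u4": u[:, 2]}
    )


def fit_mixed_model(rows: pd.DataFrame, reml: bool = True, max_iter: int = 500) -> LearningFit:
    """Fit the trial-level mixed model by (RE)ML.

    The three relative variance components (tau00, tau33, tau44 over
    sigma2) are optimized with L-BFGS-B bounded below at zero; the
    residual scale and the fixed effects are profiled out analytically.
    Empirical-Bayes slopes are the closed-form BLUPs at the estimates.
    """
    ss = _Suffstats(rows)
    theta0 = np.array([1.0, 0.25, 0.25])
    # relative variances are floored at a tiny positive value rather than
    # exactly zero: at the floor the fit is numerically identical to the
    # boundary (and is flagged as such), but the EB slopes retain each
    # subject's ranking information instead of collapsing to a constant
    res = minimize(
        _criterion,
        theta0,
        args=(ss, reml),
        method="L-BFGS-B",
        bounds=[(_VAR_FLOOR, None)] * 3,
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-8},
    )
    theta = np.maximum(res.x, _VAR_FLOOR)
    w, c, logdet, xvx, xvy, yvy = ss.gls_parts(theta)
    gamma = np.linalg.solve(xvx, xvy)
    rss = max(yvy - 2 * gamma @ xvy + gamma @ xvx @ gamma, 1e-12)
    n, p = ss.n_total, 5
    if reml:
        sigma2 = rss / (n - p)
        sign, ld_xvx = np.linalg.slogdet(xvx)
        loglik = -0.5 * (
            (n - p) * np.log(sigma2)
            + logdet
            + ld_xvx
            + (n - p)
            + (n - p) * np.log(2 * np.pi)
        )
    else:
        sigma2 = rss / n
        loglik = -0.5 * (n * np.log(sigma2) + logdet + n + n * np.log(2 * np.pi))
    gamma_cov = sigma2 * np.linalg.inv(xvx)
    gamma_se = np.sqrt(np.diag(gamma_cov))

    u = _blups(ss, gamma, theta)
    subjects = ss.subjects
    raneff = pd.DataFrame(
        {"subject_id": subjects, "u0": u[:, 0], "u3": u[:, 1], "u4": u[:, 2]}
    )
    eb_valence = pd.Series(gamma[3] + u[:, 1], index=subjects, name="valence_sensitivity")
    eb_value = pd.Series(gamma[4] + u[:, 2], index=subjects, name="value_sensitivity")
    tau = theta * sigma2
    return LearningFit(
        gamma_hat=pd.Series(gamma, index=FIXED_EFFECTS),
        gamma_se=pd.Series(gamma_se, index=FIXED_EFFECTS),
        tau00_hat=float(tau[0]),
        tau33_hat=float(tau[1]),
        tau44_hat=float(tau[2]),
        sigma2_hat=float(sigma2),
        loglik=float(loglik),
        reml=reml,
        converged=bool(res.success),
        n_iter=int(res.nit),
        boundary={
            "tau00": theta[0] < _BOUNDARY_TOL,
            "tau33": theta[1] < _BOUNDARY_TOL,
            "tau44": theta[2] < _BOUNDARY_TOL,
        },
        random_effects=raneff,
        eb_valence=eb_valence,
        eb_value=eb_value,
        n_obs=n,
        n_subjects=len(subjects),
    )


def extract_learning_indices(fit: LearningFit) -> pd.DataFrame:
    """Per-subject EB valence/value sensitivity, keyed by subject_id.

    Both indices are oriented so that larger positive values mean more
    pumps after positive feedback / after high-value feedback.
    """
    if fit is None:
        raise ValueError("model must be fitted first")
    return pd.DataFrame(
        {
            "subject_id": fit.eb_valence.index,
            "valence_sensitivity": fit.eb_valence.to_numpy(),
            "value_sensitivity": fit.eb_value.to_numpy(),
        }
    )


def unpooled_slopes(rows: pd.DataFrame) -> pd.DataFrame:
    """Per-subject OLS fits of the same design (no pooling).

    Returns NaN where a subject's own design is rank deficient.
    """
    out = []
    for sid, grp in rows.groupby("subject_id", sort=True):
        x = np.column_stack(
            [
                np.ones(len(grp)),
                grp["trial_number"].to_numpy(float),
                grp["current_outcome"].to_numpy(float),
                grp["prev_valence"].to_numpy(float),
                grp["prev_value"].to_numpy(float),
            ]
        )
        y = grp["pumps"].to_numpy(float)
        if np.linalg.matrix_rank(x) < x.shape[1]:
            out.append({"subject_id": sid, "valence": np.nan, "value": np.nan})
            continue
        beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
        out.append({"subject_id": sid, "valence": beta[3], "value": beta[4]})
    return pd.DataFrame(out)
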