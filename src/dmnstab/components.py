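"""Dimension reduction and the stability-vs-deactivation regressions.

Each subject contributes 10 deactivation betas and 10 autoregressive
stability estimates. Each set is reduced to a single score: the first
principal component of the 10-column covariance matrix (varimax rotation
of a single retained component is the identity and is applied as such).
Loadings are also reported rescaled to the correlation metric
(loading x sqrt(eigenvalue) / column SD) for comparability with factor
tables. The feedback-learning indices are then regressed on both scores
(multiple OLS, intercept included) in two separate analyses — valence
sensitivity and value sensitivity — thresholded at p = 0.025 to correct
for the two comparisons; the stability x deactivation interaction and the
correlation between the two factor scores are computed as checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import pearsonr

from .behavior import build_design_table, extract_learning_indices, fit_mixed_model
from .config import REGRESSION_P_THRESHOLD, ROI_NAMES, RunConfig
from .roiglm import build_glm_design, estimate_deactivation
from .synth import StudyBundle, make_coupled_study
from .usem import (
    FitResult,
    GroupSearchResult,
    SubjectData,
    extract_ar,
    fit_structure,
    group_search,
    individual_search,
)

logger = logging.getLogger("dmnstab")

MIN_PCA_SUBJECTS = 11


# ---------------------------------------------------------------------------
# principal components
# ---------------------------------------------------------------------------


@dataclass
class ComponentResult:
    """First principal component of a subjects x ROIs feature matrix."""

    scores: pd.Series  # per subject
    loadings: pd.Series  # unit-norm eigenvector, per ROI
    rescaled_loadings: pd.Series  # correlation-metric loadings
    eigenvalue: float
    variance_explained: float


def varimax(loadings: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    """Varimax rotation. With a single retained component the rotation is
    the identity and the loadings are returned unchanged."""
    loadings = np.asarray(loadings, dtype=float)
    if loadings.ndim == 1 or loadings.shape[1] == 1:
        return loadings
    p, k = loadings.shape
    rot = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        lam = loadings @ rot
        u, s, vt = np.linalg.svd(
            loadings.T @ (lam**3 - lam @ np.diag(np.sum(lam**2, axis=0)) / p)
        )
        rot = u @ vt
        var_new = float(np.sum(s))
        if var_new - var_old < tol:
            break
        var_old = var_new
    return loadings @ rot


def first_principal_component(matrix: pd.DataFrame) -> ComponentResult:
    """Scores and loadings of the first covariance-matrix PC.

    The sign is fixed so the loading sum is positive; negating all inputs
    therefore leaves the loadings unchanged and negates the scores.
    """
    if matrix.isna().any().any():
        raise ValueError("feature matrix contains missing cells")
    if len(matrix) < MIN_PCA_SUBJECTS:
        raise ValueError(f"need at least {MIN_PCA_SUBJECTS} subjects for the PCA")
    x = matrix.to_numpy(dtype=float)
    col_sd = x.std(axis=0, ddof=1)
    if np.any(col_sd == 0):
        bad = list(matrix.columns[col_sd == 0])
        raise ValueError(f"constant feature columns (zero covariance): {bad}")
    cov = np.cov(x, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    lam = float(eigvals[order[0]])
    v = eigvecs[:, order[0]]
    if v.sum() < 0:
        v = -v
    v = varimax(v)  # identity for a single component
    centered = x - x.mean(axis=0)
    scores = centered @ v
    rescaled = v * np.sqrt(max(lam, 0.0)) / col_sd
    return ComponentResult(
        scores=pd.Series(scores, index=matrix.index, name="score"),
        loadings=pd.Series(v, index=matrix.columns, name="loading"),
        rescaled_loadings=pd.Series(rescaled, index=matrix.columns, name="rescaled"),
        eigenvalue=lam,
        variance_explained=float(lam / np.trace(cov)),
    )


# ---------------------------------------------------------------------------
# regressions
# ---------------------------------------------------------------------------


@dataclass
class RegressionResult:
    """OLS of a learning index on the stability and deactivation scores."""

    coefficients: pd.DataFrame  # index: predictor; B, SE, t, p, significant
    n: int
    r2: float
    factor_correlation: tuple[float, float]  # (r, p) between the two scores
    interaction_p: float
    p_threshold: float
    #: outcome was numerically constant (e.g. a boundary variance estimate
    #: collapsed every EB slope onto the fixed effect); no evidence either
    #: way, so all p-values are reported as 1
    degenerate_outcome: bool = False

    def is_significant(self, predictor: str) -> bool:
        return bool(self.coefficients.loc[predictor, "significant"])


def fit_learning_regression(
    y: pd.Series,
    stability_score: pd.Series,
    deactivation_score: pd.Series,
    p_threshold: float = REGRESSION_P_THRESHOLD,
) -> RegressionResult:
    """Multiple regression of one learning index on both factor scores.

    Two-sided t-tests; the significance flag applies the multiple-
    comparison threshold (default p < 0.025). Also fits the interaction
    model and the Pearson correlation between the two scores.
    """
    df = pd.DataFrame(
        {"y": y, "stability": stability_score, "deactivation": deactivation_score}
    ).dropna()
    if len(df) < 10:
        raise ValueError("need at least 10 complete cases")
    r_scores = np.corrcoef(df["stability"], df["deactivation"])[0, 1]
    if abs(r_scores) > 0.99:
        raise ValueError("stability and deactivation scores are collinear")
    r, rp = pearsonr(df["stability"], df["deactivation"])
    y_arr = df["y"].to_numpy()
    if np.std(y_arr) <= 1e-10 * max(1.0, float(np.abs(y_arr).mean())):
        # constant outcome: typically a boundary (zero) slope-variance
        # estimate collapsing every EB slope onto the fixed effect; there
        # is no between-subject variation to explain, so report null
        # coefficients rather than numerically meaningless t-statistics
        coefs = pd.DataFrame(
            {
                "B": 0.0,
                "SE": np.inf,
                "t": 0.0,
                "p": 1.0,
                "significant": False,
            },
            index=["const", "stability", "deactivation"],
        )
        return RegressionResult(
            coefficients=coefs,
            n=len(df),
            r2=0.0,
            factor_correlation=(float(r), float(rp)),
            interaction_p=1.0,
            p_threshold=p_threshold,
            degenerate_outcome=True,
        )
    x = sm.add_constant(df[["stability", "deactivation"]])
    fit = sm.OLS(df["y"], x).fit()
    coefs = pd.DataFrame(
        {
            "B": fit.params,
            "SE": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
    coefs["significant"] = coefs["p"] < p_threshold
    xi = x.copy()
    xi["interaction"] = df["stability"] * df["deactivation"]
    inter_fit = sm.OLS(df["y"], xi).fit()
    return RegressionResult(
        coefficients=coefs,
        n=len(df),
        r2=float(fit.rsquared),
        factor_correlation=(float(r), float(rp)),
        interaction_p=float(inter_fit.pvalues["interaction"]),
        p_threshold=p_threshold,
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    """Everything one full run produces."""

    config: RunConfig
    bundle: StudyBundle
    learning_indices: pd.DataFrame
    deactivation: pd.DataFrame  # subjects x 10 pump betas
    stability: pd.DataFrame  # subjects x 10 AR estimates
    group_model: GroupSearchResult
    fits: dict[str, FitResult]
    stability_component: ComponentResult
    deactivation_component: ComponentResult
    regressions: dict[str, RegressionResult]
    excluded: dict[str, str] = field(default_factory=dict)
    learning_fit: object = None


def run_full_pipeline(
    config: RunConfig, bundle: StudyBundle | None = None
) -> PipelineResult:
    """Run every stage on a (generated or supplied) study bundle.

    Subjects failing any stage are excluded listwise with a logged
    manifest. The two outcome regressions (valence, value) are separate
    models sharing the same predictors.
    """
    if bundle is None:
        bundle = make_coupled_study(
            config.truth, config.n_subjects, config.t_range, config.seed,
            tr_seconds=config.tr_seconds,
        )
    excluded: dict[str, str] = {}

    # behavior: trial-level mixed model and EB indices
    design = build_design_table(
        bundle.sessions, percentile=config.value_percentile
    )
    learning_fit = fit_mixed_model(design)
    indices = extract_learning_indices(learning_fit).set_index("subject_id")

    # univariate deactivation betas per subject
    deact_rows: dict[str, np.ndarray] = {}
    for session in bundle.sessions:
        sid = session.subject_id
        ts = bundle.series[sid]
        try:
            glm_design = build_glm_design(
                session.event_timings,
                ts.n_volumes,
                config.tr_seconds,
                cutoff_s=config.highpass_cutoff_s,
            )
            deact_rows[sid] = estimate_deactivation(ts, glm_design).pump_betas
        except ValueError as exc:
            excluded[sid] = f"glm: {exc}"
            logger.warning("excluding %s at GLM stage: %s", sid, exc)
    deactivation = pd.DataFrame.from_dict(
        deact_rows, orient="index", columns=list(ROI_NAMES)
    )

    # network model: group search, then per-subject paths and AR extraction
    datasets: list[SubjectData] = []
    for session in bundle.sessions:
        sid = session.subject_id
        if sid in excluded:
            continue
        try:
            datasets.append(SubjectData.from_timeseries(bundle.series[sid], sid))
        except ValueError as exc:
            excluded[sid] = f"usem: {exc}"
            logger.warning("excluding %s at uSEM stage: %s", sid, exc)
    group = group_search(
        datasets,
        alpha=config.search_alpha,
        criterion=config.group_criterion,
        lagged_candidates=config.lagged_candidates,
    )
    fits: dict[str, FitResult] = {}
    for data in datasets:
        if config.individual_search:
            fits[data.subject_id] = individual_search(
                data,
                group.structure,
                alpha=config.search_alpha,
                lagged_candidates=config.lagged_candidates,
            ).fit
        else:
            fits[data.subject_id] = fit_structure(data, group.structure)
    stability = extract_ar(fits)

    # components and regressions on complete cases
    common = indices.index.intersection(deactivation.index).intersection(
        stability.index
    )
    dropped = set(indices.index) - set(common)
    for sid in dropped:
        excluded.setdefault(sid, "incomplete features")
    stab_comp = first_principal_component(stability.loc[common])
    deact_comp = first_principal_component(deactivation.loc[common])
    regressions = {
        outcome: fit_learning_regression(
            indices.loc[common, col],
            stab_comp.scores,
            deact_comp.scores,
            p_threshold=config.regression_p_threshold,
        )
        for outcome, col in (
            ("valence", "valence_sensitivity"),
            ("value", "value_sensitivity"),
        )
    }
    return PipelineResult(
        config=config,
        bundle=bundle,
        learning_indices=indices.loc[common],
        deactivation=deactivation.loc[common],
        stability=stability.loc[common],
        group_model=group,
        fits=fits,
        stability_component=stab_comp,
        deactivation_component=deact_comp,
        regressions=regressions,
        excluded=excluded,
        learning_fit=learning_fit,
    )
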