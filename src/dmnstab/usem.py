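"""Unified SEM (structural VAR) fitting and group-iterative path search.

The network model for one subject's p-ROI series is

    eta(t) = A eta(t) + Phi eta(t-1) + zeta(t),   zeta ~ N(0, diag)

with contemporaneous paths in A (zero diagonal) and first-order lagged
paths in Phi; the diagonal of Phi — each ROI's autoregressive path — is
always estimated and is the stability measure carried forward. Estimation
maximizes the Gaussian conditional likelihood of the reduced form over all
(t-1, t) volume pairs where both volumes are observed; pairs touching a
missing (NaN) volume contribute nothing.

Two estimation routes give the same maximum:

* When the contemporaneous graph is acyclic, det(I - A) = 1 for every
  parameter value, the likelihood separates by equation, and the exact ML
  solution is per-equation OLS. All of it — fits, one-path
  likelihood-ratio scores, pruning — is computed in closed form from one
  20 x 20 Gram matrix per subject, independent of series length.
* Cyclic structures (reciprocal or looped paths) couple the equations
  through the log|det(I - A)| Jacobian term; those fits run a quasi-Newton
  ascent on the variance-profiled likelihood with an analytic gradient,
  also expressed through the Gram matrix.

The search mirrors the group-iterative procedure: starting from the
AR-only null model, the candidate path significant for the largest
fraction of subjects is added while that fraction stays at or above the
group criterion (70%); group paths are then pruned to a fixed point; each
subject finally receives greedy forward addition and backward pruning of
individual paths, with group paths never pruned at the individual stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import erfc
from scipy.stats import f as f_dist

from .config import GROUP_CRITERION, ROI_NAMES, SEARCH_ALPHA
from .roiglm import ROITimeSeries

CONTEMPORANEOUS = "contemporaneous"
LAGGED = "lagged"

_COND_LIMIT = 1e8
_RSS_FLOOR = 1e-12


def _chi2_sf1(stat):
    """Survival function of chi-square with 1 df (vectorized closed form)."""
    return erfc(np.sqrt(np.maximum(stat, 0.0) / 2.0))


def _lr_pvalue(stat, n, k_unrestricted):
    """Finite-sample p-value of a one-path LR statistic.

    For the equation-wise (OLS) case the LR is a monotone transform of
    the exact added-regressor F statistic, F = (n-k)(exp(LR/n) - 1) with
    k the unrestricted regressor count; the F tail is exact under
    Gaussian innovations and corrects the chi-square's anticonservative
    far tail at fMRI-scale series lengths. The same transform is applied
    to the Jacobian-coupled (joint) LR as a small-sample correction.
    """
    dof = max(n - k_unrestricted, 1)
    fstat = dof * np.expm1(np.maximum(stat, 0.0) / n)
    return f_dist.sf(fstat, 1, dof)


# ---------------------------------------------------------------------------
# structure bookkeeping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Structure:
    """Sets of free off-diagonal paths; AR diagonals are always free.

    Paths are (source, target) ROI-index pairs: source predicts target.
    """

    p: int
    contemporaneous: frozenset[tuple[int, int]] = frozenset()
    lagged: frozenset[tuple[int, int]] = frozenset()

    def __post_init__(self) -> None:
        for src, dst in self.contemporaneous | self.lagged:
            if src == dst:
                raise ValueError("off-diagonal paths only (AR is implicit)")
            if not (0 <= src < self.p and 0 <= dst < self.p):
                raise ValueError("path index out of range")

    def has(self, kind: str, src: int, dst: int) -> bool:
        paths = self.contemporaneous if kind == CONTEMPORANEOUS else self.lagged
        return (src, dst) in paths

    def add(self, kind: str, src: int, dst: int) -> "Structure":
        if kind == CONTEMPORANEOUS:
            return replace(self, contemporaneous=self.contemporaneous | {(src, dst)})
        return replace(self, lagged=self.lagged | {(src, dst)})

    def remove(self, kind: str, src: int, dst: int) -> "Structure":
        if kind == CONTEMPORANEOUS:
            return replace(self, contemporaneous=self.contemporaneous - {(src, dst)})
        return replace(self, lagged=self.lagged - {(src, dst)})

    def paths(self) -> list[tuple[str, int, int]]:
        out = [(CONTEMPORANEOUS, s, d) for s, d in sorted(self.contemporaneous)]
        out += [(LAGGED, s, d) for s, d in sorted(self.lagged)]
        return out

    def candidates(self, lagged_candidates: bool = True) -> list[tuple[str, int, int]]:
        """All absent off-diagonal paths, in deterministic order."""
        out = []
        for src in range(self.p):
            for dst in range(self.p):
                if src == dst:
                    continue
                if (src, dst) not in self.contemporaneous:
                    out.append((CONTEMPORANEOUS, src, dst))
                if lagged_candidates and (src, dst) not in self.lagged:
                    out.append((LAGGED, src, dst))
        return sorted(out)

    def n_free(self) -> int:
        """Free parameters per subject: paths + AR diag + variances."""
        return len(self.contemporaneous) + len(self.lagged) + 2 * self.p

    def adjacency(self) -> np.ndarray:
        adj = np.zeros((self.p, self.p), dtype=bool)
        for src, dst in self.contemporaneous:
            adj[src, dst] = True
        return adj

    def reachable(self) -> np.ndarray:
        """Transitive closure of the contemporaneous graph."""
        reach = self.adjacency()
        for _ in range(int(np.ceil(np.log2(max(self.p, 2)))) + 1):
            reach = reach | (reach @ reach)
        return reach

    def is_acyclic(self) -> bool:
        return not np.any(np.diag(self.reachable()))

    def creates_cycle(self, src: int, dst: int, reach: np.ndarray | None = None) -> bool:
        """Would adding contemporaneous src -> dst close a directed loop?"""
        if reach is None:
            reach = self.reachable()
        return bool(reach[dst, src])


def structure_from_names(
    contemporaneous=(), lagged=(), roi_names: tuple[str, ...] = ROI_NAMES
) -> Structure:
    idx = {name: i for i, name in enumerate(roi_names)}
    return Structure(
        p=len(roi_names),
        contemporaneous=frozenset((idx[s], idx[d]) for s, d in contemporaneous),
        lagged=frozenset((idx[s], idx[d]) for s, d in lagged),
    )


# ---------------------------------------------------------------------------
# per-subject data: complete (t-1, t) pairs reduced to a Gram matrix
# ---------------------------------------------------------------------------


@dataclass
class SubjectData:
    """Sufficient statistics of one subject's usable volume pairs.

    Column layout of the Gram matrix: 0..p-1 current volumes, p..2p-1
    lagged volumes.
    """

    subject_id: str
    p: int
    n_pairs: int
    gram: np.ndarray  # (2p, 2p)
    roi_names: tuple[str, ...]

    @classmethod
    def from_timeseries(cls, ts: ROITimeSeries, subject_id: str = "") -> "SubjectData":
        ok = ~ts.missing_mask
        values = ts.values.copy()
        # center each ROI over its observed volumes (no mean parameters)
        values -= np.nanmean(values, axis=1, keepdims=True)
        usable = ok[1:] & ok[:-1]
        if usable.sum() < 10:
            raise ValueError("too few usable (t-1, t) pairs")
        y1 = values[:, 1:][:, usable].T  # current
        y0 = values[:, :-1][:, usable].T  # lagged
        z = np.hstack([y1, y0])
        return cls(
            subject_id=subject_id or "S000",
            p=values.shape[0],
            n_pairs=int(usable.sum()),
            gram=z.T @ z,
            roi_names=ts.roi_names,
        )


def _equation_columns(structure: Structure, k: int) -> list[int]:
    """Gram columns of equation k's regressors (deterministic order)."""
    p = structure.p
    cur = sorted(src for src, dst in structure.contemporaneous if dst == k)
    lag = sorted(src for src, dst in structure.lagged if dst == k)
    return cur + [p + k] + [p + s for s in lag]


def _equation_ols(g: np.ndarray, k: int, cols: list[int]):
    """OLS of current column k on the given Gram columns.

    Returns (beta, rss, gram_bb_inv)."""
    bb = g[np.ix_(cols, cols)]
    by = g[cols, k]
    try:
        bb_inv = np.linalg.inv(bb)
    except np.linalg.LinAlgError as exc:
        raise ValueError("rank-deficient equation regressors") from exc
    beta = bb_inv @ by
    rss = max(float(g[k, k] - beta @ by), _RSS_FLOOR)
    return beta, rss, bb_inv


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """One subject's fitted network model."""

    structure: Structure
    a: np.ndarray  # (p, p) contemporaneous estimates, zero diagonal
    phi: np.ndarray  # (p, p) lagged estimates (diagonal = AR paths)
    zeta_var: np.ndarray  # (p,) ML innovation variances
    loglik: float
    n_effective_pairs: int
    converged: bool
    method: str  # "ols" (acyclic, exact) or "ml" (quasi-Newton)
    se_a: np.ndarray | None = None
    se_phi: np.ndarray | None = None
    roi_names: tuple[str, ...] = ROI_NAMES

    @property
    def ar(self) -> np.ndarray:
        return np.diag(self.phi).copy()


def _loglik_const(n: int, p: int) -> float:
    return -0.5 * n * p * (1.0 + np.log(2.0 * np.pi))


def _fit_acyclic(data: SubjectData, structure: Structure, compute_se: bool) -> FitResult:
    p, g, n = data.p, data.gram, data.n_pairs
    a = np.zeros((p, p))
    phi = np.zeros((p, p))
    zeta = np.zeros(p)
    se_a = np.full((p, p), np.nan)
    se_phi = np.full((p, p), np.nan)
    ll = _loglik_const(n, p)
    for k in range(p):
        cols = _equation_columns(structure, k)
        beta, rss, bb_inv = _equation_ols(g, k, cols)
        zeta[k] = rss / n
        ll -= 0.5 * n * np.log(zeta[k])
        if compute_se:
            dof = max(n - len(cols), 1)
            se = np.sqrt(np.diag(bb_inv) * rss / dof)
        for i, c in enumerate(cols):
            if c < p:
                a[k, c] = beta[i]
                if compute_se:
                    se_a[k, c] = se[i]
            else:
                phi[k, c - p] = beta[i]
                if compute_se:
                    se_phi[k, c - p] = se[i]
    return FitResult(
        structure=structure,
        a=a,
        phi=phi,
        zeta_var=zeta,
        loglik=float(ll),
        n_effective_pairs=n,
        converged=True,
        method="ols",
        se_a=se_a if compute_se else None,
        se_phi=se_phi if compute_se else None,
        roi_names=data.roi_names,
    )


class _JointProblem:
    """Variance-profiled likelihood of a (possibly cyclic) structure,
    expressed entirely through the Gram matrix."""

    def __init__(self, data: SubjectData, structure: Structure):
        self.p = data.p
        self.g = data.gram
        self.n = data.n_pairs
        self.structure = structure
        # parameter order: contemporaneous paths, lagged off-diag, AR diag
        self.par_index: list[tuple[str, int, int]] = (
            [(CONTEMPORANEOUS, s, d) for s, d in sorted(structure.contemporaneous)]
            + [(LAGGED, s, d) for s, d in sorted(structure.lagged)]
            + [(LAGGED, k, k) for k in range(self.p)]
        )
        self._is_cont = np.array(
            [kind == CONTEMPORANEOUS for kind, _, _ in self.par_index]
        )
        self._src = np.array([s for _, s, _ in self.par_index], dtype=int)
        self._dst = np.array([d for _, _, d in self.par_index], dtype=int)
        self._eye = np.eye(self.p)

    def unpack(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p = self.p
        a = np.zeros((p, p))
        phi = np.zeros((p, p))
        c = self._is_cont
        a[self._dst[c], self._src[c]] = x[c]
        phi[self._dst[~c], self._src[~c]] = x[~c]
        return a, phi

    def pack(self, a: np.ndarray, phi: np.ndarray) -> np.ndarray:
        c = self._is_cont
        x = np.empty(len(self.par_index))
        x[c] = a[self._dst[c], self._src[c]]
        x[~c] = phi[self._dst[~c], self._src[~c]]
        return x

    def value_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        """Negative profiled log-likelihood and its gradient."""
        p, g, n = self.p, self.g, self.n
        a, phi = self.unpack(x)
        i_a = self._eye - a
        sign, logdet = np.linalg.slogdet(i_a)
        if sign <= 0 or logdet < -0.5 * np.log(_COND_LIMIT):
            return 1e12 + float(np.sum(x**2)), 2.0 * x
        # v_k: coefficients of residual e_k over [current | lagged] columns
        v = np.concatenate([i_a.T, -phi.T])  # (2p, p)
        gv = g @ v
        s = np.einsum("ik,ik->k", v, gv)
        s = np.maximum(s, _RSS_FLOOR)
        nll = -n * logdet + 0.5 * n * float(np.sum(np.log(s / n)))
        m = np.linalg.inv(i_a)
        c = self._is_cont
        grad = np.empty(len(x))
        # d(-ll)/dA[dst,src] = n M[src,dst] - n (G v)_src,dst / S_dst
        grad[c] = (
            n * m[self._src[c], self._dst[c]]
            - n * gv[self._src[c], self._dst[c]] / s[self._dst[c]]
        )
        grad[~c] = -n * gv[p + self._src[~c], self._dst[~c]] / s[self._dst[~c]]
        return nll, grad

    def loglik_at(self, x: np.ndarray) -> float:
        nll, _ = self.value_grad(x)
        return -nll + _loglik_const(self.n, self.p)


def _bfgs_small(
    fun_grad,
    x0: np.ndarray,
    max_iter: int = 80,
    gtol: float = 1e-5,
    ftol_abs: float = 1e-7,
    hess_scale: float = 1.0,
):
    """Dense BFGS with Armijo backtracking for the small scoring refits.

    Avoids the per-call overhead of the general-purpose optimizer; falls
    back on the caller to use the general routine when it fails.
    ``hess_scale`` seeds the inverse Hessian as I/hess_scale (the profiled
    likelihood's curvature grows with the pair count).
    """
    x = x0.copy()
    f, g = fun_grad(x)
    h = np.eye(x.size) / max(hess_scale, 1.0)
    first = True
    for _ in range(max_iter):
        if np.max(np.abs(g)) < gtol:
            return x, f, True
        d = -h @ g
        gd = g @ d
        if gd > 0:  # not a descent direction; reset
            d = -g / max(float(np.linalg.norm(g)), 1.0)
            gd = g @ d
        step = 1.0
        for _ in range(30):
            xn = x + step * d
            fn, gn = fun_grad(xn)
            if fn <= f + 1e-4 * step * gd:
                break
            step *= 0.5
        else:
            return x, f, False
        sx = xn - x
        yg = gn - g
        sy = sx @ yg
        if sy > 1e-12:
            if first:
                h = np.eye(x.size) * (sy / max(float(yg @ yg), 1e-300))
                first = False
            rho = 1.0 / sy
            hy = h @ yg
            h += (
                np.outer(sx, sx) * rho * (1.0 + rho * (yg @ hy))
                - rho * (np.outer(hy, sx) + np.outer(sx, hy))
            )
        if abs(f - fn) < ftol_abs:
            return xn, fn, True
        x, f, g = xn, fn, gn
    return x, f, np.max(np.abs(g)) < 1e-3


def _fit_joint(
    data: SubjectData,
    structure: Structure,
    compute_se: bool,
    x0: np.ndarray | None = None,
    max_iter: int = 200,
    fast: bool = False,
) -> FitResult:
    prob = _JointProblem(data, structure)
    if x0 is None:
        # warm start: per-equation OLS ignoring the Jacobian coupling
        a0 = np.zeros((data.p, data.p))
        phi0 = np.zeros((data.p, data.p))
        for k in range(data.p):
            cols = _equation_columns(structure, k)
            try:
                beta, _, _ = _equation_ols(data.gram, k, cols)
            except ValueError:
                beta = np.zeros(len(cols))
            for i, c in enumerate(cols):
                if c < data.p:
                    a0[k, c] = beta[i]
                else:
                    phi0[k, c - data.p] = beta[i]
        x0 = prob.pack(a0, phi0)
    if fast:
        x_opt, _, ok = _bfgs_small(
            prob.value_grad,
            np.asarray(x0, dtype=float),
            max_iter,
            ftol_abs=1e-5,
            hess_scale=float(data.n_pairs),
        )
        if not ok:  # fall back to the general-purpose optimizer
            res = minimize(
                prob.value_grad, x0, jac=True, method="L-BFGS-B",
                options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-6},
            )
            x_opt, ok = res.x, bool(res.success)
        res_x, res_success = x_opt, ok
    else:
        res = minimize(
            prob.value_grad,
            x0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-6},
        )
        res_x, res_success = res.x, bool(res.success)
    a, phi = prob.unpack(res_x)
    i_a = np.eye(data.p) - a
    v = np.zeros((2 * data.p, data.p))
    v[: data.p, :] = i_a.T
    v[data.p :, :] = -phi.T
    s = np.einsum("ik,ik->k", v, data.gram @ v)
    zeta = np.maximum(s, _RSS_FLOOR) / data.n_pairs
    se_a = se_phi = None
    if compute_se:
        se_a, se_phi = _joint_se(prob, res_x)
    return FitResult(
        structure=structure,
        a=a,
        phi=phi,
        zeta_var=zeta,
        loglik=float(prob.loglik_at(res_x)),
        n_effective_pairs=data.n_pairs,
        converged=res_success,
        method="ml",
        se_a=se_a,
        se_phi=se_phi,
        roi_names=data.roi_names,
    )


def _joint_se(prob: _JointProblem, x: np.ndarray):
    """Standard errors from the observed information of the profiled
    likelihood (central finite differences of the analytic gradient)."""
    d = len(x)
    h = 1e-5
    hess = np.zeros((d, d))
    for i in range(d):
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        _, gp = prob.value_grad(xp)
        _, gm = prob.value_grad(xm)
        hess[i] = (gp - gm) / (2 * h)
    hess = 0.5 * (hess + hess.T)
    p = prob.p
    se_a = np.full((p, p), np.nan)
    se_phi = np.full((p, p), np.nan)
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        return se_a, se_phi
    for i, (kind, src, dst) in enumerate(prob.par_index):
        if kind == CONTEMPORANEOUS:
            se_a[dst, src] = se[i]
        else:
            se_phi[dst, src] = se[i]
    return se_a, se_phi


def fit_structure(
    data: SubjectData,
    structure: Structure,
    compute_se: bool = False,
    x0: np.ndarray | None = None,
) -> FitResult:
    """Exact ML fit of the given structure for one subject."""
    if data.n_pairs < 5 * structure.n_free():
        warnings.warn(
            f"{data.subject_id}: only {data.n_pairs} usable pairs for "
            f"{structure.n_free()} free parameters"
        )
    if structure.is_acyclic():
        return _fit_acyclic(data, structure, compute_se)
    return _fit_joint(data, structure, compute_se, x0=x0)


def fit_usem(
    ts: ROITimeSeries,
    structure: Structure | None = None,
    subject_id: str = "",
    compute_se: bool = True,
) -> FitResult:
    """Fit the unified SEM to one subject's series.

    ``structure`` defaults to the AR-only null model. Estimation uses only
    complete (t-1, t) volume pairs; missing volumes contribute nothing.
    """
    data = SubjectData.from_timeseries(ts, subject_id)
    if structure is None:
        structure = Structure(p=data.p)
    if structure.p != data.p:
        raise ValueError("structure dimension does not match the series")
    return fit_structure(data, structure, compute_se=compute_se)


# ---------------------------------------------------------------------------
# candidate scoring (one-path likelihood ratios)
# ---------------------------------------------------------------------------


def _score_subject(
    data: SubjectData,
    structure: Structure,
    lagged_candidates: bool,
    base_fit: FitResult | None = None,
    cache: dict | None = None,
    fresh_dsts: set[int] | None = None,
) -> dict[tuple[str, int, int], tuple]:
    """(LR statistic, p-value, coupling metadata) of adding each absent
    path for one subject.

    Acyclicity-preserving candidates are scored in closed form (the exact
    one-path LR reduces to a rank-one OLS update of one equation);
    cycle-creating candidates are scored by a warm-started joint refit.

    A ``cache`` of previous scores may be reused across search iterations:
    adding a path changes only its target equation, so cached closed-form
    scores stay exact except for candidates targeting a ``fresh_dsts``
    equation; cycle-creating candidates couple equations through the
    Jacobian term and are always rescored.
    """
    p, g, n = data.p, data.gram, data.n_pairs
    out: dict[tuple[str, int, int], tuple] = {}
    acyclic = structure.is_acyclic()
    reach = structure.reachable()
    candidates = structure.candidates(lagged_candidates)
    fresh_dsts = fresh_dsts if fresh_dsts is not None else set()

    need_joint: list[tuple[str, int, int]] = []
    if acyclic:
        by_eq: dict[int, list[tuple[str, int]]] = {}
        for kind, src, dst in candidates:
            if kind == CONTEMPORANEOUS and structure.creates_cycle(src, dst, reach):
                # rows coupled to this candidate through the Jacobian: every
                # node on a dst -> src path (plus the endpoints). The score
                # is unchanged unless one of those equations changed or the
                # coupling set itself grew.
                rows = frozenset(
                    n
                    for n in range(p)
                    if (n == dst or reach[dst, n]) and (n == src or reach[n, src])
                )
                cached = cache.get((kind, src, dst)) if cache is not None else None
                if (
                    cached is not None
                    and cached[2] == rows
                    and not (fresh_dsts & rows)
                ):
                    out[(kind, src, dst)] = cached
                else:
                    need_joint.append((kind, src, dst, rows))
            elif cache is not None and dst not in fresh_dsts and (kind, src, dst) in cache:
                out[(kind, src, dst)] = cache[(kind, src, dst)]
            else:
                by_eq.setdefault(dst, []).append((kind, src))
        for k, cands in by_eq.items():
            cols = _equation_columns(structure, k)
            beta, rss, bb_inv = _equation_ols(g, k, cols)
            cand_cols = np.array(
                [src if kind == CONTEMPORANEOUS else p + src for kind, src in cands]
            )
            gcb = g[np.ix_(cand_cols, cols)]  # (C, |B|)
            r_cy = g[cand_cols, k] - gcb @ beta
            denom = np.diag(g[np.ix_(cand_cols, cand_cols)]) - np.einsum(
                "cb,bc->c", gcb, bb_inv @ gcb.T
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                delta = np.where(denom > _RSS_FLOOR, r_cy**2 / denom, 0.0)
            delta = np.minimum(delta, rss - _RSS_FLOOR)
            lr = np.maximum(n * np.log(rss / (rss - delta)), 0.0)
            pvals = _lr_pvalue(lr, n, len(cols) + 1)
            for (kind, src), stat, pval in zip(cands, lr, pvals):
                out[(kind, src, k)] = (float(stat), float(pval), None)
    else:
        need_joint = [(kind, src, dst, None) for kind, src, dst in candidates]

    if need_joint:
        if base_fit is None:
            base_fit = fit_structure(data, structure)
        for kind, src, dst, rows in need_joint:
            bigger = structure.add(kind, src, dst)
            prob = _JointProblem(data, bigger)
            x0 = prob.pack(base_fit.a, base_fit.phi)
            try:
                fit = _fit_joint(data, bigger, compute_se=False, x0=x0, max_iter=40, fast=True)
            except ValueError:
                out[(kind, src, dst)] = (np.nan, np.nan, rows)
                continue
            # identification guard: reject candidates that drive (I - A)
            # toward singularity
            if np.linalg.cond(np.eye(p) - fit.a) > _COND_LIMIT:
                out[(kind, src, dst)] = (np.nan, np.nan, rows)
                continue
            stat = max(2.0 * (fit.loglik - base_fit.loglik), 0.0)
            k_eq = len(_equation_columns(bigger, dst))
            out[(kind, src, dst)] = (stat, float(_lr_pvalue(stat, data.n_pairs, k_eq)), rows)
    if cache is not None:
        cache.clear()
        cache.update(out)
    return out


def score_candidates(
    datasets: list[SubjectData],
    structure: Structure,
    lagged_candidates: bool = True,
) -> pd.DataFrame:
    """Per-path, per-subject one-path LR improvement statistics.

    Paths already in the structure are excluded by construction.
    """
    rows = []
    for data in datasets:
        base = None if structure.is_acyclic() else fit_structure(data, structure)
        scores = _score_subject(data, structure, lagged_candidates, base)
        for (kind, src, dst), (stat, pval, _meta) in scores.items():
            rows.append(
                {
                    "subject_id": data.subject_id,
                    "kind": kind,
                    "source": data.roi_names[src],
                    "target": data.roi_names[dst],
                    "src": src,
                    "dst": dst,
                    "statistic": stat,
                    "pvalue": pval,
                }
            )
    return pd.DataFrame(rows)


def _drop_scores(
    data: SubjectData, structure: Structure, path: tuple[str, int, int]
) -> tuple[float, float]:
    """LR statistic/p-value of removing one existing path for one subject."""
    kind, src, dst = path
    smaller = structure.remove(kind, src, dst)
    n = data.n_pairs
    if structure.is_acyclic():
        cols_with = _equation_columns(structure, dst)
        cols_without = _equation_columns(smaller, dst)
        _, rss_with, _ = _equation_ols(data.gram, dst, cols_with)
        _, rss_without, _ = _equation_ols(data.gram, dst, cols_without)
        stat = max(n * np.log(rss_without / rss_with), 0.0)
        k_eq = len(cols_with)
    else:
        fit_with = fit_structure(data, structure)
        fit_without = fit_structure(data, smaller)
        stat = max(2.0 * (fit_with.loglik - fit_without.loglik), 0.0)
        k_eq = len(_equation_columns(structure, dst))
    return float(stat), float(_lr_pvalue(stat, n, k_eq))


# ---------------------------------------------------------------------------
# group and individual search
# ---------------------------------------------------------------------------


@dataclass
class GroupSearchResult:
    structure: Structure
    history: list[dict] = field(default_factory=list)
    roi_names: tuple[str, ...] = ROI_NAMES

    def edge_list(self, fits: dict[str, "FitResult"] | None = None) -> pd.DataFrame:
        """Group paths as (kind, source, target[, mean_estimate]) rows;
        estimates are averaged over the supplied subject fits."""
        rows = []
        for kind, s, d in self.structure.paths():
            row = {"kind": kind, "source": self.roi_names[s], "target": self.roi_names[d]}
            if fits:
                vals = [
                    (f.a if kind == CONTEMPORANEOUS else f.phi)[d, s]
                    for f in fits.values()
                ]
                row["mean_estimate"] = float(np.mean(vals))
            rows.append(row)
        cols = ["kind", "source", "target"] + (["mean_estimate"] if fits else [])
        return pd.DataFrame(rows, columns=cols)


def group_search(
    datasets: list[SubjectData],
    alpha: float = SEARCH_ALPHA,
    criterion: float = GROUP_CRITERION,
    lagged_candidates: bool = True,
    max_steps: int = 200,
) -> GroupSearchResult:
    """Build the shared path structure by forward search and pruning.

    Starting from the AR-only model, the candidate significant (p < alpha)
    for the largest fraction of subjects is added while that fraction is
    at least the group criterion; ties break on the larger mean |LR
    statistic|, then lexicographic path order. Afterwards each group path
    is re-tested and paths significant for fewer than the criterion
    fraction of subjects are pruned, weakest first, to a fixed point.
    """
    if len(datasets) < 2:
        raise ValueError("group search needs at least 2 subjects")
    p = datasets[0].p
    structure = Structure(p=p)
    history: list[dict] = []
    n_sub = len(datasets)
    steps = 0
    caches: list[dict] = [dict() for _ in datasets]
    fresh_dsts: set[int] | None = None  # None = first pass scores everything

    while True:
        steps += 1
        if steps > max_steps:
            raise RuntimeError(
                f"group search exceeded {max_steps} add steps; "
                f"history: {history[-10:]}"
            )
        frac: dict[tuple[str, int, int], float] = {}
        mean_stat: dict[tuple[str, int, int], float] = {}
        for data, cache in zip(datasets, caches):
            scores = _score_subject(
                data, structure, lagged_candidates,
                cache=cache if fresh_dsts is not None else None,
                fresh_dsts=fresh_dsts,
            )
            if fresh_dsts is None:
                cache.clear()
                cache.update(scores)
            for key, (stat, pval, _meta) in scores.items():
                if np.isnan(pval):
                    continue
                frac[key] = frac.get(key, 0.0) + (pval < alpha) / n_sub
                mean_stat[key] = mean_stat.get(key, 0.0) + abs(stat) / n_sub
        if not frac:
            break
        # deterministic tie-break: fraction, then mean |stat|, then path order
        best = sorted(
            frac,
            key=lambda k: (-frac[k], -mean_stat[k], k),
        )[0]
        if frac[best] < criterion:
            break
        structure = structure.add(*best)
        fresh_dsts = {best[2]}
        history.append({"op": "add", "path": best, "fraction": frac[best]})

    # prune to a fixed point
    prune_steps = 0
    while True:
        prune_steps += 1
        if prune_steps > max_steps:
            raise RuntimeError("group pruning failed to reach a fixed point")
        weakest = None
        weakest_frac = 1.1
        for path in structure.paths():
            keep_frac = 0.0
            for data in datasets:
                _, pval = _drop_scores(data, structure, path)
                keep_frac += (pval < alpha) / n_sub
            if keep_frac < criterion and keep_frac < weakest_frac:
                weakest, weakest_frac = path, keep_frac
        if weakest is None:
            break
        structure = structure.remove(*weakest)
        history.append({"op": "prune", "path": weakest, "fraction": weakest_frac})

    return GroupSearchResult(
        structure=structure, history=history, roi_names=datasets[0].roi_names
    )


@dataclass
class IndividualResult:
    subject_id: str
    structure: Structure
    individual_paths: list[tuple[str, int, int]]
    fit: FitResult


def individual_search(
    data: SubjectData,
    group_structure: Structure,
    alpha: float = SEARCH_ALPHA,
    lagged_candidates: bool = True,
    max_steps: int = 100,
    compute_se: bool = False,
    bonferroni: bool = True,
) -> IndividualResult:
    """Greedy forward addition then backward pruning of individual paths.

    At the group level the 70%-of-subjects criterion already provides
    strong family-wise control, but an individual subject faces ~180
    simultaneous candidate tests, so the per-test threshold here is
    Bonferroni-corrected over the candidate set by default (otherwise a
    null subject would accumulate ~alpha x 180 spurious paths). Group
    paths are kept in the model throughout and are never pruned here,
    even when individually nonsignificant.
    """
    n_candidates = max(len(group_structure.candidates(lagged_candidates)), 1)
    threshold = alpha / n_candidates if bonferroni else alpha
    structure = group_structure
    individual: list[tuple[str, int, int]] = []
    cache: dict = {}
    fresh: set[int] | None = None
    for _ in range(max_steps):
        scores = _score_subject(
            data, structure, lagged_candidates,
            cache=cache if fresh is not None else None, fresh_dsts=fresh,
        )
        if fresh is None:
            cache.update(scores)
        best = None
        for key in sorted(scores):
            stat, pval = scores[key][0], scores[key][1]
            if np.isnan(pval) or pval >= threshold:
                continue
            if best is None or stat > scores[best][0]:
                best = key
        if best is None:
            break
        structure = structure.add(*best)
        fresh = {best[2]}
        individual.append(best)
    else:
        raise RuntimeError("individual forward search did not terminate")

    while True:
        weakest = None
        weakest_p = -1.0
        for path in individual:
            _, pval = _drop_scores(data, structure, path)
            if pval >= threshold and pval > weakest_p:
                weakest, weakest_p = path, pval
        if weakest is None:
            break
        structure = structure.remove(*weakest)
        individual.remove(weakest)

    fit = fit_structure(data, structure, compute_se=compute_se)
    return IndividualResult(
        subject_id=data.subject_id,
        structure=structure,
        individual_paths=individual,
        fit=fit,
    )


def extract_ar(fits: dict[str, FitResult]) -> pd.DataFrame:
    """Per-subject autoregressive (stability) estimates, ROI-labeled."""
    if not fits:
        raise ValueError("no fitted subjects")
    rows = {}
    roi_names = None
    for sid, fit in fits.items():
        roi_names = fit.roi_names
        rows[sid] = fit.ar
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(roi_names))




def subject_path_table(
    fits: dict[str, FitResult], group: Structure
) -> pd.DataFrame:
    """Per-subject estimated paths: every group path plus each subject's
    individual paths, with the fitted estimate and its origin."""
    rows = []
    for sid, fit in fits.items():
        names = fit.roi_names
        for kind, s, d in fit.structure.paths():
            est = (fit.a if kind == CONTEMPORANEOUS else fit.phi)[d, s]
            rows.append(
                {
                    "subject_id": sid,
                    "kind": kind,
                    "source": names[s],
                    "target": names[d],
                    "estimate": float(est),
                    "level": "group" if group.has(kind, s, d) else "individual",
                }
            )
    return pd.DataFrame(
        rows, columns=["subject_id", "kind", "source", "target", "estimate", "level"]
    )


def export_graph(result: GroupSearchResult, path) -> None:
    """Write the group model as an adjacency-list text file."""
    import networkx as nx

    graph = nx.DiGraph()
    graph.add_nodes_from(result.roi_names)
    for kind, s, d in result.structure.paths():
        graph.add_edge(result.roi_names[s], result.roi_names[d], kind=kind)
    with open(path, "w") as fh:
        for line in nx.generate_adjlist(graph):
            fh.write(line + "\n")
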