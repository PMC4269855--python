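"""Multi-patient marker selection by L1-penalized regression.

The working objective for a continuous response is the un-halved lasso
criterion

    g_lambda(beta) = sum_i (y_i - (X beta)_i)^2 + lambda * sum_p |beta_p|

with X the patients-by-markers design (I x P, typically P >> I).  Its exact
piecewise-linear solution path in lambda is computed by the LARS homotopy
with variable deletion; lambda is then chosen by k-fold cross-validation.
Binary responses use an L1-penalized logistic deviance minimized by
iteratively reweighted least squares with coordinate-wise soft-threshold
updates and warm starts (fast but not path-exact).

KKT conditions under this convention: at a solution,
|2 x_p' (y - X beta)| = lambda for active markers (with matching sign) and
<= lambda for inactive ones; hence lambda_max = 2 max_p |x_p' y| for
centered data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit
from sklearn.model_selection import StratifiedKFold

from .io import ResponseVector, SignalMatrix

__all__ = [
    "LarsPath",
    "SelectionResult",
    "lasso_objective",
    "lars_lasso_path",
    "coefficients_at_lambda",
    "cv_select_lambda",
    "logistic_lasso",
    "logistic_lambda_max",
    "select_markers",
    "MarkerSelectionModel",
    "SelectionResults",
]

_EPS = np.finfo(float).eps


def lasso_objective(X, y, beta, lam: float) -> float:
    """g_lambda(beta) = RSS + lambda * ||beta||_1 (un-halved RSS)."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    beta = np.asarray(beta, dtype=np.float64)
    if X.shape != (len(y), len(beta)):
        raise ValueError(
            f"shape mismatch: X {X.shape}, y {len(y)}, beta {len(beta)}"
        )
    r = y - X @ beta
    return float(r @ r + lam * np.abs(beta).sum())


@dataclass
class LarsPath:
    """Exact lasso solution path (knots of the LARS homotopy).

    Coefficients are stored in the *working* space (columns centered /
    standardized as flagged); ``coef_original`` maps back to the input
    scale and supplies the intercept.  ``lambdas[0]`` is lambda_max, where
    beta = 0.
    """

    lambdas: np.ndarray          # (n_knots,), strictly decreasing
    coefs: np.ndarray            # (n_knots, P), working space
    active_sets: list            # list of np.ndarray of active column indices
    signs: list                  # matching sign vectors
    X_work: np.ndarray = field(repr=False)
    y_work: np.ndarray = field(repr=False)
    x_mean: np.ndarray = field(repr=False)
    x_scale: np.ndarray = field(repr=False)
    y_mean: float = 0.0
    centered: bool = True
    standardized: bool = True

    @property
    def n_knots(self) -> int:
        return len(self.lambdas)

    def coef_at(self, lam: float) -> np.ndarray:
        """Working-space solution at lambda, by exact linear interpolation."""
        if lam < 0:
            raise ValueError("lambda must be nonnegative")
        lams = self.lambdas
        if lam >= lams[0]:
            return np.zeros(self.coefs.shape[1])
        if lam <= lams[-1]:
            return self.coefs[-1].copy()
        hi = int(np.searchsorted(-lams, -lam, side="left"))  # lams[hi] <= lam
        lo = hi - 1
        t = (lams[lo] - lam) / (lams[lo] - lams[hi])
        return (1 - t) * self.coefs[lo] + t * self.coefs[hi]

    def coef_original(self, lam: float):
        """(intercept, beta) on the original data scale at lambda."""
        bw = self.coef_at(lam)
        beta = bw / self.x_scale
        intercept = self.y_mean - float(self.x_mean @ beta) if self.centered else 0.0
        return intercept, beta

    def predict(self, X, lam: float) -> np.ndarray:
        intercept, beta = self.coef_original(lam)
        return intercept + np.asarray(X, dtype=np.float64) @ beta

    def kkt_violation(self, knot: int) -> float:
        """Max KKT violation at a knot, in working space.

        Checks | |2 x_p' r| - lambda | on the active set and
        max(|2 x_p' r| - lambda, 0) off it.
        """
        lam = self.lambdas[knot]
        beta = self.coefs[knot]
        g = 2.0 * self.X_work.T @ (self.y_work - self.X_work @ beta)
        active = beta != 0
        scale = max(self.lambdas[0], 1.0)
        v = 0.0
        if active.any():
            v = float(np.max(np.abs(np.abs(g[active]) - lam)))
            v = max(v, float(np.max(np.abs(g[active] - lam * np.sign(beta[active])))))
        if (~active).any():
            v = max(v, float(np.max(np.abs(g[~active])) - lam))
        return v / scale

    def max_kkt_violation(self) -> float:
        return max(self.kkt_violation(k) for k in range(self.n_knots))


class _CholActive:
    """Cholesky factor of the active-set Gram, grown by rank-1 appends."""

    def __init__(self, X: np.ndarray):
        self.X = X
        self.idx: list = []
        self.L = np.zeros((0, 0))

    def add(self, j: int) -> bool:
        xj = self.X[:, j]
        if not self.idx:
            d = float(xj @ xj)
            if d <= _EPS:
                return False
            self.L = np.array([[np.sqrt(d)]])
            self.idx.append(j)
            return True
        b = self.X[:, self.idx].T @ xj
        w = np.linalg.solve(self.L, b)
        d = float(xj @ xj) - float(w @ w)
        if d <= 1e-12 * float(xj @ xj):
            return False  # numerically collinear with active set
        n = len(self.idx)
        L = np.zeros((n + 1, n + 1))
        L[:n, :n] = self.L
        L[n, :n] = w
        L[n, n] = np.sqrt(d)
        self.L = L
        self.idx.append(j)
        return True

    def drop(self, j: int) -> None:
        k = self.idx.index(j)
        self.idx.pop(k)
        G = self.X[:, self.idx].T @ self.X[:, self.idx]
        self.L = np.linalg.cholesky(G) if self.idx else np.zeros((0, 0))

    def solve_gram(self, rhs: np.ndarray) -> np.ndarray:
        z = np.linalg.solve(self.L, rhs)
        return np.linalg.solve(self.L.T, z)


def lars_lasso_path(X, y, *, center: bool = True, standardize: bool = True,
                    max_knots: Optional[int] = None,
                    min_lambda: float = 0.0) -> LarsPath:
    """Exact lasso path of g_lambda by the LARS homotopy with deletion.

    Columns are centered/standardized internally as flagged (recorded on
    the path); the path terminates at lambda = 0 or when the active set
    reaches min(I - 1, P) (I if not centering).  Ties (duplicate columns)
    are broken toward the lowest column index.  Zero-variance columns are
    excluded from the active-set search.
    """
    X = np.array(X, dtype=np.float64, copy=True)
    y = np.array(y, dtype=np.float64, copy=True)
    I, P = X.shape
    if len(y) != I:
        raise ValueError("X and y disagree on the number of patients")
    if np.ptp(y) == 0:
        raise ValueError("constant response: nothing to fit")

    x_mean = X.mean(axis=0) if center else np.zeros(P)
    Xw = X - x_mean if center else X
    sd = Xw.std(axis=0)
    excluded = sd <= 1e-12 * max(float(np.abs(X).max()), 1.0)
    if excluded.any():
        warnings.warn(f"{int(excluded.sum())} zero-variance columns excluded")
    if standardize:
        x_scale = np.where(excluded, 1.0, sd)
        Xw = Xw / x_scale
    else:
        x_scale = np.ones(P)
    y_mean = float(y.mean()) if center else 0.0
    yw = y - y_mean

    max_active = min(I - 1 if center else I, P)
    if max_knots is None:
        max_knots = 8 * max_active + 10

    c = Xw.T @ yw                       # c_p = x_p' r at beta = 0
    c[excluded] = 0.0
    lam = 2.0 * float(np.max(np.abs(c)))
    beta = np.zeros(P)

    lambdas = [lam]
    coefs = [beta.copy()]
    chol = _CholActive(Xw)
    sign = np.zeros(P)
    active_sets = [np.array([], dtype=int)]
    signs = [np.array([])]

    if lam <= 0:
        raise ValueError("response is orthogonal to every marker")

    # first variable: the equicorrelation argmax, lowest index on ties
    j0 = int(np.argmax(np.abs(c) >= np.max(np.abs(c)) - 0.0))
    chol.add(j0)
    sign[j0] = np.sign(c[j0])

    while lam > max(min_lambda, 1e-12) and len(chol.idx) > 0:
        A = np.array(chol.idx, dtype=int)
        sA = sign[A]
        # homotopy direction: beta_A(lam) = beta_A(lam_k) + (lam_k - lam)/2 * w
        w = chol.solve_gram(sA)
        a = Xw.T @ (Xw[:, A] @ w)       # d c_j / d(lam) * 2

        cands = []  # (lam_next, kind, column)
        inactive = np.ones(P, dtype=bool)
        inactive[A] = False
        inactive[excluded] = False
        for j in np.flatnonzero(inactive):
            den1 = 1.0 - a[j]
            if abs(den1) > _EPS:
                l1 = (2.0 * c[j] - lam * a[j]) / den1
                if 1e-12 < l1 < lam - 1e-12:
                    cands.append((l1, "add", j))
            den2 = 1.0 + a[j]
            if abs(den2) > _EPS:
                l2 = -(2.0 * c[j] - lam * a[j]) / den2
                if 1e-12 < l2 < lam - 1e-12:
                    cands.append((l2, "add", j))
        for k, j in enumerate(A):
            if abs(w[k]) > _EPS:
                lz = lam + 2.0 * beta[j] / w[k]
                if 1e-12 < lz < lam - 1e-12:
                    cands.append((lz, "drop", j))

        full = len(A) >= max_active
        if full:
            cands = [c_ for c_ in cands if c_[1] == "drop"]
        if cands:
            lam_next = max(c_[0] for c_ in cands)
            # deterministic tie-break: adds before drops, lowest column index
            tied = [c_ for c_ in cands if abs(c_[0] - lam_next) <= 1e-10 * max(lam, 1.0)]
            tied.sort(key=lambda t: (t[1] != "add", t[2]))
            _, kind, j_evt = tied[0]
        else:
            lam_next, kind, j_evt = 0.0, "end", -1

        step = (lam - lam_next) / 2.0
        beta[A] += step * w
        r = yw - Xw @ beta
        c = Xw.T @ r
        c[excluded] = 0.0
        lam = lam_next
        if kind == "drop":
            beta[j_evt] = 0.0
            sign[j_evt] = 0.0
            chol.drop(j_evt)
        elif kind == "add":
            if chol.add(j_evt):
                sign[j_evt] = np.sign(c[j_evt]) if c[j_evt] != 0 else 1.0
            else:
                excluded = excluded.copy()
                excluded[j_evt] = True
        lambdas.append(lam)
        coefs.append(beta.copy())
        A_now = np.flatnonzero(beta != 0)
        active_sets.append(A_now)
        signs.append(np.sign(beta[A_now]))
        if kind == "end" or len(lambdas) >= max_knots:
            break

    return LarsPath(
        lambdas=np.array(lambdas),
        coefs=np.array(coefs),
        active_sets=active_sets,
        signs=signs,
        X_work=Xw,
        y_work=yw,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        centered=center,
        standardized=standardize,
    )


def coefficients_at_lambda(path: LarsPath, lam: float) -> np.ndarray:
    """Exact working-space lasso solution at lambda (path interpolation)."""
    return path.coef_at(lam)


# ---------------------------------------------------------------------------
# Penalized logistic regression (binary responses)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _logistic_irls_cd(XT, y, eta, beta, b0, lam, elig, max_outer, max_inner, tol
                      ):  # pragma: no cover - numba
    """IRLS + coordinate descent restricted to the eligible columns.

    XT is the (P, I) transposed design so each coordinate update scans a
    contiguous row.  Sweeps cycle over the currently nonzero coefficients
    and periodically over the full eligible set.
    """
    I = XT.shape[1]
    nE = len(elig)
    for _ in range(max_outer):
        outer_delta = 0.0
        w = np.empty(I)
        z = np.empty(I)
        for i in range(I):
            e = eta[i]
            if e > 30.0:
                p_i = 1.0
            elif e < -30.0:
                p_i = 0.0
            else:
                p_i = 1.0 / (1.0 + np.exp(-e))
            wi = p_i * (1.0 - p_i)
            if wi < 1e-5:
                wi = 1e-5
            w[i] = wi
            z[i] = e + (y[i] - p_i) / wi
        it = 0
        full_sweep = True
        converged = False
        while it < max_inner:
            delta_max = 0.0
            it += 1
            num = 0.0
            den = 0.0
            for i in range(I):
                num += w[i] * (z[i] - eta[i] + b0)
                den += w[i]
            b0_new = num / den
            d0 = b0_new - b0
            if d0 != 0.0:
                for i in range(I):
                    eta[i] += d0
                b0 = b0_new
                if abs(d0) > delta_max:
                    delta_max = abs(d0)
            for k in range(nE):
                p = elig[k]
                bp = beta[p]
                if not full_sweep and bp == 0.0:
                    continue
                num = 0.0
                den = 0.0
                for i in range(I):
                    xv = XT[p, i]
                    num += w[i] * xv * (z[i] - eta[i] + xv * bp)
                    den += w[i] * xv * xv
                if den <= 0.0:
                    continue
                if num > lam:
                    b_new = (num - lam) / den
                elif num < -lam:
                    b_new = (num + lam) / den
                else:
                    b_new = 0.0
                d = b_new - bp
                if d != 0.0:
                    for i in range(I):
                        eta[i] += d * XT[p, i]
                    beta[p] = b_new
                    if abs(d) > delta_max:
                        delta_max = abs(d)
            if delta_max > outer_delta:
                outer_delta = delta_max
            if delta_max <= tol:
                if full_sweep:
                    converged = True
                    break
                full_sweep = True       # verify on the full eligible set
            else:
                full_sweep = False      # keep iterating the nonzero coords
        if converged and outer_delta <= tol:
            break
    return b0


@njit(cache=True, fastmath=True)
def _logistic_cd_path(XT, y, lambdas, max_outer, max_inner, tol):  # pragma: no cover
    P, I = XT.shape
    n_lam = len(lambdas)
    coefs = np.zeros((n_lam, P))
    intercepts = np.zeros(n_lam)
    beta = np.zeros(P)
    b0 = 0.0
    eta = np.zeros(I)
    in_model = np.zeros(P, dtype=np.bool_)
    resid = np.empty(I)
    for li in range(n_lam):
        lam = lambdas[li]
        lam_prev = lambdas[li - 1] if li > 0 else 2.0 * lam
        for i in range(I):
            e = eta[i]
            if e > 30.0:
                p_i = 1.0
            elif e < -30.0:
                p_i = 0.0
            else:
                p_i = 1.0 / (1.0 + np.exp(-e))
            resid[i] = y[i] - p_i
        # sequential strong rule screening on the current gradient
        thresh = 2.0 * lam - lam_prev
        for p in range(P):
            in_model[p] = beta[p] != 0.0
        for p in range(P):
            if in_model[p]:
                continue
            g = 0.0
            for i in range(I):
                g += XT[p, i] * resid[i]
            if abs(g) >= thresh:
                in_model[p] = True
        for _ in range(100):
            elig = np.flatnonzero(in_model)
            b0 = _logistic_irls_cd(XT, y, eta, beta, b0, lam, elig,
                                   max_outer, max_inner, tol)
            # KKT sweep over the excluded columns
            for i in range(I):
                e = eta[i]
                if e > 30.0:
                    p_i = 1.0
                elif e < -30.0:
                    p_i = 0.0
                else:
                    p_i = 1.0 / (1.0 + np.exp(-e))
                resid[i] = y[i] - p_i
            violations = 0
            for p in range(P):
                if in_model[p]:
                    continue
                g = 0.0
                for i in range(I):
                    g += XT[p, i] * resid[i]
                if abs(g) > lam * (1.0 + 1e-9):
                    in_model[p] = True
                    violations += 1
            if violations == 0:
                break
        coefs[li] = beta
        intercepts[li] = b0
    return intercepts, coefs


def logistic_lambda_max(X, y) -> float:
    """Smallest lambda with an intercept-only solution: max_p |x_p'(y - ybar)|."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    return float(np.max(np.abs(X.T @ (y - y.mean()))))


def logistic_lasso(X, y, lambdas, *, max_outer: int = 50, max_inner: int = 500,
                   tol: float = 1e-7):
    """L1-penalized logistic regression over a decreasing lambda grid.

    Minimizes -loglik + lambda*||beta||_1 (intercept unpenalized) by IRLS
    with coordinate-wise soft-threshold updates, warm-starting each lambda
    from the previous solution.  Convergence when the largest coefficient
    change drops below ``tol``.  Returns (intercepts, coefs) with one row
    per lambda.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all():
        raise ValueError("binary response must be coded 0/1")
    if len(classes) < 2:
        raise ValueError("single-class response: logistic fit impossible")
    lambdas = np.asarray(lambdas, dtype=np.float64)
    if (np.diff(lambdas) > 0).any():
        raise ValueError("lambda grid must be decreasing for warm starts")
    XT = np.ascontiguousarray(X.T)
    intercepts, coefs = _logistic_cd_path(
        XT, y, lambdas, max_outer, max_inner, tol
    )
    if np.abs(coefs).max() > 1e3:
        warnings.warn(
            "very large coefficients: possible (quasi-)separation; estimates "
            "are capped only by the L1 penalty"
        )
    return intercepts, coefs


# ---------------------------------------------------------------------------
# Cross-validation and the user-facing selection entry point
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Outcome of CV-tuned marker selection."""

    lambda_star: float
    selected: np.ndarray          # column indices with nonzero coefficients
    coefficients: np.ndarray      # (P,) on the original scale
    intercept: float
    cv_lambdas: np.ndarray
    cv_mean: np.ndarray
    cv_sd: np.ndarray
    seed: int
    response_kind: str
    path: Optional[LarsPath] = None


def _stratified_folds(y: np.ndarray, k: int, seed: int, kind: str):
    """Fold assignments stratified by class (binary) or response quantile."""
    I = len(y)
    if kind == "binary":
        strata = y.astype(int)
    else:
        n_bins = max(min(k, I // k), 1)
        order = np.argsort(y, kind="mergesort")
        strata = np.empty(I, dtype=int)
        strata[order] = np.minimum(
            np.arange(I) * n_bins // I, n_bins - 1
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(I), strata))


def _lambda_grid(lam_max: float, n: int = 100, ratio: float = 1e-3) -> np.ndarray:
    return np.geomspace(lam_max, lam_max * ratio, n)


def cv_select_lambda(X, y, k: int = 10, seed: int = 0, *,
                     response_kind: str = "continuous",
                     one_se: bool = False, n_grid: int = 100) -> SelectionResult:
    """Choose lambda by stratified k-fold cross-validation.

    The grid is 100 log-spaced values from lambda_max down to
    lambda_max/1000 (computed on the full data).  Per-fold solutions are
    evaluated on the held-out fold (squared error, or deviance for binary
    responses); lambda* minimizes the mean CV error (or, with ``one_se``,
    is the largest lambda within one standard error of that minimum).
    Deterministic given the seed.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    I = len(y)
    if not (2 <= k <= I):
        raise ValueError(f"k must be between 2 and I={I}, got {k}")

    if response_kind == "continuous":
        lam_floor = 2.0 * float(np.max(np.abs(
            (X - X.mean(0)).T @ (y - y.mean())
            / np.maximum((X - X.mean(0)).std(0), 1e-12)
        ))) * 1e-3
        path_full = lars_lasso_path(X, y, min_lambda=0.5 * lam_floor)
        lam_max = path_full.lambdas[0]
        grid = _lambda_grid(lam_max, n_grid)
        errs = np.empty((k, n_grid))
        for f, (tr, te) in enumerate(_stratified_folds(y, k, seed, response_kind)):
            p = lars_lasso_path(X[tr], y[tr], min_lambda=0.5 * grid[-1])
            for g, lam in enumerate(grid):
                pred = p.predict(X[te], lam)
                errs[f, g] = float(np.mean((y[te] - pred) ** 2))
        mean_err = errs.mean(axis=0)
        sd_err = errs.std(axis=0, ddof=1) / np.sqrt(k)
        lam_star = _pick_lambda(grid, mean_err, sd_err, one_se)
        intercept, beta = path_full.coef_original(lam_star)
        return SelectionResult(
            lambda_star=float(lam_star), selected=np.flatnonzero(beta),
            coefficients=beta, intercept=intercept, cv_lambdas=grid,
            cv_mean=mean_err, cv_sd=sd_err, seed=seed,
            response_kind=response_kind, path=path_full,
        )

    if response_kind != "binary":
        raise ValueError(f"unknown response_kind {response_kind!r}")

    mu, sdv = X.mean(axis=0), X.std(axis=0)
    sdv = np.where(sdv <= 1e-12, 1.0, sdv)
    Xs = (X - mu) / sdv
    lam_max = logistic_lambda_max(Xs, y)
    grid = _lambda_grid(lam_max, n_grid)
    errs = np.empty((k, n_grid))
    for f, (tr, te) in enumerate(_stratified_folds(y, k, seed, response_kind)):
        b0s, betas = logistic_lasso(Xs[tr], y[tr], grid)
        eta = b0s[:, None] + betas @ Xs[te].T        # (n_grid, n_test)
        # mean binomial deviance on the held-out fold
        ll = y[te][None, :] * eta - np.logaddexp(0.0, eta)
        errs[f] = -2.0 * ll.mean(axis=1)
    mean_err = errs.mean(axis=0)
    sd_err = errs.std(axis=0, ddof=1) / np.sqrt(k)
    lam_star = _pick_lambda(grid, mean_err, sd_err, one_se)
    b0s, betas = logistic_lasso(Xs, y, grid)
    g_star = int(np.argmin(np.abs(grid - lam_star)))
    beta_s = betas[g_star]
    beta = beta_s / sdv
    intercept = float(b0s[g_star] - mu @ beta)
    return SelectionResult(
        lambda_star=float(lam_star), selected=np.flatnonzero(beta),
        coefficients=beta, intercept=intercept, cv_lambdas=grid,
        cv_mean=mean_err, cv_sd=sd_err, seed=seed, response_kind=response_kind,
    )


def _pick_lambda(grid, mean_err, sd_err, one_se: bool) -> float:
    g_min = int(np.argmin(mean_err))
    if not one_se:
        return float(grid[g_min])
    cutoff = mean_err[g_min] + sd_err[g_min]
    ok = np.flatnonzero(mean_err <= cutoff)
    return float(grid[ok[0]])  # grid decreasing: first ok = largest lambda


def select_markers(signal: SignalMatrix, response: ResponseVector, *,
                   smooth_segments: Optional[pd.DataFrame] = None,
                   k: int = 10, seed: int = 0, one_se: bool = False):
    """Select genomic markers associated with the patient-level response.

    Builds the patients-by-markers design by transposing the signal matrix
    (optionally after replacing values by segment means), then dispatches
    to the LARS + CV route (continuous response) or the penalized-logistic
    route (binary).  Returns (SelectionResult, coefficient table) where the
    table annotates each selected marker with its genomic coordinates.
    """
    if smooth_segments is not None:
        from .segmentation import smooth_by_segmentation

        signal = smooth_by_segmentation(signal, smooth_segments)
    y = response.reindex(signal.samples)
    I = signal.n_samples
    if I < 3:
        raise ValueError("need at least 3 patients for selection")
    k_eff = min(k, I) if I < 10 else k
    X = signal.values.T.copy()
    result = cv_select_lambda(
        X, y, k=k_eff, seed=seed, response_kind=response.response_kind,
        one_se=one_se,
    )
    sel = result.selected
    table = pd.DataFrame(
        {
            "marker_id": signal.markers.marker_id[sel],
            "chromosome": signal.markers.chromosome[sel],
            "position": signal.markers.position[sel],
            "coefficient": result.coefficients[sel],
        }
    )
    return result, table


class MarkerSelectionModel:
    """L1-penalized multi-patient marker selection.

    Parameters
    ----------
    signal : SignalMatrix
        Copy-number (or mirrored-BAF) matrix; columns are the patients.
    response : ResponseVector
        Continuous (lasso/LARS) or binary (penalized logistic) outcome.
    smooth_segments : DataFrame, optional
        Segment table used to replace marker values by segment means
        before selection (noise/dimension reduction).
    """

    def __init__(self, signal: SignalMatrix, response: ResponseVector, *,
                 smooth_segments: Optional[pd.DataFrame] = None):
        self.signal = signal
        self.response = response
        self.smooth_segments = smooth_segments

    def fit(self, *, k: int = 10, seed: int = 0, one_se: bool = False
            ) -> "SelectionResults":
        result, table = select_markers(
            self.signal, self.response, smooth_segments=self.smooth_segments,
            k=k, seed=seed, one_se=one_se,
        )
        return SelectionResults(self, result, table)


class SelectionResults:
    """CV-tuned selection outcome with genomic annotation."""

    def __init__(self, model: MarkerSelectionModel, result: SelectionResult,
                 table: pd.DataFrame):
        self.model = model
        self.result = result
        self.table = table

    @property
    def selected_markers(self) -> np.ndarray:
        return self.table["marker_id"].to_numpy()

    def cv_curve(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lambda": self.result.cv_lambdas,
                "cv_error": self.result.cv_mean,
                "cv_se": self.result.cv_sd,
            }
        )

    def summary(self) -> str:
        r = self.result
        lines = [
            "Marker selection results",
            f"  response: {r.response_kind}   folds seeded with {r.seed}",
            f"  lambda*: {r.lambda_star:.6g}   (min CV "
            f"{'deviance' if r.response_kind == 'binary' else 'squared error'}: "
            f"{r.cv_mean.min():.4g})",
            f"  selected markers: {len(r.selected)}",
            "",
            f"  {'marker_id':<16}{'chrom':>6}{'position':>12}{'coefficient':>14}",
        ]
        for _, row in self.table.iterrows():
            lines.append(
                f"  {row['marker_id']:<16}{row['chromosome']:>6}"
                f"{row['position']:>12}{row['coefficient']:>14.5g}"
            )
        return "\n".join(lines)

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)
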