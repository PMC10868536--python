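"""REML variance-component estimation for one- and two-GRM mixed models.

Single component:  y = X b + g + e,  var(g) = G s2g,  var(e) = I s2e.
The restricted likelihood is profiled down to the single ratio
delta = s2e/s2g after one eigendecomposition of G, and maximised by a
bounded derivative-free search on log(delta); both components are then
recovered in closed form.  This is the EMMA-style exact REML.

Two components:  y = X b + f + r + e,  var(f) = Gf s2f,  var(r) = Gr s2r.
Estimated by average-information (AI) REML with EM-REML steps for the first
iterations and as a fallback whenever an AI step would decrease the
restricted likelihood or leave the parameter space.  The feature weight
lambda = s2f / (s2f + s2r) is the quantity that collapses the two GRMs into
one combined matrix for prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.optimize import minimize_scalar

from .kinship import GRM

logger = logging.getLogger(__name__)

__all__ = ["VarianceComponents", "reml_single", "reml_two", "compute_lambda"]

MAX_ITER = 100
LOGLIK_TOL = 1e-8
PARAM_TOL = 1e-6


@dataclass
class VarianceComponents:
    sigma_e2: float
    sigma_g2: float | None = None          # single-component model
    sigma_f2: float | None = None          # two-component model
    sigma_r2: float | None = None
    reml_loglik: float = np.nan
    n_iterations: int = 0
    converged: bool = False
    boundary: bool = False                 # a component pinned at the floor
    identifiable: bool = True              # False when Gf == Gr

    @property
    def genetic_variance(self) -> float:
        if self.sigma_g2 is not None:
            return self.sigma_g2
        return (self.sigma_f2 or 0.0) + (self.sigma_r2 or 0.0)

    @property
    def h2(self) -> float:
        g = self.genetic_variance
        return g / (g + self.sigma_e2)

    @property
    def lam(self) -> float:
        return compute_lambda(self)


def compute_lambda(vc: VarianceComponents) -> float:
    """Feature weight lambda = s2f / (s2f + s2r)."""
    if vc.sigma_f2 is None or vc.sigma_r2 is None:
        raise ValueError("lambda requires a two-component fit")
    total = vc.sigma_f2 + vc.sigma_r2
    if total <= 0:
        raise ValueError("no genetic variance: lambda undefined")
    return vc.sigma_f2 / total


def _as_matrix(G) -> np.ndarray:
    return G.matrix if isinstance(G, GRM) else np.asarray(G, dtype=float)


def _design(X, n: int) -> np.ndarray:
    if X is None:
        return np.ones((n, 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return X.T if X.shape[0] != n else X


def reml_single(y, G, X=None) -> VarianceComponents:
    """Exact REML for the one-GRM model via the profiled likelihood in delta.

    Returns both variance components, the restricted log-likelihood at the
    optimum (up to an additive constant not depending on the parameters) and
    h2 = s2g/(s2g+s2e).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if np.var(y) <= 0:
        raise ValueError("phenotype variance is zero")
    Gm = _as_matrix(G)
    if Gm.shape != (n, n):
        raise ValueError(f"GRM shape {Gm.shape} does not match n={n}")
    X = _design(X, n)
    p = X.shape[1]

    w, U = eigh(Gm)
    if w[0] < -1e-8:
        logger.warning("GRM min eigenvalue %.3g < 0; flooring at 0", w[0])
    w = np.maximum(w, 0.0)
    yt = U.T @ y
    Xt = U.T @ X

    def neg_profiled(log_delta: float) -> float:
        return -_profiled_loglik(np.exp(log_delta), w, yt, Xt, n, p)[0]

    # coarse grid then bounded local refinement
    grid = np.linspace(np.log(1e-6), np.log(1e6), 121)
    vals = [neg_profiled(g) for g in grid]
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = minimize_scalar(neg_profiled, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    delta = float(np.exp(res.x))
    ll, s2g = _profiled_loglik(delta, w, yt, Xt, n, p)
    return VarianceComponents(
        sigma_e2=delta * s2g,
        sigma_g2=s2g,
        reml_loglik=ll,
        n_iterations=int(res.nfev) + len(grid),
        converged=bool(res.success),
    )


def _profiled_loglik(delta, w, yt, Xt, n, p):
    """Restricted log-likelihood profiled over beta and s2g, and s2g-hat."""
    d = w + delta
    dinv = 1.0 / d
    xtdx = Xt.T @ (Xt * dinv[:, None])
    xtdy = Xt.T @ (yt * dinv)
    beta = np.linalg.solve(xtdx, xtdy)
    ypy = float(yt @ (yt * dinv) - xtdy @ beta)
    s2g = ypy / (n - p)
    ll = -0.5 * (
        (n - p) * np.log(2.0 * np.pi * s2g)
        + (n - p)
        + np.sum(np.log(d))
        + np.linalg.slogdet(xtdx)[1]
    )
    return float(ll), float(s2g)


def _reml_loglik(theta, parts, y, X):
    """Restricted log-likelihood and the projection pieces for given theta."""
    n = len(y)
    V = sum(t * M for t, M in zip(theta, parts))
    c, low = cho_factor(V, lower=True)
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    Vinv_y = cho_solve((c, low), y)
    Vinv_X = cho_solve((c, low), X)
    xvx = X.T @ Vinv_X
    xvx_chol = cho_factor(xvx)
    beta = cho_solve(xvx_chol, X.T @ Vinv_y)
    Py = Vinv_y - Vinv_X @ beta
    logdet_xvx = np.linalg.slogdet(xvx)[1]
    ll = -0.5 * (logdet_v + logdet_xvx + float(y @ Py) + (n - X.shape[1]) *
                 np.log(2.0 * np.pi))
    # P = Vinv - Vinv X (X'Vinv X)^-1 X'Vinv, needed for traces
    P = np.linalg.inv(V)
    VinvX = P @ X
    P = P - VinvX @ np.linalg.solve(X.T @ VinvX, VinvX.T)
    return float(ll), Py, P


def reml_two(y, Gf, Gr, X=None, floor_frac: float = 1e-8) -> VarianceComponents:
    """AI-REML with EM safeguards for the two-GRM model.

    Components are floored at ``floor_frac * var(y)``; a component finishing
    on the floor is flagged ``boundary``.  When the two GRMs are numerically
    identical only the sum s2f + s2r is identifiable: the fit proceeds but is
    flagged ``identifiable=False`` and ``lam`` must not be interpreted.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    Gfm, Grm = _as_matrix(Gf), _as_matrix(Gr)
    X = _design(X, n)
    vary = float(np.var(y))
    if vary <= 0:
        raise ValueError("phenotype variance is zero")
    floor = floor_frac * vary
    identifiable = bool(np.max(np.abs(Gfm - Grm)) > 1e-10)
    if not identifiable:
        logger.warning("Gf and Gr are identical: lambda is not identifiable")

    parts = [Gfm, Grm, np.eye(n)]
    theta = np.array([vary / 3.0, vary / 3.0, vary / 3.0])
    ll, Py, P = _reml_loglik(theta, parts, y, X)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        ypvpy = np.array([float(Py @ (M @ Py)) for M in parts])
        tr_pv = np.array([float(np.sum(P * M)) for M in parts])
        score = 0.5 * (ypvpy - tr_pv)
        # EM step (guaranteed uphill, slow)
        theta_em = np.maximum(theta + theta**2 / n * (ypvpy - tr_pv), floor)
        use_em = it <= 3
        theta_new = theta_em
        if not use_em:
            # active-set AI: components pinned at the floor whose gradient
            # points further down are held fixed, not dragged into the solve
            pinned = (theta <= floor * (1 + 1e-9)) & (score < 0)
            active = np.flatnonzero(~pinned)
            PV = [M @ Py for M in parts]
            ai = 0.5 * np.array(
                [[float(PV[i] @ (P @ PV[j])) for j in range(3)] for i in range(3)]
            )
            if active.size:
                try:
                    step = np.linalg.solve(
                        ai[np.ix_(active, active)], score[active]
                    )
                    # step-halving: a full AI step can overshoot on the
                    # likelihood ridge left by correlated GRMs
                    for frac in (1.0, 0.5, 0.25, 0.125):
                        theta_ai = theta.copy()
                        theta_ai[active] = theta[active] + frac * step
                        theta_ai = np.maximum(theta_ai, floor)
                        ll_ai, _, _ = _reml_loglik(theta_ai, parts, y, X)
                        if ll_ai >= ll - 1e-12:
                            theta_new = theta_ai
                            break
                except np.linalg.LinAlgError:
                    pass
        ll_new, Py_new, P_new = _reml_loglik(theta_new, parts, y, X)
        if ll_new < ll - 1e-10:
            # even EM failed numerically; keep the previous point
            theta_new, ll_new, Py_new, P_new = theta, ll, Py, P
        d_ll = abs(ll_new - ll)
        # components sitting on the floor are excluded from the relative
        # change criterion: they creep geometrically and never settle
        free = theta_new > floor * (1 + 1e-9)
        rel = np.abs(theta_new - theta) / np.maximum(theta, floor)
        d_par = float(rel[free].max()) if free.any() else 0.0
        theta, ll, Py, P = theta_new, ll_new, Py_new, P_new
        if d_ll < LOGLIK_TOL and d_par < PARAM_TOL:
            converged = True
            break
    boundary = bool(np.any(theta <= floor * (1 + 1e-9)))
    if not converged:
        logger.warning("two-component REML did not converge in %d iterations",
                       MAX_ITER)
    return VarianceComponents(
        sigma_f2=float(theta[0]),
        sigma_r2=float(theta[1]),
        sigma_e2=float(theta[2]),
        reml_loglik=ll,
        n_iterations=it,
        converged=converged,
        boundary=boundary,
        identifiable=identifiable,
    )
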