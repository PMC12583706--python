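"""REML machinery for the multi-kernel heterosis mixed model.

Model: y_MPH ~ N(X alpha, sum_* sigma2_* K_* + sigma2_eps R) with R = T T'
the covariance induced on the residuals by the MPH transformation.  The
residual structure is removed once by Cholesky whitening (y, X and every
kernel are pre-multiplied by L^-1 where L L' = R), after which residuals
are i.i.d. and standard algorithms apply.

Estimation uses average-information (AI) REML updates with step halving
and an expectation-maximization fallback on non-improving steps; variance
components are kept non-negative by an active-set rule (a component pinned
at zero is released only when its score turns positive).

Per-marker testing follows the P3D ("population parameters previously
determined") approximation: the background variance ratios r_* =
sigma2_* / sigma2_eps are estimated once in the null model and frozen,
V0 = sum_* r_* K_* + I is factored once, and each marker's test reduces to
a one-dimensional profile of the restricted likelihood over the single
ratio delta = sigma2_h / sigma2_eps after an eigendecomposition of the
doubly-whitened marker kernel.  The LR statistic for H0: sigma2_h = 0 is
referred to the boundary null 1/2 chi2_0 + 1/2 chi2_1.  Both L0 and L1 are
evaluated in the same delta-profiled parameterization (L0 is the delta = 0
point), so the ratio is internally consistent; restricted likelihoods are
used throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve, cholesky, eigh, solve_triangular

from hetscan.kernels import HeterosisKernel, KernelSet
from hetscan.popdata import CodingMatrices, MPHTransform

logger = logging.getLogger(__name__)

__all__ = [
    "VarianceComponents", "FittedNull", "MarkerTest", "WaldResult",
    "reml_multikernel", "profile_null", "marker_lr_test", "mixture_pvalue",
    "wald_component_test", "WALD_MODELS",
]


class LMMError(ValueError):
    """Raised for singular or inconsistent mixed-model inputs."""


@dataclass
class VarianceComponents:
    """REML estimates for the multi-kernel null model."""

    sigma2: dict[str, float]          # per-kernel components, e.g. D/AA/AD/DD
    sigma2_eps: float
    loglik: float                     # restricted log-likelihood (whitened scale)
    n_iter: int
    converged: bool

    @property
    def ratios(self) -> dict[str, float]:
        return {k: v / self.sigma2_eps for k, v in self.sigma2.items()}


@dataclass
class FittedNull:
    """Frozen null fit: whitening factors reused for every marker test.

    ``L_R`` is the Cholesky factor of the residual covariance R = T T';
    ``L0`` the factor of V0 = sum_* r_* K~_* + I assembled from the
    R-whitened kernels with the null variance ratios.  The full covariance
    of y under the null is sigma2_eps * (L_R V0 L_R').
    """

    vc: VarianceComponents
    ratios: dict[str, float]
    L_R: np.ndarray
    L0: np.ndarray
    kernels_whitened: dict[str, np.ndarray] = field(repr=False)
    X: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.L0.shape[0]

    def whiten_vec(self, v: np.ndarray) -> np.ndarray:
        """Apply (L_R L0)^-1, mapping the model to i.i.d. unit-ratio residuals."""
        return solve_triangular(self.L0, solve_triangular(self.L_R, v, lower=True),
                                lower=True)

    def whiten_mat(self, K: np.ndarray) -> np.ndarray:
        A = solve_triangular(self.L_R, K, lower=True)
        A = solve_triangular(self.L_R, A.T, lower=True).T
        A = solve_triangular(self.L0, A, lower=True)
        A = solve_triangular(self.L0, A.T, lower=True).T
        return 0.5 * (A + A.T)

    def restricted_loglik(self, y: np.ndarray, X: np.ndarray | None = None,
                          ) -> float:
        """Recompute the null restricted log-likelihood from the frozen factors.

        Matches the value reported by :func:`reml_multikernel` (whitened
        scale, constants dropped) up to optimizer tolerance.
        """
        yw = self.whiten_vec(np.asarray(y, dtype=float))
        n = yw.shape[0]
        s2 = self.vc.sigma2_eps
        ld_V = 2.0 * np.sum(np.log(np.diag(self.L0))) + n * np.log(s2)
        if X is None or X.size == 0:
            return float(-0.5 * (ld_V + yw @ yw / s2))
        Xw = self.whiten_vec(X)
        XtX = Xw.T @ Xw
        beta = np.linalg.solve(XtX, Xw.T @ yw)
        resid = yw - Xw @ beta
        sign, ld_X = np.linalg.slogdet(XtX / s2)
        return float(-0.5 * (ld_V + ld_X + resid @ resid / s2))


@dataclass
class MarkerTest:
    """Result of the per-marker variance-component LR test."""

    index: int
    sigma2_h: float
    sigma2_eps: float
    delta: float                      # sigma2_h / sigma2_eps at the optimum
    lr: float
    pvalue: float


@dataclass
class WaldResult:
    """Wald test for a fixed genetic component effect."""

    effect: str                       # one of d_i / aa_ij / ad_ij / ad_ji / dd_ij
    i: int
    j: int | None
    estimate: float
    variance: float
    statistic: float
    pvalue: float


# ---------------------------------------------------------------------------
# REML for the multi-kernel null model
# ---------------------------------------------------------------------------

def _chol_jitter(A: np.ndarray, what: str) -> np.ndarray:
    """Lower Cholesky factor, retrying once with a small diagonal jitter."""
    try:
        return cholesky(A, lower=True)
    except np.linalg.LinAlgError:
        jitter = 1e-8 * float(np.mean(np.diag(A)))
        try:
            return cholesky(A + jitter * np.eye(A.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            raise LMMError(f"{what} is not positive-definite "
                           f"(jitter {jitter:.3e} did not help)") from None


def _whiten_by(L: np.ndarray, K: np.ndarray) -> np.ndarray:
    A = solve_triangular(L, K, lower=True)
    A = solve_triangular(L, A.T, lower=True).T
    return 0.5 * (A + A.T)


def _reml_loglik_parts(theta: np.ndarray, Ks: list[np.ndarray], y: np.ndarray,
                       X: np.ndarray | None):
    """Restricted log-likelihood, projection P and Py for a whitened model."""
    n = y.shape[0]
    V = theta[-1] * np.eye(n)
    for t, K in zip(theta[:-1], Ks):
        if t > 0.0:
            V += t * K
    cf = cho_factor(V, lower=True)
    ld_V = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vinv = cho_solve(cf, np.eye(n))
    if X is not None and X.size:
        VX = Vinv @ X
        XVX = X.T @ VX
        sign, ld_X = np.linalg.slogdet(XVX)
        if sign <= 0:
            raise LMMError("X'V^-1 X singular: collinear covariates")
        P = Vinv - VX @ np.linalg.solve(XVX, VX.T)
    else:
        ld_X = 0.0
        P = Vinv
    Py = P @ y
    ll = -0.5 * (ld_V + ld_X + y @ Py)
    return ll, P, Py


def reml_multikernel(y: np.ndarray, kernels: KernelSet | dict[str, np.ndarray],
                     X: np.ndarray | None = None,
                     residual_cov: np.ndarray | None = None,
                     max_iter: int = 100, tol: float = 1e-6,
                     ) -> VarianceComponents:
    """Fit y ~ N(X alpha, sum_* sigma2_* K_* + sigma2_eps R) by AI-REML.

    ``kernels`` is a :class:`~hetscan.kernels.KernelSet` (which carries R)
    or a plain name -> matrix dict with ``residual_cov`` given separately
    (identity if omitted).  Components are constrained non-negative;
    convergence is declared when successive restricted log-likelihoods
    agree to ``tol`` (relative), with a warning -- not an error -- if the
    iteration cap is hit first.
    """
    y = np.asarray(y, dtype=float)
    if isinstance(kernels, KernelSet):
        kdict = kernels.kernels
        R = kernels.R
    else:
        kdict = dict(kernels)
        R = residual_cov if residual_cov is not None else np.eye(y.shape[0])
    names = list(kdict)
    n = y.shape[0]
    q = 0 if X is None or X.size == 0 else np.asarray(X).shape[1]
    if n <= q + 1:
        raise LMMError(f"n = {n} too small for {q} covariates")

    L_R = _chol_jitter(R, "residual covariance R")
    yw = solve_triangular(L_R, y, lower=True)
    Xw = None
    if q:
        Xw = solve_triangular(L_R, np.asarray(X, dtype=float), lower=True)
    Ks = [_whiten_by(L_R, kdict[name]) for name in names]

    var_y = float(np.var(yw))
    if var_y <= 0:
        raise LMMError("phenotype has zero variance")
    k = len(Ks)
    theta = np.full(k + 1, 0.5 * var_y / max(k, 1))
    theta[-1] = 0.5 * var_y
    floor = 1e-10 * var_y

    ll, P, Py = _reml_loglik_parts(theta, Ks, yw, Xw)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mats = Ks + [np.eye(n)]
        # scores and AI matrix for the free (and boundary) components
        s = np.empty(k + 1)
        t_vecs = []
        for j, K in enumerate(mats):
            KPy = K @ Py
            s[j] = -0.5 * (np.sum(P * K) - Py @ KPy)
            t_vecs.append(KPy)
        Tm = np.column_stack(t_vecs)
        AI = 0.5 * (Tm.T @ P @ Tm)

        active = (theta[:-1] <= floor) & (s[:-1] <= 0.0)   # pinned at zero
        free = np.r_[~active, True]
        delta = np.zeros(k + 1)
        try:
            delta[free] = np.linalg.solve(AI[np.ix_(free, free)], s[free])
        except np.linalg.LinAlgError:
            delta[free] = np.nan

        improved = False
        if np.all(np.isfinite(delta)):
            step = 1.0
            for _ in range(12):
                cand = theta + step * delta
                cand[:-1] = np.maximum(cand[:-1], 0.0)
                cand[-1] = max(cand[-1], floor)
                cand[:-1][active] = 0.0
                try:
                    ll_new, P_new, Py_new = _reml_loglik_parts(cand, Ks, yw, Xw)
                except (np.linalg.LinAlgError, LMMError):
                    step *= 0.5
                    continue
                if ll_new >= ll - 1e-10:
                    theta, ll, P, Py = cand, ll_new, P_new, Py_new
                    improved = True
                    break
                step *= 0.5
        if not improved:
            # EM fallback: guaranteed-direction multiplicative update
            cand = theta.copy()
            for j, K in enumerate(mats):
                KPy = K @ Py
                cand[j] = theta[j] + theta[j] ** 2 * (Py @ KPy - np.sum(P * K)) / n
            cand[:-1] = np.maximum(cand[:-1], 0.0)
            cand[-1] = max(cand[-1], floor)
            ll_new, P_new, Py_new = _reml_loglik_parts(cand, Ks, yw, Xw)
            if ll_new < ll - 1e-8 * (abs(ll) + 1.0):
                converged = True          # no direction improves: at optimum
                break
            theta, ll, P, Py = cand, ll_new, P_new, Py_new
        if it > 1 and abs(ll - ll_prev) < tol * (abs(ll) + 1.0):
            converged = True
            break
        ll_prev = ll
    if not converged:
        warnings.warn(f"REML did not converge in {max_iter} iterations "
                      f"(last restricted log-likelihood {ll:.6g})",
                      RuntimeWarning, stacklevel=2)
    sigma2 = {name: float(max(theta[j], 0.0)) for j, name in enumerate(names)}
    return VarianceComponents(sigma2=sigma2, sigma2_eps=float(theta[-1]),
                              loglik=float(ll), n_iter=it, converged=converged)


def profile_null(fit: VarianceComponents, kernels: KernelSet,
                 X: np.ndarray | None = None) -> FittedNull:
    """Freeze the null variance ratios and factor V0 once (P3D).

    V0 = sum_* r_* K~_* + I is assembled from the R-whitened kernels with
    the ratios r_* = sigma2_* / sigma2_eps of the null fit and Cholesky
    factored; the factor is reused for every marker test.
    """
    if not fit.converged:
        warnings.warn("profiling a non-converged null fit", RuntimeWarning,
                      stacklevel=2)
    L_R = _chol_jitter(kernels.R, "residual covariance R")
    Kw = {name: _whiten_by(L_R, K) for name, K in kernels.kernels.items()}
    ratios = fit.ratios
    n = kernels.n
    V0 = np.eye(n)
    for name, K in Kw.items():
        r = ratios.get(name, 0.0)
        if r > 0.0:
            V0 += r * K
    L0 = _chol_jitter(V0, "null covariance V0")
    return FittedNull(vc=fit, ratios=dict(ratios), L_R=L_R, L0=L0,
                      kernels_whitened=Kw, X=X)


# ---------------------------------------------------------------------------
# Per-marker LR test with the chi-square-mixture null
# ---------------------------------------------------------------------------

def mixture_pvalue(lam: float) -> float:
    """P-value under the boundary null 1/2 chi2_0 + 1/2 chi2_1.

    The point mass at zero makes p = 1 whenever the LR statistic is zero
    (a convention: the statistic sits exactly on the null's point mass).
    """
    if not np.isfinite(lam):
        raise LMMError("LR statistic must be finite")
    if lam < -1e-8:
        raise LMMError(f"negative LR statistic {lam}: floor it at 0 upstream")
    if lam <= 0.0:
        return 1.0
    return float(0.5 * stats.chi2.sf(lam, df=1))


def _profile_reml_delta(delta: float, lam_eig: np.ndarray, y: np.ndarray,
                        X: np.ndarray | None) -> tuple[float, float]:
    """Restricted log-likelihood (constants dropped) and profiled sigma2_eps."""
    n = y.shape[0]
    w = 1.0 + delta * lam_eig
    log_w = float(np.sum(np.log(w)))
    if X is None or X.size == 0:
        s2 = float(np.mean(y * y / w))
        ll = -0.5 * (log_w + n * np.log(s2) + n)
        return ll, s2
    q = X.shape[1]
    Wi = 1.0 / w
    XtWX = X.T @ (X * Wi[:, None])
    beta = np.linalg.solve(XtWX, X.T @ (Wi * y))
    resid = y - X @ beta
    rss = float(resid @ (Wi * resid))
    s2 = rss / (n - q)
    sign, ld_X = np.linalg.slogdet(XtWX)
    ll = -0.5 * (log_w + ld_X + (n - q) * np.log(s2) + (n - q))
    return ll, s2


def marker_lr_test(H: HeterosisKernel, null: FittedNull, y: np.ndarray,
                   X: np.ndarray | None = None, grid_size: int = 64,
                   delta_bounds: tuple[float, float] = (1e-6, 1e6),
                   ) -> MarkerTest:
    """LR test of H0: sigma2_h = 0 for one marker under the P3D null.

    y, X and the marker kernel are whitened by the frozen V0 factor, the
    whitened kernel is eigendecomposed, and the restricted likelihood is
    profiled over delta = sigma2_h / sigma2_eps (coarse log-grid warm start
    followed by bounded scalar optimization, plus the boundary delta = 0).
    """
    y = np.asarray(y, dtype=float)
    yw = null.whiten_vec(y)
    Xw = null.whiten_vec(np.asarray(X, dtype=float)) if X is not None and np.size(X) else None
    Hw = null.whiten_mat(H.H)
    lam_eig, U = eigh(Hw)
    lam_eig = np.clip(lam_eig, 0.0, None)
    yr = U.T @ yw
    Xr = U.T @ Xw if Xw is not None else None

    ll0, s2_0 = _profile_reml_delta(0.0, lam_eig, yr, Xr)
    lo, hi = delta_bounds
    grid = np.logspace(np.log10(lo), np.log10(hi), grid_size)
    lls = np.array([_profile_reml_delta(d, lam_eig, yr, Xr)[0] for d in grid])
    k = int(np.argmax(lls))
    left = np.log10(grid[max(k - 1, 0)])
    right = np.log10(grid[min(k + 1, grid_size - 1)])
    res = optimize.minimize_scalar(
        lambda t: -_profile_reml_delta(10.0 ** t, lam_eig, yr, Xr)[0],
        bounds=(left, right), method="bounded",
        options={"xatol": 1e-8})
    cand = [(ll0, 0.0)]
    cand.append((float(lls[k]), float(grid[k])))
    cand.append((float(-res.fun), float(10.0 ** res.x)))
    ll1, delta_hat = max(cand, key=lambda t: t[0])
    lr = max(0.0, 2.0 * (ll1 - ll0))
    if lr <= 1e-12:
        lr, delta_hat = 0.0, 0.0
    _, s2_hat = _profile_reml_delta(delta_hat, lam_eig, yr, Xr)
    return MarkerTest(index=H.index, sigma2_h=float(delta_hat * s2_hat),
                      sigma2_eps=float(s2_hat), delta=float(delta_hat),
                      lr=float(lr), pvalue=mixture_pvalue(lr))


# ---------------------------------------------------------------------------
# Wald tests for fixed component effects
# ---------------------------------------------------------------------------

#: fixed-effect layouts for the component models; the focal effect is listed
#: last.  Additive main effects are omitted everywhere because T M_A = 0.
WALD_MODELS = {
    "dominance": {"effect": "d_i", "needs_j": False},
    "aa": {"effect": "aa_ij", "needs_j": True},
    "ad": {"effect": "ad_ij", "needs_j": True},
    "da": {"effect": "ad_ji", "needs_j": True},
    "dd": {"effect": "dd_ij", "needs_j": True},
}


def _component_regressors(model: str, i: int, j: int | None,
                          codings: CodingMatrices, transform: MPHTransform,
                          ) -> tuple[list[np.ndarray], np.ndarray]:
    """Companion and focal regressors (on the MPH scale) for one model."""
    T = transform.T
    M_A, M_D = codings.M_A, codings.M_D
    if model == "dominance":
        return [], np.asarray(T @ M_D[:, i])
    if j is None:
        raise LMMError(f"model {model!r} requires a partner marker j")
    m_i, l_i = M_A[:, i], M_D[:, i]
    m_j, l_j = M_A[:, j], M_D[:, j]
    if model == "aa":
        return [], np.asarray(T @ (m_i * m_j))
    if model == "ad":        # additive of i x dominance of j; companion d_j
        return [np.asarray(T @ l_j)], np.asarray(T @ (m_i * l_j))
    if model == "da":        # dominance of i x additive of j; companion d_i
        return [np.asarray(T @ l_i)], np.asarray(T @ (l_i * m_j))
    if model == "dd":
        return [np.asarray(T @ l_i), np.asarray(T @ l_j)], \
            np.asarray(T @ (l_i * l_j))
    raise LMMError(f"unknown component model {model!r}; "
                   f"choose one of {sorted(WALD_MODELS)}")


def wald_component_test(model: str, i: int, j: int | None,
                        codings: CodingMatrices, transform: MPHTransform,
                        null: FittedNull, y: np.ndarray,
                        X: np.ndarray | None = None) -> WaldResult:
    """Wald test W = x^2 / var(x) for one fixed genetic component effect.

    The focal effect (dominance d_i, or one of the four digenic epistatic
    effects of the pair (i, j)) enters as a fixed regressor together with
    the companion dominance terms its model requires; estimation is
    generalized least squares under the frozen null covariance
    sigma2_eps * V0, and W is referred to chi2 with 1 df.
    """
    if model not in WALD_MODELS:
        raise LMMError(f"unknown component model {model!r}; "
                       f"choose one of {sorted(WALD_MODELS)}")
    companions, focal = _component_regressors(model, i, j, codings, transform)
    if float(np.ptp(focal)) == 0.0:
        raise LMMError(f"focal regressor for {model!r} (i={i}, j={j}) has "
                       "zero variance")
    cols = []
    if X is not None and np.size(X):
        Xa = np.asarray(X, dtype=float)
        cols.extend(Xa.T if Xa.ndim == 2 else [Xa])
    cols.extend(companions)
    cols.append(focal)
    Z = np.column_stack([null.whiten_vec(c) for c in cols])
    yw = null.whiten_vec(np.asarray(y, dtype=float))
    n, q = Z.shape
    ZtZ = Z.T @ Z
    if np.linalg.matrix_rank(ZtZ) < q:
        raise LMMError(f"rank-deficient design for {model!r} (i={i}, j={j}): "
                       "collinear regressors (e.g. identical dominance columns)")
    beta = np.linalg.solve(ZtZ, Z.T @ yw)
    resid = yw - Z @ beta
    s2 = float(resid @ resid) / (n - q)
    cov = s2 * np.linalg.inv(ZtZ)
    est = float(beta[-1])
    var = float(cov[-1, -1])
    W = est * est / var
    return WaldResult(effect=WALD_MODELS[model]["effect"], i=i, j=j,
                      estimate=est, variance=var, statistic=float(W),
                      pvalue=float(stats.chi2.sf(W, df=1)))
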