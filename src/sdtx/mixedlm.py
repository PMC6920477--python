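"""Maximum-likelihood linear mixed models with independent variance components.

The model is

    y = X beta + sum_k Z_k u_k + e,      u_k ~ N(0, sigma_e^2 * gamma_k I),
                                          e  ~ N(0, sigma_e^2 I),

i.e. each random term contributes an iid block of effects with its own
variance ratio gamma_k >= 0.  Random terms may be *crossed* (e.g. subject
intercepts crossed with gene-level time deviations), which is what the
set-level trajectory model requires.

Fitting profiles beta and sigma_e^2 out analytically: for fixed gamma the
GLS estimate and the profiled residual variance are closed-form via the
Woodbury identity (all dense algebra is q x q where q is the total number of
random effects), leaving a 1- or 2-dimensional bounded optimisation over
log gamma.  gamma = 0 is a representable boundary, so a singular fit
degenerates smoothly to OLS with the exact OLS log-likelihood.

Likelihood-ratio tests for nested *fixed-effect* structures compare two fits
of this family by 2*(l1 - l0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

_THETA_LO = -18.0  # gamma = e^-18 ~ 1.5e-8: numerically OLS
_THETA_HI = 12.0


@dataclass
class LMMFit:
    """Result of one maximum-likelihood fit."""

    loglik: float
    beta: np.ndarray
    sigma2: float
    gamma: np.ndarray  # variance ratios sigma_k^2 / sigma_e^2, one per term
    converged: bool
    boundary: bool  # any variance component at (numerical) zero
    n: int

    @property
    def variance_components(self) -> np.ndarray:
        return self.gamma * self.sigma2


class LMMDesign:
    """Fixed + random design with cached cross-products.

    Build once per model structure and reuse across many responses (e.g. the
    same study design fitted gene by gene): only the y-dependent
    cross-products are recomputed per fit.
    """

    def __init__(self, X: np.ndarray, z_list: list[np.ndarray]):
        self.X = np.asarray(X, dtype=float)
        self.n, self.p = self.X.shape
        self.block_sizes = [Z.shape[1] for Z in z_list]
        self.k = len(z_list)
        self.U = (
            np.hstack([np.asarray(Z, dtype=float) for Z in z_list])
            if z_list
            else np.zeros((self.n, 0))
        )
        self.q = self.U.shape[1]
        self.XtX = self.X.T @ self.X
        self.UtU = self.U.T @ self.U
        self.UtX = self.U.T @ self.X
        self._expand = np.repeat(np.arange(self.k), self.block_sizes)


class _Profile:
    """Profiled negative log-likelihood over theta = log(gamma) for one y."""

    def __init__(self, design: LMMDesign, y: np.ndarray):
        self.d = design
        self.n = design.n
        self.Xty = design.X.T @ y
        self.Uty = design.U.T @ y
        self.yty = float(y @ y)

    def _gls(self, gamma: np.ndarray):
        d = self.d
        s = np.sqrt(gamma[d._expand]) if d.q else np.zeros(0)
        M = np.eye(d.q) + (s[:, None] * d.UtU) * s[None, :]
        cf = linalg.cho_factor(M, lower=True, check_finite=False)
        logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        AX = s[:, None] * d.UtX
        Ay = s * self.Uty
        MiAX = linalg.cho_solve(cf, AX, check_finite=False)
        MiAy = linalg.cho_solve(cf, Ay, check_finite=False)
        XtWX = d.XtX - AX.T @ MiAX
        XtWy = self.Xty - AX.T @ MiAy
        ytWy = self.yty - Ay @ MiAy
        beta = linalg.solve(XtWX, XtWy, assume_a="pos", check_finite=False)
        rss = max(ytWy - beta @ XtWy, 1e-300)
        return beta, rss, logdet

    def nll(self, theta: np.ndarray) -> float:
        gamma = np.exp(np.clip(theta, _THETA_LO, _THETA_HI))
        try:
            _, rss, logdet = self._gls(gamma)
        except (linalg.LinAlgError, ValueError):
            return np.inf
        n = self.n
        return 0.5 * (n * np.log(2.0 * np.pi * rss / n) + n + logdet)

    def fit_at(self, theta: np.ndarray) -> LMMFit:
        gamma = np.exp(np.clip(theta, _THETA_LO, _THETA_HI))
        beta, rss, logdet = self._gls(gamma)
        n = self.n
        sigma2 = rss / n
        ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + n + logdet)
        at_lo = theta <= _THETA_LO + 1e-9
        return LMMFit(
            loglik=float(ll),
            beta=beta,
            sigma2=float(sigma2),
            gamma=np.where(at_lo, 0.0, gamma),
            converged=True,
            boundary=bool(np.any(at_lo)),
            n=n,
        )


def fit_lmm_ml(
    y: np.ndarray,
    X: np.ndarray | LMMDesign,
    z_list: list[np.ndarray] | None = None,
    n_starts: int = 3,
) -> LMMFit:
    """Fit the mixed model by ML, profiling over the variance ratios.

    Parameters
    ----------
    y
        Response vector.
    X
        Fixed-effect design (full column rank), or a prebuilt
        :class:`LMMDesign` (in which case ``z_list`` is ignored).
    z_list
        One dense indicator/design matrix per random term; each term gets a
        single iid variance.  Empty list = ordinary least squares.
    """
    y = np.asarray(y, dtype=float)
    design = X if isinstance(X, LMMDesign) else LMMDesign(X, z_list or [])
    if y.ndim != 1 or design.n != y.shape[0]:
        raise ValueError("y must be 1-D and aligned with the design rows")
    prof = _Profile(design, y)
    k = design.k
    if k == 0:
        return prof.fit_at(np.zeros(0))
    if k == 1:
        res = optimize.minimize_scalar(
            lambda t: prof.nll(np.array([t])),
            bounds=(_THETA_LO, _THETA_HI),
            method="bounded",
            options={"xatol": 1e-10},
        )
        best_t = np.array([res.x])
        # the bounded minimiser can miss a boundary optimum; check gamma ~ 0
        if prof.nll(np.array([_THETA_LO])) < prof.nll(best_t):
            best_t = np.array([_THETA_LO])
        fit = prof.fit_at(best_t)
        fit.converged = bool(res.success)
        return fit
    # k >= 2: Nelder-Mead from a few starts on log-gamma
    best = None
    for x0 in (np.zeros(k), np.full(k, -3.0), np.full(k, 2.0))[: max(n_starts, 1)]:
        res = optimize.minimize(
            lambda t: prof.nll(np.asarray(t)),
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-11, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = np.clip(np.asarray(best.x), _THETA_LO, _THETA_HI)
    fit = prof.fit_at(theta)
    fit.converged = bool(best.success) and np.isfinite(fit.loglik)
    return fit


def lrt(fit1: LMMFit, fit0: LMMFit) -> float:
    """Likelihood-ratio statistic 2*(l1 - l0), tiny negatives clipped to 0."""
    stat = 2.0 * (fit1.loglik - fit0.loglik)
    if stat < -1e-6:
        # a genuinely negative statistic would mean the models are not nested
        # or the optimiser failed; refuse to silently clip large negatives
        raise RuntimeError(f"non-nested LRT: statistic {stat:.3g} < 0")
    return max(stat, 0.0)


def indicator(labels: np.ndarray) -> np.ndarray:
    """Dense one-hot design for a label vector (columns in first-seen order)."""
    labels = np.asarray(labels)
    _, inv = np.unique(labels, return_inverse=True)
    Z = np.zeros((labels.shape[0], inv.max() + 1))
    Z[np.arange(labels.shape[0]), inv] = 1.0
    return Z
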