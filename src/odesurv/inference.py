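"""Posterior computation: MAP, Hessian, normal approximation, Laplace
marginal likelihood, adaptive Metropolis MCMC, and information criteria.

The posterior of a regular ODE hazard regression is asymptotically normal
(a Bernstein-von Mises argument), so a cheap and often sufficient
approximation is N(eta_map, H^{-1}) with H the negative Hessian of the log
posterior at the MAP.  All derivatives are taken by central finite
differences: the batched fixed-step likelihood is an exactly smooth
function of the parameters, so finite differences are clean and avoid
differentiating through an adaptive solver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import optimize

__all__ = [
    "MapFit",
    "NormalApprox",
    "McmcSample",
    "find_map",
    "hessian_at",
    "normal_approx",
    "normal_approx_sample",
    "laplace_log_marginal",
    "adaptive_metropolis",
    "aic_bic",
]


@dataclass
class MapFit:
    """Result of a MAP optimisation."""

    eta: np.ndarray
    logpost: float
    converged: bool
    n_iter: int = 0
    nfev: int = 0
    message: str = ""


@dataclass
class NormalApprox:
    """Normal approximation N(mean, cov) to the posterior."""

    mean: np.ndarray
    cov: np.ndarray
    repaired: bool = False

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise ValueError("covariance shape does not match mean")


@dataclass
class McmcSample:
    """Post-burn-in, thinned MCMC draws."""

    draws: np.ndarray
    acceptance_rate: float
    seed: int
    settings: dict = field(default_factory=dict)


def find_map(
    logpost: Callable[[np.ndarray], float],
    eta_init,
    bounds=None,
    maxiter: int = 300,
    gtol: float = 0.02,
    seed: int = 0,
    precondition: str = "auto",
) -> MapFit:
    """Maximise a log-posterior: quasi-Newton polish with a derivative-free
    rescue for cold starts.

    The primary pass is L-BFGS-B with finite-difference gradients.  ODE
    hazard posteriors have narrow curved basins in which a cold-started
    line search can stall, so when the quasi-Newton pass fails to converge
    (and ``precondition`` is 'auto' or 'always'), a Powell search is run
    from the best point found and the result polished again.  Parameters
    are box-bounded (default +-15 on each coordinate) to keep the ODE
    solves finite; infeasible points contribute a smooth coercive penalty
    rather than an infinite cliff.  A hopeless start (no finite
    log-posterior after jittering) returns a non-converged fit rather than
    raising.
    """
    eta_init = np.asarray(eta_init, dtype=float)
    d = eta_init.size
    if bounds is None:
        bounds = [(-15.0, 15.0)] * d
    rng = np.random.default_rng(seed)

    def neg(x):
        v = logpost(x)
        return -v if np.isfinite(v) else 1e8 * (1.0 + float(np.sum(x * x)))

    x0 = np.clip(eta_init, [b[0] for b in bounds], [b[1] for b in bounds])
    if not np.isfinite(logpost(x0)):
        for _ in range(8):
            trial = x0 + 0.5 * rng.standard_normal(d)
            if np.isfinite(logpost(trial)):
                x0 = trial
                break
        else:
            return MapFit(eta=eta_init, logpost=-np.inf, converged=False,
                          message="no finite start found")

    def grad(x, h0=1e-5):
        # central differences: forward 2-point gradients are biased enough
        # to stall the line search in the posterior's curved valleys
        g = np.empty(d)
        for i in range(d):
            e = np.zeros(d)
            e[i] = h0 * max(1.0, abs(x[i]))
            g[i] = (neg(x + e) - neg(x - e)) / (2.0 * e[i])
        return g

    def polish(x):
        # cheap forward-difference pass first; fall back to the costlier
        # central-difference gradient only when its line search stalls
        res = optimize.minimize(
            neg, x, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-11, "eps": 1e-5},
        )
        if res.success:
            return res
        res2 = optimize.minimize(
            neg, res.x if res.fun < neg(x) else x, jac=grad, method="L-BFGS-B",
            bounds=bounds, options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-11},
        )
        return res2 if res2.fun <= res.fun else res

    nfev = 0
    res = None
    if precondition != "always":
        res = polish(x0)
        nfev += res.nfev
    if precondition != "never" and (res is None or not res.success):
        start = res.x if res is not None and res.fun < neg(x0) else x0
        pre = optimize.minimize(
            neg, start, method="Powell",
            options={"maxfev": 150 * d, "xtol": 1e-2, "ftol": 1e-8},
        )
        nfev += pre.nfev
        res2 = polish(pre.x)
        nfev += res2.nfev
        if res is None or res2.fun <= res.fun:
            res = res2
    return MapFit(
        eta=res.x, logpost=-float(res.fun),
        converged=bool(res.success) and res.fun < 1e7,
        n_iter=int(res.nit), nfev=nfev, message=str(res.message),
    )


def hessian_at(
    f: Callable[[np.ndarray], float], x, step=1e-4, relative: bool = True,
) -> np.ndarray:
    """Central finite-difference Hessian of a scalar function, symmetrised.

    ``step`` may be a scalar (steps ``step * max(1, |x_i|)`` when
    ``relative``, else constant) or a per-coordinate array of absolute
    steps.  Diagonal entries use the 3-point second difference,
    off-diagonals the 4-point cross difference; both are exact for
    quadratics up to roundoff.
    """
    x = np.asarray(x, dtype=float)
    d = x.size
    if np.ndim(step) > 0:
        hs = np.asarray(step, dtype=float)
    elif relative:
        hs = step * np.maximum(1.0, np.abs(x))
    else:
        hs = np.full(d, float(step))
    f0 = f(x)
    H = np.empty((d, d))
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = hs[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / hs[i] ** 2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = hs[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * hs[i] * hs[j])
    return 0.5 * (H + H.T)


def _spd_inverse(neg_hessian: np.ndarray, what: str = "negative Hessian"):
    """Inverse of an (almost) SPD matrix, with a narrow nearest-SPD repair.

    Eigenvalues below zero are tolerated (clipped) only when the minimum
    eigenvalue exceeds -1e-6 times the maximum; anything worse raises.
    Returns (inverse, repaired_flag).
    """
    A = 0.5 * (neg_hessian + neg_hessian.T)
    w, V = np.linalg.eigh(A)
    if w[-1] <= 0:
        raise np.linalg.LinAlgError(f"{what} is not positive definite")
    repaired = False
    if w[0] <= 0:
        if w[0] < -1e-6 * w[-1]:
            raise np.linalg.LinAlgError(
                f"{what} indefinite (min eig {w[0]:.3e} vs max {w[-1]:.3e})"
            )
        warnings.warn(f"{what} repaired to nearest SPD (tiny negative eigenvalues)", stacklevel=2)
        w = np.maximum(w, 1e-12 * w[-1])
        repaired = True
    inv = (V / w) @ V.T
    return 0.5 * (inv + inv.T), repaired


def normal_approx(map_fit: MapFit, hessian_logpost: np.ndarray) -> NormalApprox:
    """Normal approximation from a MAP fit and the log-posterior Hessian."""
    cov, repaired = _spd_inverse(-hessian_logpost)
    return NormalApprox(mean=map_fit.eta, cov=cov, repaired=repaired)


def normal_approx_sample(approx: NormalApprox, n_draws: int, seed: int) -> np.ndarray:
    """iid draws from N(mean, cov) via Cholesky; bit-reproducible per seed."""
    d = approx.mean.size
    if n_draws == 0:
        return np.empty((0, d))
    w = np.linalg.eigvalsh(0.5 * (approx.cov + approx.cov.T))
    if w[0] <= 0:
        raise np.linalg.LinAlgError("covariance is not positive definite")
    L = np.linalg.cholesky(approx.cov)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, d))
    return approx.mean + z @ L.T


def laplace_log_marginal(map_fit: MapFit, hessian_logpost: np.ndarray) -> float:
    """Laplace approximation of the log marginal likelihood.

    log p^ = logpost(eta~) + (d/2) log 2pi - 1/2 log det(-Hessian).
    Exact when likelihood x prior is Gaussian in eta.  A non-SPD curvature
    matrix returns -inf (model vetoed) with a warning.
    """
    if not map_fit.converged or not np.isfinite(map_fit.logpost):
        warnings.warn("Laplace marginal requested for a non-converged MAP", stacklevel=2)
        return -np.inf
    A = -0.5 * (hessian_logpost + hessian_logpost.T)
    w = np.linalg.eigvalsh(A)
    if w[0] <= 0:
        warnings.warn("negative curvature at MAP; Laplace marginal set to -inf", stacklevel=2)
        return -np.inf
    d = map_fit.eta.size
    return float(map_fit.logpost + 0.5 * d * np.log(2.0 * np.pi) - 0.5 * np.sum(np.log(w)))


def adaptive_metropolis(
    logpost: Callable[[np.ndarray], float],
    eta_init,
    n_iter: int = 55000,
    burn_in: int = 5000,
    thin: int = 50,
    seed: int = 0,
    cov0: np.ndarray | None = None,
    adapt_start: int = 200,
    eps: float = 1e-10,
) -> McmcSample:
    """Haario-style adaptive random-walk Metropolis.

    The proposal covariance is ``(2.38^2/d) * (running empirical posterior
    covariance + eps I)`` with the running covariance updated recursively
    over the whole history — a diminishing adaptation, preserving
    ergodicity.  Before ``adapt_start`` accepted moves, a fixed initial
    covariance is used.
    """
    x = np.asarray(eta_init, dtype=float).copy()
    d = x.size
    lp = logpost(x)
    if not np.isfinite(lp):
        raise ValueError("log posterior must be finite at the MCMC start")
    rng = np.random.default_rng(seed)
    sd = 2.38 ** 2 / d
    C0 = cov0 if cov0 is not None else np.diag((0.1 * np.maximum(1.0, np.abs(x))) ** 2) / d
    mean = x.copy()
    M2 = np.zeros((d, d))  # sum of outer products of deviations
    n_acc = 0
    bad_streak = 0
    keep = []
    for it in range(1, n_iter + 1):
        if it > adapt_start:
            C = sd * (M2 / (it - 1) + eps * np.eye(d))
        else:
            C = C0
        try:
            prop = x + rng.multivariate_normal(np.zeros(d), C, method="cholesky")
        except np.linalg.LinAlgError:
            prop = x + rng.multivariate_normal(np.zeros(d), C0)
        lp_prop = logpost(prop)
        if np.isnan(lp_prop):
            bad_streak += 1
            if bad_streak > 1000:
                raise RuntimeError("NaN log-posterior streak in adaptive Metropolis")
            lp_prop = -np.inf
        else:
            bad_streak = 0
        if np.log(rng.uniform()) < lp_prop - lp:
            x, lp = prop, lp_prop
            n_acc += 1
        # recursive running mean / scatter over the chain history
        delta = x - mean
        mean += delta / it
        M2 += np.outer(delta, x - mean)
        if it > burn_in and (it - burn_in) % thin == 0:
            keep.append(x.copy())
    draws = np.asarray(keep)
    acc = n_acc / n_iter
    if acc == 0.0:
        raise RuntimeError("adaptive Metropolis accepted no moves")
    return McmcSample(
        draws=draws, acceptance_rate=acc, seed=seed,
        settings={"n_iter": n_iter, "burn_in": burn_in, "thin": thin,
                  "adapt_start": adapt_start},
    )


def aic_bic(loglik_at_point: float, k_params: int, n: int) -> tuple:
    """AIC = 2k - 2l and BIC = k log n - 2l at the maximised log-likelihood."""
    if n < 1 or k_params < 1:
        raise ValueError("need n >= 1 and k >= 1")
    return (
        2.0 * k_params - 2.0 * loglik_at_point,
        k_params * np.log(n) - 2.0 * loglik_at_point,
    )
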