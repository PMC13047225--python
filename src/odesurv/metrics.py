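"""Evaluation metrics: replication summaries, hazard distances, TV
distances between posterior samples, predictive bands, Kaplan-Meier, and
attractor posterior probabilities."""

from __future__ import annotations

from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .mapping import PredictorSpec, individual_parameters
from .solver import hazard_curve
from .systems import HazardResponseParams, classify_attractor

__all__ = [
    "simulation_summary",
    "restricted_l1",
    "tv_distance_marginal",
    "predictive_curves",
    "kaplan_meier",
    "attractor_posterior_probs",
]


def simulation_summary(maps, lowers, uppers, truth, names=None) -> pd.DataFrame:
    """Per-parameter summary of a replicated simulation.

    maps, lowers, uppers : (M, d) arrays of MAP estimates and 95% interval
        endpoints across M replicates.
    truth : length-d true parameter vector.

    Returns a table with mean/median/SE/RMSE of the MAPs, mean interval
    width, and empirical coverage.
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    lowers = np.atleast_2d(np.asarray(lowers, dtype=float))
    uppers = np.atleast_2d(np.asarray(uppers, dtype=float))
    truth = np.asarray(truth, dtype=float)
    if maps.shape[0] < 2:
        raise ValueError("need at least 2 replicates")
    cover = (lowers <= truth) & (truth <= uppers)
    out = pd.DataFrame(
        {
            "truth": truth,
            "mean": maps.mean(axis=0),
            "median": np.median(maps, axis=0),
            "se": maps.std(axis=0, ddof=1),
            "rmse": np.sqrt(np.mean((maps - truth) ** 2, axis=0)),
            "width": (uppers - lowers).mean(axis=0),
            "coverage": cover.mean(axis=0),
        },
        index=list(names) if names is not None else range(truth.size),
    )
    return out


def restricted_l1(h_a: Callable, h_b: Callable, t_star: float) -> float:
    """Restricted L1 distance between hazard curves: int_0^{t*} |h_a - h_b| dt.

    Curves are callables accepting a float (or array) time; the integral is
    evaluated by adaptive quadrature with a generous subdivision limit to
    cope with the kinks of the absolute difference.
    """
    if t_star <= 0:
        raise ValueError("t_star must be positive")
    val, _ = integrate.quad(
        lambda t: abs(float(h_a(t)) - float(h_b(t))), 0.0, t_star, limit=200,
    )
    return float(val)


def tv_distance_marginal(draws_a, draws_b, n_grid: int = 4001) -> np.ndarray:
    """Total-variation distance between marginal posterior samples.

    Gaussian kernel density estimates with Silverman bandwidths are
    compared coordinate-wise: TV = 0.5 * int |kde_a - kde_b|, integrated
    on a fine regular grid (trapezoid) spanning both samples plus five
    bandwidths on each side.  Returns one value in [0, 1] per coordinate.
    """
    a = np.atleast_2d(np.asarray(draws_a, dtype=float).T).T
    b = np.atleast_2d(np.asarray(draws_b, dtype=float).T).T
    if a.shape[0] < 100 or b.shape[0] < 100:
        raise ValueError("need at least 100 draws per sample")
    if a.shape[1] != b.shape[1]:
        raise ValueError("samples must share dimensionality")
    out = np.empty(a.shape[1])
    for j in range(a.shape[1]):
        xa, xb = a[:, j], b[:, j]
        if xa.std() == 0 or xb.std() == 0:
            raise ValueError(f"degenerate (zero-variance) sample in coordinate {j}")
        ka = stats.gaussian_kde(xa, bw_method="silverman")
        kb = stats.gaussian_kde(xb, bw_method="silverman")
        bw = max(ka.factor * xa.std(), kb.factor * xb.std())
        lo = min(xa.min(), xb.min()) - 5 * bw
        hi = max(xa.max(), xb.max()) + 5 * bw
        grid = np.linspace(lo, hi, n_grid)
        diff = np.abs(ka(grid) - kb(grid))
        out[j] = min(0.5 * np.trapezoid(diff, grid), 1.0)
    return out


def predictive_curves(
    draws,
    spec: PredictorSpec,
    profile: Mapping[str, float],
    t_grid,
    quantiles=(0.025, 0.975),
    max_draws: int | None = 200,
    seed: int = 0,
) -> dict:
    """Pointwise posterior bands of hazard and survival for one profile.

    ``draws`` is an (n_draws, d) matrix of eta draws (a single eta row
    gives collapsed, plug-in bands).  Failed trajectory solves are dropped
    with a count.
    """
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    if max_draws is not None and draws.shape[0] > max_draws:
        idx = np.random.default_rng(seed).choice(draws.shape[0], max_draws, replace=False)
        draws = draws[idx]
    X = pd.DataFrame([profile])
    t_grid = np.asarray(t_grid, dtype=float)
    hs, Ss = [], []
    n_failed = 0
    for eta in draws:
        try:
            theta = individual_parameters(eta, spec, X)[0]
            curve = hazard_curve(spec.system, theta, t_grid, fixed=spec.fixed_constants(eta))
        except (RuntimeError, FloatingPointError):
            n_failed += 1
            continue
        hs.append(curve["h"])
        Ss.append(curve["S"])
    if not hs:
        raise RuntimeError("all trajectory solves failed")
    hs = np.asarray(hs)
    Ss = np.asarray(Ss)
    lo, hi = quantiles
    return {
        "t": t_grid,
        "hazard_mean": hs.mean(axis=0),
        "hazard_lo": np.quantile(hs, lo, axis=0),
        "hazard_hi": np.quantile(hs, hi, axis=0),
        "survival_mean": Ss.mean(axis=0),
        "survival_lo": np.quantile(Ss, lo, axis=0),
        "survival_hi": np.quantile(Ss, hi, axis=0),
        "n_failed": n_failed,
        "n_used": hs.shape[0],
    }


def kaplan_meier(t, delta) -> pd.DataFrame:
    """Product-limit survival estimate; columns ``time`` and ``survival``.

    The first row is (0, 1); subsequent rows give the post-jump value at
    each distinct event time.
    """
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(np.asarray(t, dtype=float), event_observed=np.asarray(delta, dtype=int))
    sf = km.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy()})


def attractor_posterior_probs(
    draws, spec: PredictorSpec, profile: Mapping[str, float]
) -> dict:
    """Posterior probability of each hazard-response regime for a profile.

    Each posterior draw of eta is mapped to the profile's ODE parameters
    and classified; returns regime frequencies (summing to 1, with
    degenerate draws counted separately).
    """
    if spec.system.name != "hazard_response":
        raise ValueError("attractor probabilities apply to the hazard-response system")
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    X = pd.DataFrame([profile])
    counts = {"hazard_wins": 0, "response_wins": 0, "coexistence": 0, "degenerate": 0}
    for eta in draws:
        theta = individual_parameters(eta, spec, X)[0]
        fixed = spec.fixed_constants(eta)
        p = HazardResponseParams(lam=theta[0], kappa=theta[1], alpha=theta[2], mu=theta[3],
                                 h0=fixed["h0"], q0=fixed["q0"])
        counts[classify_attractor(p).regime] += 1
    total = draws.shape[0]
    return {k: v / total for k, v in counts.items()}
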