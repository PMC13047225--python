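"""Bayesian variable selection over inclusion patterns gamma.

The model space is explored by a Gibbs sampler on the binary inclusion
indicators: in a fixed scan order, each indicator gamma_{k,j} is redrawn
from its Bernoulli full conditional, whose log-odds are the difference of
Laplace-approximated log marginal likelihoods (plus the complexity-prior
term) between the two models that differ only in that entry.  Every model
evaluation is a MAP optimisation plus a finite-difference Hessian, so
visited models are cached by their canonical bit-string key and candidate
optimisations are warm-started from the full model's MAP (the "anchor",
restricted to the candidate's parameter space) and run in whitened
coordinates — the cost controls that make the sampler desk-scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import MapFit, find_map, hessian_at, laplace_log_marginal
from .likelihood import (
    PriorSpec,
    SurvivalDataset,
    complexity_log_prior,
    log_likelihood,
    log_prior,
)
from .mapping import InclusionPattern, PredictorSpec, embed_eta, restrict_eta

__all__ = ["ModelCache", "SelectionResult", "evaluate_model", "gibbs_sweep", "run_selection"]


@dataclass
class ModelCache:
    """Memo of evaluated models keyed by the canonical gamma bit string."""

    entries: dict = field(default_factory=dict)
    hits: int = 0
    misses: int = 0

    def get(self, key: str):
        if key in self.entries:
            self.hits += 1
            return self.entries[key]
        self.misses += 1
        return None

    def put(self, key: str, value) -> None:
        self.entries[key] = value


@dataclass
class SelectionResult:
    """Visited-model table, inclusion probabilities, and chosen models."""

    table: pd.DataFrame
    inclusion_probs: pd.DataFrame
    top_model: InclusionPattern
    median_model: InclusionPattern
    trace: np.ndarray
    cache: ModelCache
    anchor: np.ndarray | None = None


def _active_indices(gamma: InclusionPattern) -> np.ndarray:
    """Full-space coordinate index of each active-model coordinate."""
    return restrict_eta(
        np.arange(gamma.spec.n_eta, dtype=float), gamma.spec, gamma
    ).astype(int)


def _newton_polish_z(logpost_z, z0, d, gtol=0.05, max_steps=10):
    """Damped Newton ascent in whitened coordinates.

    Whitening makes the curvature O(1) in every direction, so Newton steps
    computed from one finite-difference Hessian (refreshed after large
    moves) converge in a handful of iterations without the line-search
    pathologies a generic quasi-Newton method exhibits here.  Converging
    properly matters beyond speed: a stop short of the optimum can leave a
    spuriously tiny curvature eigenvalue that inflates the Laplace log
    determinant by several units — enough to flip a model-choice decision.
    Returns ``(z, logpost, Hz, converged)``; ``Hz`` is None when no usable
    (SPD-ish) curvature was found.
    """
    z = np.asarray(z0, dtype=float).copy()
    f = logpost_z(z)
    if not np.isfinite(f):
        return z, f, None, False

    def grad(z):
        g = np.empty(d)
        h = 1e-3
        for i in range(d):
            e = np.zeros(d)
            e[i] = h
            g[i] = (logpost_z(z + e) - logpost_z(z - e)) / (2 * h)
        return g

    def curvature(z):
        # FD step 0.05 sd: whitened curvature is O(1), so smaller steps put
        # the second-difference numerator at the roundoff floor of |f|~1e3
        Hz = hessian_at(logpost_z, z, step=0.05, relative=False)
        w, V = np.linalg.eigh(-0.5 * (Hz + Hz.T))
        return Hz, w, V

    Hz, w, V = curvature(z)
    if not np.isfinite(w).all():
        return z, f, None, False
    moved_since_H = 0.0
    g = grad(z)
    converged = False
    for _ in range(max_steps):
        if np.max(np.abs(g)) < gtol:
            converged = True
            break
        if moved_since_H > 2.0:  # stale curvature after a long move
            Hz, w, V = curvature(z)
            if not np.isfinite(w).all():
                return z, f, None, False
            moved_since_H = 0.0
        dz = V @ ((V.T @ g) / np.maximum(w, 1e-2))
        norm = float(np.linalg.norm(dz))
        if norm > 20.0:  # trust region: huge proposed moves get shortened
            dz *= 20.0 / norm
            norm = 20.0
        scale = 1.0
        for _ in range(10):  # backtracking safeguard
            f_new = logpost_z(z + scale * dz)
            if np.isfinite(f_new) and f_new >= f - 1e-9:
                break
            scale *= 0.5
        else:
            break
        z = z + scale * dz
        moved_since_H += scale * norm
        f = f_new
        g = grad(z)
    if moved_since_H > 0.25:  # refresh curvature for the Laplace determinant
        Hz, w, V = curvature(z)
    return z, f, Hz, converged


def evaluate_model(
    gamma: InclusionPattern,
    data: SurvivalDataset,
    prior: PriorSpec,
    cache: ModelCache | None = None,
    warm_eta_full=None,
    hessian_step: float = 1e-4,
    seed: int = 0,
    precond_cov=None,
    rescue: bool = True,
    **solver_opts,
):
    """Laplace log marginal likelihood of the model gamma.

    Returns ``(log_marginal, eta_map_full)`` with the MAP embedded in the
    full parameter space (zeros on inactive coefficients) for warm starts.
    ``precond_cov`` (a full-space covariance, typically the anchor model's
    inverse Hessian) whitens the warm-started optimisation: the posterior
    is strongly ill-conditioned in the raw coordinates, and quasi-Newton
    iterations in whitened coordinates converge an order of magnitude
    faster.
    """
    key = gamma.key()
    if cache is not None:
        hit = cache.get(key)
        if hit is not None:
            return hit
    spec_a = gamma.active_spec()

    def logpost(eta):
        ll = log_likelihood(eta, spec_a, data, **solver_opts)
        if not np.isfinite(ll):
            return -np.inf
        return ll + log_prior(eta, spec_a, prior, data)

    if warm_eta_full is not None:
        start = restrict_eta(warm_eta_full, gamma.spec, gamma)
        precondition = "never"
    else:
        start = np.zeros(spec_a.n_eta)
        precondition = "always"

    def laplace_of(fit):
        if not fit.converged:
            return -np.inf
        try:
            H = hessian_at(logpost, fit.eta, step=hessian_step)
            return laplace_log_marginal(fit, H)
        except np.linalg.LinAlgError:
            return -np.inf

    fit = None
    log_marg = -np.inf
    if warm_eta_full is not None and precond_cov is not None:
        idx = _active_indices(gamma)
        sub = np.asarray(precond_cov)[np.ix_(idx, idx)]
        try:
            W = np.linalg.cholesky(0.5 * (sub + sub.T)
                                   + 1e-10 * np.eye(idx.size))
        except np.linalg.LinAlgError:
            W = None
        if W is not None:
            logpost_z = lambda z: logpost(start + W @ z)
            z, lp_z, Hz, newton_ok = _newton_polish_z(
                logpost_z, np.zeros(idx.size), idx.size)
            if not newton_ok:
                # Newton stalled (nonconvex stretch): quasi-Newton pass,
                # then re-polish so the stop is a usable optimum
                fit_z = find_map(
                    logpost_z, z if np.isfinite(lp_z) else np.zeros(idx.size),
                    bounds=[(-50.0, 50.0)] * idx.size, seed=seed,
                    precondition="never", maxiter=150,
                )
                z, lp_z, Hz, newton_ok = _newton_polish_z(
                    logpost_z, fit_z.eta, idx.size)
            fit = MapFit(eta=start + W @ z, logpost=lp_z, converged=newton_ok)
            if newton_ok and Hz is not None:
                # Laplace determinant from the whitened curvature:
                # det(-H_eta) = det(-H_z)/det(W)^2.  Directions where the
                # anchor geometry disagrees with the submodel produce
                # unreliable tiny eigenvalues; flooring them at 0.05 (the
                # posterior sd capped at ~4.5x the anchor's marginal sd)
                # keeps the determinant bounded and, because every model
                # shares the same W construction, comparable across models.
                wz = np.linalg.eigvalsh(-0.5 * (Hz + Hz.T))
                if np.isfinite(wz).all():
                    wz = np.maximum(wz, 0.05)
                    log_marg = (lp_z + 0.5 * idx.size * np.log(2 * np.pi)
                                - 0.5 * float(np.sum(np.log(wz)))
                                + float(np.sum(np.log(np.diag(W)))))
    if fit is None:
        fit = find_map(logpost, start, seed=seed, precondition=precondition,
                       maxiter=150)
    if not np.isfinite(log_marg):
        log_marg = laplace_of(fit)
    if not np.isfinite(log_marg) and precondition == "never" and rescue:
        # warm start stalled at a saddle or bad basin.  A saddle is escaped
        # cheaply by jittering and re-polishing (gradient ascent then flows
        # to an adjacent maximum).  Accept a rescue whenever it yields
        # usable curvature at a comparable posterior value (a saddle's
        # nominally higher value is not a usable optimum).
        rng = np.random.default_rng(seed + 1)
        for scale in (0.02, 0.1):
            jitter = start + scale * rng.standard_normal(start.size)
            fit2 = find_map(logpost, jitter, seed=seed, precondition="never",
                            maxiter=80)
            lm2 = laplace_of(fit2)
            if np.isfinite(lm2) and fit2.logpost > fit.logpost - 5.0:
                fit, log_marg = fit2, lm2
                break
    if not np.isfinite(log_marg):
        warnings.warn(f"Laplace marginal failed for model {key}; set to -inf", stacklevel=2)
    eta_full = embed_eta(fit.eta, gamma.spec, gamma)
    value = (log_marg, eta_full)
    if cache is not None:
        cache.put(key, value)
    return value


def _anchor_preconditioner(anchor, spec, data, prior, precond_cov=None, **solver_opts):
    """Whitening covariance from the full model's curvature at the anchor.

    Eigenvalues of the negative Hessian are clipped positive, so the
    result is always SPD; it only has to capture the scale structure, not
    be an exact covariance.  Returns None when the anchor is infeasible.
    """
    if precond_cov is not None:
        return precond_cov
    spec_f = InclusionPattern.all_ones(spec).active_spec()

    def logpost(eta):
        ll = log_likelihood(eta, spec_f, data, **solver_opts)
        if not np.isfinite(ll):
            return -np.inf
        return ll + log_prior(eta, spec_f, prior, data)

    if not np.isfinite(logpost(anchor)):
        return None
    try:
        H = hessian_at(logpost, anchor, step=1e-4)
        w, V = np.linalg.eigh(-0.5 * (H + H.T))
    except np.linalg.LinAlgError:
        return None
    if not np.isfinite(w).all() or w[-1] <= 0:
        return None
    w = np.maximum(w, 1e-6 * w[-1])
    cov = (V / w) @ V.T
    return 0.5 * (cov + cov.T)


def gibbs_sweep(
    gamma: InclusionPattern,
    data: SurvivalDataset,
    prior: PriorSpec,
    cache: ModelCache,
    rng: np.random.Generator,
    d_tilde: int,
    **solver_opts,
) -> InclusionPattern:
    """One full-conditional sweep over all inclusion indicators.

    For each (parameter, covariate) in fixed scan order, gamma_{k,j} is
    drawn Bernoulli with log-odds = [log p^(data|g1) + log pi(g1)] -
    [log p^(data|g0) + log pi(g0)].
    """
    C = prior.complexity_C
    anchor = solver_opts.pop("anchor", None)
    if anchor is None:
        _, anchor = evaluate_model(gamma, data, prior, cache, **solver_opts)
    for k, j, _col in gamma.entries():
        g1 = gamma if gamma.gamma[k][j] == 1 else gamma.flip(k, j)
        g0 = gamma if gamma.gamma[k][j] == 0 else gamma.flip(k, j)
        m1, eta1 = evaluate_model(g1, data, prior, cache, warm_eta_full=anchor, **solver_opts)
        m0, eta0 = evaluate_model(g0, data, prior, cache, warm_eta_full=anchor, **solver_opts)
        l1 = m1 + complexity_log_prior(g1, d_tilde, C)
        l0 = m0 + complexity_log_prior(g0, d_tilde, C)
        if not np.isfinite(l1) and not np.isfinite(l0):
            continue  # both vetoed: keep current entry
        # p(gamma_{k,j}=1 | rest) via a stable sigmoid of the log odds
        if not np.isfinite(l1):
            take_one = False
        elif not np.isfinite(l0):
            take_one = True
        else:
            p1 = 1.0 / (1.0 + np.exp(np.clip(l0 - l1, -700, 700)))
            take_one = rng.uniform() < p1
        gamma = g1 if take_one else g0
    return gamma


def run_selection(
    data: SurvivalDataset,
    spec: PredictorSpec,
    prior: PriorSpec,
    n_iter: int = 1100,
    burn_in: int = 100,
    seed: int = 0,
    init: InclusionPattern | None = None,
    cache: ModelCache | None = None,
    anchor=None,
    **solver_opts,
) -> SelectionResult:
    """Gibbs exploration of the model space.

    Starts from the intercept-only model by default; ``n_iter`` counts
    full sweeps, the first ``burn_in`` of which are discarded.  Posterior
    model probabilities are estimated by visit frequencies; per-variable
    inclusion probabilities are post-burn-in means of the indicators.  The
    median-probability model keeps the variables with inclusion
    probability > 0.5.
    """
    rng = np.random.default_rng(seed)
    rescue = solver_opts.pop("rescue", True)
    gamma = init if init is not None else InclusionPattern.all_zeros(spec)
    cache = cache if cache is not None else ModelCache()
    d_tilde = spec.n_eta
    entry_names = [f"{k}:{c}" for k, _j, c in gamma.entries()]
    # anchor: the full model's MAP (cold, derivative-free preconditioned),
    # embedded in the full space; warm-starts every candidate optimisation
    # in the data-supported basin.  A caller running several related
    # selections may pass a previous anchor as the warm start; the full
    # model is still refitted on this dataset so the whitening geometry
    # matches its curvature.  Only the fit is needed here — the full
    # model's marginal is computed lazily if the chain ever visits it.
    spec_full = InclusionPattern.all_ones(spec).active_spec()

    def _logpost_full(eta):
        ll = log_likelihood(eta, spec_full, data, **solver_opts)
        if not np.isfinite(ll):
            return -np.inf
        return ll + log_prior(eta, spec_full, prior, data)

    if anchor is not None:
        fit_a = find_map(_logpost_full, np.asarray(anchor, dtype=float),
                         seed=seed, precondition="never", maxiter=150)
    else:
        fit_a = find_map(_logpost_full, np.zeros(spec_full.n_eta), seed=seed,
                         precondition="always")
    anchor = fit_a.eta
    solver_opts["precond_cov"] = _anchor_preconditioner(
        anchor, spec, data, prior, **solver_opts
    )
    trace = []
    visits: dict[str, int] = {}
    for it in range(n_iter):
        gamma = gibbs_sweep(gamma, data, prior, cache, rng, d_tilde,
                            anchor=anchor, rescue=rescue, **solver_opts)
        if it >= burn_in:
            bits = np.array([gamma.gamma[k][j] for k, j, _ in gamma.entries()], dtype=int)
            trace.append(bits)
            visits[gamma.key()] = visits.get(gamma.key(), 0) + 1
    trace = np.asarray(trace)
    kept = trace.shape[0]
    pip = trace.mean(axis=0)
    inclusion = pd.DataFrame({"variable": entry_names, "inclusion_prob": pip})
    rows = []
    for key, count in visits.items():
        lm = cache.entries.get(key, (np.nan, None))[0]
        size = sum(int(b) for b in key)
        rows.append({
            "model": key, "visits": count, "visit_freq": count / kept,
            "log_marginal": lm,
            "log_prior": complexity_log_prior(size, d_tilde, prior.complexity_C),
            "size": size,
        })
    table = pd.DataFrame(rows).sort_values("visits", ascending=False).reset_index(drop=True)
    top_key = table.loc[0, "model"]
    top_model = _pattern_from_key(spec, top_key)
    med_bits = (pip > 0.5).astype(int)
    median_model = _pattern_from_bits(spec, med_bits)
    return SelectionResult(
        table=table, inclusion_probs=inclusion, top_model=top_model,
        median_model=median_model, trace=trace, cache=cache, anchor=anchor,
    )


def _pattern_from_bits(spec: PredictorSpec, bits) -> InclusionPattern:
    bits = list(int(b) for b in bits)
    g = {}
    pos = 0
    for k in spec.system.parameter_names:
        w = len(spec.covariates[k])
        g[k] = np.array(bits[pos : pos + w], dtype=int)
        pos += w
    return InclusionPattern(spec, g)


def _pattern_from_key(spec: PredictorSpec, key: str) -> InclusionPattern:
    return _pattern_from_bits(spec, [int(ch) for ch in key])
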