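"""Model / Results objects for ODE hazard regression.

`OdeHazardRegression` bundles a right-censored dataset, a predictor
specification (which covariates drive which ODE parameter, through which
link) and a prior; ``fit()`` computes the MAP, the finite-difference
Hessian and the normal (Bernstein-von Mises) posterior approximation, and
returns an `OdeHazardResults` carrying estimates, uncertainties and the
usual conveniences (``summary()``, credible intervals, posterior sampling,
predictive curves, attractor reports, AIC/BIC, MCMC).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import systems as _systems
from .inference import (
    MapFit,
    NormalApprox,
    adaptive_metropolis,
    aic_bic,
    find_map,
    hessian_at,
    normal_approx,
    normal_approx_sample,
)
from .likelihood import PriorSpec, SurvivalDataset, log_likelihood, log_posterior
from .mapping import PredictorSpec, individual_parameters
from .solver import DEFAULT_STEP, hazard_curve

__all__ = ["OdeHazardRegression", "OdeHazardResults"]


class OdeHazardRegression:
    """Hazard-based distributional survival regression via an ODE system.

    Parameters
    ----------
    data : SurvivalDataset (or anything `SurvivalDataset.from_dataframe`
        accepts via :meth:`from_formulas`).
    spec : PredictorSpec mapping covariates to ODE parameters.
    priors : PriorSpec; defaults to weakly informative N(0, 10) normals.
    solver : dict of ensemble-solver options (method, step, rtol, atol).
    """

    def __init__(
        self,
        data: SurvivalDataset,
        spec: PredictorSpec,
        priors: PriorSpec | None = None,
        solver: Mapping | None = None,
    ) -> None:
        self.data = data
        self.spec = spec
        self.priors = priors if priors is not None else PriorSpec()
        self.solver = dict(solver or {})
        self.exog_names = spec.eta_names

    @classmethod
    def from_formulas(
        cls,
        df: pd.DataFrame,
        formulas: Sequence[str],
        system: str | _systems.OdeHazardSystem = "hazard_response",
        time_col: str = "time",
        status_col: str = "status",
        free_initials: Sequence[str] = (),
        fixed: Mapping[str, float] | None = None,
        priors: PriorSpec | None = None,
        solver: Mapping | None = None,
    ) -> "OdeHazardRegression":
        """Build from a tidy DataFrame and formula strings.

        >>> OdeHazardRegression.from_formulas(
        ...     df, ["log(lam) ~ x1", "log(kappa) ~ x2"], system="logistic")
        """
        spec = PredictorSpec.from_formulas(system, formulas, free_initials, fixed)
        data = SurvivalDataset.from_dataframe(df, time_col, status_col)
        return cls(data, spec, priors=priors, solver=solver)

    # ---- posterior pieces -------------------------------------------
    def loglike(self, eta) -> float:
        return log_likelihood(eta, self.spec, self.data, **self.solver)

    def logpost(self, eta) -> float:
        return log_posterior(eta, self.spec, self.data, self.priors, **self.solver)

    def start_params(self) -> np.ndarray:
        return np.zeros(self.spec.n_eta)

    # ---- fitting ----------------------------------------------------
    def fit(
        self,
        start=None,
        seed: int = 0,
        hessian_step: float = 1e-4,
        precondition: str = "auto",
        **map_kwargs,
    ) -> "OdeHazardResults":
        """MAP + normal posterior approximation."""
        start = self.start_params() if start is None else np.asarray(start, dtype=float)
        map_fit = find_map(self.logpost, start, seed=seed, precondition=precondition,
                           **map_kwargs)
        H = hessian_at(self.logpost, map_fit.eta, step=hessian_step)
        approx = None
        if map_fit.converged:
            try:
                approx = normal_approx(map_fit, H)
            except np.linalg.LinAlgError:
                approx = None
        if approx is not None:
            # second pass with steps at the statistical scale: tiny steps
            # can read micro-curvature of the discretised likelihood
            # instead of the posterior bowl
            try:
                sd = np.sqrt(np.diag(approx.cov))
                H2 = hessian_at(self.logpost, map_fit.eta,
                                step=np.maximum(sd / 3.0, 1e-5))
                approx = normal_approx(map_fit, H2)
                H = H2
            except np.linalg.LinAlgError:
                pass
        return OdeHazardResults(model=self, map_fit=map_fit, hessian=H, approx=approx)


@dataclass
class OdeHazardResults:
    """Fit results: MAP estimates with normal-approximation uncertainty."""

    model: OdeHazardRegression
    map_fit: MapFit
    hessian: np.ndarray
    approx: NormalApprox | None = None
    _loglik: float | None = field(default=None, repr=False)

    # ---- point estimates and uncertainty ----------------------------
    @property
    def params(self) -> pd.Series:
        return pd.Series(self.map_fit.eta, index=self.model.exog_names, name="MAP")

    @property
    def converged(self) -> bool:
        return self.map_fit.converged

    @property
    def cov_params(self) -> pd.DataFrame:
        if self.approx is None:
            raise ValueError("no valid normal approximation (fit not converged or "
                             "indefinite curvature)")
        names = self.model.exog_names
        return pd.DataFrame(self.approx.cov, index=names, columns=names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params.to_numpy())),
                         index=self.model.exog_names, name="sd")

    def sample(self, n_draws: int = 1000, seed: int = 0) -> np.ndarray:
        """iid draws from the normal posterior approximation."""
        if self.approx is None:
            raise ValueError("no valid normal approximation")
        return normal_approx_sample(self.approx, n_draws, seed)

    def conf_int(self, alpha: float = 0.05, n_draws: int = 1000, seed: int = 0) -> pd.DataFrame:
        """Credible intervals from empirical quantiles of normal-approx draws."""
        draws = self.sample(n_draws, seed)
        lo, hi = np.percentile(draws, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)
        return pd.DataFrame({"lower": lo, "upper": hi}, index=self.model.exog_names)

    # ---- fit quality -------------------------------------------------
    @property
    def loglike_at_map(self) -> float:
        if self._loglik is None:
            self._loglik = self.model.loglike(self.map_fit.eta)
        return self._loglik

    @property
    def aic(self) -> float:
        return aic_bic(self.loglike_at_map, self.map_fit.eta.size, self.model.data.n)[0]

    @property
    def bic(self) -> float:
        return aic_bic(self.loglike_at_map, self.map_fit.eta.size, self.model.data.n)[1]

    def summary(self, alpha: float = 0.05, n_draws: int = 1000, seed: int = 0) -> str:
        spec = self.model.spec
        lines = [
            "ODE hazard regression results",
            "=" * 64,
            f"system: {spec.system.name}    n: {self.model.data.n} "
            f"(events: {self.model.data.n_events})",
            f"log-posterior at MAP: {self.map_fit.logpost:.3f}    "
            f"converged: {self.map_fit.converged}",
            f"AIC: {self.aic:.2f}    BIC: {self.bic:.2f}",
            "-" * 64,
        ]
        tab = pd.DataFrame({"MAP": self.params})
        if self.approx is not None:
            ci = self.conf_int(alpha=alpha, n_draws=n_draws, seed=seed)
            tab["sd"] = self.bse
            tab[f"{100 * alpha / 2:g}%"] = ci["lower"]
            tab[f"{100 * (1 - alpha / 2):g}%"] = ci["upper"]
        lines.append(tab.round(4).to_string())
        lines.append("=" * 64)
        return "\n".join(lines)

    # ---- sampling-based posterior ------------------------------------
    def mcmc(
        self, n_iter: int = 55000, burn_in: int = 5000, thin: int = 50, seed: int = 0,
        **kwargs,
    ):
        """Adaptive-Metropolis posterior sample started at the MAP.

        The initial proposal covariance is a scaled normal-approximation
        covariance when available.
        """
        cov0 = None
        if self.approx is not None:
            cov0 = (2.38 ** 2 / self.map_fit.eta.size) * self.approx.cov
        return adaptive_metropolis(
            self.model.logpost, self.map_fit.eta, n_iter=n_iter, burn_in=burn_in,
            thin=thin, seed=seed, cov0=cov0, **kwargs,
        )

    # ---- prediction ---------------------------------------------------
    def _theta_for_profile(self, profile: Mapping[str, float], eta=None) -> np.ndarray:
        eta = self.map_fit.eta if eta is None else eta
        X = pd.DataFrame([profile])
        return individual_parameters(eta, self.model.spec, X)[0]

    def predict_curve(self, profile: Mapping[str, float], t_grid, eta=None) -> dict:
        """Plug-in hazard/response/survival trajectory for a covariate profile."""
        eta = self.map_fit.eta if eta is None else eta
        theta = self._theta_for_profile(profile, eta)
        fixed = self.model.spec.fixed_constants(eta)
        return hazard_curve(self.model.spec.system, theta, t_grid, fixed=fixed)

    def attractor_report(self, profile: Mapping[str, float], eta=None):
        """Attractor classification at the (plug-in) parameters of a profile."""
        theta = self._theta_for_profile(profile, eta)
        p = _systems.HazardResponseParams(
            lam=theta[0], kappa=theta[1], alpha=theta[2], mu=theta[3],
            **self.model.spec.fixed_constants(eta if eta is not None else self.map_fit.eta),
        )
        return _systems.classify_attractor(p)
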