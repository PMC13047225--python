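"""ODE systems whose solutions are hazard functions.

A survival model is specified through an autonomous system of first-order
ODEs in which the hazard ``h(t)`` is the first state variable, optionally
accompanied by auxiliary states ``q_1..q_m``.  The cumulative hazard is
obtained by augmenting the system with ``H'(t) = h(t)``, ``H(0) = 0``, so a
single integration yields both quantities needed by the censored-data
likelihood.

Two systems ship built in:

* the logistic-growth hazard, whose solution is available in closed form
  and approaches a finite carrying capacity ``kappa``;
* the hazard-response model, a competitive Lotka-Volterra system in which
  a latent "response" process ``q(t)`` (immune response, therapeutic
  action, ...) competes with the hazard through a term ``-alpha*q*h`` in
  both equations.

The long-run behaviour of the hazard-response system is governed by its
attractors; :func:`classify_attractor` reports which of the three regimes
(hazard reaches ``kappa``, hazard driven to 0, interior coexistence) a
parameter value belongs to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "OdeHazardSystem",
    "LogisticParams",
    "HazardResponseParams",
    "AttractorReport",
    "logistic_hazard",
    "logistic_cumhaz",
    "hazard_response_rhs",
    "classify_attractor",
    "get_system",
    "register_system",
    "LOGISTIC",
    "HAZARD_RESPONSE",
]


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value <= 0:
            raise ValueError(f"parameter {name!r} must be positive and finite, got {value}")


@dataclass(frozen=True)
class LogisticParams:
    """Parameters of the logistic-growth hazard.

    lam : intrinsic growth rate of the hazard (1/time)
    kappa : carrying capacity, the bound the hazard approaches (1/time)
    h0 : hazard at t=0 (1/time)
    """

    lam: float
    kappa: float
    h0: float

    def __post_init__(self) -> None:
        _check_positive(lam=self.lam, kappa=self.kappa, h0=self.h0)


@dataclass(frozen=True)
class HazardResponseParams:
    """Parameters of the competitive hazard-response system.

    ``alpha`` is the common competition coefficient and may be exactly 0,
    in which case hazard and response decouple into independent logistic
    equations.  The response's carrying capacity is tied to ``kappa``
    (its scale is arbitrary since q is latent).
    """

    lam: float
    kappa: float
    alpha: float
    mu: float
    h0: float
    q0: float

    def __post_init__(self) -> None:
        _check_positive(lam=self.lam, kappa=self.kappa, mu=self.mu, h0=self.h0, q0=self.q0)
        if not np.isfinite(self.alpha) or self.alpha < 0:
            raise ValueError(f"alpha must be finite and >= 0, got {self.alpha}")


@dataclass(frozen=True)
class AttractorReport:
    """Equilibrium analysis of the hazard-response system.

    h_star, q_star : interior equilibrium values
    d_det : D = 1 - (alpha*kappa)^2 / (lam*mu)
    regime : 'hazard_wins' | 'response_wins' | 'coexistence' | 'degenerate'
    stable : False when the interior equilibrium is a saddle (D < 0 with
        h* > 0 and q* > 0), i.e. the long-run limit depends on the
        initial condition.
    """

    h_star: float
    q_star: float
    d_det: float
    regime: str
    stable: bool = True


def logistic_hazard(t, p: LogisticParams):
    """Closed-form logistic hazard h(t) = kappa*h0*e^{lam t} / (kappa + h0(e^{lam t}-1)).

    Evaluated as ``kappa / (1 + ((kappa-h0)/h0) e^{-lam t})`` so large
    ``lam*t`` cannot overflow.
    """
    t = np.asarray(t, dtype=float)
    return p.kappa / (1.0 + ((p.kappa - p.h0) / p.h0) * np.exp(-p.lam * t))


def logistic_cumhaz(t, p: LogisticParams):
    """Closed-form cumulative hazard of the logistic model.

    H(t) = (kappa/lam) log((kappa + h0(e^{lam t}-1))/kappa), evaluated in
    the overflow-safe form kappa*t + (kappa/lam)*log((h0 + (kappa-h0)e^{-lam t})/kappa).
    """
    t = np.asarray(t, dtype=float)
    decayed = p.h0 + (p.kappa - p.h0) * np.exp(-p.lam * t)
    return p.kappa * t + (p.kappa / p.lam) * (np.log(decayed) - np.log(p.kappa))


def hazard_response_rhs(state, p: HazardResponseParams):
    """Vector field of the hazard-response system at ``state = (h, q)``.

    dh/dt = lam*h*(1-h/kappa) - alpha*q*h
    dq/dt = mu*q*(1-q/kappa) - alpha*q*h

    Both axes are invariant (h=0 => dh=0, q=0 => dq=0), which keeps exact
    solutions nonnegative.
    """
    h, q = state
    dh = p.lam * h * (1.0 - h / p.kappa) - p.alpha * q * h
    dq = p.mu * q * (1.0 - q / p.kappa) - p.alpha * q * h
    return (dh, dq)


def classify_attractor(p: HazardResponseParams, tol: float = 1e-8) -> AttractorReport:
    """Classify the long-run regime of the hazard-response system.

    With D = 1 - (alpha*kappa)^2/(lam*mu), the interior equilibrium is
    h* = kappa*(1 - alpha*kappa/lam)/D and q* = kappa*(1 - alpha*kappa/mu)/D.
    The regimes follow from linearising at the boundary equilibria
    (kappa, 0) — stable iff alpha*kappa > mu — and (0, kappa) — stable iff
    alpha*kappa > lam:

    * mu < alpha*kappa < lam -> hazard wins: h(t) -> kappa, q(t) -> 0
      (here q* < 0 when D > 0)
    * lam < alpha*kappa < mu -> response wins: h(t) -> 0, q(t) -> kappa
      (here h* < 0 when D > 0)
    * alpha*kappa < min(lam, mu) -> coexistence: h(t) -> h* in (0, kappa),
      q(t) -> q* (stable interior equilibrium, D > 0)
    * alpha*kappa > max(lam, mu) -> bistable: both boundary equilibria are
      stable and the interior point (h*, q* > 0, D < 0) is a saddle, so
      the limit depends on the initial condition; reported as coexistence
      with ``stable=False``.

    For D > 0 this coincides with classifying by the signs of (h*, q*);
    for D < 0 the sign rule can point at an unstable boundary equilibrium,
    so the stability criterion is authoritative.

    ``alpha = 0`` gives D=1, h*=q*=kappa; the hazard reaches its carrying
    capacity, so the case is reported as hazard_wins.  |D| below ``tol``,
    or an equilibrium value within ``tol*kappa`` of 0 (a measure-zero
    boundary), is degenerate.
    """
    ak = p.alpha * p.kappa
    d_det = 1.0 - ak * ak / (p.lam * p.mu)
    if p.alpha == 0.0:
        return AttractorReport(h_star=p.kappa, q_star=p.kappa, d_det=1.0, regime="hazard_wins")
    if abs(d_det) < tol:
        warnings.warn("attractor analysis degenerate: D within tolerance of 0", stacklevel=2)
        return AttractorReport(h_star=np.nan, q_star=np.nan, d_det=d_det, regime="degenerate")
    h_star = p.kappa * (1.0 - ak / p.lam) / d_det
    q_star = p.kappa * (1.0 - ak / p.mu) / d_det
    scale = p.kappa * tol
    if abs(h_star) < scale or abs(q_star) < scale:
        warnings.warn("attractor analysis degenerate: equilibrium on a boundary", stacklevel=2)
        return AttractorReport(h_star=h_star, q_star=q_star, d_det=d_det, regime="degenerate")
    if ak < min(p.lam, p.mu):
        return AttractorReport(h_star=h_star, q_star=q_star, d_det=d_det, regime="coexistence")
    if ak > max(p.lam, p.mu):
        return AttractorReport(
            h_star=h_star, q_star=q_star, d_det=d_det, regime="coexistence", stable=False
        )
    if p.mu < ak < p.lam:
        return AttractorReport(h_star=h_star, q_star=q_star, d_det=d_det, regime="hazard_wins")
    return AttractorReport(h_star=h_star, q_star=q_star, d_det=d_det, regime="response_wins")


@dataclass(frozen=True)
class OdeHazardSystem:
    """An autonomous ODE system whose first state variable is the hazard.

    Parameters
    ----------
    name : registry key.
    state_dim : number of state variables (hazard plus auxiliary states),
        excluding the cumulative-hazard augmentation.
    parameter_names : ordered names of the ODE parameters theta.
    positive : per-parameter positivity flags (log links by default).
    rhs : ``rhs(y, theta) -> dy/dt`` where ``y`` has shape (state_dim,)
        (or (n, state_dim) for a batch with theta of shape (n, d)); must be
        written with numpy ufuncs so both shapes work.
    initial_state : ``initial_state(theta, fixed) -> y0`` mapping the
        parameter vector and the dict of fixed constants to Y(0).
    fixed_defaults : default fixed constants (e.g. h0, q0 when they are
        not regression parameters).
    """

    name: str
    state_dim: int
    parameter_names: tuple
    positive: tuple
    rhs: Callable
    initial_state: Callable
    fixed_defaults: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.state_dim < 1:
            raise ValueError("state_dim must be >= 1")
        if len(self.parameter_names) != len(self.positive):
            raise ValueError("parameter_names and positive flags must align")

    @property
    def n_params(self) -> int:
        return len(self.parameter_names)


def _logistic_rhs(y, theta):
    h = y[..., 0]
    lam = theta[..., 0]
    kappa = theta[..., 1]
    return np.stack([lam * h * (1.0 - h / kappa)], axis=-1)


def _logistic_init(theta, fixed):
    h0 = float(fixed["h0"])
    shape = np.shape(theta)[:-1]
    return np.full(shape + (1,), h0)


def _hr_rhs(y, theta):
    h = y[..., 0]
    q = y[..., 1]
    lam = theta[..., 0]
    kappa = theta[..., 1]
    alpha = theta[..., 2]
    mu = theta[..., 3]
    comp = alpha * q * h
    dh = lam * h * (1.0 - h / kappa) - comp
    dq = mu * q * (1.0 - q / kappa) - comp
    return np.stack([dh, dq], axis=-1)


def _hr_init(theta, fixed):
    h0 = float(fixed["h0"])
    q0 = float(fixed["q0"])
    shape = np.shape(theta)[:-1]
    out = np.empty(shape + (2,))
    out[..., 0] = h0
    out[..., 1] = q0
    return out


LOGISTIC = OdeHazardSystem(
    name="logistic",
    state_dim=1,
    parameter_names=("lam", "kappa"),
    positive=(True, True),
    rhs=_logistic_rhs,
    initial_state=_logistic_init,
    fixed_defaults={"h0": 0.01},
)

HAZARD_RESPONSE = OdeHazardSystem(
    name="hazard_response",
    state_dim=2,
    parameter_names=("lam", "kappa", "alpha", "mu"),
    positive=(True, True, True, True),
    rhs=_hr_rhs,
    initial_state=_hr_init,
    fixed_defaults={"h0": 0.01, "q0": 1e-6},
)

_REGISTRY: dict[str, OdeHazardSystem] = {
    "logistic": LOGISTIC,
    "hazard_response": HAZARD_RESPONSE,
}


def register_system(system: OdeHazardSystem, overwrite: bool = False) -> None:
    """Register a user-defined ODE hazard system under ``system.name``."""
    if system.name in _REGISTRY and not overwrite:
        raise ValueError(f"system {system.name!r} already registered")
    _REGISTRY[system.name] = system


def get_system(name: str) -> OdeHazardSystem:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown system {name!r}; available: {sorted(_REGISTRY)}"
        ) from None
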