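"""Covariate-to-ODE-parameter mapping via link-transformed linear predictors.

Each ODE parameter ``theta_k`` receives its own linear predictor
``phi_k(theta_{k,i}) = beta_{k,0} + x_{k,i}' beta_k`` with a monotone link
``phi_k`` (log for positive parameters, identity otherwise).  The full
parameter vector ``eta`` concatenates the (intercept, coefficients) blocks
in system-parameter order, optionally followed by free initial conditions
carried on the log scale so unconstrained optimisers can be used.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .systems import OdeHazardSystem, get_system

__all__ = [
    "LinkFunction",
    "LOG_LINK",
    "IDENTITY_LINK",
    "PredictorSpec",
    "InclusionPattern",
    "individual_parameters",
    "restrict_eta",
    "embed_eta",
]

#: linear predictors beyond this magnitude are clamped before exp() to keep
#: the inverse link finite; exp(+-LINPRED_CLAMP) ~ 1e15.
LINPRED_CLAMP = 35.0

_clamp_warned: set = set()

_ALIASES = {"lambda": "lam"}


@dataclass(frozen=True)
class LinkFunction:
    """Monotone map of an ODE parameter onto the real line."""

    name: str

    def forward(self, theta):
        if self.name == "log":
            return np.log(theta)
        return np.asarray(theta, dtype=float)

    def inverse(self, x):
        if self.name == "log":
            return np.exp(x)
        return np.asarray(x, dtype=float)


LOG_LINK = LinkFunction("log")
IDENTITY_LINK = LinkFunction("identity")


@dataclass(frozen=True)
class PredictorSpec:
    """Which covariates (and which link) model each ODE parameter.

    covariates : per ODE parameter, the ordered tuple of dataset columns in
        its linear predictor (an intercept is always included and is not
        listed).
    links : per-parameter link; defaults to log for positivity-flagged
        parameters and identity otherwise.
    free_initials : names of initial conditions estimated as free
        parameters (appended to eta on the log scale); the rest are fixed
        at ``fixed`` (falling back to the system defaults).
    """

    system: OdeHazardSystem
    covariates: Mapping[str, tuple]
    links: Mapping[str, LinkFunction] = field(default_factory=dict)
    free_initials: tuple = ()
    fixed: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cov = {k: tuple(v) for k, v in self.covariates.items()}
        for k in cov:
            if k not in self.system.parameter_names:
                raise ValueError(f"unknown ODE parameter {k!r} for system {self.system.name!r}")
        for k in self.system.parameter_names:
            cov.setdefault(k, ())
        links = dict(self.links)
        for k, pos in zip(self.system.parameter_names, self.system.positive):
            links.setdefault(k, LOG_LINK if pos else IDENTITY_LINK)
        for name in self.free_initials:
            if name not in self.system.fixed_defaults:
                raise ValueError(f"unknown initial condition {name!r}")
        object.__setattr__(self, "covariates", cov)
        object.__setattr__(self, "links", links)
        object.__setattr__(self, "free_initials", tuple(self.free_initials))

    # ---- eta layout -------------------------------------------------
    @property
    def eta_names(self) -> list:
        names = []
        for k in self.system.parameter_names:
            names.append(f"{k}:intercept")
            names.extend(f"{k}:{c}" for c in self.covariates[k])
        names.extend(f"log_{name}" for name in self.free_initials)
        return names

    @property
    def n_eta(self) -> int:
        return sum(1 + len(self.covariates[k]) for k in self.system.parameter_names) + len(
            self.free_initials
        )

    def block_slices(self) -> dict:
        out = {}
        pos = 0
        for k in self.system.parameter_names:
            width = 1 + len(self.covariates[k])
            out[k] = slice(pos, pos + width)
            pos += width
        for name in self.free_initials:
            out[f"log_{name}"] = slice(pos, pos + 1)
            pos += 1
        return out

    def unflatten(self, eta) -> dict:
        eta = np.asarray(eta, dtype=float)
        if eta.shape != (self.n_eta,):
            raise ValueError(f"eta has length {eta.shape}, spec expects {self.n_eta}")
        return {k: eta[sl].copy() for k, sl in self.block_slices().items()}

    def flatten(self, blocks: Mapping[str, Sequence[float]]) -> np.ndarray:
        out = np.empty(self.n_eta)
        for k, sl in self.block_slices().items():
            out[sl] = np.asarray(blocks[k], dtype=float)
        return out

    def fixed_constants(self, eta=None) -> dict:
        """Fixed initial-condition constants, with free entries read off eta."""
        fixed = dict(self.system.fixed_defaults)
        fixed.update(self.fixed)
        if eta is not None and self.free_initials:
            eta = np.asarray(eta, dtype=float)
            for j, name in enumerate(self.free_initials):
                fixed[name] = float(np.exp(eta[self.n_eta - len(self.free_initials) + j]))
        return fixed

    # ---- construction helpers --------------------------------------
    @classmethod
    def from_formulas(
        cls,
        system: OdeHazardSystem | str,
        formulas: Sequence[str],
        free_initials: Sequence[str] = (),
        fixed: Mapping[str, float] | None = None,
    ) -> "PredictorSpec":
        """Build a spec from formula strings like ``"log(lambda) ~ nodes + trt"``.

        The left side names the ODE parameter (optionally wrapped in the
        link), the right side lists covariate columns; ``1`` means
        intercept only.
        """
        if isinstance(system, str):
            system = get_system(system)
        covariates: dict[str, tuple] = {}
        links: dict[str, LinkFunction] = {}
        for f in formulas:
            lhs, _, rhs = f.partition("~")
            lhs = lhs.strip()
            m = re.fullmatch(r"(?:(log|identity)\s*\(\s*)?([A-Za-z_][\w]*)\s*\)?", lhs)
            if m is None:
                raise ValueError(f"cannot parse predictor formula {f!r}")
            link_name, param = m.groups()
            param = _ALIASES.get(param, param)
            if param not in system.parameter_names:
                raise ValueError(f"unknown ODE parameter {param!r} in formula {f!r}")
            terms = [t.strip() for t in rhs.split("+") if t.strip() not in ("", "1")]
            covariates[param] = tuple(terms)
            if link_name:
                links[param] = LinkFunction(link_name)
        return cls(
            system=system,
            covariates=covariates,
            links=links,
            free_initials=tuple(free_initials),
            fixed=dict(fixed or {}),
        )


def _design_matrix(X, columns: Sequence[str]) -> np.ndarray:
    if len(columns) == 0:
        n = len(X) if hasattr(X, "__len__") else 1
        return np.empty((n, 0))
    if isinstance(X, pd.DataFrame):
        missing = [c for c in columns if c not in X.columns]
        if missing:
            raise KeyError(f"covariate columns missing from data: {missing}")
        return X.loc[:, list(columns)].to_numpy(dtype=float)
    return np.asarray(X, dtype=float)[:, : len(columns)]


def individual_parameters(eta, spec: PredictorSpec, X) -> np.ndarray:
    """Per-subject ODE parameters theta_i = phi_k^{-1}(beta_{k,0} + x_{k,i}'beta_k).

    ``X`` is a DataFrame (or ndarray whose leading columns match the spec)
    with one row per subject; returns an (n, d) array in system parameter
    order.  Non-finite linear predictors raise; overflowing log links are
    clamped at exp(+-35) with a warning.
    """
    eta = np.asarray(eta, dtype=float)
    blocks = spec.unflatten(eta)
    n = len(X)
    theta = np.empty((n, spec.system.n_params))
    for j, k in enumerate(spec.system.parameter_names):
        block = blocks[k]
        lp = np.full(n, block[0])
        cols = spec.covariates[k]
        if cols:
            lp = lp + _design_matrix(X, cols) @ block[1:]
        if not np.all(np.isfinite(lp)):
            bad = int(np.flatnonzero(~np.isfinite(lp))[0])
            raise FloatingPointError(
                f"non-finite linear predictor for parameter {k!r} at subject {bad}"
            )
        if spec.links[k].name == "log" and np.any(np.abs(lp) > LINPRED_CLAMP):
            if k not in _clamp_warned:  # warn once per parameter per process
                _clamp_warned.add(k)
                warnings.warn(
                    f"linear predictor for {k!r} clamped at +-{LINPRED_CLAMP} before exp",
                    stacklevel=2,
                )
            lp = np.clip(lp, -LINPRED_CLAMP, LINPRED_CLAMP)
        theta[:, j] = spec.links[k].inverse(lp)
    return theta


@dataclass(frozen=True)
class InclusionPattern:
    """Binary inclusion indicators gamma_{k,j}; intercepts always included."""

    spec: PredictorSpec
    gamma: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        g = {}
        for k in self.spec.system.parameter_names:
            arr = np.asarray(self.gamma.get(k, np.zeros(len(self.spec.covariates[k]))), dtype=int)
            if arr.shape != (len(self.spec.covariates[k]),) or not np.isin(arr, (0, 1)).all():
                raise ValueError(f"gamma block for {k!r} must be 0/1 of matching length")
            g[k] = arr
        object.__setattr__(self, "gamma", g)

    @classmethod
    def all_ones(cls, spec: PredictorSpec) -> "InclusionPattern":
        return cls(spec, {k: np.ones(len(spec.covariates[k]), dtype=int) for k in spec.covariates})

    @classmethod
    def all_zeros(cls, spec: PredictorSpec) -> "InclusionPattern":
        return cls(spec, {k: np.zeros(len(spec.covariates[k]), dtype=int) for k in spec.covariates})

    @property
    def size(self) -> int:
        """|gamma|, the number of active variables."""
        return int(sum(arr.sum() for arr in self.gamma.values()))

    def key(self) -> str:
        """Canonical row-major bit-string key (cache identity)."""
        return "".join(
            "".join(map(str, self.gamma[k])) for k in self.spec.system.parameter_names
        )

    def flip(self, param: str, j: int) -> "InclusionPattern":
        g = {k: arr.copy() for k, arr in self.gamma.items()}
        g[param][j] = 1 - g[param][j]
        return InclusionPattern(self.spec, g)

    def active_spec(self) -> PredictorSpec:
        """PredictorSpec of the active model (inactive covariates dropped)."""
        cov = {
            k: tuple(c for c, g in zip(self.spec.covariates[k], self.gamma[k]) if g)
            for k in self.spec.system.parameter_names
        }
        return replace(self.spec, covariates=cov)

    def entries(self):
        """Iterate (param, j, column) over all candidate covariates in scan order."""
        for k in self.spec.system.parameter_names:
            for j, c in enumerate(self.spec.covariates[k]):
                yield k, j, c


def restrict_eta(eta_full, spec: PredictorSpec, gamma: InclusionPattern) -> np.ndarray:
    """Drop coefficient entries with gamma=0 (intercepts and free initials kept)."""
    blocks = spec.unflatten(eta_full)
    out = []
    for k in spec.system.parameter_names:
        b = blocks[k]
        out.append(b[:1])
        out.append(b[1:][gamma.gamma[k].astype(bool)])
    for name in spec.free_initials:
        out.append(blocks[f"log_{name}"])
    return np.concatenate(out)


def embed_eta(eta_active, spec: PredictorSpec, gamma: InclusionPattern) -> np.ndarray:
    """Inverse of :func:`restrict_eta`: zero-fill the inactive coefficients."""
    eta_active = np.asarray(eta_active, dtype=float)
    out = np.zeros(spec.n_eta)
    slices = spec.block_slices()
    pos = 0
    for k in spec.system.parameter_names:
        sl = slices[k]
        out[sl.start] = eta_active[pos]
        pos += 1
        mask = gamma.gamma[k].astype(bool)
        idx = np.flatnonzero(mask)
        out[sl.start + 1 + idx] = eta_active[pos : pos + mask.sum()]
        pos += int(mask.sum())
    for name in spec.free_initials:
        sl = slices[f"log_{name}"]
        out[sl] = eta_active[pos]
        pos += 1
    return out
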