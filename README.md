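# odesurv

Hazard-based distributional survival regression in which the hazard
function is a state variable of an autonomous system of ODEs.

Classical survival regression (proportional hazards, AFT, general
hazards) shares one baseline hazard across the population, so every
subgroup is forced into the same hazard *shape*.  `odesurv` instead
defines the hazard through a dynamical system

```
Y'(t) = psi_theta(Y(t)),  Y = (h, q_1, ..., q_m),   H'(t) = h(t)
```

and lets covariates act on the ODE parameters through link-transformed
linear predictors `phi_k(theta_k,i) = beta_k,0 + x_k,i' beta_k`.  Subjects
with different covariates can then have qualitatively different hazard
trajectories — increasing, plateauing, or collapsing to zero — and the
attractor structure of the system says *why*: for the built-in
hazard-response model (a competitive Lotka–Volterra system in which a
latent response process `q(t)` competes with the hazard),

```
h' = lam·h·(1 − h/kappa) − alpha·q·h
q' = mu·q·(1 − q/kappa) − alpha·q·h
```

the long-run regime (hazard reaches its bound `kappa`, hazard driven to 0
by the response, or an interior equilibrium `h* = kappa(1 − alpha·kappa/lam)/D`
with `D = 1 − (alpha·kappa)²/(lam·mu)`) is a deterministic function of the
subject's parameters, so posterior probabilities of regime membership are
directly interpretable statements about treatment response.

The package is aimed at biostatisticians analysing right-censored
time-to-event data with crossing hazards or treatment-response dynamics:

* right-censored log-likelihood `sum delta_i log h(t_i) − sum H(t_i)`
  evaluated by solving one small ODE system per subject (compiled
  fixed-step RK4 ensemble solver plus an adaptive reference path);
* MAP estimation with a normal (Bernstein–von Mises) posterior
  approximation `N(eta_MAP, (−Hessian)⁻¹)`, and Haario-style adaptive
  Metropolis MCMC when asymptotics are in doubt;
* Bayesian variable selection per linear predictor: group g-priors,
  a complexity prior `pi(gamma) ∝ d~^(−C|gamma|)`, Laplace-approximated
  marginal likelihoods explored by a cached, warm-started Gibbs sampler;
* a survival-time simulator (inverse cumulative hazard of Exponential(1)
  draws), evaluation metrics (replication summaries, restricted-L1 hazard
  distances, TV distances between posterior samples, Kaplan–Meier), and a
  general-hazards Power-Generalised-Weibull comparator;
* a thin `odesurv` CLI (`simulate`, `fit`, `mcmc`, `select`, `predict`,
  `evaluate`, `compare`).

## Worked example

Simulate two treatment arms with crossing hazards from the logistic model
and refit them:

```python
import numpy as np, pandas as pd
from odesurv import OdeHazardRegression
from odesurv.simulate import simulate_times, apply_censoring
from odesurv.systems import LOGISTIC

rng = np.random.default_rng(21)
n = 400
trt = rng.integers(0, 2, n).astype(float)
lam = np.exp(0.3 + 0.5 * trt)       # treated arm: faster hazard growth
kap = np.exp(0.2 - 0.4 * trt)       # ... but a lower hazard plateau
o = simulate_times(LOGISTIC, np.column_stack([lam, kap]), rng, fixed={"h0": 0.1})
t, d = apply_censoring(o, 8.0)
df = pd.DataFrame({"time": np.maximum(t, 1e-6), "status": d, "trt": trt})

model = OdeHazardRegression.from_formulas(
    df, ["log(lam) ~ trt", "log(kappa) ~ trt"], system="logistic",
    fixed={"h0": 0.1},
)
res = model.fit(seed=0)
print(res.summary(seed=0))
```

```
ODE hazard regression results
================================================================
system: logistic    n: 400 (events: 399)
log-posterior at MAP: -597.934    converged: True
AIC: 1187.27    BIC: 1203.24
----------------------------------------------------------------
                    MAP      sd    2.5%   97.5%
lam:intercept    0.2319  0.0965  0.0427  0.4119
lam:trt          0.4484  0.1644  0.1316  0.7718
kappa:intercept  0.2914  0.1714 -0.0297  0.6255
kappa:trt       -0.1731  0.2247 -0.6326  0.2845
================================================================
```

The treatment's growth-rate effect is recovered (truth 0.5, interval
[0.13, 0.77]); the carrying-capacity effect (truth −0.4) points the right
way but — with nearly all events observed early — is not yet resolved at
n=400.  `res.mcmc(...)` draws an adaptive-Metropolis sample from the same
posterior, and
`res.predict_curve({"trt": 1.0}, grid)` returns the fitted hazard and
survival trajectories.  For the hazard-response model,
`res.attractor_report(profile)` classifies a covariate profile's long-run
regime and `odesurv.metrics.attractor_posterior_probs` turns posterior
draws into regime probabilities.

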