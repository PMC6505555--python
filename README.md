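# mominf

Moment-based parameter inference for a negative auto-regulatory
transcriptional feedback loop — and a systematic study of how accurate that
inference can be.

## The problem

Negative autoregulation, where a protein represses its own gene, is one of
the most common motifs in gene regulatory networks.  Given single-cell or
population-snapshot measurements of protein copy numbers (e.g. flow
cytometry of a fluorescent reporter at a series of time points), one would
like to infer the kinetic parameters of the circuit:

- `rho_u` — burst-firing (protein production) rate while the gene is ON,
- `b` — mean translational burst size (bursts are geometric,
  `psi(m) = b^m / (1+b)^(m+1)`),
- `d` — protein degradation rate,
- `sigma_b` — protein–DNA binding rate (feedback strength),
- `sigma_u` — gene reactivation (unbinding) rate.

The reaction scheme is

```
G  --rho_u-->  G + m*P        (m ~ psi, geometric)
G + P  --sigma_b*n-->  G*
G*  --sigma_u-->  G
P  --d*n-->  0
```

The standard inference route summarises the data by its sample central
moments per time point, and evaluates a Gaussian likelihood of those moments
whose means come from an approximate solution of the chemical master
equation (CME).  Because the binding reaction is bimolecular the moment
hierarchy does not close, so a *moment closure* must be chosen — and that
choice, it turns out, is the dominant source of error in the estimated
parameters.  This package implements the complete pipeline and quantifies
the estimation error as a function of sample size, number of time points,
highest moment order used, and closure scheme.  It is aimed at researchers
in stochastic gene expression and at anyone benchmarking moment-closure
inference methods.

## What is inside

| Stage | Module | Method |
|---|---|---|
| Synthetic data | `mominf.ssa` | exact Gillespie simulation per cell, population snapshot moments; optional lognormal cell-to-cell variability in `rho_u`; multiplicative measurement noise |
| Ground truth | `mominf.fsp` | finite state projection of the CME (sparse generator, stiff implicit integration, certified truncation leak) |
| Likelihood approximations | `mominf.closures` | six schemes: LNA, 3MA, DM, CDM, CG, LMA (see `docs/methods.md` for the equations and closures) |
| Estimators | `mominf.inference` | `MomentMLE` (differential evolution over `ln(theta)`) and `MomentMCMC` (adaptive Metropolis, split-R-hat, KDE-based MAP), both scikit-learn-style estimators |
| Benchmarks | `mominf.evaluation` | fractional-error reports, mean–variance independence diagnostic, closure benchmarks, parameter sweeps, heterogeneity study |

The numerical hot path (SSA, closure ODE integration, objective and MCMC
kernels) is compiled with numba; a full five-parameter maximum-likelihood
fit takes a few seconds.

## Worked example

Fit infinite-sample (master-equation) moment data at the reference
parameter set `theta = (13, 3, 1, 0.001, 0.1)` with a good closure (CDM,
conditional derivative matching) and a poor one (LNA, linear noise
approximation):

```python
import numpy as np
from mominf import FeedbackLoopParams, TimeGrid, fsp_solve, fsp_moments, MomentMLE

theta = FeedbackLoopParams(rho_u=13, b=3, d=1, sigma_b=0.001, sigma_u=0.1)
grid = TimeGrid.default()                      # t = 1, 2, ..., 30
data = fsp_moments(fsp_solve(theta, grid), 6)  # infinite-sample moments

for closure in ("cdm", "lna"):
    est = MomentMLE(closure=closure, k_max=2, bounds_center=theta.as_array(),
                    random_state=1).fit_moments(data, np.inf)
    fe = 100 * np.mean(np.abs(est.theta_ - theta.as_array()) / theta.as_array())
    print(f"{closure}: mean FE {fe:5.2f}%  theta_hat = {np.round(est.theta_, 4)}")
```

prints

```
cdm: mean FE  0.00%  theta_hat = [1.3e+01 3.0e+00 1.0e+00 1.0e-03 1.0e-01]
lna: mean FE 22.31%  theta_hat = [1.22754e+01 2.96960e+00 8.82400e-01 7.00000e-04 3.26000e-02]
```

The data are noise-free (infinite sample size), so everything the fit gets
wrong is *systematic* error from approximating the likelihood.  With the
CDM the parameters come back essentially exactly; with the LNA the estimate
of the unbinding rate is off by a factor of three even though the fitted
moment curves look reasonable.  The mean fractional error ("mean FE") is
the average over the five parameters of `|theta_hat - theta_true| /
theta_true`, in percent.

A command-line interface mirrors the library stages (`mominf simulate`,
`mominf fsp`, `mominf closure`, `mominf fit-mle`, `mominf fit-mcmc`,
`mominf evaluate`); stages exchange a simple moments CSV and JSON parameter
files.

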