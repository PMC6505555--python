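# Methods

## Model

A single-copy gene switches between a transcribing state `G` (ON) and a
repressed state `G*` (OFF).  While ON, proteins are produced in
instantaneous bursts at rate `rho_u`; each burst adds `m ~ psi(m) = b^m /
(1+b)^(m+1)` proteins (`m = 0, 1, 2, ...`, mean `b`).  The geometric burst
law is the fast-mRNA-decay limit of translational bursting, so mRNA is not
modelled explicitly.  The protein represses its own gene by binding to it
(propensity `sigma_b * n` while ON, consuming one protein); the bound state
reverts at rate `sigma_u`; protein decays at rate `d * n`.  The state space
is `{ON, OFF} x {n >= 0}` with a single gene copy, and every experiment in
the package starts from zero proteins with the gene ON.  Units are
nondimensional; the study parameter sets use `d = 1`, so time is measured
in protein lifetimes.

Raw burst moments used throughout: `E[m] = b`, `E[m^2] = 2b^2 + b`,
`E[m^3] = 6b^3 + 6b^2 + b` (falling-factorial moments of the geometric law
are `k! b^k`).

Cell-to-cell variability is modelled as a lognormal distribution of
`rho_u` across cells, all other rates shared.  Two conventions for the
spread parameter are supported: `rho_u_scale="log"` interprets
(`mean_rho_u`, `sd_rho_u`) as the median and the log-scale sigma of the
lognormal; `"arithmetic"` as its arithmetic mean and standard deviation.
The study conditions use the log scale: a log-sigma of 0.1–0.3 (10–30%
cell-to-cell CV) is the regime in which the spread is identifiable from
10^5–10^6 cells and materially changes the population moments.  With the
arithmetic reading, a standard deviation of 0.1 on a mean of 13 is a 0.8%
CV, which is statistically invisible at these sample sizes (the fit pins
the spread at its box bound); this identifiability argument is why the log
convention is the default for the heterogeneity benchmarks.

## Synthetic data

Each cell is one exact realization of the Gillespie direct method.  A
master seed spawns per-cell seeds through `numpy.random.SeedSequence`, so
enlarging the population extends rather than reshuffles the stream
assignment, and two populations with the same master seed share their
common prefix of cells.  Population snapshot data are emulated by sampling
each cell's trajectory at the grid times and treating per-time-point
moments as independent in the likelihood.  This mirrors flow-cytometry
snapshot data, where different times measure different cells; for tracked
single-cell data the assumption additionally requires measurement intervals
longer than the protein autocorrelation time.  The generator simulates one
trajectory per cell rather than fresh cells per time point — the residual
autocorrelation this leaves in the sample moments is precisely what the
mean–variance independence diagnostic (below) quantifies.

Sample central moments use the population (1/N) normalisation: the mean,
then `(1/N) sum_i (x_i - mean)^k` for `k >= 2`.

Optional measurement noise multiplies every count by `exp(eps)`,
`eps ~ N(0, noise_scale^2)` i.i.d. — unit-median lognormal noise emulating
fluorescence calibration error.  The default study conditions add none.

What the generator does *not* emulate: cell division and lineage
correlations, partitioning noise, explicit mRNA dynamics, autofluorescence
background, or gating artefacts.  Conclusions drawn from passing tests
therefore concern the inference machinery under the model's own
assumptions, not instrument-specific effects in real cytometry data.

## Ground truth: finite state projection

The master equation is solved on the truncated space `{ON, OFF} x {0..n_max}`
by integrating `dP/dt = A P` with BDF on the sparse generator (rtol 1e-8,
atol 1e-12; the generator's stiffness grows with `d * n_max`).  Burst jumps
past the boundary are dropped, so `1 - sum(P)` is the classic certified
truncation error; if it exceeds the tolerance (default 1e-8) anywhere on
the grid, `n_max` doubles and the solve repeats.  The default truncation is
`max(200, 10 * rho_u * b / d)` — ten times the unrepressed mean.  Burst
transition probabilities are truncated where the geometric tail drops below
1e-14.  Moments come from the leak-renormalised marginal protein
distribution.  Against a dense matrix-exponential reference on a small
truncation the solver agrees to 1e-8 in every probability; doubling `n_max`
moves reported moments by far less than 0.1%.

FSP moments play the role of infinite-sample data: fitting them isolates
the *systematic* error of a likelihood approximation from sampling noise.

## The six likelihood approximations

Each closure integrates a small ODE system from the zero-protein ON state
and returns central moments `mu_tilde_k(t, theta)`, `k <= 3`.  Writing
`y` for the gene-ON indicator and `n` for protein number:

**LNA (linear noise approximation).**  Deterministic rate equations for
`<y>` and `<n>` (mean-field factorisation of the binding term) plus the
Lyapunov equation for the Gaussian covariance.  The diffusion matrix is
burst-augmented: production contributes `rho_u <y> E[m^2]` to the protein
diffusion.  Third central moments are identically zero.

**3MA (three-moment approximation).**  Exact raw-moment equations of the
joint `(y, n)` pair up to total order three — nine states, with the gene
treated as an ordinary mass-action species, i.e. the binary identity
`y^2 = y` is *not* substituted, matching standard moment-closure practice
for reaction networks.  The fourth-order moments `<y^3 n>`, `<y^2 n^2>`,
`<y n^3>` that the bilinear binding propensity pulls in are closed by
setting the corresponding fourth joint cumulants to zero.  The exact
dynamics preserve `<y^2> = <y>`; the closure perturbs the system off that
manifold, which is the origin of its characteristic error at strong
feedback or large bursts.  The symbolic derivation of these equations is
regenerable with `scripts/derive_moment_equations.py`.

**DM (derivative matching).**  Same nine-state hierarchy; the fourth-order
moments are instead replaced by products of lower-order moments with
binomial-coefficient exponents chosen so that the closure is exact for
jointly lognormal statistics (equivalently, matches time derivatives of the
exact hierarchy at the initial time), e.g.
`<y^3 n> ≈ <y>^3 <y^2>^-3 <y^3> <n> <yn>^-3 <y^2 n>^3`.
The closure formulas were verified against exact bivariate-lognormal
moments to machine precision.

**CDM / CG (conditional closures).**  Seven states: the gene-ON
probability plus protein moments conditional on each gene state,
`c_k = <y n^k>` and `z_k = <(1-y) n^k>`, `k <= 3`.  The only unclosed
moment is `<y n^4>` from the binding reaction; CDM closes it by univariate
derivative matching on the ON-conditional moments
(`E[n^4|ON] ≈ E[n|ON]^4 E[n^3|ON]^4 / E[n^2|ON]^6`), CG by a vanishing
fourth conditional cumulant (conditional Gaussian).  Conditioning on the
low-copy species is what makes these closures accurate: within a gene
state the protein dynamics are linear, so the conditional distributions
are nearly of known form.  Predicted population moments are the mixtures
`m_k = c_k + z_k`.

**LMA (linear-mapping approximation).**  The bimolecular binding reaction
is replaced by a first-order gene switch `G -> G*` with the self-consistent
rate `sigma_b * E[n | ON]`, mapping the circuit onto a bursty telegraph
model whose moment equations close exactly at every order.  The
conditional mean is part of the ODE state, so the effective rate updates
continuously during integration rather than by outer fixed-point
iteration.  The mapped network has no binding reaction, so the consumption
of one protein per binding event is dropped — an `O(sigma_b <n> / d)`
(~0.1% at the study conditions) effect on the moments.

**Exactness guard.**  At `sigma_b = 0` the network is linear and all six
schemes must agree with the master equation; the test suite enforces
agreement to 1e-4 relative in mean and variance (and third moment where
defined).  This property pins down the non-closure parts of every system,
so a transcription error in any equation is detectable.

**Heterogeneous populations.**  Population moments of the lognormal-
`rho_u` mixture are computed by Gauss–Hermite quadrature (default 20
nodes) over the conditional (fixed-`rho_u`) closure predictions, mixing
*raw* moments by the law of total expectation and re-centralising.
Doubling the node count changes the moments by less than 1e-6 relative at
the study conditions; the mixture agrees with a stratified per-node FSP
reference within the homogeneous closure error.

**Numerics.**  All closure systems are integrated with an adaptive
Dormand–Prince 5(4) method compiled in numba (rtol 1e-8, atol 1e-10).
The systems are small (5–9 states) and non-stiff in the parameter ranges
of interest, and one integration over the 30-point grid costs ~0.1 ms,
which is what makes global optimisation and MCMC affordable.  Pathological
parameter combinations (encountered by the global optimiser, or genuinely
divergent closures — the 3MA blows up in finite time at strong feedback,
a known failure mode of cumulant truncations) hit a step-count cap or
produce negative variances; such evaluations are flagged and treated as
infinite-penalty by the likelihood rather than clipped.

## Likelihood and weights

With many cells, sample moments are asymptotically Gaussian around the
master-equation moments, and snapshot independence factorises the
likelihood over time points and moment orders.  Maximising it is
minimising

    chi^2(theta) = sum_k sum_l (mu_hat_k(t_l) - mu_tilde_k(t_l, theta))^2 / sigma_k^2(t_l).

`sampling_variances` provides the exact statistical quantities:
`sigma_1^2 = mu_2/N`, `sigma_2^2 = (mu_4 - (N-3)/(N-1) mu_2^2)/N`,
`sigma_3^2 = (mu_6 - mu_3^2)/N` (the last a leading-order expression).
For infinite-sample data the common 1/N drops; the argmin is unchanged.

For the *fitting objective* two weight conventions are supported.  The
default, `variance-matched`, replaces the first-moment weight by
`mu_2^2 / N`, making the mean and variance terms enter on a common
(relative) scale — with the exact sampling variance the mean term carries
a weight `~mu_2` times larger, and the fit is almost entirely
mean-driven.  The choice matters: the two conventions land at different
points along the sloppy directions of biased closures (the benchmark
numbers in this package are defined under `variance-matched`).  The
`sampling` convention (exact CLT weights) remains available, and is what
the independence diagnostic below uses.

Identifiability: `rho_u` and `b` enter the mean dynamics only through
their product (the mean production flux is `rho_u * b * <y>`), so a
mean-only likelihood cannot separate them — the profile along
`rho_u * b = const` is exactly flat for the LNA.  The variance depends on
`E[m^2] = 2b^2 + b` and breaks the ridge, which is why at least two moment
orders are required.

## Estimators

**MLE.**  `chi^2` is minimised over `ln(theta)` (positivity by
construction) with scipy's differential evolution: population `15 * p`,
up to 400 generations, vectorised objective (the whole population is
evaluated in one compiled call), followed by an L-BFGS-B polish.
Deterministic for a fixed `random_state`; independent seeds agree to
better than 0.1% at the benchmark conditions.  The search box defaults to
one decade either side of a caller-supplied centre (the generating
parameters, in a synthetic study — the analogue of a wide prior).  The box
width is deliberate: under the variance-matched weighting the large-burst
benchmark develops a spurious distant basin (a slow-timescale parameter
combination reproducing the variance trajectory) beyond ~1.5 decades, which
a two-decade box lets a global optimiser find.

**MCMC.**  Adaptive Metropolis in `ln(theta)` under a uniform prior on the
box.  The proposal is `N(0, lambda^2 (2.38^2/p) Sigma)` with `Sigma`
re-estimated every 500 iterations from the most recent half of the chain
and the scalar `lambda` tuned toward 25% acceptance on a diminishing
schedule (vanishing adaptation, so the ergodic limit is unaffected).
Four chains by default, first half discarded as burn-in, convergence
summarised by split-R-hat (threshold 1.1; at the benchmark conditions the
chains reach R-hat < 1.01).  The MAP point estimate is the sample with the
highest Gaussian-KDE density in log space over a thinned subsample
(default 4000 draws); per-parameter marginal KDE modes are reported
alongside, since for skewed posteriors joint and marginal modes differ.
Under a flattened likelihood the sampler reproduces the uniform prior box
(checked in the test suite), and with 10^5-cell data the MAP and the MLE
agree to better than 1% per parameter.

## Error metrics and benchmark drivers

Fractional errors per parameter: `FE_MLE-MAP = |MLE - MAP| / MAP`,
`FE_MAP-True` and `FE_MLE-True` analogously against the generating values;
"mean FE" is their arithmetic average over parameters (x100 as percent).

The mean–variance independence diagnostic uses the exact small-sample
identity `cov(mu_hat_1, mu_hat_2) = mu_3 / N`:
`rho(t_l) = mu_hat_3 / (N sigma_1 sigma_2)` with the exact sampling
standard deviations, averaged over the grid (`Lambda`).  At the reference
conditions `Lambda ~ -0.05`: the transient protein distribution is nearly
symmetric, so treating mean and variance as independent in the likelihood
is a mild approximation.  The formula is validated against the bootstrap
correlation of (sample mean, sample variance) in the test suite.

Benchmark drivers assemble the study designs: `run_closure_benchmark`
(several closures against common FSP or SSA data),
`run_sweep` (systematic error over a `(sigma_b, b, rho_u)` grid on FSP
data; per-cell failures are recorded and the sweep continues), and
`run_heterogeneity_study` (six-parameter fits on lognormal mixtures).

## Problem sizes

The test suite and the acceptance script run at sizes chosen to keep a full
reproduction on a single core comfortable while leaving every conclusion
stable across seeds: populations of 10^4–10^5 cells (flow-cytometry scale),
30 time points, 10 replicate samples for the moment-order comparison, four
MCMC chains of 4–6 x 10^4 iterations, 8
quadrature nodes inside heterogeneous fits (20 for reported predictions),
and 3 x 3 parameter subgrids for the sweep trends.

## Known limitations

- The 3MA and DM can diverge in finite time at strong feedback
  (`sigma_b * <n>` comparable to `d`) or large bursts; the package flags
  rather than repairs such trajectories, and fits with these closures in
  those regimes converge to whatever biased optimum the penalty landscape
  leaves — at `b = 10` the 3MA fit is sensitive to the optimiser seed.
- The LMA drops protein consumption by binding; at very strong feedback
  with few proteins this approximation degrades.
- Sampling variances for the third moment use the leading-order formula;
  at small N it understates the true sampling noise.
- The snapshot-independence likelihood ignores the (small but nonzero)
  mean–variance sampling covariance; `Lambda` quantifies the residue.
- Heterogeneity is restricted to the production rate; spreading other
  parameters, or time-varying rates within a cell, are out of scope.
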