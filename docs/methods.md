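# Methods

## Elimination-curve model

The concentration of each analyte after bolus injection is modelled as
`x(t) = t·exp(B − A·t)`: a linear rise out of the origin, a single peak,
then exponential decay. It is the solution of
`dx/dt = (1 − A·t)·exp(B − A·t)` with `x(0) = 0`. The model is
deliberately empirical — a two-parameter peaked curve, not a
compartmental absorption/elimination mechanism — and dose never enters
it; only the shape of the blood time course is fitted.

Derived quantities are computed in closed form:

- `t_peak = 1/A` (the stationary point of x);
- `x_peak = exp(B−1)/A`;
- `t_1/2`: the unique root of `x(t) = x_peak/2` beyond the peak, found
  by Brent's method on `[t_peak, t_peak + 60/A]` (absolute tolerance
  1e-10 h), minus `t_peak`. Since `A·t` rescales time, `A·t_1/2` is a
  universal constant (≈ 1.67835), independent of both parameters;
- decay-phase AUC: the antiderivative
  `exp(B)·[−(t/A + 1/A²)·exp(−A·t)]` evaluated from `t_peak` to the last
  scheduled sampling time (6 h). Adaptive quadrature serves as an
  independent oracle in the tests, not as the runtime path.

Units are fixed throughout: hours for time, ng/ml for concentration,
ng·h/ml for AUC.

## Least-squares fitting

Each replicate (animal × analyte) is fitted independently by minimizing
the residual sum of squares on the linear concentration scale. Under the
additive-Gaussian noise model this is the σ-profiled maximum-likelihood
estimate, which keeps the frequentist and Bayesian paths consistent.
Implementation choices:

- bounded trust-region least squares with box `[1e-6, 100]²` for (A, B),
  the same box as the Bayesian prior;
- multistart: a data-driven initial guess (terminal slope of `ln(c/t)`
  for A₀, clamped to [0.05, 50]; B₀ through the observed maximum) plus
  four seeded perturbations; the lowest-SSE solution wins, so the fit is
  deterministic given data and seed. The objective is benign, but
  bimodality under heavy noise is cheap to guard against;
- the pre-dose (t = 0) sample is retained — the model passes through the
  origin, so it contributes nothing to the fit — while post-dose values
  below the limit of quantification (10 ng/ml for caffeine, 1 ng/ml
  otherwise) are dropped: a censored value carries no calibrated
  magnitude, and three quantifiable post-dose points are required.

`PKCurveModel` exposes this as a scikit-learn regressor (get/set params,
clone, `predict`), so it composes with sklearn model-selection tooling.

## Pooled Bayesian inference

All replicates of one condition share a single (A, B, σ); the likelihood
is the product of normal densities over replicates and time points.
Priors are uniform: [0, 100] for A and B, [0, 1000] for σ. The sampler
is an adaptive parallel-tempering Metropolis scheme written for this
package:

- geometric inverse-temperature ladder from 1 down to 0.1 across 4
  chains (the likelihood is tempered, the prior is not);
- per-chain Gaussian random-walk proposals; the proposal scale adapts by
  a Robbins–Monro recursion toward 23.4 % acceptance during the first
  quarter of the run only, so detailed balance holds for the retained
  portion;
- adjacent-rung swap proposals every 100 iterations, hottest pair first;
- chains start at the pooled least-squares estimate (jittered per rung)
  with a residual-based σ, which shortens burn-in without affecting the
  stationary distribution;
- only the cold chain is kept. Default budget is 20,000 samples — enough
  for the ~2–3 effective digits these posteriors need — with the
  study-scale 200,000 available via `n_samples`.

Burn-in is cut by the Geweke stationarity test with a floor of 100
samples: candidate cut points are scanned on a coarse grid from the
floor to half the chain; at each cut the z-score compares the means of
the leading 10 % and trailing 50 % of the remaining chain (conventional
window fractions), and the first cut with |z| < 2 for every parameter is
taken, so an already-stationary chain returns exactly the floor. The
variance and autocorrelation time entering the standard errors are
estimated from the trailing segment only; estimating them from the
leading segment would let a level shift inflate its own standard error
and mask itself. If no cut passes, half the chain is discarded with a
warning.

Effective sample size uses `N / (1 + 2·Σρ_t)` with Geyer's
initial-positive-sequence truncation of the autocorrelation sum
(pairwise sums accumulated while positive), capped at N, computed per
parameter; constant chains are rejected as undefined.

Posterior-predictive bands simulate `x(t; A_i, B_i)` for every retained
draw over a time grid; the band is the pointwise equal-tailed percentile
envelope (2.5/97.5 for the 95 % level — equal-tailed, not HPD) and the
center the pointwise mean. By default the band covers the noise-free
model output; `include_noise=True` adds a per-draw σ_i Gaussian draw for
a predictive band of new observations. Two conditions are compared by
closed-interval overlap of their bands at a time point (closed: a shared
endpoint counts as overlap, the conservative significance call).

## Group and correlation statistics

Ordinary (equal-variance) one-way ANOVA and Tukey's HSD come from scipy;
Pearson r uses Fisher-z 95 % confidence intervals and a two-tailed t
test (n − 2 df). Correlation strength is classed on |r|: ≥ 0.7 strong,
[0.5, 0.7) moderate, [0.3, 0.5) fair, < 0.3 negligible — boundaries
closed at the lower edge. The correlation matrix adjusts all
off-diagonal p values jointly by Benjamini–Hochberg (statsmodels
`fdr_bh`) and annotates stars at 0.05/0.01/0.001. Zero-variance features
are excluded with a warning rather than propagating NaNs.

## Steatosis quantification

Slide tiles labelled micro/macro/non-steatotic/lumen (the upstream
machine-learning classifier is out of scope; the generator emulates its
output) are aggregated into surface percentages over non-lumen tiles,
requiring ≥ 30 tiles per image. Severity grading is < 33 % mild, 33–66 %
moderate (both boundaries inclusive, the literal reading of the printed
convention), > 66 % severe. The micro:macro ratio is rounded half-up to
one decimal to match the "x.y : 1" printing convention — note that
recomputing it from already-rounded group means need not reproduce a
ratio computed on unrounded data. Per-animal severity averages the four
liver lobes weighted by lobe surface area; an unweighted mode exists
because the averaging convention admits either reading.

## Synthetic-data generator

The generator defines the study conditions for every test:

- **Sampling design:** ten scheduled times over six hours (0, 0.25, 0.5,
  1, 1.5, 2, 2.5, 3, 4, 6 h); three groups (control, 2- and 4-week
  high-fat diet); default n = 6 animals per group; three analytes.
- **Features:** truncated normals within valid ranges (percentages in
  [0, 100], TG and CYP activities positive), calibrated to the published
  group summaries — lipid droplets 9.3 ± 1.3 % (2 wk) and 13.9 ± 2.7 %
  (4 wk); micro 48.6 ± 12.9 vs 33.4 ± 10.2 %; macro 20.7 ± 7.1 vs
  39.9 ± 8.6 %; TG 99.6 ± 42.3, 252.8 ± 43.0, 296.1 ± 91.6 nmol/100 mg.
  The underlying location of each truncated normal is solved so the
  truncated mean equals the target (scale kept at the target SD): with a
  naive parameterization the zero floor would bias e.g. control TG by
  ≈ 0.37 nmol/100 mg. Control steatosis surfaces default to 1 ± 0.5 %
  (no published control surfaces; small positive values avoid degenerate
  zero-variance columns). CYP activities have no published group means,
  so the defaults (e.g. CYP3A 80/65/55, CYP1A 120/100/70, CYP2E1
  50/75/95 pmol·min⁻¹·mg⁻¹) are the package's own plausible choices that
  reproduce the reported direction of the diet effects. An optional
  Gaussian copula (user-supplied positive-definite correlation matrix)
  induces cross-feature association within groups.
- **Time courses:** model value at each scheduled time plus additive
  N(0, σ²) noise, clamped at zero, pre-dose exactly zero, sub-LOQ values
  flagged. Per-analyte σ is set to ~10 % CV at the control peak (no
  published value). Group-specific (A, B) encode the reported direction
  of effects (caffeine elimination faster under microvesicular
  steatosis, midazolam slower under macrovesicular), with all peaks in
  the 15–60 min window.
- **Tiles:** multinomial labels at the requested surface shares plus a
  configurable lumen fraction.

What the generator does *not* emulate: between-animal PK variability
(one (A, B) per condition), within-animal correlation between features
and PK outcomes unless a copula is supplied, assay drift, and — notably —
the interaction between noise clamping and the Gaussian likelihood: for
curves that approach zero within the sampling window, clamping censors
the noise and the uncensored Gaussian model is then mildly misspecified
(visible as slight undercoverage of credible intervals). Passing tests
therefore demonstrate correctness of the machinery under the stated
noise model, not robustness to real-data artefacts.

## Problem sizes and numerical choices

The test suite and acceptance script run everything at desk scale as the
package's own defaults: 20,000 MCMC samples per run (coverage checked
over 100 seeded runs), 100,000 animals per group for generator
calibration (accepted within 3 Monte-Carlo SEs), 500 repetitions for the
false-discovery null simulation, 20,000 permutations for the
studentized-range oracle. Optimizer tolerances are 1e-14 (ftol/xtol/gtol)
for curve fits, 1e-10 h for root brackets, 1e-12 for the quadrature
oracle. All random streams are `numpy.random.default_rng` with explicit
seeds; reruns are bit-identical.

## Known limitations

- The Geweke z-test at the 100-sample floor has the usual ~5 % false
  alarm rate per scan point; an unlucky stationary chain can receive a
  larger cut than necessary (harmless, some samples are wasted).
- The half-life bracket `[t_peak, t_peak + 60/A]` is generous but
  finite; it cannot fail for parameters in the prior box.
- Credible-interval coverage assumes the generating process matches the
  likelihood (see the clamping caveat above).
- The Tukey comparison relies on scipy's studentized-range
  implementation; the package does not attempt bit-parity with GraphPad
  Prism.
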