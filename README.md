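# steatopk

Pharmacokinetic and statistical analysis pipeline for a drug-cocktail
study in a mouse model of periportal hepatic steatosis. A high-fat,
methionine/choline-reduced diet (2 or 4 weeks) induces micro- and
macrovesicular steatosis; the study asks whether this alters the activity
of pericentral drug-metabolizing CYP enzymes, probed in vivo by a bolus
cocktail of caffeine (CYP1A2), midazolam (CYP3A4) and codeine (CYP2D6)
with micro-blood sampling at ten scheduled time points over six hours.

The package is aimed at PK/systems-biology analysts who want the whole
analysis — curve fitting, Bayesian uncertainty quantification, group and
correlation statistics, steatosis quantification — as tested, reusable,
seed-reproducible code driven by a calibrated synthetic-data generator
(no animal data required).

## The model

Each blood concentration time course is described by the single-peak
elimination curve

    x(t) = t · e^(B − A·t),        dx/dt = (1 − A·t) · e^(B − A·t)

with rate parameter *A* (1/h) and log-amplitude *B*. Derived quantities
have closed forms: t_peak = 1/A, x_peak = e^(B−1)/A, the half-life t_1/2
(peak to half-peak, ≈1.6784/A) and the decay-phase AUC ∫ x dt from
t_peak to 6 h.

Two estimation paths share one noise model (additive Gaussian, SD σ):

- **Per-replicate least squares** (`PKCurveModel`, a scikit-learn
  regressor; `fit_replicate` / `derive_pk` wrappers) — bounded
  multistart trust-region minimization of Σ (x(t_k) − c_k)².
- **Pooled Bayesian inference** (`sample_posterior`, `BayesianPKModel`) —
  all replicates of one condition share (A, B, σ) with uniform priors
  A, B ∈ [0, 100], σ ∈ [0, 1000], sampled by adaptive parallel-tempering
  MCMC (4 chains, geometric temperature ladder). Burn-in is cut by the
  Geweke test (≥ 100 samples), mixing checked by effective sample size,
  and posterior-predictive 95 % credibility bands are compared between
  conditions by interval overlap at each time point.

Downstream, `one_way_anova` / `tukey_hsd` test diet effects,
`pearson_with_ci` / `correlation_matrix` quantify steatosis–CYP
associations with Benjamini–Hochberg adjustment, and the `steatosis`
module aggregates classified slide tiles into surface percentages with
clinical severity grading (< 33 % mild, 33–66 % moderate, > 66 % severe).

## Worked example

```python
>>> import steatopk as sp
>>> params, series = sp.fixture_fig10()   # control codeine-6-glucuronide replicate
>>> fit = sp.fit_replicate(series)
>>> round(fit.params.A, 3), round(fit.params.B, 3)
(2.168, 5.397)
>>> d = sp.derive_pk(series)
>>> print(f"t_peak={d.t_peak:.3f} h  x_peak={d.x_peak:.2f} ng/ml  "
...       f"t_half={d.t_half:.3f} h  AUC={d.auc:.2f} ng·h/ml")
t_peak=0.461 h  x_peak=37.46 ng/ml  t_half=0.774 h  AUC=34.55 ng·h/ml
```

The curve peaks at 0.461 h (= 1/A) at 37.46 ng/ml, falls to half the
peak 0.774 h later, and the decay phase from the peak to the last
sampling time (6 h) encloses 34.55 ng·h/ml of drug exposure.

The same pipeline runs from the shell:

```sh
steatopk simulate --seed 1 --n-per-group 6 --out-dir run/
steatopk fit run/timecourses.csv --out run/pk_derived.csv
steatopk bayes run/timecourses.csv --out-dir run/posteriors/
steatopk stats run/features.csv --out-dir run/
steatopk report run/pk_derived.csv run/features.csv --out run/report.json
```

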