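# Methods

This note records the statistical model behind passclock, the defaults
and why they were chosen, what the simulator does and does not emulate,
and the numerical choices that affect reproducibility.

## Data model

The substrate is a probe-by-sample matrix of methylation fractions
`β = M/(M + U + offset)` with `offset = 100` (the platform-standard
stabiliser, exposed as a flag). Inputs are assumed to be
background-corrected upstream (e.g. Noob); passclock deliberately does
not re-implement array normalisation, dye-bias correction or batch
correction. Missing measurements are empty fields on disk and NaN in
memory, so "not measured" is never conflated with `β = 0`.

Probe-level quality gates: a probe is removed when its detection
p-value exceeds 0.01 in *any* sample (strictest reading; a `mean` rule
is exposed for reproduction studies), when it appears on a
user-supplied cross-hybridising blocklist (one ID per line; published
blocklists are not bundled), or when any value is missing. Filters act
on probes only, never samples, and are idempotent and mutually
commutative — properties the test suite asserts.

## Screening drifting CpGs

Each probe is regressed on passage by OLS (`β ~ a + b·p`); the
two-sided t-test of the slope (df = n − 2) gives the screening
p-value. For a single covariate this is identical to the F-test of the
per-probe linear model used by standard differential-methylation
position finders, and it admits a closed-form oracle. Regression is on
the β scale (no M-value/logit transform), matching how the clock is
trained and how drift magnitudes are calibrated. No donor or cell-type
covariates enter the per-probe model.

Numerical conventions: an exactly linear probe (residual RMS below
1e-12 β units) is flagged and assigned `p = 0` with `t = ±inf`, so
ordering stays deterministic instead of depending on underflow; an
exactly constant probe carries no drift evidence and gets
`t = 0, p = 1`. Screened results are ordered by p-value with probe ID
as the tie-break.

The screening threshold defaults to τ = 1e-11. `select_threshold_loo`
can choose τ from a grid (default `1e-5 … 1e-13`) by leave-one-out
validation: for each candidate and each held-out sample the screen and
the clock are refit from scratch and the held-out passage predicted;
the τ with the lowest LOO RMSE wins, ties breaking toward the most
stringent candidate. RMSE of predicted passage is used as the
criterion because it is the clock's own headline metric; a candidate
that yields an empty screened set in any fold is marked infeasible
(infinite RMSE) rather than fatal.

## The elastic-net clock

The clock minimises

    (1/2n) Σᵢ (pᵢ − w₀ − xᵢᵀw)² + λ·[ α‖w‖₁ + ((1−α)/2)‖w‖₂² ]

with mixing α = 0.5. Predictors are standardised to mean 0/variance 1
over the full training set; reported coefficients are mapped back to
the β scale, and the intercept is unpenalised. The λ grid is
auto-generated: 100 log-spaced values descending from
`λ_max = max_j |x_jᵀ(y − ȳ)|/(n·α)` (the smallest penalty that zeroes
every coefficient) down to `1e-4·λ_max`. λ is selected by seeded
k-fold cross-validation (default 10 folds) minimising mean squared
prediction error; folds are assigned by dealing the seed-shuffled
members of each passage level round-robin, keeping folds
passage-balanced at small n. A one-standard-error selection rule is
exposed as an alternative; the choice is recorded in the model's
training metadata. Fold scoring uses scikit-learn's coordinate-descent
path at a loose tolerance (1e-4) — ample for comparing fold MSEs — and
the final refit at the selected λ runs at tolerance 1e-12. The solver
is cross-checked in the tests against an independently written cyclic
coordinate descent via objective values and KKT subgradient residuals.

Prediction is the affine map `p̂ = w₀ + Σ wⱼ βⱼ`. A clock probe that is
absent or missing-valued at prediction time is a hard error — silent
imputation would mask platform mismatches. Constant predictor columns
are dropped with a warning at fit time.

Evaluation reports RMSE and Spearman's rank correlation (average-rank
ties, asymptotic p-value); a constant prediction vector sets an
undefined-ρ flag rather than returning a misleading coefficient.

## Deceleration readout

For each sample with known passage, `Δ = p̂ − p`. The cohort comparison
groups Δ by passage level (or by equal-width cumulative-PD bins when
population-doubling data are the more faithful time axis) and reports,
per level where both cohorts are present, the cohort means and the
effect `mean Δ(treated) − mean Δ(control)`; the overall effect is the
unweighted mean of per-level effects, with a standard error pooled
from per-sample Δ variances (`sqrt(var_t/n_t + var_c/n_c)`). The
pipeline's verdict is a two-standard-error call on the overall effect:
clearly negative → "decelerated", clearly positive → "accelerated",
otherwise "no effect".

## Screening statistics

Robust Z uses the control median and the *unscaled* MAD
(`median(|x − median(x)|)`; no 1.4826 consistency factor) — the formula
as used in high-content screening practice. Calls at cutoff 0.5 are
polarity-aware: p16, p21, SA-β-Gal, IL-6 and the morphometric areas
increase with senescence, nucleolin signal decreases; a panel table
ships with these defaults. Zero control MAD is an error naming the
marker. Population doublings use the literal constant 0.6931 (an
`exact_ln2` flag switches to ln 2); the `seeded/2` reference encodes
the convention that about half the seeded cells reattach, making
`final = seeded/2` the exact fixed point `PD = −1`.

## The simulator

`passclock.simulate` emulates the serially passaged study design that
motivates the toolkit:

* **Design.** Two default cohorts: 39 training samples (six each at
  P10/12/14, seven each at P16/18/20) and 26 held-out samples spread
  over P9–P20 weighted toward late passages. Drug arms are profiled at
  P16/18/20 (six per passage); immortalised arms span P10–P20.
* **Background.** 10,000 probes by default, of which all but the
  drifters are static, with baselines drawn from a bimodal mixture
  (Beta(5,45) and Beta(45,5) modes near 0.1 and 0.9, equal weight) —
  the familiar two-humped methylome.
* **Drifters.** 23 hypomethylating + 19 hypermethylating CpGs plus 18
  extra drifters of random direction (60 total). Slopes are
  `±drift_total/10` jittered ±20% (uniform), so the mean absolute
  change between P10 and P20 is calibrated to `drift_total = 0.2`.
  Hypomethylating probes start in the methylated regime (baseline
  uniform 0.60–0.85), hypermethylating ones in the unmethylated regime
  (0.15–0.40): drift moves CpGs away from established methylation
  states, which also keeps trajectories clear of the [0.01, 0.99]
  clipping bounds.
* **Noise.** Observations are `Beta(μκ, (1−μ)κ)` with precision
  κ = 200 (SD ≈ 0.035 at β = 0.5, comparable to array replicate
  noise). Beta noise keeps draws inside [0,1] without clipping
  artefacts. κ has no measured counterpart and is documented as a free
  parameter.
* **Treatment.** Deceleration compresses effective passage:
  `p_eff = p₀ + (p − p₀)(1 − d)` from onset p₀ — a cumulative slowing
  that grows with treatment duration, not a constant offset.
  Immortalisation multiplies drift by a residual rate r beyond a
  breakpoint m (`p_eff → m + (p_eff − m)·r`), so r = 1 reproduces a
  control trajectory and r = 0 freezes ageing at m.
* **Determinism.** One `numpy` generator seeded from the config; the
  same config and seed reproduce byte-identical TSV/CSV/JSON outputs.

What the simulator does *not* emulate: probe-type chemistry
differences, batch/chip effects, donor heterogeneity (available as an
off-by-default baseline-offset option), detection-p structure, or raw
intensities. Tests that pass on simulated cohorts therefore establish
that the pipeline recovers known structure under idealised array-like
noise — not that any particular real dataset will reach the same
accuracy.

## Problem sizes and seeds

Unit tests run on scaled-down designs (a few hundred probes); the
acceptance tests and `scripts/acceptance.py` use the full default
design (10,000 probes, 65–75 samples per scenario), which completes in
seconds. The acceptance script derives all stage seeds from its
`--seed` argument through counter-keyed seed sequences, so any single
stage can be reproduced in isolation.

## Known limitations

* The per-probe screen at τ = 1e-11 has, by construction, borderline
  power for the weakest drifters: a slope at the −20% jitter edge has
  an expected p-value within one t-statistic standard deviation of the
  threshold, so exhaustive recovery of every drifting CpG in a single
  seeded run is not guaranteed — a property of the stringent-threshold
  design itself, visible in the test suite.
* Clock weights are only identified on the training β scale; applying
  a clock across platforms or preprocessing pipelines requires the
  same scale and probe set (hence the hard missing-probe error).
* The cohort comparison assumes cohorts share the passage (or
  cumulative-PD) axis; levels present in only one cohort are excluded
  rather than extrapolated.
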