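# Methods

## Model and measurement structure

The package analyses constant-load creep tests on isolated cell-wall
specimens. Its generative and inferential model is a Lockhart-type linear
law for the relative creep rate,

    rate = φ · max(0, σ − y)    [% h⁻¹],

with extensibility φ (% h⁻¹ MPa⁻¹) and yield threshold y (MPa). The
`max(0, ·)` keeps sub-threshold specimens at zero expected creep rather than
negative creep, which is the physical meaning of a yield threshold;
specimen-level noise added on top of the rate may still produce small
negative observed rates, as real traces do.

Wall stress is never measured directly. It is derived from segment dry mass
m (µg) via the cross-section area of the wall material,

    A = m / (ρ · l),   σ = F / A,   F = m_load · g,

with assumed wall density ρ = 1.5 g cm⁻³, segment length l = 5 mm and
g = 9.80665 m s⁻². Units are handled exactly (µg, mm, g cm⁻³ → µm²;
N/µm² → MPa); rounding happens only in report tables. ρ is exposed as a
configuration parameter because it is an assumption, not a measurement.

Because the stress sample (n = 4 dry-mass replicates) and the creep-rate
sample (n ≈ 10 specimens per load) come from different material, two
complementary analyses are provided.

## Bootstrap creep-rate × stress⁻¹

Each bootstrap replicate draws `resample_size` values with replacement from
the rate pool and, independently, from the stress pool, and forms the ratio
of the resample means (default; a mean-of-pointwise-ratios variant is
available). The estimate is the mean over `n_boot = 10,000` replicates and
its spread the SD. The default resample size is 4 on both axes — the size
of the stress pool.

Between-group contrasts use t = (m₁ − m₂)/√(sd₁² + sd₂²): the bootstrap SD
estimates the standard error of each group's ratio estimate, so it enters
the denominator un-divided by √n_boot (dividing by √n_boot would declare any
two groups different at n_boot = 10⁴ and would break the null-experiment
property that identical generating scenarios produce no significant
contrasts). Degrees of freedom follow Welch–Satterthwaite with the bootstrap
replicate counts, which at equal n_boot is effectively normal. Raw p-values
are adjusted by Benjamini–Hochberg step-up across all contrasts in a batch
(`statsmodels.stats.multitest`), flagging discoveries at FDR 5%. Because the
resample size (4) is smaller than the rate pool (10), the bootstrap SD
slightly over-states the standard error of the full-sample estimate; the
contrasts are accordingly conservative, which the global-null test in the
suite confirms.

In the pipeline, bootstrap streams are seeded per *condition* (load, pH,
inactivation) but not per group, so paired groups share resampling draws
(common random numbers): identical input data yield exactly identical
estimates and exactly-zero contrasts.

## Errors-in-both-variables line fit (MLFR)

The rate-vs-stress line is fitted by maximising the functional-relationship
likelihood, i.e. minimising

    Σᵢ [(yᵢ − α − βξᵢ)²/σ²_{y,i} + (xᵢ − ξᵢ)²/σ²_{x,i}]

over (α, β) and the latent true stresses ξᵢ, with error SDs proportional to
the supplied standard errors of each point (stress SE = SD/√4 of the mass
replicates; rate SE = SD/√n of the specimens). Each ξᵢ has the closed-form
optimum ξᵢ = (β(yᵢ−α)σ²ₓ + xᵢσ²ᵧ)/(β²σ²ₓ + σ²ᵧ), collapsing the objective
to R(α, β) = Σᵢ(yᵢ − α − βxᵢ)²/(σ²ᵧᵢ + β²σ²ₓᵢ); α is then profiled as a
weighted mean, leaving a 1-D problem in β. The solver scans a 512-point
bracket spanning the OLS(y|x) and 1/OLS(x|y) slopes and refines the root of
the analytic derivative dR/dβ by Brent's method to machine precision — the
precision matters because the estimator's axis-symmetry (swap x and y,
slopes are mutual reciprocals, and the x-intercept of one orientation is
the intercept of the other) is verified to 1e-8 relative tolerance in the
diagnostics. Per-point weighting λᵢ = (σᵧᵢ/σₓᵢ)² is the default; a pooled-λ
option reproduces classical Deming regression (and its closed-form slope,
used as a cross-check in the tests). If every SE is zero the fit falls back
to unweighted Deming (λ = 1) and says so in `lambda_weighting`.

φ is the slope; y is −α/β, which by the symmetry property equals the
intercept obtained by regressing stress on rate. Standard errors for both
are leave-one-out jackknife over the N load points:
SE = √[((N−1)/N)·Σ(θ₍ᵢ₎ − θ̄)²]. Slope significance is a two-tailed t-test
on N − p − 1 = N − 2 df (N = 4 loads ⇒ 2 df); when p ≥ 0.05 the report
prints φ and y as ND (not determined), since an x-intercept of a
non-significant line is not interpretable. Two fitted lines are compared by
t = (coef₁ − coef₂)/√(0.5(σ₁² + σ₂²)) on df₁ + df₂ df, where σ are the
jackknife SEs. The pipeline computes these comparisons for every
condition-matched group pair with defined SEs and flags `nd_either` when
either fit is ND, rather than suppressing the comparison: at N = 4 the
2-df slope test is conservative, and the between-model question (is φ
different?) is distinct from the within-model one (is φ nonzero?).

## Creep-rate extraction

The relative creep rate of a specimen is the OLS slope of relative extension
(% of initial length) versus time, converted to % h⁻¹, over a configurable
window — by default the final 10 minutes of a 15-minute test, excluding the
early viscoelastic transient after load application. The endpoint-difference
alternative is deliberately not used: a regression slope uses every sample
and is far less sensitive to single-point noise. R² of the fit is recorded;
specimens below a configurable R² floor (default 0, i.e. no filtering) are
flagged, never dropped, because no exclusion rule is part of the protocol.
A perfectly flat trace is reported as rate 0 with R² = 1 (a flat line fits
it perfectly), so heat-inactivated-like specimens are not flagged spuriously.

## Synthetic-data generator

`synthetic.SimulationScenario` emulates the study design: 4 loads
(400–700 mg), 10 creep specimens per load, 4 dry-mass replicates per group,
15-min traces sampled at 1 s, a 1% instantaneous elastic jump at load
application. Group defaults are control φ = 0.80 % h⁻¹ MPa⁻¹,
y = 15.23 MPa, dry mass 1.52 ± 0.11 µg, and treated (`ebl_scenario`)
φ = 0.31, y = 5.42, dry mass 2.30 ± 0.13 µg. Noise enters at three points:

- **Dry mass**: Gaussian truncated at zero (rejection sampling). At the
  realistic CV of ~7% the truncation is numerically negligible; it exists
  to guarantee physical positivity for any parameter choice.
- **Creep rate**: one Gaussian draw per specimen (between-specimen SD
  `creep_rate_noise_sd`), not per time point, matching the
  between-specimen SE structure of replicated creep tests. The default,
  1.5 % h⁻¹ for the control (0.75 for the treated group), was chosen once
  so that group SEs at n = 10 are ≈ 0.5 (0.25) % h⁻¹, the rate-mean noise
  level used by the recovery analyses; no numeric within-group scatter is
  available to calibrate against more directly.
- **Trace samples**: optional small per-point jitter (`point_noise_sd`,
  default 0) for exercising the rate-extraction regression.

The generator reproduces the *statistical* structure of the measurements,
not their physics: no polymer/microfibril mechanics, no pH kinetics of
wall-loosening proteins, no drift or autocorrelation within traces.
Passing recovery tests therefore demonstrate that the estimators are
consistent and well-calibrated under the assumed noise model, not that the
model captures every feature of real extensometer data.

Determinism: every group's stream derives from its own scenario seed via
`numpy.random.SeedSequence` spawning, so identical scenarios (same seed)
generate byte-identical group tables, and rerunning any configuration
reproduces outputs exactly.

## Numerical and design choices

- g = 9.80665 m s⁻² reproduces the conventional load→force table at the
  tabulated precision (three of the four entries exactly; the 700 mg entry
  is conventionally printed one unit high in its last digit).
- Stress tables default to `per_replicate` mode (stress computed per mass
  replicate, reported mean ± SD), which is what a replicate-level SD
  implies; `mean_mass` mode (stress from the mean mass, SD 0) is provided
  because, by Jensen's inequality on 1/m, the two differ slightly.
- The MLFR solver's derivative root is bracketed by a grid argmin; if the
  bracket shows no sign change (flat or boundary cases) it falls back to
  bounded golden-section minimisation and reports convergence accordingly.
- Zero SEs mixed with non-zero SEs are floored at 1e-14 of the data scale
  to keep the objective finite; all-zero SEs trigger the unweighted
  fallback instead.
- Jackknife refits that turn degenerate (e.g. identical abscissae after
  deletion) make the SEs undefined (NaN) with a warning rather than a
  crash; downstream comparisons then refuse that parameter explicitly.

## Problem sizes in the test suite

Monte-Carlo checks use sizes chosen to make their statistical assertions
stable: 200-replicate ensembles for parameter recovery and interval
coverage, 400 replicates for jackknife-vs-ensemble calibration (the
mean-jackknife/ensemble-SD ratio at N = 4 is noisy below that), 100 seeded
pipeline runs for two-group discrimination (bootstrap scaled to 500
replicates there, since the discrimination statistic does not involve the
bootstrap), and 300 repetitions of a 6-contrast global null for FDR
calibration. The exhaustive bootstrap oracle runs on a reduced instance
(3 rates × 2 stresses, resample size 2) where full enumeration is feasible.

## Known limitations

- With N = 4 loads the slope test has 2 df: true lines with moderate noise
  are regularly ND. This is a property of the design, not the estimator;
  the recovery tests quantify it.
- The jackknife SE at N = 4 is upward-biased by roughly 25–45% relative to
  the ensemble SD under the default noise model; confidence intervals are
  therefore conservative.
- The bootstrap ratio contrast treats the two bootstrap distributions as
  independent summaries; it does not model shared stress replicates across
  loads within a group.
- The creep-rate window (default 300–900 s) is a convention; rates from a
  different window are not comparable across studies without restating it.
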