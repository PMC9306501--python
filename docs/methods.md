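# Methods

## Isotope pool dilution model and estimators

The forward model treats each assayed pool (free amino acids FAA, ammonium,
nitrate) as a single well-mixed compartment over the incubation interval,
with constant (zero-order) gross influx GI and gross efflux GE
(µg N g⁻¹ dm d⁻¹). Influx enters at natural ¹⁵N abundance, so it carries no
excess label; efflux removes N at the pool's current enrichment. Hence

    C(t)   = C₀ + (GI − GE)·t
    dE/dt  = −GE · E / C(t)          (E = excess ¹⁵N amount)

with closed forms APE(t) = APE₀·(C/C₀)^(−GE/(GI−GE)−1) for GI ≠ GE and
APE(t) = APE₀·exp(−GE·t/C₀) for GI = GE. The Kirkham–Bartholomew
estimators are the exact inverse of this model; the test suite verifies the
closed forms against an independent ODE integration (rtol 1e-12) and the
round trip estimator∘simulator to 1e-9 relative over a rate grid.

Numerics: GI is evaluated as L(C₁,C₂)·ln(APE₁/APE₂)/Δt with the logarithmic
mean L = (C₂−C₁)/ln(C₂/C₁) computed via `log1p`, and GE as GI − ΔC/Δt.
Both are algebraically identical to the textbook expressions but keep the
mass-balance identity GI − GE = ΔC/Δt exact in floating point and remain
stable as C₂ → C₁. When |C₂−C₁|/C₁ < 1e-8 the constant-pool limit
L → (C₁+C₂)/2 is used and the pair is flagged `DEGENERATE_POOL`; the
measured maximum relative jump across that boundary is ~1e-10, far below
assay precision. Non-decreasing enrichment or negative computed rates are
returned unclamped with `NONDECREASING_APE` / `NEGATIVE_RATE` flags —
clamping would bias downstream treatment means. Non-positive atom% excess
raises an undefined-rate error (the table-level estimator converts this to
a NaN row flagged `UNDEFINED_RATE`).

Parameter conventions: the background atom%¹⁵N defaults to 0.3663 (the
atmospheric N₂ reference) and is configurable per run, since laboratories
may prefer a measured soil background. Tracer dosing plans 20% of the
native pool at 96–98 atom% (default 97); incubation stop times default to
15/60 min for FAA and 4/24 h for the inorganic pools. The residence-time
pool size defaults to the mean of the two timepoint concentrations
(symmetric to the (GI+GE)/2 flux average) and is configurable to the t₁,
t₂, or pre-tracer native pool; the validation metrics use the native basis,
matching how an assayed amino-acid content (measured before tracer
addition) enters the calculation in practice.

## Assay calibration chain

Raw fluorimetric signals become dry-mass pool concentrations through a
fixed, documented order: blank subtraction → ammonium-fluorescence
interference correction (signal − NH₄ concentration × response slope,
floored at zero with a QC flag) → quench correction (division by the
spike-standard recovery) → inverse prediction on the OLS calibration line
(≥ 3 distinct standards) → extract-to-soil mass balance
(conc × volume / dry mass, dry mass = fresh mass / fw:dw ratio). The NH₄⁺
response slope is a per-batch calibration input, never a constant, and the
quench correction uses the recovery-ratio form (a regression-based form
would need multiple spike levels, which the single-spike protocol does not
provide). Spike recoveries outside (0.5, 1.5) carry a QC warning.

## Experimental layout

The facility is a 3 × 3 warming (0/+1.5/+3.0 °C) × CO₂ (0/+150/+300 ppm)
response surface realizing 7 of 9 combinations over 54 plots; 34 plots are
sampled, with per-combination replication between 2 and 8; a summer drought
is imposed on 4 ambient and 3 "future scenario" (+3.0 °C, +300 ppm) plots.
Exact per-combination replicate numbers and the identity of the two
unrealized combinations are not fully constrained by the published totals;
the defaults here (sampled 8/4/4/4/4/4/6; excluded combinations = the
anti-diagonal corners (0, +300) and (+3.0, 0)) are a reconstruction that
satisfies every published count and keeps both drought scenarios on
realized corners. Both are configurable. A consequence of the
reconstruction: the non-drought subset has 27 plots (81 plot × season
observations) and the drought-experiment subset 14 plots (42 observations),
which need not equal the field study's exact subset sizes.

## Synthetic-data generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs. Per plot × season it draws true rates lognormally around
season × treatment means and then produces raw measurements with the exact
forward model plus noise.

* Seasonal FAA pool means 7.9 / 4.1 / 3.7 µg N g⁻¹ dm (May/Jul/Oct) with
  the corresponding observed CVs (≈16/10/13%); ammonium and nitrate pools
  2.5/2.0/1.8 and 4.0/5.0/6.0 µg N g⁻¹ dm (CV 20%), typical for fertilized
  montane grassland topsoil.
* Ambient depolymerization bases 110 / 55 / 45 µg N g⁻¹ dm d⁻¹, chosen so
  that with the printed pool means the May amino-acid residence times fall
  inside the observed 1.04–2.52 h window. Amino-acid consumption is
  0.95 × depolymerization (near steady state over the assay) with a small
  independent lognormal factor (sd 0.08), times a +2.5%-at-+300-ppm CO₂
  multiplier.
* The +3 °C warming multiplier on organic-N rates is season-dependent:
  0.74 (May), 1.00 (Jul), 1.55 (Oct), interpolated geometrically as
  mult^(ΔT/3) across the three levels — the season × temperature
  interaction that the inference chain must detect.
* Drought multiplies depolymerization and consumption by 2.27 (ambient) or
  2.34 (future scenario) at the July peak-drought sampling only, with full
  recovery by October; nitrification doubles under drought; the FAA pool
  rises 15% at peak drought and sits 15% low at the October recovery
  sampling.
* Mineralization is season-invariant at 4.0 µg N g⁻¹ dm d⁻¹ with a mild
  warming decrease (×0.85 at +3 °C under ambient CO₂, attenuated to 1 at
  +300 ppm — a CO₂ × temperature interaction); nitrification rises through
  the season (3.7/4.2/4.5). These keep depolymerization 10–30-fold above
  both inorganic gross rates in every season.
* Biological variability: lognormal plot intercepts (sd 0.12, shared across
  seasons — the source of within-plot correlation) and plot × season
  deviations (sd 0.15). Measurement noise: multiplicative lognormal on
  concentrations (CV 5%) and additive Gaussian on atom%¹⁵N (sd = 2% of the
  value). The true assay CVs are unpublished; these are realistic defaults
  for fluorimetric/IRMS workflows and are exposed in the config.
* Covariates (ANPP, root biomass and turnover, microbial biomass C/N, PLFA
  marker sums, enzyme activities, SWC, total N, δ¹⁵N proxies) are lognormal
  with a plot intercept and a within-plot component drawn conditionally on
  the standardized within-plot deviation of log depolymerization — a
  Gaussian copula on log scales — so the repeated-measures correlations hit
  configured targets (ANPP +0.576 on the warming/CO₂ subset, SWC −0.710 on
  all data, and the remaining signs/magnitudes of the published correlation
  structure). The standardization excludes the drought plots' July spike
  (a treatment effect, not copula scale), and the noise component is
  pre-centered within plots so the centering step of the correlation does
  not inflate the realized values.

What the generator does **not** emulate: within-season dynamics (season is
purely categorical), mechanistic soil-moisture or plant feedbacks
(covariates are statistically, not causally, linked to the rates),
first-order (concentration-dependent) consumption kinetics, assay-specific
artifacts such as incomplete microdiffusion or Strecker interference, and
real spatial layout. Passing tests therefore demonstrate that the
estimators and the inference chain behave correctly under the stated
statistical structure — not that field data satisfy that structure.

All randomness flows from a master seed through named substreams
(`SeedSequence([seed, crc32(stage)])`), so stages are individually
reproducible and toggling one stage does not shift another's stream.

## Statistical inference

**Response-surface GLS.** Fixed effects up to quadratic in the dose levels
(coded 0/1/2 per factor) with season and interactions; residual covariance
within a plot is heterogeneous compound symmetry, Σ = D(σ_season) R(ρ)
D(σ_season), estimated by REML (Nelder–Mead over ρ and log σ, profile over
fixed effects). Responses follow the transform policy: mineralization, FAA
contents, and residence times are log-transformed by default; rates are
analyzed untransformed (overridable). F-tests use a between–within
stratification: terms constant within a plot (CO₂, temperature, their
quadratics and product) are tested by the exact between-stratum OLS F on
unweighted plot season-means (the classic split-plot test — exact for
balanced data regardless of ρ and the season variances, and measured at
nominal level under 1000-run null simulation); season-varying terms use the
Wald F from the REML covariance with containment denominator df
(N − plots − within-parameters), which simulates at nominal level as well.
Backward reduction removes, at each step, the largest-p removable term
above α = 0.05, where removable means no retained higher-order term
implies it (marginality closure includes the polynomial hierarchy:
temp² ⟹ temp, season × temp² ⟹ season × temp and temp²). With k null
candidate terms this procedure ends at exactly the true model with
probability ≈ (1−α)^k — e.g. 0.857 for k = 3 — which the Monte-Carlo test
asserts as a binomial band rather than an arbitrary higher figure.
Degenerate designs are rejected with the aliased columns named (pivoted-QR
diagnostic). Assumption checks (Shapiro–Wilk, Levene) are advisory flags
only; nothing auto-transforms.

**Drought contrasts.** Per season, a two-way ANOVA (climate scenario ×
drought, Type-II SS — identical to Type I/III in the balanced default) with
Tukey–Kramer all-pair contrasts. The compact letter display assigns one
letter per maximal clique of the nonsignificance graph (cliques ordered by
mean response), so two groups share a letter exactly when their adjusted
p ≥ α.

**Repeated-measures correlation.** r_rm is the Pearson correlation of
within-plot centered x and y, identical (to 1e-10 in tests, against both a
linear-algebra ANCOVA oracle and pingouin) to the ANCOVA partial
correlation with subject as a factor; error df = N − k − 1. The parametric
p comes from t(df); the bootstrap p resamples plots with replacement (2000
draws, seeded; two-sided sign criterion on the bootstrap distribution).
The confidence interval uses a Fisher z with se = 1/√(df−1). Plots with
fewer than two complete observations are excluded with a warning; zero
within-plot variance yields a flagged undefined result.

## Pipeline and problem sizes

`run_pipeline` executes design → synth → rates → stats → report into a run
directory with a JSON manifest (stage seeds, config hash, package version);
identical config + seed reproduces identical outputs byte-for-byte. The
validation suite sizes are: a 10 × 11 (GI, GE) inversion grid, 10⁴ random
pairs for the mass-balance identity, 200 Monte-Carlo replicates per pool
condition for noise bias, 1000 null simulations each for the ANOVA and GLS
type-I error, 200 seeded end-to-end runs for detection power, and a
20-fold replicated design (680 plots) for recovering the calibrated effect
percentages; these give Monte-Carlo standard errors comfortably below the
corresponding acceptance bands while keeping the full suite to a few
minutes on one CPU.

## Known limitations

* The REML F-tests are exact only for balanced between-stratum contrasts;
  unbalanced season patterns fall back to containment-df Wald tests, which
  can be mildly liberal.
* The estimators assume zero-order kinetics over the interval; real assays
  with strongly concentration-dependent consumption would need the
  first-order variants, which are out of scope.
* Covariate–rate dependence is calibrated on true rates; correlations
  measured on estimated rates are attenuated by a few percent at the
  default measurement CVs (visible in the acceptance output).
* Incubation temperature is carried as metadata only; rates are whatever
  the generator draws, with no Arrhenius correction.
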