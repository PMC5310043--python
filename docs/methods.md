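# Methods

Models, assumptions, parameters and numerical choices behind `reefcarb`.
Units: carbonate fluxes in kg CaCO₃ m⁻² yr⁻¹; percent covers on the 0–100
scale; fish biomass in kg ha⁻¹.

## 1. Census model

Five CSV tables keyed on `(reef_id, year, site_id)`: sites, benthic visual
cover, line-intercept colony records, parrotfish observations, urchin
observations. Validation is fail-fast and names offending rows: depths
positive, rugosity classes 0–5, covers in [0, 100] with sums ≤ 100, linear
intercept length ≤ surface (rugose) length, no orphan records, no duplicate
keys. Fish biomass uses the allometry *B* = *a·L^b* (g, cm); per-site
functional-group biomass is summed over records and scaled to kg ha⁻¹ by
the census area (default: the 7 m-radius point count, 153.938 m²).

Rate tables (coral growth/density/geometry, parrotfish feeding, length–
weight constants, urchin erosion, endolithic rates) are editable CSV inputs
with documented invariants (growth lo95 ≤ mean ≤ hi95, densities > 0,
scar fractions in [0, 1]). The packaged defaults are synthetic stand-ins
with realistic magnitudes, flagged per row in a `provenance` column.

## 2. Production engine

One colony intercepted by a 10 m line transect contributes

    G = 10 × growth × density × (surface_length / transect_length) × r

with growth in cm yr⁻¹, density in g cm⁻³ and *r* a dimensionless geometry
multiplier; the factor 10 converts g cm⁻² yr⁻¹ to kg m⁻² yr⁻¹. Growth is
selectable as lo95/mean/hi95. Crustose coralline algae contribute through
their own rate per percent planar cover (default 0.0105). Unknown
genus × morphology combinations fall back to a configurable "other coral"
entry (logged) or raise when none exists.

Site production is factorized as **G = L·g** where `L[s, e]` is the
production of site *s* per unit growth rate of rate-table row *e*. The
sensitivity analysis exploits this: thousands of growth-rate draws become a
single matrix product.

**Hindcast.** Years with visual covers only get production from a multiple
regression of census production on the four morphology covers, fitted
*through the origin* on the census year (no coral ⇒ no coral production).
The fit is ordinary least squares via `numpy.linalg.lstsq`; *R²* is
uncentred, as appropriate without an intercept. The fit requires at least
twice as many sites as covers and raises on rank deficiency, naming
all-zero columns.

## 3. Bioerosion engine

All components are positive magnitudes; the sign convention is applied only
at budget assembly.

- **Parrotfish**: per individual, `bite_rate × feeding_hours × 365 ×
  scar_fraction × scar_volume × substrate_density × 10⁻³` kg yr⁻¹, with
  rates resolved by functional group and 10 cm size class. Browsers erode
  nothing by definition; fish below the minimum eroding length (10 cm)
  contribute zero; fish above the largest rated class use the largest
  class's rates. Site erosion divides the summed individual rates by the
  census area. A vectorized size-class join reproduces the per-record
  arithmetic exactly (tested).
- **Urchins**: species × test-size rates per individual over the 10 × 2 m
  belt transect. Urchin erosion is computed but **excluded from totals by
  default**: urchins are too rare in the emulated system to move the budget
  balance and were not censused consistently across years.
- **Endolithic borers**: `(micro_rate + macro_rate) × accessible_fraction ×
  rugosity_multiplier`, where accessible substrate is rock + rubble + CCA
  cover by default and the multiplier maps the 6-point visual rugosity
  class to a linear surface factor (1.0–3.0, monotone).

## 4. Budget assembly and sensitivity

Net *G* = gross production − gross erosion. A site or reef is *positive*
only when net *G* is strictly greater than zero. The trajectory panel uses
census production in the census year and hindcast production elsewhere;
erosion comes from the fish census in every year. Reef-year rows are means
over sites; reefs missing a survey year keep a flagged all-NaN row so the
panel shape is stable.

Growth-rate sensitivity: each draw samples every coral rate-table row
uniformly within its 95% CI and recomputes all site budgets (and the
implied hindcast coefficients via a fixed pseudoinverse). Because the
loadings are non-negative, lo95 ≤ mean ≤ hi95 holds per site and every
draw lies inside the endpoint envelope. A nonparametric alternative
resamples sites with replacement within reefs.

## 5. Trajectory statistics

**Variance-weighted mixed model.** Reef-year responses are modelled with
fixed year and regime-status effects, a reef random intercept, and
observation weights equal to the reciprocal of the (year × status) group
variance. With weights *w* the marginal covariance is
σ²(diag(1/w) + λ **ZZ**ᵀ); the single variance ratio λ is profiled out and
estimated by REML with bounded scalar minimization. `statsmodels`' MixedLM
does not accept observation weights, hence the direct implementation; with
all-equal weights the two agree to numerical precision (tested).

Inference is CI-based on standardized coefficients. Intervals use
**inner–outer degrees of freedom**: a design column constant within every
reef (e.g. regime status) is a between-reef effect tested with
df = n_reefs − q_between; within-reef columns use residual df. At 21 reefs
this matters — plug-in Wald z-intervals undercover by several points, and
the t correction restores near-nominal coverage (verified by simulation;
the calibration test runs 200 seeded replicates). Cells with fewer than two
observations or zero variance are an error rather than a silent infinite
weight. An optional square-root transform is applied automatically when a
Breusch–Pagan check on unweighted OLS residuals rejects homoscedasticity.

Post hoc group contrasts are estimated-marginal-mean differences with
Tukey (studentized-range) multipliers.

**Zero-inflated Poisson.** Responses with excess zeros (browser biomass,
macroalgal cover) are rounded to counts and fitted with a logit
zero-inflation component that is intercept-only — a single structural-zero
probability keeps the model identifiable at panel sizes of a couple of
hundred rows. The year × status interaction is tested by likelihood ratio
against the additive model.

## 6. Boosted-tree classification and forecast

The response is the census-year *sign* of each site's net budget;
predictors are reef-level means from an earlier year (parrotfish group
biomasses, morphology covers, macroalgae, depth, wave exposure, rugosity,
reserve status, habitat). For 1994 predictors macroalgal cover is reduced
to presence/absence (most reefs had none). Zero-variance predictors are
dropped with a warning.

Fitting uses scikit-learn's `GradientBoostingClassifier` (Bernoulli
deviance, depth-3 trees, bag fraction 0.75, minimum 10 observations per
leaf) inside a cross-validated tree-count search: trees are evaluated in
blocks of `step_size`, folds are stratified **by reef** so sites of one
reef never straddle a train/test split, and the selected count minimizes
held-out deviance. A minimum still falling at `max_trees` raises rather
than silently truncating. Rows are canonicalized by (reef, site) before
fitting so results are invariant to input order under a fixed seed.

Backward simplification drops the lowest-influence predictor while
cross-validated deviance at the parent model's tree count stays within one
standard error of the best value, then refits the surviving set with a
full tree search. Partial dependence follows the standard recipe (clamp
the predictor, average ensemble predictions) on the probability scale.

Classification probabilities are cut at the prevalence-matching threshold:
the midpoint between the *k*-th and (*k*+1)-th largest predictions, *k*
being the observed positive count; ties that straddle the cut make exact
matching unachievable and the achieved gap is reported. The forecast
reapplies the 1994 → census-year transition model to current predictors —
no additional dynamics — and reports per-reef probabilities (reef
probability = mean of its site probabilities) and thresholded states.

## 7. Synthetic-data generator

Scope: the generator reproduces the *statistical structure* the analysis
assumes, not reef physics. Reef-level 1994 covariates are drawn with
overlapping distributions (regime-shifted reefs: lower massive coral, more
frequent macroalgae, somewhat higher excavator biomass); a latent
resilience score — massive coral, macroalgae absence, excavator biomass
(negative), plus noise — decides which recovered reefs also regain a
positive budget, so each driver carries partial, not individually
sufficient, information. Trajectories: bleaching multiplies 1994 coral
cover by (1 − 0.92) in 2005; recovered reefs rebound toward 1994 by the
census year while regime-shifted reefs stay low-coral and gain macroalgae;
massive coral rebounds far less on weakly recovering and shifted reefs;
excavator biomass grows system-wide, most on non-budget-recovered reefs.

Ground truth closes the loop with the engines: the coral rate table is
back-computed so engine arithmetic yields production = Σ β_m × cover_m for
a configurable β; colonies are placed until planar intercepts sum to the
site's true cover (colonies shorter than 0.5 cm are skipped, so noiseless
recovery is near-exact rather than exact); fish are drawn to hit per-site
group biomass targets with the final length solved to close the sum; site
and visual observation noise are multiplicative lognormal with unit mean.

Focused simulators (`simulate_lmm_panel`, `simulate_zip`,
`simulate_hindcast_pairs`, `simulate_brt_panel`) generate data from exactly
the statistical model each harness fits, for calibration and
structure-recovery tests. `simulate_brt_panel` assigns a fixed division of
labour (macroalgae resolves most reefs; massive coral ranks the algae-free
group; excavator biomass resolves exactly the two remaining ambiguous
reefs) so influence *ranks* are identified at 21 reefs; every other
predictor varies at site level independently of state, and a null variant
decouples all drivers for baseline checks.

## 8. Determinism and numerical choices

- All pipeline randomness descends from one master seed through named
  `numpy.random.SeedSequence` substreams; derived seeds are reduced mod
  2³¹. CSVs are written with a fixed `%.10g` float format; identical
  configurations produce byte-identical outputs (tested end to end).
- REML profiling uses bounded scalar minimization on log λ in [−12, 8];
  the lower bound doubles as a boundary (singular-fit) diagnostic.
- Through-origin regressions use `lstsq`; the sensitivity analysis uses a
  precomputed pseudoinverse for the per-draw hindcast coefficients.
- Bernoulli deviance is computed from margins with `logaddexp` for
  stability.

## 9. Limitations

- **Mixed-model inference** uses plug-in REML covariance with inner–outer
  df. With *estimated* reciprocal-variance weights and strong
  heteroscedasticity, simulated coverage of 95% intervals is ≈ 92% at 21
  reefs (z-intervals would be ≈ 89%); with known or equal weights it is
  ≈ 95%. No Kenward–Roger-style small-sample covariance correction is
  implemented.
- **BRT influence rankings on full generated panels are seed-dependent.**
  With 21 reefs, realized covariate–state correlations vary enough between
  panels that no moderate generating effect stabilizes the influence
  order; structure recovery is therefore assessed on the purpose-built
  classification design (`simulate_brt_panel`), where the division of
  labour between drivers is identified.
- The generator skips colonies under 0.5 cm planar intercept, so
  noiseless β recovery through the census engine is accurate to ~0.5%
  rather than machine precision (the regression harness itself recovers
  coefficients to 1e-8 on exact pairs).
- Packaged rate tables are synthetic stand-ins; absolute budget magnitudes
  are only as meaningful as the rates supplied.
- The forecast applies the fitted transition model to current predictors
  with no growth, mortality or recruitment dynamics, and the urchin census
  is excluded from budget totals by default.
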