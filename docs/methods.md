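# Methods

This note records the model assumptions, numerical choices and known
limitations behind `plumemix`, in the order the pipeline applies them.

## Three end-member mixing

A surface sample is assumed to be a conservative mixture of exactly
three water masses whose temperature and salinity set the vertices of a
triangle on the T–S plane. The mixing fractions are the barycentric
coordinates of the observation; they exist and are unique whenever the
triangle is non-degenerate (we refuse end-member sets whose triangle
area is below 1e-6 °C·PSU). Neither diapycnal/isopycnal mixing nor
air–sea heat exchange is modelled; summer sea-surface temperature is
therefore less conservative than salinity, which can be reflected by
configuring a larger temperature observation SD for summer rather than
by any bias correction.

Stations whose barycentric coordinates fall outside `[-tol, 1+tol]`
(default `tol = 0.03`, roughly two end-member SDs expressed in fraction
units) are excluded from all downstream stages, always with a logged
reason; in-tolerance negatives are clipped to `[0, 1]` and
renormalized.

### Bayesian solver

The posterior is over the simplex point `f` with

* flat Dirichlet(1,1,1) prior;
* Gaussian observation error on T and S (defaults σ_T = 0.05 °C,
  σ_S = 0.05);
* Gaussian uncertainty on each end-member's T and S with the configured
  mean ± SD.

Because the model is linear in the end-member values for fixed `f`,
those nuisance parameters are integrated out analytically: the marginal
likelihood for temperature is Gaussian with variance
`σ_T² + Σ fᵢ²·σ_{T,i}²` (and likewise for salinity). The sampler
therefore only explores the 2-D softmax transform of the simplex
(third logit pinned at 0), with the transform's Jacobian `f₁f₂f₃`
folded into the target density.

Sampling is random-walk Metropolis, 4 chains × 5000 iterations with
1000 burn-in. The posterior is strongly anisotropic in softmax space
near simplex edges, so the proposal is shaped by the Cholesky factor of
the inverse log-posterior Hessian at the mode (identity fallback if the
curvature is not positive definite), and the global step scale adapts
during burn-in toward ~30% acceptance (adaptation stops at the end of
burn-in, so retained samples come from a fixed kernel). Convergence is
declared when the Gelman–Rubin statistic is below 1.05 on all three
fractions; non-converged stations still return their summaries, flagged.

Two properties of the posterior mean are worth knowing. First, it
converges to the exact barycentric solution as all SDs shrink. Second,
near a simplex edge the positivity constraint plus the `f₁f₂f₃`
density factor pull the mean inward by up to ~1.3 posterior SDs — a
station observed exactly at a vertex has posterior mean ≈ 0.99, not
1.0. This is a property of the model, not a sampler artifact, and it is
why point-agreement checks against the exact solver use interior
solutions.

At the default noise levels the cruise-mean posterior fraction SD is
~0.013, consistent with the ~1–2% average uncertainties such unmixing
analyses report.

## Preformed nutrients

Preformed (initial) concentrations are fraction-weighted end-member
nutrient values — linear in `f`, hence bounded by the end-member values
on the simplex. Measured DIP below the 0.02 µmol L⁻¹ detection limit
is set to 0.01 µmol L⁻¹ before any ratio is formed, which caps
computable N/P at 100·NOx and explains extreme ratios in
phosphate-depleted plume water. Anomaly tags use thresholds of
0.5 µmol L⁻¹ (NOx) and 0.05 µmol L⁻¹ (DIP), values near analytical
precision; the tags are qualitative descriptors, not tests.

## Community metrics and outliers

∑PB is the plain sum of the three lipid concentrations; group shares
are each biomarker over ∑PB. A station with ∑PB = 0 has undefined
(missing) shares — zero biomass carries no community information. A
configurable outlier rule (explicit station ids and/or a ∑PB
threshold) flags stations out of the fraction–response regressions
while keeping them in maps, summaries and fluxes; the default rule
flags nothing. Chlorophyll *a* is carried as an independent biomass
variable and never used as a denominator.

## Subregionalization

The four threshold clauses overlap (e.g. `f_CDW = 0.60, f_KSSW = 0.07`
satisfies the C-KMR, CDWR and KSSWR clauses simultaneously), so they
are evaluated in fixed precedence TSWR → C-KMR → CDWR → KSSWR, with
C-KMR first among the three CDW/KSSW clauses because it is two-sided in
both fractions and hence the most specific. A 0.01-step simplex sweep
in the tests confirms every on-simplex point receives exactly one
label. Thresholds are configuration with the defaults given in the
README.

## Statistical stage

* **Model selection.** Degree-1 and degree-2 least-squares fits are
  both computed and retained. RMSE is the df-adjusted residual standard
  error `sqrt(SSR/(n−p))` — with the raw in-sample RMSE the nested
  quadratic could never lose and the rule would be vacuous. The
  quadratic is selected only when it is better on both the overall-F
  *p* value and the RMSE; when the criteria disagree the simpler model
  is kept and the conflict is logged and flagged. Near-equality at
  float precision (rtol 1e-8) counts for the line, so noiseless linear
  data select the line. The polynomial degree is fixed at 2. Pointwise
  95% confidence bands come from the selected model's prediction
  variance; the significance level is 0.05 throughout.
* **Rank tests.** Spearman (average ranks), Kruskal–Wallis
  (tie-corrected H, χ² p on k−1 df), Brown–Forsythe Levene
  (median-centred) and Shapiro–Wilk are delegated to scipy.stats; the
  pre-tests motivate the rank-based group comparison rather than gate
  it.
* **RDA.** Both matrices are standardized (zero-variance columns
  dropped); rows with any missing value are dropped with a log message;
  mutually collinear predictors are removed left-to-right by a greedy
  rank filter. The multivariate least-squares fitted values are
  SVD-decomposed; the constrained variance fraction is
  `‖Ŷ‖²/‖Y‖²`. Per-variable contributions are the marginal
  constrained fractions of single-predictor fits — a ranking device,
  not an additive decomposition under collinearity. The implementation
  reproduces vegan's `rda()` eigenvalue fractions to 1e-5 on a fixed
  test matrix. Whether to standardize was an open choice; standardizing
  makes the contributions comparable across variables with different
  units.

## Export flux

Flux = concentration × sinking rate × k, with k = 0.365 derived by
dimensional analysis: ng L⁻¹ = µg m⁻³, times m day⁻¹ gives
µg m⁻² day⁻¹, times 365 day a⁻¹ × 10⁶ m² km⁻² × 10⁻⁹ kg µg⁻¹. Only
brassicasterol (diatoms, 0.95 m day⁻¹) and dinosterol (dinoflagellates,
0.37 m day⁻¹) contribute; alkenones are excluded. Subregion fluxes are
means of per-station fluxes (not fluxes of mean concentrations); the
two coincide only under equal weighting. k and both rates are
configuration so alternative published unit chains (different export
depths, burial efficiencies) can be swapped in.

## Synthetic cruise generator

The generator emulates a ~60-station surface survey over a
120–124°E × 26.6–32.5°N box:

1. Water-mass fractions are the softmax of three smooth
   linear-plus-sinusoidal spatial trends, oriented so river water is
   high nearshore/north, strait water in the southeast, and upwelled
   water along the central coast. The coefficients were chosen once so
   that (a) all four subregions are populated in realistic proportions,
   and (b) the CDW and KSSW fractions are nearly uncorrelated across
   non-TSWR stations — without (b) the two community slopes confound
   each other and no marginal regression could recover either.
2. T and S are conservative mixtures plus Gaussian noise (σ = 0.05).
3. Preformed nutrients follow conservative mixing; measured nutrients
   subtract a biomass-proportional uptake (α = 0.002 µmol L⁻¹ per
   ng L⁻¹ of ∑PB for NOx, α/16 for DIP) plus noise, floored at zero,
   with the DIP detection-limit rule applied.
4. ∑PB is a baseline (150 ng L⁻¹) plus a peak (2400 ng L⁻¹) inside a
   smooth window centred on the C-KMR fraction ranges, so
   mixing-window stations exceed ~1000 ng L⁻¹.
5. Community shares are linear in the fractions
   (B/∑PB = 0.55 + 0.5·f_KSSW − 0.25·f_CDW, D/∑PB mirrored, A/∑PB the
   remainder) with share noise 0.01/0.02/0.02 — the measurement
   repeatability of the three proportions — then simplex-clipped.
6. TSM rises with the river fraction; Chl *a* is proportional to ∑PB
   with noise.

Everything is deterministic given the seed. What the generator does
**not** emulate: advection and fronts, vertical structure, seasonal
field shifts (summer differs only in its end-member set), patchy
biomass beyond the single mixing-window peak, and correlated
measurement errors. Passing recovery tests therefore demonstrate that
the pipeline inverts its own generative assumptions at realistic noise
— not that those assumptions hold in any particular sea.

## Problem sizes used in tests

The test suite and the acceptance script run 60-station cruises, 100
recovery replicates with the exact solver, full-cruise MCMC once, and
brute-force solver oracles on ~100 points — a few minutes end to end on
one CPU. These sizes match the surveyed-cruise scale the package
targets.

## Known limitations

* Exactly three end-members; no provision for a fourth tracer or water
  mass.
* The flux constant encodes one specific unit chain; burial efficiency
  and POC conversion are out of scope.
* Subregion thresholds are treated as exact cutoffs; stations near a
  boundary can flip label under observation noise (the recovery tests
  quantify this at ~8% label error).
* The RDA reports variance fractions and contribution rankings only; no
  permutation tests of axis significance.
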