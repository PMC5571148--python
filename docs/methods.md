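# Methods

This note records the statistical model, the numerical choices, and the
limits of what the test suite demonstrates. It is the package's own account
of its methods; all empirical statements here are quantities the tests or
`scripts/acceptance.py` actually compute.

## Model and procedure

**Species distribution models.** Presence/absence of each species is
modelled by logistic regression (logit link, binomial error) on
standardized environmental variables, with optional quadratic terms to
capture unimodal niches: `logit P = β₀ + Σₙ (βₙ zₙ + βₙ′ zₙ²)`.
Standardization uses the sample mean and the n−1 standard deviation over
all modelled sites; parameters are stored so native-unit sweep grids map
exactly onto the fitted scale and averaged coefficients can be re-expressed
in native units. Candidate models are the full `3^p` assignments of
{absent, linear, linear+quadratic} per predictor; a quadratic term is
structurally impossible without its linear term. Candidates are ranked by
AIC (`2k − 2ℓ`, `k` counting the intercept); coefficients are averaged with
Akaike weights `wᵢ = exp(−Δᵢ/2)/Σ exp(−Δⱼ/2)` over the models with
`Δᵢ ≤ 2`.

**Curves, critical levels, EVDs, overlay.** One stressor is swept over the
regional 1st–99th percentile range (outlier clamp; configurable, clipped to
any declared natural bounds such as a [0, 1] toxic-pressure fraction, and
extended to cover every reference site's observed value). Expected species
richness is the sum of occurrence probabilities over the site's species
pool; relative species richness (RSR) divides by the richness at observed
conditions. Critical levels come from the first crossing of `1 − T` along
the stress direction, linearly interpolated between grid points; no
crossing within the range means the site is censored at the grid end.
The EVD's exceedance at stressor value `s` is the number of uncensored
critical levels passed divided by the *total* number of reference sites, so
censored sites dilute and never inflate apparent risk. Overlay
classification is inclusive at the EVD range endpoints (at risk), and for
decrease-direction stressors the axis is reversed. Ranking sorts by
impacted fraction, then at-risk fraction, then name.

## Design choices made where the design was open

- **Averaging mode.** Full (shrinkage) averaging: a term absent from a
  model contributes zero to its average. Conditional averaging is available
  behind a configuration switch (`full_averaging: false`). Full averaging
  is the conservative default because it shrinks weakly supported terms
  toward zero instead of conditioning on their inclusion.
- **Greedy VIF elimination.** "Sequential removal" is pinned as: recompute
  all VIFs, drop the single highest, repeat while any VIF meets the limit;
  ties drop the variable later in the input order. This makes screening
  deterministic and order-reproducible.
- **Aggregation of repeat samplings.** Environmental values collapse to the
  per-site median; occurrence collapses to the maximum (ever observed =
  present). The occurrence rule is an assumption — a defensible alternative
  (most recent survey) would need sampling dates, which the table contract
  does not carry.
- **Separation handling.** A candidate whose IRLS fit fails to converge or
  lands any standardized coefficient beyond 15 in magnitude is treated as
  (quasi-)separated and excluded from the confidence set, with a logged
  count. At |β| = 15 the logistic is saturated to within 3×10⁻⁷, so the cap
  cannot bite on a genuinely informative fit.
- **First-crossing rule.** Skewed optima can make a curve re-cross `1 − T`;
  the first crossing from the point of departure is used, which is the
  conservative (earliest-impact) choice. Curves with two or more crossings
  feed the advisory `complex_response` suitability flag (default: flag the
  EVD when more than 25% of curves re-cross; `low_response` when more than
  50% of sites are censored). These cutoffs are operational defaults for a
  judgment the field usually makes by inspection; the flags are advisory
  and never block EVD emission unless every site is censored.
- **AUC.** In-sample, as the Mann–Whitney probability with ties counted
  one half (delegated to scikit-learn's ROC implementation). An optional
  AUC floor can exclude poorly fitting species; it is off by default — on
  the generated landscapes, spot checks in the test suite show rankings do
  not depend on it, and weak models carry little weight in the stacked sums.
- **Both-direction stressors.** pH-like variables get one EVD per
  direction. The ranking table keeps the two directional rows; a combined
  worst-case-per-site row is also emitted (`ranking_combined.csv`) for a
  single-bar-per-stressor view.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `threshold_T` | 0.05 | fraction of species richness lost that defines the critical level |
| `min_occurrences` | 20 | minimum presences for a species to be modelled |
| `vif_limit` | 5 | VIF at or above which a predictor is eliminated |
| `delta_aic` | 2 | AIC width of the model confidence set |
| `sweep_points` | 1001 | grid resolution of the stressor sweep (native units) |
| `sweep_quantiles` | (0.01, 0.99) | regional quantiles clamping the sweep (outlier exclusion) |
| `band_quantiles` | (0.05, 0.95) | central band of regional stressor variability drawn on plots |
| `all_species_mode` | false | stack every modelled species at every reference site |
| `separation_cap` | 15 | standardized-coefficient magnitude treated as separation |
| `use_aicc` | false | small-sample AIC correction |

With 1001 grid points the linear-interpolation error of a critical level is
far below any ecological precision; the ground-truth inverter uses a 10×
denser grid so discretization never favours the estimate.

## The synthetic landscape: what it does and does not emulate

The generator draws environmental gradients from uniform/normal/lognormal
marginals (optionally rank-correlated through a Gaussian copula), builds
each species' true occurrence probability from a quadratic-logit niche on
the standardized scale of the generated sample, and samples presences as
independent Bernoulli draws, optionally thinned by a detection probability.
The bundled study landscape (`demo_spec`) uses 2000 sites, 30 species, 18
reference sites and four freshwater-flavoured variables — a lognormal
nutrient (stress by increase), a normal acidity optimum (stress in both
directions), a normal habitat-quality index (stress by decrease) and a
lognormal drainage-area covariate. Species niches vary in optimum, breadth
and sign; roughly one species in ten is drawn rare enough to fall under the
occurrence filter, emulating the prevalence heterogeneity of real survey
data. Reference sites are the least-stressed sites by mean standardized
stress (signed by direction, absolute for both-direction variables) — a
pragmatic stand-in for field designation of minimally disturbed sites.

By default the generating family equals the fitted family (the
well-specified case), so passing recovery tests demonstrates that the
pipeline's estimation, stacking, inversion and ranking machinery is
correct — not that quadratic-logit SDMs suffice for any real community.
Asymmetric (skewed) niches, spatial autocorrelation, species interactions,
observation covariates and temporal trends are all absent; real-data
performance depends on how well the model family approximates the true
responses. Misspecification can be probed by generating with
quadratic terms on variables withheld from fitting, or by the detection
thinning.

## Problem sizes used in validation

Full-scale recovery runs on the 2000-site landscape (26–27 modelled
species, 4 predictors, 81 candidate models per species); ranking recovery
uses 20 replicate 600-site landscapes with two stressors whose per-species
slopes differ threefold; the brute-force likelihood oracle runs at 300
sites and up to two predictors, where an independent BFGS maximizer is
cheap and exact. These sizes give stable statistics (rank correlations,
replicate win fractions) while keeping the whole suite fast enough to run
routinely.

## Known limitations

- Critical levels are bounded by the swept range: a site more tolerant than
  the regional 99th percentile is censored, not extrapolated.
- The EVD is the empirical distribution; no parametric smoothing is fitted,
  and plotted curves are presentation only.
- In-sample AUC overstates out-of-sample accuracy; no cross-validation is
  performed.
- One stressor is varied at a time; correlated stressor changes and
  biotic interactions are out of scope.
- Reference-site selection is consumed as an input (or simulated); the
  package takes no position on how reference status should be assigned in
  the field.
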