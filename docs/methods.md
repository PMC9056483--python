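# Methods

`altishift` estimates how the altitudinal centre of bird abundance moves
between two multi-year study periods, and which species traits predict the
speed of that movement. It operates on long-format point-count records from
two national monitoring schemes with different designs, and it ships a
synthetic-survey generator with known ground truth so every stage can be
validated by parameter recovery.

## The derived statistic

For a species in a grid cell and a study period:

1. **Mean annual count per point.** A = Σ observations / N, where N is the
   number of years the point was surveyed in the period. Surveyed-but-empty
   visits must be present as explicit zero rows, otherwise N is not
   observable; the generator and the schema both enforce this.
2. **Fixed altitudinal gradient.** Points are binned from 300 to 1400 m in
   50 m intervals. Bins are half-open [lower, upper) with the final bin
   closed at 1400 m (a convention choice; it only affects points exactly on
   an edge). Points outside the gradient are excluded from profiles — not
   clamped — and logged; they still count toward grid-level selection.
3. **Mean abundance per bin.** R_i = ΣA / n_p over the n_p surveyed points in
   bin i. Zero-A points are surveyed points and stay in the denominator.
4. **Mean altitude of abundance.** M_alt = Σ (R_i / ΣR_i) · M_i, where M_i is
   the mean altitude of the points in bin i. M_alt is undefined (and the
   record dropped, with a log entry) when ΣR_i = 0.

The altitudinal abundance shift of a (species, grid) pair is
M_alt(period 2) − M_alt(period 1); positive means uphill.

## Data selection

Defaults: points surveyed ≥ 1 year in *each* period; grids with ≥ 300 m of
observed altitudinal range and ≥ 10 such points; a (species, grid) pair
qualifies when the summed per-point mean annual abundance reaches 5 in both
periods; species retained when they qualify in ≥ 3 grids; an exclusion list
drops species whose dynamics are known to be non-climatic (introduced
populations). Two readings of the "mean of five individuals" rule are
implemented — sum of per-point means over the grid (default) or mean per
point — because the per-point reading excludes nearly everything at
realistic densities. Grid membership is an input column: gridding is a
design property of each survey, not an algorithm.

All filters are idempotent and monotone in their thresholds (tested), and a
sensitivity mode re-estimates the headline shift over a threshold grid.

## Community shift model

The response is M_alt per (species, grid, period). Fixed effects: period
(numeric 1/2 — identical to a two-level factor up to intercept coding), grid
mean longitude, grid altitudinal range; the interaction model adds
period × longitude and period × range. Random intercepts for country, grid
and species are *crossed*. The period coefficient is the community mean
uphill shift in metres per period step; division by the midpoint-to-midpoint
year span (16 yr for 1999–2002 → 2015–2018) converts it to m/yr. That
conversion is made explicit because "metres per period" and "metres per
year" are otherwise easy to conflate.

### REML implementation

The model is y = Xβ + Σ_k Z_k b_k + e with b_k ~ N(0, σ²_k I). The REML
criterion is profiled over variance ratios γ_k = σ²_k/σ²_e: for fixed γ the
GLS β̂ and σ̂²_e are closed-form, so the optimiser (Nelder–Mead, started at
γ = 1, log γ clipped to ±20, criterion tolerance 1e-10, ≤ 500·K evaluations)
searches only the K-dimensional log-ratio space. All solves use the Woodbury
identity on W = I + ZΓZᵀ, i.e. O(n·q²) for q total random levels, so the fit
is cheap even at the full two-country scale. Single-level factors are
dropped with a warning; rank-deficient fixed designs raise an error naming
the collinear columns. Fixed-effect SEs come from σ̂²(XᵀW⁻¹X)⁻¹ with
residual degrees of freedom n − rank(X) — a deliberate, labelled
approximation (no Satterthwaite/Kenward–Roger); nothing downstream depends
on the df choice. The engine is validated against closed-form balanced
one-way ANOVA REML estimators and against an independent general-purpose
variance-components implementation (agreement ~1e-4 on fixed effects).

### Diagnostics

Residuals are averaged per grid and screened with a Moran's I correlogram:
equal-width great-circle distance classes up to 500 km, binary weights, and
a 999-permutation null envelope (2.5/97.5 percentiles), seeded. Under
independence E[I] = −1/(n−1); a genuine longitude gradient in the residuals
is flagged in the first distance class (both tested). Per-species shifts are
additionally tested with two-sided one-sample t-tests across grids
(species with < 2 grids are reported untested; zero-variance cases are
flagged rather than silently given p = 0 semantics).

## Trait analysis

The species-level response is the unweighted mean shift across the grids
where the species qualifies. Continuous traits (clutch size, longevity, body
mass, STI, population trend, diet specialization score) are standardized to
mean 0, SD 1 over the included species; habitat and migration strategy
(resident / partial / short-distance / long-distance) are dummy-coded.
Four hypothesis groups — fastness–slowness {clutch size, longevity},
ecological niche {habitat, diet, STI}, migratory behaviour {migration},
population dynamics {trend} — generate all 2⁴ = 16 candidate models from
null to full. Body mass never co-occurs with longevity: a variant model set
swaps longevity for mass. Pairwise |Spearman r| ≥ 0.5 among continuous
predictors triggers a warning naming the pair; nothing is auto-excluded.

Each candidate is fitted by PGLS with error covariance σ²C, where
C[i,j] is the root-to-MRCA shared path length (Brownian motion, Pagel's
λ fixed at 1; an ML-λ mode exists behind a flag). β̂ = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y via
Cholesky whitening; σ̂² is the ML estimate (used in the log-likelihood),
while coefficient SEs use the unbiased n−p denominator, matching common GLS
software. A non-PD C receives a logged 1e-10 diagonal jitter.

Ranking uses AICc = −2logL + 2k + 2k(k+1)/(n−k−1) with k counting the
intercept, every slope/dummy column and σ² — stated explicitly because AICc
is sensitive to the k convention. Models within 4 AICc units of the best are
averaged with renormalized Akaike weights; averaging is *conditional*
(natural) by default — each coefficient averaged over window models that
contain it, SE = Σw·sqrt(se² + (β−β̄)²) — with zero-substitution ("full")
averaging behind a flag, since the field's tooling supports both and the
choice materially shrinks rarely-selected coefficients.

Consensus trees (majority rule) are supported for multi-tree inputs; since
consensus topologies carry no usable branch lengths, lengths are assigned by
Grafen's method (node height ∝ clade size, tree height 1), which is flagged
as a methodological choice and guarantees an ultrametric, PSD covariance.

## Temperature stage

Monthly grid temperatures are averaged into March–April, May–June and
July–August windows per year, then across the years of each period
(two-stage, so unbalanced month availability fails loudly rather than
reweighting years). Change is tested with a paired t-test across grid cells
(pairing unit = grid, df = n_grids − 1).

## Synthetic-data generator

The generator is first-class, tested code and defines the study conditions:

- **Landscape.** Grids draw an altitude band: low ~ U(300, 360) m, extent
  ~ U(800, 1000) m; the last grid always gets a 250 m band so the range
  filter has something to reject. The first ⌈n/5⌉ grids form country "NOR",
  the rest "SWE"; points are uniform in altitude within the band, with
  lon/lat scatter around a grid centroid (latitude is generated but unused
  by the models — it feeds only the correlogram distances).
- **Counts.** Species s at altitude a in year y:
  count ~ Poisson(exp(b − (a − μ_s)²/(2σ_niche²))), with base log-abundance
  b = 2 (≈ 7.4 birds per point-visit at the niche centre), σ_niche = 120 m,
  and niche centres μ_s ~ U(600, 800) m. In period 2 the centre moves by
  δ_sg = β₀ + β_L·z(longevity_s) + β_R·(range_g − mean range) + ε_s with
  defaults β₀ = 12 m, β_L = −1.3 m/SD, β_R = 0. The residual ε evolves as
  Brownian motion on the phylogeny, scaled so every tip is marginally
  N(0, 3.5²): the trait stage assumes Brownian residuals, and a generator
  whose species-level noise were instead independent would make λ = 1 PGLS
  badly inefficient (independent noise on near-zero contrasts between close
  relatives is amplified by the C⁻¹ weighting) — the generator defines
  conditions under which the stage's own assumptions hold. The niche
  geometry keeps centres ≥ ~2σ inside grid supports so truncation attenuates
  the realized M_alt shift by only a few percent; σ_ε = 3.5 m matches the
  residual scale implied by a species-level trait model with SE ≈ 0.4 at
  n ≈ 75. Survey effort is Bernoulli(0.8) per point-year, resampled until
  every point has ≥ 1 visit per period (so the point-selection rule is
  satisfiable by construction); surveyed point-years carry explicit zeros.
- **Traits and tree.** A pure-birth (Yule) ultrametric tree is simulated
  directly (exponential holding times between splits plus a final holding
  time — this avoids the zero-length terminal branches some off-the-shelf
  birth–death samplers produce at the stopping boundary, which would make C
  singular). Longevity evolves as Brownian motion on that tree (rate scaled
  to a ≈ 4 yr SD), so the PGLS error model is correctly specified for the
  one trait that truly drives the shift; all other traits are independent
  noise, and categorical traits are uniform over their levels.
- **Temperature.** Per-grid baseline + seasonal sinusoid + second-period
  offsets (+0.54, −0.25, −0.04 °C for the three windows) + N(0, 0.1²) noise.

What the generator does *not* emulate: route geometry and within-route
spatial autocorrelation of counts, overdispersion (counts are exactly
Poisson — a modelling choice, not a claim about real data), observer and
detectability effects, temporal population trends within periods, and
correlated trait evolution. Passing recovery tests therefore demonstrates
the correctness of the estimators under the assumed data-generating process,
not robustness to these real-data complications.

## Validation design and problem sizes

The statistical guarantees are checked at deliberately reduced scales:
interval calibration (with every species shifted by exactly +12 m, isolating
the fixed effect) and type-I control of the period effect use 10 analysis
grids × 30 points × 20 species (100 and 200 replicates); the
range-interaction power check widens grid extents to U(500, 1000) m and sets
β_R = 0.05 m/m, chosen by an a priori power calculation (measured
SE ≈ 0.009 ⇒ z ≈ 5). Trait-sign and AICc-window recovery are checked at the
species level — the response is the generator's true per-species shift,
which is exactly the generative analogue of the trait-model response — with
75 species (the real survey's scale), isolating the PGLS/AICc/averaging
stage from count-level measurement noise; the count-to-trait linkage is
exercised end-to-end by the pipeline tests and the acceptance script, which
runs one full analysis at 30 grids × 100 points × 75 species.

## Known limitations

- The period test of the community model is *conservative* under these study
  conditions: M_alt carries a deterministic species × grid component (each
  species' profile meets each grid's specific point layout and support),
  which the three-random-intercept model cannot absorb. It inflates the
  residual variance estimate but cancels in the within-pair period contrast,
  so the period SE is overestimated (~15% at default sizes) and the empirical
  type-I rate is ≈ 1% at nominal 5%. Error control holds; power is somewhat
  understated. The real analysis, which uses the same model on the same kind
  of statistic, shares this property.
- Residual df is the n − rank(X) approximation; p-values for small random-
  effect designs are anti-conservative relative to Satterthwaite.
- Species-level measurement noise from finite counts is independent across
  species, while λ = 1 PGLS assumes fully Brownian residuals; with noisy
  count data the trait stage therefore loses efficiency (no measurement-error
  PGLS is offered).
- λ = 1 PGLS assumes pure Brownian structure; the ML-λ option mitigates but
  no OU or measurement-error models are offered.
- The correlogram is diagnostic only; no spatially correlated error model is
  fitted.
- The "mean of five individuals" selection rule is ambiguous in prose; both
  readings are implemented and the grid-sum reading is the default.
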