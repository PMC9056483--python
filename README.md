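# altishift

Abundance-weighted altitudinal range-shift analysis for repeated point-count
bird surveys, built for the question: *is the centre of gravity of mountain
bird abundance moving uphill between two study periods, and do species traits
predict how fast?*

It is aimed at quantitative ecologists working with long-format count data
from structured monitoring schemes (multiple countries or designs, grid
cells, fixed survey points, repeated years), and it ships a fully synthetic
survey generator with known ground truth so every estimator in the chain can
be validated by parameter recovery.

## The statistic and the models

For each species *s*, grid cell *g* and study period:

1. Mean annual count per point: `A = Σ observations / N` (N = years the point
   was surveyed in the period; surveyed-but-empty visits count as zeros).
2. Points are binned on a fixed 300–1400 m gradient in 50 m intervals.
3. Mean abundance per interval *i*: `R_i = Σ A / n_p` over the `n_p` points
   in the interval.
4. Mean altitude of abundance: `M_alt = Σ (R_i / Σ R_i) · M_i`, with `M_i`
   the mean altitude of the interval's points.

The altitudinal abundance shift of a (species, grid) pair is
`M_alt(period 2) − M_alt(period 1)` (positive = uphill). Community-wide
shift is estimated by a Gaussian linear mixed model fitted by REML:

    M_alt ~ period + mean longitude + altitudinal range
            + (1 | country) + (1 | grid) + (1 | species)

with crossed random intercepts (an interaction model adds period × longitude
and period × altitudinal range). The period coefficient is the mean uphill
shift in metres. Species-level mean shifts are then regressed on trait
combinations by phylogenetic generalized least squares (Brownian covariance,
λ = 1), over all 2⁴ = 16 combinations of four trait-hypothesis groups
(fastness–slowness, ecological niche, migratory behaviour, population
dynamics), ranked by AICc and model-averaged within 4 AICc units. Monthly
grid temperatures are aggregated into three seasonal windows per period and
compared with paired t-tests; mixed-model residuals are screened with a
permutation-enveloped Moran's I correlogram. See `docs/methods.md` for the
full model descriptions and numerical choices.

## Worked example

```
$ altishift simulate --seed 42 --preset small --out sim
wrote 6 files to sim
$ altishift run --inputs sim --out results --seed 42
$ altishift report --results results
Headline uphill shift: 15.89 m (0.99 m/yr over 16.0 yr)
Species uphill/downhill: 20/0 (significant: 14/0)
Best trait model: ecological_niche of 16 candidates
  Mar-Apr: +0.53 C (t=106.04, df=10, p=0)
  May-Jun: -0.23 C (t=-23.05, df=10, p=0)
  Jul-Aug: -0.06 C (t=-5.05, df=10, p=0.000499)
```

What the numbers mean: the generator's default ground truth moves every
species' altitudinal abundance profile uphill by 12 m on average between
1999–2002 and 2015–2018 (species-specific shifts vary with longevity and a
Brownian noise term, so any single replicate's realized community shift
wanders around 12 m — here the mixed model estimates 15.9 m, i.e. 0.99 m per
year over the 16-year midpoint-to-midpoint span). All 20 species trend
uphill, 14 of them significantly in per-species t-tests. At this deliberately
small scale (10 analysis grids, 20 species) the trait stage has little power
and a noise hypothesis can top the 16-model AICc ranking, as it does here;
the seasonal temperature tests recover the injected +0.54 / −0.25 / −0.04 °C
offsets. Full tables (model coefficients, per-species tests, model selection,
correlogram) are written as CSV under `results/`.

The `simulate` command also writes `ground_truth.json` with every true
parameter, `--preset paperlike` generates a two-country survey at the real
schemes' scale (37 grids, 76 species), and `altishift sensitivity` re-runs
the headline model over a grid of data-selection thresholds. Analyses can be
restricted to one country (`altishift run --country SWE ...`). All stages are
importable as plain functions (`altishift.metrics`, `altishift.lmm`,
`altishift.traits`, ...) for use outside the CLI.

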