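# Methods

This note documents the models, numerical choices, and defaults behind
`leafchl`, and what the synthetic study conditions do and do not show
about real field data.

## Spectral model and pretreatments

All spectra live on the 350–2500 nm instrument grid with 1 nm spacing
(2151 bands); band *i* holds wavelength 350 + *i*, so band lookup is an
exact integer offset and no nearest-band tolerance is needed. Inputs on
other grids are resampled by linear interpolation at load time (no
extrapolation).

A reflectance factor is the per-band ratio of leaf radiance to the mean
radiance of the bracketing white-reference scans. Six pretreatments are
derived from it:

- **Savitzky–Golay derivatives** (ρ′, ρ″ and the derivatives of
  log₁₀ ρ⁻¹). Defaults: window 15 bands, fitted polynomial order 2,
  derivatives taken per nm. The literature this pipeline follows states
  the filter but not its parameters; 15/2 is a common chemometric
  choice that suppresses band-to-band noise without flattening the red
  edge, and both values are exposed in configuration. Edges use the
  same polynomial fit extended outward (`mode="interp"`), so index
  formulas near 350 and 2500 nm stay defined.
- **Apparent absorbance** log₁₀(1/ρ). Field spectra can dip to or below
  zero from noise in strongly absorbing bands, so ρ is floored at 10⁻⁶
  with a logged warning rather than failing.
- **Continuum removal** ρ_CR = ρ / hull(ρ), where hull is the upper
  convex hull of (λ, ρ) over the interval (default: the full grid;
  per-feature intervals override). The hull is built by a monotone-chain
  scan, which handles exactly collinear spectra (where general-position
  hull codes reject the degenerate input) and makes ρ_CR ≤ 1 with
  equality at hull-contact bands by construction. The test suite checks
  it against an O(n²) chord-maximum oracle.

The derivative-area operation (used by integral-type indices) sums
central differences (trapezoid on the 1 nm grid) rather than the
smoothed derivative, so the integral telescopes to the net reflectance
rise over the interval.

## The vegetation-index registry

The 148 index definitions live in a declarative data file
(`data/indices.json`): name, formula expression, kind, citation, and an
optional cluster letter. Expressions are written in a small DSL —
`R700` (reflectance), `D700`/`DD700` (first/second derivative), `CR700`
(continuum-removed), plus range functions (derivative sums, maxima and
their wavelengths, band-depth areas) and the red-edge estimators — and
are evaluated vectorized over a spectra matrix. The roster spans the
main index lineages of the remote-sensing literature (simple ratios and
normalized differences, soil-adjusted forms, chlorophyll-absorption
indices and their red-edge revisions, photochemical reflectance
indices, carotenoid/anthocyanin indices, water/nitrogen/cellulose
indices, derivative integrals, band depths, and red-edge positions).
It is a reconstruction from the cited primary sources, not a
transcription of any single published table; the named indices that
anchor the analysis (NDVI, GTSR2, CRSR2, CPSR2, PRI2, PSSRB, WUMCARI,
WLREIPG, MOR, DDN, CAR, CAI, DCNI) follow their printed formulas.

Undefined values (zero denominators, failed fits) are encoded as NaN
with a logged count and excluded pairwise from downstream regressions;
in the machine-learning feature sets they are imputed with the
training-column mean before standardization.

**Red-edge inflection point.** Three estimators: argmax of the smoothed
first derivative in 670–800 nm; the four-band linear-interpolation
estimator REIP = 700 + 40·(ρ_re − ρ₇₀₀)/(ρ₇₄₀ − ρ₇₀₀) with
ρ_re = (ρ₆₇₀+ρ₇₈₀)/2; and an inverted-Gaussian model
R(λ) = Rs − (Rs−R0)·exp(−(λ−λ₀)²/(2σ²)) fit by bounded least squares
(λ₀ ∈ [680, 780], σ ∈ [5, 60], started at the max-d1 wavelength) whose
inflection is reported as λ₀+σ. A spectrum with ρ₇₈₀ ≤ ρ₆₇₀ has no
rising red edge and raises. Note that on an asymmetric (e.g. logistic)
edge the best-fitting inverted Gaussian places its inflection below the
logistic center — the implementation is validated against an exhaustive
(λ₀, σ) grid-search oracle, not against the logistic's own center.

## Chlorophyll laboratory data

One tissue sample is two 0.283 cm² leaf punches (0.566 cm²). Area-basis
chlorophyll is (concentration × extract volume)/area; mass basis is
pigment mass over dry tissue mass (mg g⁻¹, numerically µg/mg). The
extract volume is not a printed constant of the protocol; it is a
required configuration field (default 1.0 mL) so the conversion is
dimensionally honest. Outlier removal — whose exact published recipe is
deferred to a companion protocol — is implemented as a documented,
configurable 1.5×IQR fence per (experiment, collection) group on the
chosen metric; groups smaller than 4 pass through with a warning, and
the filter is idempotent.

Repeatability of paired samples reports the r² of a least-squares fit
of sample 2 on sample 1 and RMSD% = 100·√mean((x₁−x₂)²)/grand mean.
Whether published RMSD percentages are normalized by the mean, range,
or maximum is ambiguous; mean normalization is used and isolated in one
function.

## Dataset assembly and evaluation

Aggregation scales: *sample* (each tissue sample paired with its leaf's
spectrum, spectra duplicated within a leaf), *leaf* (samples averaged),
*plot* (chlorophyll averaged over the plot-collection's samples,
spectra over its leaves), *entry* (genotype × collection means, which
removes replication). Splits are by experiment (first experiment
trains, second tests) or random without replacement with
floor(fraction·n) training rows under a seed; partition manifests are
written as CSV so any run is reproducible from disk. Standardization is
fit on the training set only and applied to the test set — a
leakage-free convention chosen where the source protocol is silent —
with constant training features mapped to zero.

The zoo holds the 14 scikit-learn regressors with their documented
static settings; dynamic hyperparameters are tuned by repeated k-fold
(5 splits × 10 repeats by default) grid search on negative RMSE, ties
broken to the first candidate in grid order, and the winner refit on
the full training set. BayesianRidge and the Gaussian process take no
dynamic search. The candidate grids are this package's reconstruction
(regularization over six log-decades, 1–20 for components/neighbors,
standard depth/leaf grids for trees) and are fully configurable — the
published roster names which hyperparameters were tuned but not their
candidate values. PLS component counts are capped by the feature count
and fold size. Model errors (RMSE as % of the observed mean) are
compared by main-effects ANOVA plus Tukey HSD with a compact letter
display; a factor with zero between-level variation reports F = 0, and
an unreplicated factor raises by name.

## Clustered permutation importance

Hyperspectral bands and many indices are strongly collinear, so
per-feature permutation importance is uninterpretable on the full set.
Features are clustered by Ward linkage on d = 1 − |Pearson r| (the
absolute form treats anti-correlated features as equivalent information;
1 − r is available), with the dendrogram truncated at a Ward-distance
cutoff or to a fixed cluster count. Each iteration draws one feature
uniformly per cluster, fits a random forest (fixed, not searched:
60 trees, minimum leaf 5 — the leaf floor limits in-sample overfitting
so permuting a noise feature moves the score little), and credits each
drawn feature's permutation importance (mean r² drop over 5 in-sample
shuffles; the score is configurable) to its cluster. The default
iteration count is 10,000 for full runs; tests and the acceptance
script use 50–200 iterations, which is ample to separate a planted
signal cluster from noise clusters.

## The synthetic trial generator

The generator defines the study conditions under which everything is
tested; it emulates the two experiment designs exactly
(6 entries × 2 planting dates × 3 irrigation levels × 3 replicates ×
9 collections × 3 leaves × 2 samples → 5832 samples; and
379 entries × 2 replicates × 6 collections × 1 leaf × 1 sample thinned
by uniform random plot dropout to 572 units, the attrition case).

- **Chlorophyll marginals** are log-normal (positivity plus right
  skew), parameterized per experiment by the observed interquartile
  ranges of area-basis Chl *a+b* (32.3–40.4 µg cm⁻² and
  40.7–63.6 µg cm⁻²), with the median defaulting to the geometric mean
  of the quartiles. Design factors (entry, planting date, irrigation,
  plot, collection, leaf) act as centered log-additive effects whose
  variance shares (0.20/0.05/0.20/0.10/0.25/0.20) sum to the marginal
  log-variance, so the marginal distribution is preserved. The Chl a:b
  ratio is log-normal around 5.5 (first experiment) or 3.6 (second),
  matching the per-pigment quartile ratios.
- **Measurement error**: each tissue sample's concentrations carry a
  common assay error calibrated so paired samples differ by ~9% RMSD
  (within the 8–20% band reported for such assays), plus small
  pigment-specific errors (Chl b noisier than Chl a). Tissue mass is
  normal around 3.2 mg per two-punch sample.
- **The forward reflectance model** is phenomenological, not
  radiative-transfer: Gaussian pigment absorbances in the blue
  (430/460 nm) and red (645/662 nm) applied to a visible baseline (so
  the red trough saturates at moderate chlorophyll, as in real leaves),
  a logistic red edge whose center shifts from 700 nm toward 735 nm
  with chlorophyll (half-shift at 30 µg cm⁻²), a NIR plateau with a dry-
  matter slope, water absorptions at 970/1200/1450/1940 nm scaled by a
  per-leaf relative water content, and additive Gaussian noise
  (sd 0.004) clipped to (10⁻⁴, 0.99). A swap-in interface
  (`ForwardModelParams`) leaves room for a radiative-transfer backend.

All randomness flows from one seed through spawned child generators per
stage (effects, attrition, leaf noise, measurement error, spectra), so
stages are independently reproducible and output files are
byte-identical under a fixed seed.

**What passing tests do and do not show.** The generator reproduces the
designs' bookkeeping, the configured chlorophyll distributions and
paired error, a monotone chlorophyll–red-edge link, and realistic
collinearity structure along the wavelength axis. It does not reproduce
leaf structural effects, canopy/soil mixing, instrument splice
artifacts, or the real covariance between chlorophyll, water, and dry
matter — so quantitative error statistics obtained on synthetic data
characterize the pipeline, not field performance. Cross-experiment
transfer failure is reproduced qualitatively (the two experiments'
chlorophyll distributions differ significantly by Welch's t-test, and
models trained on one experiment degrade on the other), as is the
dominance of red-edge wavebands (696–721 nm region) in clustered
permutation importance.

## Problem sizes used by tests and the acceptance script

Unit tests run on thinned designs (tens to hundreds of rows). The
acceptance script generates both full experiments (5832 + 572 samples),
evaluates the 14-member zoo on the 148-index feature set at plot scale
(n = 1544) with reduced candidate grids (two candidates per tuned
hyperparameter, 5×2-fold search; tree ensembles and the MLP fit at
fixed settings), and runs the importance procedure for 200 iterations
on the planted-signal fixture and 100 iterations on the waveband set.
These sizes were chosen so a complete from-scratch run finishes in a
few minutes on one CPU while leaving every qualitative comparison
well-resolved.

## Known limitations

- The index roster is a literature reconstruction; codes and exact
  band choices for less-common indices may differ from any specific
  published compilation.
- The inverted-Gaussian red-edge estimator is sensitive to the shape of
  the trough side of the window on asymmetric edges (see above).
- ANOVA on RMSE% treats realizations as independent observations; with
  shared training data they are not, so p-values are descriptive, as in
  the source workflow.
- The forward model's absorbance coefficients are calibrated for
  plausibility (trough depths, red-edge span), not fit to measured
  cotton spectra.
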