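# Methods

This note records the models the package implements, the defaults it
ships, the places where the underlying methodology left genuine choices
open, and what the synthetic test conditions do and do not establish.

## BMWP scoring

The index is a presence/absence sum: each distinct family found at a site
contributes its bioindication score (integer, 1–10) once. Family names
are matched after whitespace trimming and case folding; no fuzzy matching
is attempted, because a silently misassigned family corrupts the score
while an unknown-family warning is auditable. Unknown families contribute
zero, are listed in the result and logged — community-collected lists
routinely contain taxa outside the calibrated table, and rejecting the
whole sample would discard usable data. Duplicated records collapse to
one occurrence, so double-counted field entries are harmless, and
abundances are carried for provenance only.

Category bounds are inclusive lower limits, best class first, and the
scheme must reach zero so every non-negative score classifies. The
default six-class scheme (Excellent ≥ 121, Very Good 101–120, Good
61–100, Fair 36–60, Poor 16–35, Extremely polluted < 16) is the six-class
partition of the conventional BMWP scale consistent with every published
value–category pair this package reproduces (28.3 → Poor, 83.8 → Good,
102.72/104.88/108.71 → Very Good, 79.75 → Good); the calibrated cutoffs
themselves were never published, so this is a constrained reconstruction
and the scheme is an ordinary config object.

Seasonal aggregation reports the arithmetic mean with its standard error
(sample SD/√n, defined as 0 for n = 1) and classifies the mean — per-site
categories are conventionally reported on the dry/rainy average.
Tabulation supports both round-half-up and truncation at a chosen decimal
precision because published percentage tables use both conventions
(5/18 prints as 27.77 only under truncation; 8/11 prints as 73 only at
zero decimals).

## Dinius WQI

The index is the weighted geometric mean WQI = Π I_i^{w_i} with weights
summing to one. Subindices are computed from named transform families
(linear, power a·x^b, 10^(a+bx), piecewise-linear, a pH plateau curve,
and two two-argument transforms: dissolved oxygen as percent of
temperature-dependent saturation, and a decay in |water − air|
temperature difference), then clamped to [0, 100] *before*
exponentiation, which keeps the product interpretable and bounded. The
product is evaluated in log space; any zero subindex annihilates it to 0
by construction. Weights must sum to 1 within 1e-6; an opt-in
renormalization mode rescales a reduced spec set for incomplete field
records and logs that it did so.

The shipped default — 12 subindices over the 13 measured parameters
(atmospheric and water temperature share the temperature-difference
subindex), weights 0.109 DO … 0.090 nitrate summing to exactly 1 — is a
transcription of the Dinius 1987 formulation and should be treated as a
reconstruction: the tested contract is the product machinery, clamping,
and category logic, not the constants. Coliform counts of 0 MPN/100 mL
are floored at 1 before the negative-exponent power transforms, mapping a
sterile sample to the best subindex instead of diverging.

Category scales are inclusive-lower-bound walks like the BMWP scheme. On
the general scale the Mild contamination/Acceptable boundary sits at 70,
the only value consistent with the published pairs 68.48 → Mild
contamination and 70.83 → Acceptable; the remaining cutoffs are
conventional. The agriculture and public-water-supply use scales order
their classes as published (for agriculture, best to worst: Purification
Not Necessary → Minor Purification for Crops Requiring High-Quality
Water → No Treatment Necessary for Most Crops → Extensive Treatment for
Most Crops → Unacceptable) with reconstructed numeric bounds; the two
published spellings of the "minor purification" class are display aliases
of one class.

## Riparian NDVI

Rasters are handled by a minimal in-package container: a 2-D grid with a
north-up square-pixel georeference and a CRS label, serialized as ESRI
ASCII grids (plain text, readable by any GIS). Only projected meter-unit
coordinates are accepted; inputs whose CRS label looks geographic (or
unlabelled coordinates inside the ±180/±90 box) raise with an instruction
to reproject, since a "200 m" buffer in degrees is meaningless.

NDVI is computed per pixel with pixels where NIR + R = 0 or either band
is missing set to nodata. The buffer is an oriented rectangle extending
`length_m` (default 200) from the site along the upstream azimuth
(degrees clockwise from grid north) and `half_width_m` (default 120) to
each side — the default total width is therefore 240 m, reading "120 m
at both sides" literally; programs that intend 60 m per side pass
`half_width_m=60`. Zonal statistics use the pixel-center-in-polygon rule
(simple, deterministic, standard); nodata pixels inside the buffer are
excluded from the mean and counted in logs; an empty intersection or
all-nodata buffer is an error rather than a silent NaN.

## Extension validation

The regression stage is ordinary least squares of observed BMWP on any
subset of the eleven admitted qualifiers (salinity, conductivity, Cl,
NO₂, NH₃, color, NO₃, N_total, pH, hardness, SO₄), via statsmodels.
Backward elimination (default α = 0.05) repeatedly drops the least
significant predictor with p > α — the simplest selection procedure that
reduces an eleven-qualifier fit to a two-variable equation. One numerical
guard matters: on noiseless (zero-residual) data OLS standard errors are
0/0 and p-values NaN; the eliminator treats a NaN p-value as droppable
only when the coefficient is negligible relative to the response scale,
so exact generating variables are retained and spurious ones removed. A
constant response defines R² = 0. Rank-deficient designs raise, naming
the columns.

`predict_bmwp` is plain affine evaluation, never clamped; negative
predictions are logged and reported as-is. Band flagging fits calc ~ obs
and computes the pointwise t-based band at each observed value; both the
mean-response (confidence) and new-observation (prediction) bands are
available because point membership is scientifically a prediction-band
question while monitoring practice often quotes "confidence interval" —
the default follows the latter wording and every verdict records which
band was used. An optional test-pairs argument fits the band on
calibration pairs and judges held-out sites against it. Membership gets
1e-9-relative numerical slack so exactly colinear points are never
flagged by float noise.

## Integration

PCA is performed on the Pearson correlation matrix: columns standardized
(ddof = 1), `numpy.linalg.eigh` on the correlation matrix, scores =
standardized data × eigenvectors, components ordered by decreasing
eigenvalue, and each loading vector oriented so its largest-magnitude
element is positive (a deterministic sign convention; eigenvectors are
otherwise sign-ambiguous). Correlation rather than covariance scaling is
forced by the three indices living on incommensurate scales (0–∞, 0–100,
−1–1). Matrix assembly is an inner join on (site, season); rows missing
any index are dropped and logged, and an empty join is an error.

Group comparisons report Shapiro–Wilk per group (NaN for constant
groups, where the statistic is undefined), Levene centered on medians
(robust to non-normality at small n), and one-way ANOVA. The diagnostics
are reported alongside the ANOVA and never used to switch tests
automatically — the workflow this supports reports ANOVA regardless, and
silent test-switching would make runs incomparable. Identical values in
all groups define F = 0, p = 1.

## Synthetic study conditions

The generator emulates the study design the analysis targets: sites
spanning clean to polluted conditions in two seasons, with the first half
of the sites carrying an extra ionic load (conductivity +1500 µS/cm,
chlorides +200, hardness +250, alkalinity +100 mg/L) to emulate the
endogenous salty-river/exogenous-river contrast between sub-basins.

- **Communities.** Family f with tolerance s_f is present at gradient g
  with probability logistic(k(s_f/10 − g)), k = 10 by default — the
  minimal mechanism linking tolerance scores to a pollution gradient, so
  that declining BMWP under pollution is a testable consequence rather
  than an assumption. Every family's occurrence probability is monotone
  decreasing in g, hence so is expected BMWP (a closed-form expectation
  is exposed for tests). The default pool holds 30 illustrative families,
  three per tolerance score.
- **Physicochemistry.** Each parameter is baseline + slope·g + Gaussian
  noise, clipped to its physical range, with slope signs fixed (DO
  −6 mg/L per unit g; BOD₅, coliforms, color, nutrients, ionic load
  positive; water warms 6 °C relative to air). At zero noise the default
  Dinius WQI is non-increasing in g — checked, not assumed, since it
  depends on every default subindex being monotone over these ranges.
- **Rasters.** The NDVI target field is constant inside each site's
  buffer (default target 0.65 − 0.45 g plus +0.10 in the rainy season, a
  dryland range) and the NIR band is the exact inverse
  NIR = R(1 + t)/(1 − t), so the analysis round trip recovers targets to
  machine precision; sites are spaced 600 m so buffers never overlap.
- **Regression tables.** Qualifiers are uniform over realistic field
  ranges and the response follows the published equation plus optional
  noise (floored at 0; inactive at the default ranges and moderate
  noise).

Randomness discipline: one master seed, per-generator derived streams
(`default_rng([seed, stream])`), identical outputs under identical seeds.

What passing these tests does *not* show: the generator has no seasonal
hydrology, no species interactions or dispersal, linear (not saturating)
chemistry, and vegetation painted as uniform blocks — so the tests
establish the *correctness of the computations* and the qualitative
gradient behaviour, not ecological realism, and say nothing about field
values such as a particular basin's R² or PCA variance share, which
depend on undeposited field data.

## Problem sizes and numerical choices

Default test/acceptance sizes — 12 sites × 2 seasons, 500 band-coverage
replicates, 50–200 community replicates, rasters of order 100 × 750
pixels at 10 m — were chosen as the smallest sizes at which the Monte
Carlo assertions are stable (e.g. coverage SE ≈ 0.01 at 500 replicates).
Weight-sum tolerance 1e-6; PCA/OLS oracle agreement asserted at 1e-8;
NDVI round trip at 1e-12; band membership slack 1e-9 relative. Boundary
ties on every category scale go to the higher class.

## Known limitations

- Subindex constants and use-scale cutoffs are reconstructions (see
  above); deployments with the original tables should load them as
  config.
- No map projection machinery: coordinates must arrive already projected
  in meters, and CRS labels are carried, not interpreted.
- No spatial autocorrelation or robust/regularized variants in the
  extension regression; qualifier units are assumed mg/L for nutrients.
- The PCA supports site × season rows (default) and season-averaged rows
  via `SiteIndexMatrix.season_averaged()`; it does not handle missing
  cells.
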