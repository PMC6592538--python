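# Methods

## The measurement model

An ICG angiography recording is treated as a uniformly sampled grayscale
stack `F(x, y, t)` in absolute perfusion units (APU), with `t = 0` at dye
injection. APU are relative fluorescence units; nothing in the pipeline
depends on their absolute scale, and both regional parameters are
affine-equivariant (replacing `F` by `aF + b`, `a > 0`, scales ingress and
rate by `a` and leaves onset/peak times unchanged — a tested invariant).

**Standardization.** Recordings of different lengths are made comparable by
cutting every video 20 s after the start. The cut keeps frames with
`t ∈ [0, 20)` (half-open; the boundary frame is excluded) and a recording
shorter than 20 s is rejected as failing the inclusion criteria rather than
padded. `trim` is idempotent and never alters retained pixel values.

**Regional parameters.** For a region with spatial-mean curve `f(t)`:

* baseline `B̂` = mean of the first `window` frames (default 4 frames, i.e.
  1 s at 4 Hz — recording starts at injection, so the first second precedes
  dye arrival);
* **ingress** = `max f − B̂`, floored at 0. The maximum is taken on the raw
  curve — the parameter is defined as the difference between initial and
  maximal fluorescence, and a brute-force frame scan is the test oracle;
* onset = first time the smoothed curve exceeds `B̂ + k·σ̂` with `k = 3`
  and `σ̂` the baseline-window standard deviation (first frame if the
  threshold is never crossed); peak time = first maximum of the smoothed
  curve. Smoothing is a centered 3-frame moving average used for *detection
  only*, so one noisy frame cannot set the onset or peak;
* **ingress rate** = ingress / (t_peak − t_onset). The rise-based
  definition uses only quantities already defined; a maximum-smoothed-slope
  variant is available as `rate_method="max_slope"`. A curve that peaks at
  (or before) onset has no defined rate and raises a degenerate-rise error;
  a flat curve has ingress 0 and rate 0 by convention.

**Whole-flap selection.** Whole-flap parameters are computed on the "bright
zone": flap pixels whose peak fluorescence lies in the top quantile
(default fraction 0.2). Ties at the threshold are kept, so a uniform image
selects the whole flap, and membership depends only on intensity ranks
(invariant to monotone rescaling). The fraction is a free parameter of the
emulated proprietary function and results should be read with that in mind;
sensitivity enters only the whole-flap numbers, never the ROI ones.

**Zone partition.** The flap mask is split by the midline column; each half
is divided at the midpoint of its column extent, the half nearest the
midline forming the central ROI. This yields ROI1 (ipsilateral periphery,
Hartrampf III), ROI2 (perforator area, Hartrampf I), ROI3 (contralateral
central, Hartrampf II), ROI4 (contralateral periphery, Hartrampf IV) —
pairwise disjoint, union exactly the flap mask, mirror-symmetric under
reflection. The equal-width split is a reproducible convention; arbitrary
ROI polygons can be supplied instead by constructing a `ZoneSet` directly.
A perforator whose column equals the midline column is rejected as
ambiguous (its side is undefined); consequently the column just left of the
boundary has no valid mirror image, the one asymmetry of the convention.

**Pattern classification.** The per-pixel ingress map stands in for the
visual color overlay. Features: zone-mean ratios `r1 = ROI1/ROI2`,
`r3 = ROI3/ROI2`, `r4 = ROI4/ROI2` and a midline-crossing index (mean
ingress in a band just across the midline over the mirror band on the
perforator side; band width 10 % of flap length per side). Rule, with
defaults `τ_cross = τ_periph = 0.5`:

1. crossing ≥ τ_cross and `min(r1, r4) < τ_periph` → type 3;
2. crossing < τ_cross and `r1 ≥ τ_periph` → type 1;
3. otherwise → type 2.

The rule is total and deterministic, and because all features are ratios it
is invariant to positive rescaling of the map. The original patterns were
assigned by eye, so no published thresholds exist; the defaults are round
numbers whose adequacy is established by the recovery experiment (≥ 95 %
correct labels over 300 simulated flaps; measured: 100 %).

## The synthetic-data generator

**What it emulates.** Bolus kinetics per pixel follow a peak-normalized
gamma-variate (the standard indicator-dilution form), so the peak is
exactly `B + A` and true ingress is closed-form. Spatial structure: the
amplitude decays exponentially with Euclidean distance from the perforator
(length scale λ), is multiplied by `m ∈ (0, 1]` beyond the midline and by
`p ∈ (0, 1]` in the outermost 15 % of flap length at each end; arrival is
delayed by `d/v`. The three presets are: type 1 — λ = 200 mm, m = 0.3,
p = 1; type 2 — λ = 20 mm, m = 0.6, p = 1; type 3 — λ = 200 mm, m = 1,
p = 0.3. Noise is additive zero-mean Gaussian (default sd 2 APU), clipped
to [0, 255]; identical seeds give bit-identical stacks.

Default conditions: 128 × 256 px elliptical flap at 1 mm/px, midline at the
central column, perforator 36 px left of the midline; 4 Hz, 25 s (so the
20-s cut is exercised); B = 5, A₀ = 150 APU; t₀ = 2 s, t_p = 10 s, α = 2,
v = 30 mm/s. The rise time and speed were chosen so that every pixel peaks
inside the 20-s window and regional rise times come out near 10–13 s,
matching the scale implied by the clinical medians the generator emulates
(ingress ≈ 127 APU at ≈ 9.4 APU/s); the preset-2 decay length was chosen
tight enough (20 mm) that the confined phenotype survives the upward bias
that frame-wise maxima acquire under noise (≈ +2.5 APU per pixel at sd 2).

**Two deliberate idealizations.**

* Arrival times are quantized to the frame grid (`snap_arrival=True`), so
  every pixel's sampled maximum attains its analytic peak exactly and the
  noiseless per-pixel ingress equals the amplitude field to float32
  precision — the property the exactness tests rely on. Disabling the snap
  reintroduces a small (≲ 0.1 APU) sampling deficit.
* Per-zone "true" ingress is defined as the ingress of the *noiseless
  region-mean curve* (computed exactly by the simulator), not the mean
  amplitude: with finite propagation speed pixels peak at different times,
  so the mean curve's maximum is strictly below the mean per-pixel maximum
  (max-of-mean ≤ mean-of-max). The tested equality of map-mean and
  curve-ingress therefore holds only in the synchronized (infinite-speed)
  limit.

**What it does not emulate** — and hence what passing tests do not show
about real recordings: washout/egress (videos end before it matters),
Poisson shot noise, camera PSF and vignetting, breathing/motion, ambient
light, and any physiologic ICG pharmacokinetics beyond the single-bolus
rise. Real SPY-type systems may also define their bright zone and "blush
rate" differently; the definitions here are explicit and the rate's
alternative is exposed as an option.

**Cohort generator.** One row per patient: binary covariates at configured
prevalences (defaults from a 40-patient series: diabetes 0.05, overweight
0.525, hormone therapy 40/47.5/12.5 % none/tamoxifen/aromatase-inhibitor,
…), a pattern label at 14/16/10 frequencies, and log-normal perfusion
outcomes `center × ∏(effects of positive covariates) × exp(N(0, σ))` with
σ = 0.45 (chosen to reproduce the emulated whole-flap ingress IQR of
roughly [86, 167] around a 127 APU median). Default effects are stratum
mean ratios of the emulated series (diabetes 0.34 on whole-flap ingress,
0.20 on whole-flap rate; tamoxifen 0.42 on zone-I rate; age > 60: 1.89 on
zone-I ingress, 3.66 on zone-I rate, …). Because outcomes are exactly
multiplicative, stratum-mean ratios recover the configured effects — the
large-n law-of-large-numbers tests use balanced covariates (prevalence 0.5)
where a ±0.02 band is several standard errors wide; at prevalence 0.05 the
ratio's sampling error (~2 % at n = 10 000) makes such a band meaningless.

## Statistical engine

Continuous outcomes: two-sided pooled-variance (classical) t test for two
groups — Welch by flag — and one-way ANOVA beyond two; complete-case per
comparison. Categorical associations: contingency table, chi-square when
every expected count is ≥ 5, Fisher's exact test otherwise. Two choices to
note: the chi-square is applied **without** Yates continuity correction so
the test attains its nominal level (measured type-I error 4.6 %/4.75 % for
the two families over 2000 null replicates, inside [3.5 %, 6.5 %]); and
Fisher's exact test covers 2×2 tables (larger sparse tables fall back to
chi-square with an explicit validity warning — the comparisons this package
targets are 2×2 or near). The Fisher path is verified against an exhaustive
hypergeometric enumeration oracle over every 2×2 table with margins ≤ 15
(maximum deviation ~3e-16). The univariate report applies no
multiple-testing correction and performs no multivariate modelling, by
design; its note says so.

## Numerical conventions and degenerate inputs

0-based row/col pixel coordinates, half-open intervals throughout; the
midline column index is the boundary (first contralateral column). Ties:
first maximum for peak time; `≥` threshold for bright-zone membership.
float32 storage for frames (lossless for simulated APU); float64
arithmetic in analysis. Empty masks, single-level grouping variables,
stacks shorter than the cut, metadata/page-count mismatches and
out-of-range parameters raise typed errors (`GeometryError`,
`ParameterError`, `QualityCriteriaError`, `MetadataError`, `SchemaError`,
`DegenerateRiseError`) rather than propagating NaNs.

## Problem sizes

The test suite and the acceptance script run on the desk-scale defaults:
300 flaps for pattern recovery, 40 for zone ordering, 100 noisy replicates
for regional recovery, 2000 null replicates per test family, ~10 800
Fisher tables, n = 10 000 for cohort effect recovery — a few minutes in
total on one CPU. These sizes were chosen as the smallest at which the
stochastic checks have comfortable statistical margins.

## Known limitations

* The bright-zone fraction, onset multiplier, baseline window and
  classification thresholds are conventions standing in for undocumented
  proprietary choices; all are exposed as parameters and the defaults are
  validated only against the synthetic conditions above.
* The classifier reads the static ingress map; if clinical pattern typing
  also used temporal order of arrival, the time-to-peak map carries that
  information but no rule for it is implemented.
* Perforator-anatomy analysis, outcome prediction and flap segmentation
  from raw video are out of scope; geometry (mask, midline, perforator) is
  an input.
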