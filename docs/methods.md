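# Methods

This note documents the models, conventions and design choices behind the
package, in the order the pipeline runs them.

## Synthetic survey generator

No public survey pairs full-waveform bathymetric LiDAR with georeferenced
photo-quadrats, so the generator produces one with the statistical structure
the downstream analysis assumes.  It is first-class, tested code, and its
defaults *are* the study conditions used throughout the test suite.

**Depth model.** A 2-m grid (default 60 × 80 cells) with depth increasing
from the shore (north edge) seaward over 2–16 m, a power-law shore-normal
profile, and a smooth embayment indenting the central shoreline.  The
embayment multiplier is monotone along every column, so with zero
small-scale noise each column is strictly increasing seaward — a property
the tests assert.  Small-scale relief is a Gaussian-filtered noise field
(default sd 0.15 m).

**Structural complexity.** A latent [0,1] field rising with depth (deeper
bottoms see stronger hydrodynamics and coarser, more structured substrata in
the emulated system) plus smooth spatial noise.  Substratum truth
(fine sand / pebbles / cobbles / boulders) is complexity thresholded at
0.3 / 0.55 / 0.75, so hard substrata are structurally complex by
construction.

**Waveforms.** Each sounding is a 1 ns-sampled trace: Gaussian surface peak
(amplitude 100, σ 1.5 ns, at t = 12 ns), exponential water-column decay
(amplitude 12, 0.1 ns⁻¹), constant 2-count baseline, additive Gaussian noise
(default sd 0.6 counts), and a skew-normal benthic pulse whose *mode* sits
exactly at t_surface + κ·depth with κ = 8.9 ns/m (two-way travel at
≈ 0.225 m/ns in water; the paper-scale physics fixes only the product, any
consistent constant works).  Complexity c drives the pulse shape through
shape α = 5(1 − 2c) and scale ω = 6 − 4.5c ns: flat ground returns a narrow
pulse with an elongated right tail (photons straggling off a flat bottom),
complex ground a broadened leading edge with no tail (photons intercepted by
canopy strata above the bottom), so the time-skewness of the return
decreases strictly with complexity.  Benthic amplitude decays with depth
(0.09 m⁻¹) and is multiplied by a per-sounding lognormal bottom-reflectance
factor (log-sd 0.6 by default): natural seabeds are patchy in albedo, which
makes the return's *amplitude* statistics unreliable structural cues and
leaves the signal in its *shape* — without this term, amplitude features
dominate every model and no real-world sensor would behave that way.

**Stations and quadrats.** 300 stations uniform over the grid without
substratum stratification (one per cell).  Quadrat covers are built from a
habitat-suitability score u = (w_d·depth_norm + w_c·complexity)/(w_d+w_c)
plus Gaussian noise (defaults: w_d = w_c = 0.5, sd 0.08).  Species
occurrence is logistic along u with species-specific preference centres;
covers follow a geometric dominance profile with ratio 0.15 + 0.85u that
flattens as u rises, jittered by a Dirichlet draw (concentration ∝ 1/0.25),
quantized to integer percents by largest-remainder rounding on the 100-cell
grid.  Abiotic covers fill the residual image area, weighted 0.7 toward the
station's true substratum.  Simpson diversity therefore increases with both
depth and complexity, spans the full [0, 1] interval across a survey, and
empty or monospecific quadrats occur at low suitability.  A `layered_cover`
switch permits Σ biotic > 100 (canopy layering); it is off by default
because the layering protocol of real image scoring is not standardized.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: instrument telemetry and flight-line geometry,
water-column inhomogeneity (turbidity layering), sensor saturation, species
identity (taxa are exchangeable labels), and any ecological dynamics beyond
the static depth/complexity gradients.  Recovery results on this generator
demonstrate that the pipeline is correct and sensitive at realistic noise
levels, not that a particular field system attains a particular accuracy.

## Waveform segmentation and features

The noise floor is the median of the first five pre-surface samples, its sd
the detection scale.  Peaks are detected on a 5-sample moving average with
prominence ≥ 3 sd; the first prominent peak is the surface, the last the
benthic return; fewer than two peaks raises a "bottom signal lost" error
(the emulated system loses bottom beyond ~16 m).  The surface flank ends
where its decay rate falls to water-column levels; the water column is
fitted by a line over the first 70% of the inter-peak stretch, and the
transition begins where the trace leaves that line.  The benthic interval
extends from the peak outward to the noise floor on both sides (trough
fallback on the shore side), widened to a 10-sample minimum so the decile
statistic is defined.

Twelve statistics summarize the benthic interval and four the transition.
Mean, variance, median, mean absolute deviation, min, max and the intensity
range are moments of the *intensity sample* distribution (photo counts).
Skewness and kurtosis are computed on the *time axis* with
baseline-subtracted intensity as probability mass, trimmed below 5% of the
segment peak: these quantify the left/right asymmetry of the return in time,
which is the quantity the diversity models exploit (a time-mirrored pulse
has an identical intensity multiset, so intensity-sample skewness cannot
express the tail direction).  Kurtosis is non-excess; degenerate segments
report 0 for both by convention.  AUC is trapezoidal; the time range is the
time between the interval's global intensity maximum and minimum.  H′dec
normalizes the ten deciles (10th..100th percentiles, linear interpolation)
of benthic intensity to q_j and returns −Σ q_j ln q_j ∈ [0, ln 10].

Depth detrending fits each feature with a 2nd-degree polynomial in depth and
standardizes the residuals (exact fits report zeros rather than amplified
rounding noise); PCA keeps the smallest component set reaching 95% variance.

## Diversity indices

H′ deliberately uses image fractions (cover%/100), not abundance-normalized
proportions — the index is therefore not scale-free, which the tests assert
as a property.  Log transforms are base-10 with the argument floored at
1e-4 so monospecific quadrats (D = 0) stay finite and order-preserving;
empty quadrats report D = H′ = mJ′ = 0.

## Morphometry

Quadratic coefficients come from an ordinary least-squares fit in
cell-centred metric coordinates (edge cells use nearest padding).  Slope is
atan √(d²+e²); aspect is the compass bearing of the downslope vector
(NaN on flats); shaded relief is the clipped Lambertian cosine against a
315°/45° sun; profile/plan and longitudinal/cross-sectional convexities
follow Wood's formulas with positive = convex; principal curvatures are
−a−b ± √((a−b)²+c²); absolute roughness is the 3×3 depth SD and local
roughness the SD after removing the 3×3 best-fit plane.  Terrain typing
uses slope tolerance 1° and curvature tolerance 0.005: sloping cells split
ridge/plane/channel on the cross-sectional convexity sign, level cells split
peak/ridge/pass/plane/channel/pit on the principal-curvature signs.  The
6 m and 12 m scales map to 3×3 and 7×7 windows on the 2-m grid (the nearest
odd cell counts).  The grid values are analysed as the surface itself; pass
negated depths for an elevation-convention analysis — the pipeline's
labels are internally consistent either way, and negating the input swaps
peak↔pit and ridge↔channel exactly (a tested property).

## Substratum map and kernel β-diversity

Ground truth is sampled per class from the truth raster (60 pixels/class by
default), split 2/3 training, 1/3 validation.  The classifier is an RBF-SVM
on standardized PC scores with a small C/γ grid search under stratified
cross-validation; no post-classification resampling.  Bray–Curtis compares
the class composition of the focal disc (default radius 6 m, matching the
smaller terrain scale) with an equal-area surrounding annulus (outer radius
r√2): BC% = 100·Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ), 0 for identical and 100 for disjoint
compositions; a map-wide comparison is available behind a flag.  Evenness
divides the disc's composition entropy by ln R over the R classes present
(0 when R = 1).  Both are computed by per-class convolution and match
brute-force per-cell recomputation exactly.

## Learners and evaluators

Settings are fixed, not tuned: trees never split nodes below 10 samples;
leaf probabilities are m-estimate smoothed with m = 5 toward the training
priors; the classification tree uses information gain; C4.5 uses gain ratio
with pessimistic-error pruning at 25% confidence (Clopper–Pearson upper
bound on the leaf error count); the random forest has 10 trees with
6-variable split subsets (recomputed as round(√p) when the predictor table
is not the canonical 34 columns); the SVM standardizes inputs; CN2 runs a
beam-5 general-to-specific search over decile-threshold selectors with
Laplace rule evaluation, likelihood-ratio significance (α = 0.05 against
the remaining examples, stopping α = 0.2 per specialization) and exclusive
covering.  The regression tree predicts the numeric class index and is
scored after rounding to the nearest class (one-hot probabilities).

CA is argmax accuracy.  AUC is macro one-vs-rest rank probability with ties
counted ½ (the printed definition covers only the binary case; macro
averaging is this package's multi-class reading).  The information score
credits, in bits, probability assigned beyond the class prior and penalizes
probability withdrawn from it; a prior-emitting predictor scores exactly 0.
The Brier score is halved so that certain-wrong prediction scores 1 and
certain-correct 0 on its printed [0,1] bounds.

The protocol uses a single fixed 200/100 train/test split per survey (test
count takes precedence over the nominal 34%), equal-width bins over the
observed response range except for the Simpson index, which is binned on its
theoretical [0,1] interval (its tercile cuts are then 0.3333/0.6667);
binary models are excluded from selection, ties on CA break by lower Brier
then by fixed learner order.  Accuracy decay over k = 2..10 is fitted by
OLS on 1/k with R²adj = 1 − (1−R²)(n−1)/(n−2); a constant series reports
R² = 0 by convention.

## Spatial statistics

Moran's I uses row-standardized 8-nearest-neighbour weights for stations
(rook/queen builders exist for rasters) and a seeded 999-permutation pseudo
p-value measured as distance from the null expectation −1/(n−1).  Because
the synthetic seascape varies smoothly, station diversity is strongly
autocorrelated by construction; the permutation test will call it
significant, and no attempt is made to calibrate this to any particular
survey's verdict.  The predictive map applies the selected learner to every
valid cell of the 34-band stack, propagating no-data, and retains the
per-class probability layers so users can re-threshold.

## Problem sizes and runtime

The default survey is a 60 × 80 grid (4 800 soundings) with 300 stations —
dense enough for every stage to operate at its intended scale while a full
survey → predictors → 8-response × 7-learner × 9-k benchmark runs in well
under a minute.  The recovery tests replicate this ten times with seeds
1..10.  Raster I/O is ESRI ASCII grid; waveforms use a documented
space-separated text table; all outputs are plain text.

## Known limitations

The water-column linear fit is a segmentation device, not an attenuation
model; transition statistics depend on its 70% fit window.  The time range
is bimodal under noise (the global minimum falls on either flank), which
adds variance but preserves its negative relationship with diversity.  CN2
restricts selectors to decile thresholds and caps rule length at 5 for
tractability.  The m-estimate post-pruning of the CART-style trees is
realized as probability smoothing, not structural pruning.  Moran's I
significance is permutation-based and will disagree with tools that use
analytic normality assumptions.
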