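# Methods

## SMI quantification

Monochrome SMI encodes Doppler flow strength as an 8-bit gray value per
pixel.  For a region of interest given as a polygon (or rectangle as two
corners) in (row, col) coordinates with a 0-based top-left origin, the pixel
mask contains every pixel whose center (r + 0.5, c + 0.5) lies strictly
inside the polygon; integer-corner rectangles therefore behave half-open
(a (0,0)–(2,2) rectangle covers exactly 4 pixels).  Pixel centers exactly on
the boundary are excluded.  This convention is unambiguous, matches common
raster practice, and makes the rasterization testable against a brute-force
point-in-polygon loop.

Two ROI statistics are computed:

* **mean gray** — the arithmetic mean of the masked pixel values;
* **area fraction** — the proportion of masked pixels with value ≥ a
  flow-positivity threshold.

The threshold is a configurable rule resolved *per analyzed region*:

* `fixed(k)` — a constant, used wherever determinism matters;
* `isodata` (default) — the intermeans (Ridler–Calvard) fixed point
  t = round((μ(values < t) + μ(values ≥ t)) / 2) of the masked histogram,
  the default auto-threshold family of the common interactive tools for this
  task.  The iteration starts from the midpoint of the occupied gray range;
  this start matters: it selects the between-class fixed point even when the
  flow-positive class is rare (~1 % of pixels), whereas starting from the
  histogram mean can converge to a spurious split *inside* the dominant
  background mode.  A constant region has no intermeans split; the rule then
  returns max + 1 (area fraction 0) with a warning instead of dividing by
  zero.  The intermeans iteration is implemented directly rather than via a
  generic library threshold because the contract requires integer
  thresholds, the ≥ classification rule, masked histograms and the
  constant-region fallback.

Each nodule statistic is divided by its parenchyma counterpart to give a
vascularization quotient.  A zero parenchyma denominator yields an
*undefined* quotient, stored as NaN — never ±inf — and excluded pairwise
from downstream statistics.  Two frames are acquired per section plane; the
*parameter* (not the pixels) is averaged across frames, which is robust to
frame-to-frame misalignment and makes averaging idempotent on duplicated
frames.  ROI-B is expected to match ROI-A in size and depth; since this
cannot be enforced from pixels alone, the code only warns when the
rasterized areas differ by more than 25 %.

The ten-parameter profile (per-plane mean gray and area fraction, their
quotients, and the whole-lobe "all" quotients) treats gray values as
dimensionless and fractions as proportions in [0, 1].  Whether whole-lobe
quotients should reuse a nodule threshold is open; the implementation
resolves the threshold independently for every analyzed region.

## IHC quantification

RGB micrographs are converted to optical density per channel as
OD = −log10(max(I, 1) / 255) (intensities clamped to 1 so the transform
never diverges; OD(white) = 0).  Per pixel, the two-stain model
OD = M·c is solved by least squares for the concentration vector c, where M
holds the unit-norm haematoxylin and Fast-Red OD vectors as columns;
negative components are clipped to zero after solving.  Default vectors are
the published haematoxylin vector (0.650, 0.704, 0.286) and the Fast-Red
vector (0.214, 0.851, 0.478) from the standard colour-deconvolution vector
sets, normalized; real-slide vectors vary with staining batch and camera and
are overridable in configuration.  A third (residual) channel is not fitted:
the protocol has exactly two chromogens, and the clipped two-stain least
squares is better conditioned.

A pixel is CD34-positive when its Fast-Red *concentration* (OD units)
reaches a configurable threshold, default 0.15.  Thresholding is done in
concentration units rather than in an 8-bit rescaled extracted image: it is
the physically meaningful scale and is independent of display rescaling.
Sampling rectangles are explicit inputs (JSON), never auto-selected,
trading automation for reproducibility.  The standard rectangle is
1440 × 1443 px = 2,077,920 px; its physical area is 1 mm² at 100× and
scales as (100/mag)², hence 16 mm² at 25×.  Non-standard rectangle sizes
(used for small synthetic images) scale the area linearly in pixel count.
The per-nodule summary averages four 100× field fractions (*CD34 100-fold*),
takes one 25× fraction (*CD34 25-fold*), and averages those two (*CD34
all*), so *CD34 all* always lies between the other two.

## Statistics

Group summaries report n, mean, SD (n − 1 denominator), median and range;
an SD over a single observation is NaN.

**Wilcoxon rank-sum.** Statistic: sum of pooled mid-ranks of the first
sample.  For n₁ + n₂ ≤ 20 the two-sided p is exact: all C(n₁+n₂, n₁)
assignments of the (tie-respecting) mid-ranks are enumerated and the smaller
tail (including the observed point) is doubled, capped at 1.  Above 20, a
normal approximation with tie-corrected variance and 0.5 continuity
correction is used.  Exact enumeration is the default at the study's sizes
because asymptotics are unreliable at n = 16.

**Spearman.** r is the Pearson correlation of mid-ranks.  The two-sided p
is a permutation p: full n! enumeration for n ≤ 8; for 8 < n ≤ 20 a
Monte-Carlo permutation distribution with 10⁵ draws under the fixed seed
20210, using the (hits + 1)/(draws + 1) estimator so the p-value is never
exactly zero; a t-approximation with n − 2 df is used above 20 or on
request.  Zero rank variance leaves r undefined (flagged NaN).

**Partial Spearman.** All variables are rank-transformed over complete
cases; the partial correlation is the Pearson correlation of the residuals
of the x- and y-ranks after least-squares regression on the covariate ranks
(algebraically equivalent to the inverse-correlation-matrix formula, but
well-defined when x and y are perfectly correlated with each other), with a
t-approximate p on n − 2 − k df.  Zero residual rank variance — e.g. a
covariate identical to one of the variables — flags the result undefined.
Partialling is done on ranks (partial *Spearman*) since the analysis is
rank-based throughout.

Missing and undefined values (e.g. 0/0 quotients) are deleted pairwise per
test or correlation cell, and the exclusion count is carried in every
result.  No multiple-testing adjustment is applied anywhere; all p-values
are raw.

## Synthetic data

**SMI scenes.** Vessels are planted as curvilinear random-walk strokes
(default width 3 px, direction jitter sd 0.35 rad) inside each polygon until
an exact target pixel count round(fraction × polygon pixels) is reached —
strokes mimic the curvilinear appearance of real flow signals rather than
salt-and-pepper noise, and the exact count makes the placement quantum one
pixel.  If strokes stall in dense fills the remainder is completed
pixel-wise, so the realized count is always exact and is returned as ground
truth.  Background (and vessel) pixels get Gaussian noise (default sd 8)
and the image is clipped to [0, 255] and quantized to 8 bits.  Default
intensities: background 30, vessels 180 — an 18-sd class separation, which
is what makes auto-thresholding near-exact in the recovery tests.  This is
deliberately *not* a physical speckle model (no Rayleigh statistics, no
point-spread correlation): passing recovery tests shows the measurement
chain is correct, not that it is robust to real acoustic texture.

**IHC scenes.** A vessel mask is planted the same way across the image; a
Poisson-like scatter of nucleus disks (default 2000 mm⁻², radius 5 px at
100×, scaled with magnification) carries haematoxylin OD (default 0.6);
vessel pixels carry Fast-Red OD (default 0.8).  RGB is the Beer–Lambert
forward map of M·c plus optional Gaussian OD noise.  The generator returns
*continuous* RGB in [0, 255]; quantization to 8 bits happens only when an
image file is written.  This keeps the forward→unmix round trip exact to
machine precision, which is what the round-trip invariant tests; quantized
files add a bounded OD error (~2 × 10⁻³ at mid-gray) that is irrelevant at
the 0.15 positivity threshold but would dominate a 10⁻⁶ tolerance.

**Cohorts.** Per group (benign/malignant), the quotient outcome follows a
Gamma distribution (positive support) and the CD34 fraction a Beta
distribution (support [0, 1]), moment-matched to the group mean/SD defaults
(quotient 0.88 ± 0.89 vs 1.13 ± 0.19; CD34 0.05 ± 0.05 vs 0.08 ± 0.06;
age 39.75 ± 12.74 y; BMI 26.08 ± 5.18 kg/m²; nodule length 27.92 mm benign
/ 35 mm malignant, sd 10 mm — the group SDs of length are not reported, so
10 mm was chosen as a typical clinical spread).  The two outcomes are
coupled by a Gaussian copula with latent Pearson correlation
ρ_z = 2 sin(π ρ_s / 6), so the *population Spearman* coefficient within a
group equals the requested ρ_s exactly (the copula is rank-preserving under
the monotone marginal transforms; ρ_s = ±1 produces identical/reversed rank
orders exactly).  Note that the pooled two-group Spearman correlation
slightly exceeds the within-group latent value when both outcomes shift in
the same direction between groups; at the study's 13:3 composition the
inflation is within the recovery tolerance.  Default cohort: 13 benign + 3
malignant, latent ρ_s = 0.556 (the scale of the observed headline
correlation).

**Synthetic studies.** `pipeline.synthesize_study` ties the three
generators together: per patient the planted SMI node fraction is the
cohort quotient × a base parenchyma fraction of 0.15 (clipped to 0.9) and
the planted IHC vessel fraction is the cohort CD34 outcome, so the full
pipeline can be validated against the cohort table.  Exact per-field
ground-truth fractions are also written, because a field rectangle samples
a clumpy stroke pattern and its exact fraction differs from the scene-wide
target by sampling noise.

## Numerical and design choices

* Polygon interiors are evaluated with exact geometric predicates
  (`shapely`); rasterization excludes boundary centers on both the
  implementation and oracle side.
* The least-squares unmixing uses the pseudo-inverse of the 3 × 2 stain
  matrix; collinear stain vectors are rejected at configuration time.
* The exact rank-sum enumeration is vectorized over all index combinations;
  at the package's enumeration limit (n₁ + n₂ = 20) this is ~185 k sums.
* All generators take one integer seed and draw from a single `numpy`
  Generator, so identical specs produce bit-identical images, masks and
  cohorts; pipeline outputs embed the seed and a configuration hash and are
  byte-identical on rerun.
* Problem sizes in the test and acceptance runs (images of 64 × 128 to
  100 × 256 px, cohorts of 16 to 500, 400 null replicates) were chosen as
  the smallest sizes at which each property is cleanly measurable.

## Limitations

* The synthetic sonograms and micrographs are measurement-chain phantoms:
  correct geometry, intensity classes and stain algebra, but no acoustic
  speckle physics, no out-of-focus light, no chromatic vignetting, no
  segmentation-hard nuclei.  Passing tests validate the quantification
  code, not its behaviour on clinical images.
* The cohort generator targets the reported group-level means/SDs only; the
  real per-patient joint distribution of all thirteen parameters is unknown,
  so cross-parameter correlation structure beyond the single modelled pair
  is not emulated.
* Stain vectors and the 0.15 positivity threshold are sensible defaults,
  not calibrated constants; real studies should calibrate both per batch.
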