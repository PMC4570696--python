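# Methods

## The scoring model

`histoseverity` turns a 512×512 grayscale histology cutout into a single
continuous inflammation-severity score in [0, 1]. The pipeline has four
stages.

**1. Illumination normalization.** Brightfield slides always contain
empty (tissue-free) regions whose intensities form a peak on the right
side of the histogram. Illumination differences shift that peak, so each
image receives a constant additive bias chosen by grid search (default
range ±0.2, step 1/512) to maximize the Pearson correlation between its
histogram and a reference image's histogram inside a window of ±10% of
the intensity range around the reference's white peak. Pixels are
clipped, not rescaled, after biasing — the correction is purely additive.
A histogram peak qualifies as "white" if it is a local maximum of the
256-bin histogram, exceeds 1% of the modal bin height, and lies at or
above intensity 0.25; the floor encodes the prior that empty slide
regions are bright, and makes an all-dark image fail loudly rather than
align on a dark mode. Windowed correlation is the default; a
`windowed=False` flag compares full histograms instead.

**2. Gabor filter bank.** Each cutout is convolved with 216 real Gabor
filters

g(x, y) = exp(−(x′² + γ²y′²)/2σ²) · cos(2π x′/λ + φ),
x′ = x cos θ + y sin θ, y′ = −x sin θ + y cos θ,

over the grid φ = 0; θ ∈ {0°, 30°, 60°, 90°, 120°, 150°};
γ ∈ {0.5, 2, 4}; λ ∈ {20, 30, 40} px; b ∈ {5, 10, 15, 20} octaves.
The envelope width is tied to the half-response spatial-frequency
bandwidth b by σ/λ = (1/π)(√ln2/2)(2ᵇ+1)/(2ᵇ−1). Note that these
bandwidths are far above the ~1 octave customary for Gabor analysis:
σ/λ is nearly constant (0.1411 → 0.1325) across the grid, so the four
bandwidth levels produce almost identical filters and every filter is
broadband with substantial DC gain. The grid is implemented exactly as
specified; its consequences (feature redundancy across b, mean-dominated
variance) are noted below.

Kernels are sampled on integer offsets with support ±⌈3·max(σ, σ/γ)⌉
(γ < 1 widens the y′ envelope). Convolution is true convolution with
symmetric (edge-mirroring) boundary handling, which avoids the dark-frame
artifacts zero padding would inject into every map statistic. The FFT
path pads, transforms, multiplies and crops; it matches direct
spatial-domain convolution to better than 1e−8 and is the default. A
`BankConvolver` caches the kernel spectra at a common FFT size so a
cohort costs one forward transform per image plus one inverse per filter.

Responses are *signed* convolution values, max-pooled elementwise over
the six orientations — the literal reading of taking "maximal values of
responses"; pooling magnitudes instead is available via
`orientation_max`/`pooled_response_stack` on absolute responses if
wanted for sensitivity analysis. Pooling leaves 36 maps, one per
(b, λ, γ) triple, and makes the downstream statistics invariant to the
arbitrary rotation of tissue in the slide: for an oriented grating
rotated by multiples of 30° the pooled map means move by < 0.2%.

**3. Feature generalization.** Each pooled map is reduced to three
histogram functionals: the arithmetic mean; the population skewness
(third central moment over s³, s = √(second central moment), matching
the 1/mn normalization of the defining formulas; zero-spread maps return
0 with a warning); and the Shannon entropy in bits of a 256-bin
histogram spanning the map's own [min, max]. A per-map histogram range
is used because pooled response scales differ by orders of magnitude
across triples; bin count and range convention are configurable. The
36 triplets concatenate to the 108-feature vector in canonical bank
order (bandwidth outermost, then wavelength, then aspect ratio).

**4. PCA severity score.** The training matrix X (n cutouts × 108
features) is mean-centered (default) and the m×m feature scatter
S = WᵀW/(nm) is eigendecomposed. Operating on the feature-space scatter
is the dimensionally coherent reading of the defining equations (the
n×n image-Gram alternative yields the same projections up to scale).
Centering can be disabled (`center=False`) to decompose the literal
uncentered second-moment matrix; in that regime PC1 largely encodes the
global feature mean and its variance fraction is inflated. No per-feature
standardization is applied by default, matching the raw-scale convention;
a `standardize=True` flag exists for exploration. Because the mean
features carry DC gains proportional to σ²/γ, raw-scale PC1 is dominated
by large-wavelength mean features and behaves mostly as a calibrated
overall-brightness axis — which is exactly what tracks crypt loss and
infiltrate density in these images.

The first eigenvector's sign is arbitrary; when per-row ordinal severity
hints are given (e.g. control < chronic < acute), PC1 is oriented so the
raw projection increases with them, otherwise the largest-magnitude
loading is made positive. Training projections are min-max normalized to
[0, 1] (1 = most severe); new cutouts are projected onto the stored axis
and clipped into range with a `clipped` flag, since the scale is defined
only on the training sample. `SeverityResults` exposes the scree table,
per-feature PC1 loadings (`contributions`), grouped |loading| reports,
plots, JSON persistence with a feature-layout hash, and a `summary()`.

## Expert-validation protocol

Validation imitates a double-blind pairwise experiment: two cutouts are
shown, the expert picks the more inflamed one, and agreement is the
fraction of non-tied pairs where the pick has the higher score (ties,
possible after clipping, are excluded and counted separately). Binning
pairs by score difference Δ gives the mismatch-ratio curve (default 20
equal-width bins over [0, 1]); the smallest Δ beyond which every bin's
mismatch stays below an acceptable threshold is reported as the method's
effective resolution. The threshold is a free parameter — what mismatch
level is "acceptable" is a judgment the data cannot make — so no default
is endorsed beyond the CLI's 0.05 example. Real choices arrive as a CSV
(`id_a,id_b,expert_choice`); for tests and calibration a simulated
expert errs with logistic probability P(mistake) = 1/(1 + e^{kΔ}),
maximally confused at Δ = 0 and reliable for well-separated pairs.

## Synthetic cutouts

With no public image archive for this method, validation uses a
generator that emulates the relevant morphology of HE-stained colon
mucosa at the native geometry (512×512 px, ~0.6 μm/px):

- **crypts**: bright (0.92) elliptic regions, full axes 180–350 px by
  50–130 px, random centers/orientations;
- **inflammatory spots**: dark (0.18) discs 7–25 px in diameter;
- **stroma**: mid-gray background (0.55) with Gaussian noise
  (σ = 0.02).

One latent severity in [0, 1] drives three linear trends chosen to
mirror inflammation progression: crypt count falls from 12 to 4, crypt
boundary irregularity (low-order radial harmonics of relative amplitude
up to 0.35) rises, and spot density rises from 0 to ~6.1×10⁻⁴ spots/px²
(~160 spots per cutout). Slopes and levels are configurable on
`SyntheticSpec`. Generation is bit-reproducible from the seed; cohorts
derive per-cutout seeds from the cohort seed via
`SeedSequence([seed, index])` so members are independently regenerable.
The realized object lists are retained as ground truth.

What the generator does *not* emulate: stain color (everything is
luminance), nuclei-level texture, spatially varying illumination, tissue
folds/gaps, and the long-range glandular organization of real mucosa.
Passing recovery tests therefore demonstrates that the pipeline measures
the intended geometric signal (spot density, crypt loss/distortion)
under controlled conditions — not that it attains any particular
accuracy on real slides.

## Numerical choices and edge cases

- Intensities are floats in [0, 1]; 8-/16-bit inputs divide by their max
  code value; RGB reduces by Rec. 601 luminance.
- Bias grid is built as integer multiples of the step so 0 is always a
  candidate; correlation ties resolve to the smallest-|bias|.
- Entropy of a constant map is 0 (single occupied bin); skewness of a
  zero-spread map is 0 with a warning rather than an error so degenerate
  fixtures don't abort batch runs.
- The bandwidth↔σ/λ inversion has a pole at σ/λ = √ln2/(2π); the
  round trip is exact to ~1e−10 on the working grid but inherently
  ill-conditioned within ~1e−7 of the pole (b ≳ 24), where the ratio's
  own float rounding costs ~2e−9 in b.
- Eigendecomposition uses `eigh` of the explicitly formed 108×108
  scatter (symmetric solver, full orthonormal basis even when n < m);
  eigenvalues are clipped at 0 against roundoff.
- A degenerate fit (zero variance, or constant PC1 projections) raises
  instead of returning an uncalibratable score.

## Problem sizes

Tests and the acceptance script run the full pipeline on cohorts of 3
severity levels × 20 cutouts (matching the healthy/chronic/acute
three-group design at a computationally comfortable size), with 2000
simulated expert pairs; smaller fixed-seed cohorts back the individual
property tests. A 60-cutout cohort completes in a few minutes on one
CPU thanks to the cached-spectrum convolver.

## Known limitations

- The printed 5–20-octave bandwidths make the four bandwidth levels of
  the bank nearly redundant and every filter broadband; wavelength
  selectivity is weak, so per-feature loadings should not be
  over-interpreted as scale-specific (the narrowband selectivity of the
  machinery itself is verified separately at b = 1).
- The [0, 1] score is calibrated per training set; scores are not
  comparable across independently fitted models.
- Pooled signed maxima discard response magnitude asymmetries that a
  quadrature-pair energy model would retain; φ = 0 only, as specified.
- The synthetic-data entropy response to spot density is not monotone at
  low densities (sparse spots stretch the per-map histogram range before
  they populate it), so only the extreme-level contrast is asserted.
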