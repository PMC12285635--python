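# Methods

## The naturalness factor

Natural-scene images share a remarkably stable statistical signature:
the distribution of pixel-wise intensity gradients is heavy-tailed, and
its cumulative form is well described by a one-parameter arctan law
(a hyper-Laplace distribution),

    F(g; T) = 1/2 + arctan(T g) / π .

`T` is an inverse scale: large `T` concentrates the mass near zero
(few strong edges), small `T` spreads it (many strong edges).  The same
law describes the distribution of the discrete Laplacian.  For 8-bit
natural-scene images the reference ("prior") parameters are
`T1_prior = 0.38` for first-order gradients and `T2_prior = 0.14` for
the Laplacian; these published constants ship as defaults and are not
re-estimated here.

For an image under test the package converts to 8 bits (linear min-max
rescale to [0, 255], round half-to-even — so the statistics are
comparable with the 8-bit reference regardless of acquisition depth),
computes forward-difference gradients `Gx(x,y) = I(x+1,y) − I(x,y)`,
`Gy(x,y) = I(x,y+1) − I(x,y)` and the 5-point Laplacian on the interior
valid region (no padding: fabricated edge gradients would bias the
statistics), builds the empirical cumulative distributions, and fits
`T1` (jointly against the two stacked gradient marginals, which share
one parameter in the model) and `T2` by bounded least squares on the
CDF values.  The scalar search runs over `T ∈ [1e-4, 1e4]`: a 161-point
log-spaced grid brackets the optimum, then a bounded minimization over
log10(T) refines it (absolute exponent tolerance 1e-10).  The fit is
deterministic; a unit test pins it against a dense 1e5-point grid
search.

The naturalness factor is the prior-normalized mixture

    N_f = (1 − θ) · T1/T1_prior + θ · T2/T2_prior ,      θ ∈ [0, 1],

with `θ = 0.5` by default.  `N_f = 1` means natural-scene-like
statistics; `N_f > 1` means an excess of small gradients (typically
blur), `N_f < 1` an excess of large gradients (sharp detail or noise).
`N_f` needs no reference image.

Degenerate inputs (constant images, all-zero gradient fields) raise
errors rather than returning a divergent `T`.

## Naturalization

Naturalization transforms an image so its gradient statistics match the
natural-scene prior: each gradient component is remapped by monotone
CDF matching `g → F_target⁻¹(F_emp(g))` and the remapped field is
reintegrated into an image.  Three numerical choices matter, each
forced by a measurable failure of the naive pipeline:

1. **Truncated target law.**  The arctan law's tails are unbounded: the
   top-ranked gradient of an n-sample image maps to ~n/(π T) — far
   beyond anything an 8-bit image can hold.  The resulting spike pixels
   inflate the dynamic range and, after min-max renormalization,
   crush every other gradient (measured N_f ≈ 35).  The target is
   therefore the law conditioned on [−255, 255], the representable
   gradient range of the 8-bit frame.  The empirical CDF uses the
   midpoint (Hazen) convention, and the map is shifted so a zero
   gradient stays exactly zero.

2. **Screened reintegration.**  The two components are matched
   independently, so the remapped field is not a gradient field of any
   image; the reconstruction is the least-squares fit, i.e. a Poisson
   equation with Neumann boundary conditions, solved exactly by a
   type-II DCT (the DCT basis diagonalizes the Neumann Laplacian; a
   test checks agreement with a dense normal-equations solve to 1e-8).
   Pure least squares, however, integrates the remapped background
   noise into a low-frequency random walk that inflates the intensity
   range ~2.7×.  `naturalize` therefore adds a small data-fidelity term
   (screened Poisson, weight 0.03): frequencies whose Laplacian
   eigenvalue is small compared to the weight follow the input image,
   the rest follow the matched gradients.  With `fidelity = 0` the
   solver reduces to the pure least-squares contract (zero field →
   constant image; consistent field → exact reconstruction up to a
   constant).

3. **Self-calibration.**  The least-squares projection and the 8-bit
   quantization inside the N_f measurement each perturb the realized
   `T1`, `T2` by a roughly multiplicative factor, so matching at a
   fixed scale systematically overshoots.  `naturalize` measures the
   naturalness factor of its own output and secant-corrects the
   matching scale (`t ← t / N_f_out`), up to four passes, stopping once
   `|N_f − 1| ≤ 0.01` and keeping the best iterate.  The procedure is
   deterministic.

The output is mapped back to the input intensity scale.  Range
preservation saturates out-of-range pixels rather than rescaling the
whole tonal scale: an affine rescale would divide every gradient by the
range-inflation factor and undo the matching.  Only 8-bit outputs are
rounded to integers in memory; rounding at the matched gradient scale
(≈2.6 8-bit units) measurably inflates the fitted parameters.  The
output raster is two pixels smaller per side (gradients exist only on
the interior).

On a 50-phantom corpus spanning N_f ≈ 0.3–3.1, this pipeline reduces
the median |N_f − 1| from 0.42 to 0.02, worsens no image by more than
0.01, and a second application moves N_f by at most 0.04.

## Quality metrics

* **MAE / MSE / PSNR** are the standard pixel-wise comparisons.  The
  functions operate on raw intensities (so the arithmetic identities
  hold exactly); `mae` takes a `scale=` option ('unit' min-max
  normalizes each image to [0,1] independently, '8bit' multiplies by
  255).  `batch_evaluate` compares normalized images by default and
  then also computes PSNR in the normalized frame — PSNR is invariant
  to the particular scale choice, and on corpora mixing photon budgets
  the raw-unit MSE would be dominated by absolute intensity rather than
  by quality.  PSNR of identical images is an error, not infinity.

* **MS-SSIM** uses the standard five dyadic scales (2×2 mean pooling),
  an 11-tap Gaussian window (σ = 1.5), stabilizers `K1 = 0.01`,
  `K2 = 0.03`, and the canonical cross-scale exponents
  {0.0448, 0.2856, 0.3001, 0.2363, 0.1333} normalized to sum to one;
  contrast·structure enters at every scale, luminance only at the
  coarsest.  Negative contrast·structure means are clipped at zero so
  the product stays in [0, 1].  The default `data_range` is the joint
  intensity span of the two images, which keeps the metric symmetric
  and the stabilizers meaningful for low-dynamic-range microscopy
  frames.  Images must be at least 176 px per side (11-px window
  through four halvings).  The per-scale SSIM is cross-checked against
  scikit-image's implementation in the test suite.

* **RMS contrast** is the population standard deviation of the
  intensities — reference-free, structure-insensitive.

* **Decorrelation resolution.**  The mean-subtracted image is tapered
  by a separable raised-cosine window over the outer 12% of each
  dimension (suppressing the periodic-boundary discontinuity), Fourier
  transformed, and correlated with its phase-only normalization under
  circular low-pass masks at 50 radii uniformly spaced over (0, 1] in
  Nyquist-normalized frequency.  Because the integrand `I · conj(I_n)`
  is just `|I|`, the correlation reduces to
  `d(r) = Σ_{|k|≤r} |I| / sqrt(Σ|I|² · N(r))` — identical to an
  uncentered Pearson correlation of the masked spectra (asserted by an
  oracle test).  The zero-frequency bin is excluded (it carries no
  structural phase).  The argmax radius `r_c` (smallest on ties, a
  conservative choice) gives `Resolution = 2 · pixel_size / r_c`;
  with the default 32.3 nm pixel the best reportable value is 64.6 nm.
  The refined local-maximum search of the original decorrelation
  method is out of scope.

* **Blur with renormalization** reproduces the metric-failure
  experiment: Gaussian blur (σ = kernel/6, truncated to the kernel
  support) compresses the intensity range; re-stretching to the
  original range inflates the variance, so RMS contrast *rises* for
  most images even though they are objectively degraded.

## Phantom generator

The generator emulates the two structure classes the metrics target:
filamentous cytoskeleton images (smooth cubic-spline curves with
anti-aliased ~2 px strokes, crossing the frame) and dot-like vesicular
images (hard disks of 2–4 px radius).  The imaging model is structure →
Gaussian PSF → expected photons (`background + photon_budget ·
structure`) → per-pixel Poisson noise, written as 16-bit counts with a
32.3 nm pixel pitch.  There is no read-noise or camera-gain term, no
structured background, and no anisotropy — conclusions from phantom
tests about those aspects of real data are therefore limited; what the
phantoms do establish is the response of every metric to controlled
blur, photon count and structure density.

Defaults (12 filaments on 256², PSF σ = 0.8 px, 400 photons,
background 2) were calibrated once so that the default phantom lies in
the natural-like regime N_f ∈ [0.8, 1.3], mirroring the behavior of
real super-resolved filament images; background photons are the main
N_f-lowering factor because their shot noise contributes heavy-tailed
i.i.d. gradients.  All generators are pure functions of their spec
(seed included): corpora regenerate bit-exactly.

`degraded_pair` renders a matched (low-resolution, high-resolution)
pair from one geometry with two PSF widths.  The low-resolution image
is a 25-frame average (Poisson at 25× expectation, divided by 25),
emulating the frame-averaged widefield acquisitions that matched
super-resolution data sets provide; without averaging, single-exposure
shot noise dominates the LR gradients and inverts the expected
N_f ordering.

## Correlation analysis

`batch_evaluate` scores (generated, reference) pairs with all metrics,
recording per-image failures in flags instead of aborting.
`metric_correlations` computes Pearson r over every unordered pair of
{MS-SSIM, MAE, PSNR, Contrast, Resolution, 1 − N_f} with two-sided
t-test p-values at n − 2 degrees of freedom (scipy's `pearsonr`);
incomplete reports are dropped pairwise-complete and the per-cell n
reflects that.  The naturalness factor enters as its deviation
`1 − N_f` because N_f itself is not monotone in quality.  Zero-variance
columns yield degenerate (NaN) cells rather than errors.  Resolution
enters in nanometers as computed.  A permutation-test oracle (10⁴
shuffles) pins the parametric p-values in the test suite.

The test corpus that reproduces the published sign structure (MS-SSIM
and PSNR negative against 1 − N_f, MAE positive) is a noise-dominated
ladder: photon budgets 15–400 with mild smoothing, scored against
noise-free references.  In that regime noisier images are
simultaneously sharper (lower N_f) and worse on every reference metric.
A pure blur ladder produces the opposite signs — blur destroys
structure faster than it suppresses noise — which is worth remembering
when interpreting metric correlations on any particular corpus.

## Problem sizes and determinism

Parameter-recovery checks draw 10⁶ inverse-transform samples; corpus
properties use 50–100 phantoms of 256² pixels; oracle equivalences run
on 16² (dense least squares) and 64² (spectral) inputs.  Every random
draw flows from an explicit seed through `numpy`'s `default_rng`;
nothing reads global random state.
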