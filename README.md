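# natfactor

Reference-free image-quality assessment and training-data
regularization for super-resolution fluorescence microscopy, built
around the **naturalness factor** of an image's gradient statistics.

Deep-learning super-resolution models are usually judged by
reference-based metrics (MAE, PSNR, MS-SSIM) that can prefer a *blurred*
reconstruction over a sharp one — blurring a noisy image toward its
local mean reduces pixel-wise error while destroying exactly the
fine-scale content super-resolution is supposed to recover.  The
naturalness factor exploits a prior from natural-scene statistics
instead: the cumulative distributions of an image's gradients and
Laplacians follow an arctan-shaped hyper-Laplace law

    F(g; T) = 1/2 + arctan(T·g)/π,

with natural-scene reference parameters `T1_prior = 0.38` (gradients)
and `T2_prior = 0.14` (Laplacian).  Fitting `T1`, `T2` to an image and
normalizing by the prior gives

    N_f = (1 − θ)·T1/T1_prior + θ·T2/T2_prior,   θ = 0.5 by default.

`N_f = 1` is the target: blurred images score `N_f > 1` (too many small
gradients), noisy or over-sharpened ones `N_f < 1` — no ground-truth
image required.  The package also implements **image naturalization**
(gradient-histogram matching to the prior followed by screened-Poisson
reintegration), the full metric suite used alongside `N_f` (MAE, PSNR,
MS-SSIM, RMS contrast, decorrelation-analysis resolution), seeded
synthetic filament/dot phantoms with a controllable PSF-and-Poisson
imaging model, and a batch evaluation layer with pairwise metric
correlations.

## Worked example

```python
import natfactor as nf

# a microtubule-like phantom in the natural-like regime
img = nf.filament_phantom(nf.PhantomSpec(seed=0))
res = nf.naturalness_factor(img)
print(f"T1 = {res.t1:.3f}  T2 = {res.t2:.3f}  N_f = {res.nf:.3f}")

# blur it 5x5 and re-stretch the intensity range
blurred = nf.gaussian_blur_renormalize(img, 5)
print(f"blurred: N_f = {nf.naturalness_factor(blurred).nf:.3f}")
print(f"resolution sharp = {nf.decorrelation_curve(img).resolution_nm:.1f} nm, "
      f"blurred = {nf.decorrelation_curve(blurred).resolution_nm:.1f} nm")
print(f"contrast sharp = {nf.rms_contrast(img):.2f}, "
      f"blurred+renorm = {nf.rms_contrast(blurred):.2f}")

# naturalization pulls the statistics back to the prior
nat = nf.naturalize(blurred)
print(f"naturalized blurred: N_f = {nf.naturalness_factor(nat).nf:.3f}")
```

prints

```
T1 = 0.278  T2 = 0.143  N_f = 0.876
blurred: N_f = 1.268
resolution sharp = 215.3 nm, blurred = 269.2 nm
contrast sharp = 39.61, blurred+renorm = 41.85
naturalized blurred: N_f = 1.026
```

Read this as: the sharp phantom is slightly *more* detailed than a
natural scene (`N_f < 1`); blurring pushes `N_f` well above 1 and
worsens the estimated resolution (215 → 269 nm at a 32.3 nm pixel),
while the renormalized RMS contrast *improves* (39.6 → 41.9) — the
failure mode that motivates a reference-free statistic.  Naturalizing
the blurred image restores near-natural gradient statistics
(`N_f = 1.03`).

## Command line

```bash
natfactor phantom phantom.tif --seed 3            # synthetic image + JSON sidecar
natfactor score phantom.tif                       # per-image T1, T2, N_f
natfactor blur phantom.tif blurred.tif --kernel 5
natfactor metrics blurred.tif phantom.tif         # full metric report
natfactor naturalize blurred.tif natural.tif
natfactor correlate manifest.csv --out-dir report # batch + correlation matrix
```

`correlate` takes a CSV manifest with `generated_path` and
`reference_path` columns and writes `reports.csv`, `correlations.csv`
and `correlations.json`.

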