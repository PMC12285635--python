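"""Reference-based and reference-free image quality metrics.

Reference-based: mean absolute error (MAE), mean squared error / peak
signal-to-noise ratio (PSNR), and multi-scale structural similarity
(MS-SSIM).  Reference-free: RMS contrast (the population standard
deviation of the intensities) and image resolution estimated by Fourier
decorrelation analysis.

Decorrelation analysis estimates resolution without a second acquisition:
the image spectrum ``I(k)`` is correlated with its phase-only (unit
magnitude) normalization ``I_n(k)`` restricted to circular low-pass masks
of normalized radius ``r``; the radius ``r_c`` maximizing the correlation
marks the highest spatial frequency carrying structured (phase-coherent)
signal, and the resolution is ``2 * pixel_size / r_c``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import (
    DegenerateInputError,
    InvalidImageError,
    InvalidInputError,
    MissingMetadataError,
    UndefinedPSNRError,
)
from .image import GrayImage, as_gray_image

#: Cross-scale exponents of the standard 5-scale MS-SSIM.
MS_SSIM_WEIGHTS = np.array([0.0448, 0.2856, 0.3001, 0.2363, 0.1333])

#: Number of decorrelation mask radii, uniformly spaced over (0, 1].
N_DECORR_RADII = 50

#: Fraction of each image dimension tapered by the edge apodization.
APODIZATION_FRACTION = 0.12


@dataclass(frozen=True)
class MetricReport:
    """Named metric values for one image (pair); missing ones are flagged."""

    mae: float | None = None
    psnr: float | None = None
    ms_ssim: float | None = None
    contrast: float | None = None
    resolution_nm: float | None = None
    nf: float | None = None
    flags: frozenset = dc_field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "flags", frozenset(self.flags))
        for name in ("mae", "psnr", "ms_ssim", "contrast", "resolution_nm", "nf"):
            v = getattr(self, name)
            if v is not None and not np.isfinite(v):
                raise InvalidInputError(f"{name} must be finite or None")
        if self.ms_ssim is not None and not 0.0 <= self.ms_ssim <= 1.0:
            raise InvalidInputError("ms_ssim must lie in [0, 1]")


@dataclass(frozen=True, eq=False)
class DecorrelationCurve:
    """d(r) sampled at 50 radii, the argmax radius and the resolution."""

    radii: np.ndarray
    d_values: np.ndarray
    rc: float
    resolution_nm: float

    def __post_init__(self) -> None:
        radii = np.asarray(self.radii, dtype=np.float64)
        d = np.asarray(self.d_values, dtype=np.float64)
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "d_values", d)
        if radii.shape != d.shape:
            raise InvalidInputError("radii and d_values must have equal length")
        if not np.any(np.isclose(radii, self.rc)):
            raise InvalidInputError("rc must be one of the sampled radii")
        if np.any(np.abs(d) > 1 + 1e-9):
            raise InvalidInputError("d values must lie in [-1, 1]")


# ---------------------------------------------------------------------------
# pixel-wise reference metrics


def _pair(generated, reference) -> tuple[np.ndarray, np.ndarray]:
    a = as_gray_image(generated).pixels
    b = as_gray_image(reference).pixels
    if a.shape != b.shape:
        raise InvalidInputError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def _unit_normalize(a: np.ndarray) -> np.ndarray:
    lo, hi = a.min(), a.max()
    if hi == lo:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)


def mae(generated, reference, scale: str | None = None) -> float:
    """Mean absolute pixel-wise difference.

    ``scale=None`` compares raw intensities; ``'unit'`` min-max normalizes
    each image to [0, 1] independently first (the convention used for
    reference comparisons of images with differing dynamic range);
    ``'8bit'`` additionally multiplies by 255.
    """
    a, b = _pair(generated, reference)
    if scale is not None:
        if scale not in ("unit", "8bit"):
            raise InvalidInputError("scale must be None, 'unit' or '8bit'")
        a, b = _unit_normalize(a), _unit_normalize(b)
        if scale == "8bit":
            a, b = a * 255.0, b * 255.0
    return float(np.mean(np.abs(a - b)))


def mse(generated, reference) -> float:
    """Mean squared pixel-wise difference (raw intensities)."""
    a, b = _pair(generated, reference)
    return float(np.mean((a - b) ** 2))


def psnr(generated, reference, max_intensity: float | None = None) -> float:
    """Peak signal-to-noise ratio, ``10 log10(MAX^2 / MSE)`` in dB.

    ``max_intensity`` defaults to the reference's bit-depth maximum
    (e.g. 65535 for 16-bit).  Identical images have no defined PSNR.
    """
    err = mse(generated, reference)
    if err == 0.0:
        raise UndefinedPSNRError("PSNR undefined for identical images (MSE = 0)")
    if max_intensity is None:
        max_intensity = as_gray_image(reference).max_value
    if not max_intensity > 0:
        raise InvalidInputError("max_intensity must be positive")
    return float(10.0 * np.log10(max_intensity**2 / err))


# ---------------------------------------------------------------------------
# MS-SSIM


def _ssim_components(a, b, data_range) -> tuple[float, float]:
    """Mean SSIM and mean contrast*structure over an 11-px Gaussian window."""
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    # 11-tap window: sigma 1.5, radius 5
    blur = lambda x: gaussian_filter(x, 1.5, truncate=5.0 / 1.5, mode="reflect")
    mu_a, mu_b = blur(a), blur(b)
    var_a = blur(a * a) - mu_a**2
    var_b = blur(b * b) - mu_b**2
    cov = blur(a * b) - mu_a * mu_b
    lum = (2 * mu_a * mu_b + c1) / (mu_a**2 + mu_b**2 + c1)
    cs = (2 * cov + c2) / (var_a + var_b + c2)
    return float(np.mean(lum * cs)), float(np.mean(cs))


def _downsample2(a: np.ndarray) -> np.ndarray:
    h, w = a.shape
    a = a[: h - h % 2, : w - w % 2]
    return 0.25 * (a[0::2, 0::2] + a[1::2, 0::2] + a[0::2, 1::2] + a[1::2, 1::2])


def ms_ssim(generated, reference, data_range: float | None = None) -> float:
    """Multi-scale SSIM over 5 dyadic scales.

    Scales are produced by 2x2 mean pooling; contrast*structure terms
    enter at every scale and the luminance term only at the coarsest,
    with the standard exponents normalized to sum to one.  Negative
    contrast*structure means are clipped at zero so the product stays in
    [0, 1].  ``data_range`` defaults to the joint intensity span of the
    two images (symmetric in the arguments), which keeps the stabilizing
    constants meaningful for low-dynamic-range microscopy data.
    """
    a, b = _pair(generated, reference)
    n_scales = MS_SSIM_WEIGHTS.size
    min_side = (2 ** (n_scales - 1)) * 11
    if min(a.shape) < min_side:
        raise InvalidImageError(
            f"MS-SSIM over {n_scales} scales needs at least {min_side} px per side"
        )
    if data_range is None:
        data_range = float(max(a.max(), b.max()) - min(a.min(), b.min())) or 1.0
    weights = MS_SSIM_WEIGHTS / MS_SSIM_WEIGHTS.sum()
    result = 1.0
    for j in range(n_scales):
        ssim_mean, cs_mean = _ssim_components(a, b, data_range)
        if j < n_scales - 1:
            result *= max(cs_mean, 0.0) ** weights[j]
            a, b = _downsample2(a), _downsample2(b)
        else:
            result *= max(ssim_mean, 0.0) ** weights[j]
    return float(min(result, 1.0))


# ---------------------------------------------------------------------------
# reference-free metrics


def rms_contrast(image) -> float:
    """Population standard deviation of the pixel intensities."""
    return float(np.std(as_gray_image(image).pixels))


def _apodization_window(n: int, fraction: float = APODIZATION_FRACTION) -> np.ndarray:
    """1D taper: raised-cosine ramps over the outer ``fraction`` of the axis."""
    w = np.ones(n)
    e = int(round(fraction * n))
    if e > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * (np.arange(e) + 0.5) / e))
        w[:e] = ramp
        w[-e:] = ramp[::-1]
    return w


def decorrelation_curve(image) -> DecorrelationCurve:
    """Resolution estimate by Fourier decorrelation analysis.

    The mean-subtracted, edge-apodized image is Fourier transformed; for
    each of 50 mask radii r the masked correlation

        d(r) = sum_{|k|<=r} |I(k)|
               / sqrt( sum_k |I(k)|^2 * sum_{|k|<=r} |I_n(k)|^2 )

    is computed (the zero-frequency bin is excluded everywhere).  ``rc``
    is the smallest radius attaining the maximum of d, and the returned
    resolution is ``2 * pixel_size_nm / rc``.
    """
    img = as_gray_image(image)
    if img.pixel_size_nm is None:
        raise MissingMetadataError("decorrelation resolution needs pixel_size_nm")
    px = img.pixels
    if px.max() == 0.0 and px.min() == 0.0:
        raise DegenerateInputError("all-zero image has no spectral content")
    if min(px.shape) < 64:
        raise InvalidImageError("decorrelation analysis needs at least 64 px per side")
    # center square crop
    s = min(px.shape)
    oy = (px.shape[0] - s) // 2
    ox = (px.shape[1] - s) // 2
    crop = px[oy : oy + s, ox : ox + s].astype(np.float64)
    crop = crop - crop.mean()
    win = _apodization_window(s)
    crop = crop * win[:, None] * win[None, :]

    spec = np.fft.fft2(crop)
    mag = np.abs(spec)
    freq = np.fft.fftfreq(s) / 0.5  # normalized so Nyquist = 1
    rgrid = np.hypot(freq[None, :], freq[:, None]).ravel()
    mag = mag.ravel()
    keep = rgrid > 0  # exclude the DC bin from every sum
    rgrid, mag = rgrid[keep], mag[keep]

    order = np.argsort(rgrid, kind="stable")
    r_sorted = rgrid[order]
    mag_sorted = mag[order]
    cum_mag = np.cumsum(mag_sorted)
    cum_cnt = np.cumsum((mag_sorted > 0).astype(np.float64))
    total_sq = float(np.sum(mag_sorted**2))

    radii = np.linspace(1.0 / N_DECORR_RADII, 1.0, N_DECORR_RADII)
    idx = np.searchsorted(r_sorted, radii, side="right") - 1
    d = np.zeros(N_DECORR_RADII)
    valid = idx >= 0
    num = np.where(valid, cum_mag[np.clip(idx, 0, None)], 0.0)
    cnt = np.where(valid, cum_cnt[np.clip(idx, 0, None)], 0.0)
    denom = np.sqrt(total_sq * cnt)
    np.divide(num, denom, out=d, where=denom > 0)

    rc = float(radii[int(np.argmax(d))])  # argmax takes the smallest r on ties
    resolution = 2.0 * img.pixel_size_nm / rc
    return DecorrelationCurve(radii=radii, d_values=d, rc=rc, resolution_nm=resolution)


def resolution_nm(image) -> float:
    """Convenience wrapper returning only the resolution estimate."""
    return decorrelation_curve(image).resolution_nm


def gaussian_blur_renormalize(image, kernel_px: int, renormalize: bool = True) -> GrayImage:
    """Gaussian blur with a square kernel of odd size; optional re-stretch.

    The Gaussian sigma is ``kernel_px / 6`` truncated to the kernel
    support.  With ``renormalize`` the blurred image is linearly
    rescaled back to the input's [min, max]; without it, blurring
    compresses the intensity range (and hence the RMS contrast).
    """
    img = as_gray_image(image)
    if kernel_px < 1 or kernel_px % 2 == 0:
        raise InvalidInputError("kernel_px must be a positive odd integer")
    if kernel_px > min(img.shape):
        raise InvalidInputError("kernel_px exceeds the image size")
    px = img.pixels
    radius = (kernel_px - 1) // 2
    if radius == 0:
        out = px.copy()
    else:
        sigma = kernel_px / 6.0
        out = gaussian_filter(px, sigma, truncate=radius / sigma, mode="reflect")
    if renormalize:
        lo, hi = px.min(), px.max()
        omin, omax = out.min(), out.max()
        if omax > omin:
            out = lo + (out - omin) * ((hi - lo) / (omax - omin))
    return GrayImage(
        np.clip(out, 0.0, img.max_value),
        bit_depth=img.bit_depth,
        pixel_size_nm=img.pixel_size_nm,
    )
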