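"""Seeded synthetic microscopy phantoms.

Two structure classes cover the image types the metrics are aimed at:

* ``filament`` — smooth random curves emulating microtubule / F-actin
  images: thin, highly detailed, frequently crossing strands.
* ``dots`` — disks of a few pixels radius emulating clathrin-coated-pit
  images with their sparse "salt and pepper" appearance.

The imaging model is: render sub-pixel structure on the pixel grid,
convolve with a Gaussian PSF, scale to an expected photon count, add a
uniform background and draw per-pixel Poisson noise.  There is no camera
read-noise term.  Every generator is a pure function of its spec (seed
included), so corpora regenerate bit-exactly.

Defaults place filament phantoms in the "natural-like" regime
(N_f roughly within [0.8, 1.3]); blurring or starving them of photons
moves N_f up or down, which is what the test corpora exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy.interpolate import make_interp_spline
from scipy.ndimage import gaussian_filter

from .errors import InvalidInputError
from .image import DEFAULT_PIXEL_SIZE_NM, GrayImage


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of one synthetic image.

    ``photon_budget`` is the expected photon count on the brightest
    structure pixel; ``background`` the uniform background expectation.
    """

    kind: str = "filament"  # "filament" or "dots"
    size_px: int = 256
    n_objects: int = 12
    psf_sigma_px: float = 0.8
    photon_budget: float = 400.0
    background: float = 2.0
    seed: int = 0
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM

    def __post_init__(self) -> None:
        if self.kind not in ("filament", "dots"):
            raise InvalidInputError("kind must be 'filament' or 'dots'")
        if self.size_px < 64:
            raise InvalidInputError("size_px must be at least 64")
        if self.n_objects < 0:
            raise InvalidInputError("n_objects must be non-negative")
        if self.psf_sigma_px < 0:
            raise InvalidInputError("psf_sigma_px must be non-negative")
        if not self.photon_budget > 0:
            raise InvalidInputError("photon_budget must be positive")
        if self.background < 0:
            raise InvalidInputError("background must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# structure rendering (noise-free, unit amplitude)


def _splat_curve(canvas: np.ndarray, xs: np.ndarray, ys: np.ndarray, amp: float) -> None:
    """Accumulate a polyline onto the canvas with bilinear sub-pixel splats.

    Each dense sample deposits its local arc-length so the stroke has
    uniform linear density regardless of parameter speed.
    """
    n = canvas.shape[0]
    dx = np.diff(xs, prepend=xs[0])
    dy = np.diff(ys, prepend=ys[0])
    ds = np.hypot(dx, dy)
    inside = (xs > -1) & (xs < n) & (ys > -1) & (ys < n)
    xs, ys, ds = xs[inside], ys[inside], ds[inside]
    x0 = np.floor(xs).astype(int)
    y0 = np.floor(ys).astype(int)
    fx = xs - x0
    fy = ys - y0
    for ox, oy, w in (
        (0, 0, (1 - fx) * (1 - fy)),
        (1, 0, fx * (1 - fy)),
        (0, 1, (1 - fx) * fy),
        (1, 1, fx * fy),
    ):
        xi = x0 + ox
        yi = y0 + oy
        ok = (xi >= 0) & (xi < n) & (yi >= 0) & (yi < n)
        np.add.at(canvas, (yi[ok], xi[ok]), amp * w[ok] * ds[ok])


def _filament_structure(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.size_px
    canvas = np.zeros((n, n))
    for _ in range(spec.n_objects):
        k = int(rng.integers(4, 7))
        # control points slightly outside the frame so strands cross it
        ctrl = rng.uniform(-0.15 * n, 1.15 * n, size=(k, 2))
        t = np.linspace(0.0, 1.0, k)
        spline = make_interp_spline(t, ctrl, k=3)
        dense = spline(np.linspace(0.0, 1.0, 8 * n))
        amp = rng.uniform(0.6, 1.0)
        _splat_curve(canvas, dense[:, 0], dense[:, 1], amp)
    # sub-pixel stroke profile: ~2 px FWHM
    canvas = gaussian_filter(canvas, 0.85)
    peak = canvas.max()
    if peak > 0:
        canvas /= peak
    return canvas


def _dot_structure(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.size_px
    canvas = np.zeros((n, n))
    yy, xx = np.mgrid[0:n, 0:n]
    for _ in range(spec.n_objects):
        cx, cy = rng.uniform(0, n, size=2)
        radius = rng.uniform(2.0, 4.0)
        canvas[(xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2] = 1.0
    return canvas


def structure_image(spec: PhantomSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Noise-free expected-photon image: background + budget * PSF(structure)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if spec.kind == "filament":
        struct = _filament_structure(spec, rng)
    else:
        struct = _dot_structure(spec, rng)
    if spec.psf_sigma_px > 0:
        struct = gaussian_filter(struct, spec.psf_sigma_px)
    return spec.background + spec.photon_budget * struct


def _finalize(expected: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> GrayImage:
    counts = rng.poisson(expected).astype(np.float64)
    return GrayImage(
        np.clip(counts, 0, 65535),
        bit_depth=16,
        pixel_size_nm=spec.pixel_size_nm,
    )


def filament_phantom(spec: PhantomSpec) -> GrayImage:
    """Render a filamentous phantom (deterministic given the spec)."""
    if spec.kind != "filament":
        raise InvalidInputError("filament_phantom requires kind='filament'")
    rng = np.random.default_rng(spec.seed)
    return _finalize(structure_image(spec, rng), spec, rng)


def dot_phantom(spec: PhantomSpec) -> GrayImage:
    """Render a dot-like phantom (deterministic given the spec)."""
    if spec.kind != "dots":
        raise InvalidInputError("dot_phantom requires kind='dots'")
    rng = np.random.default_rng(spec.seed)
    return _finalize(structure_image(spec, rng), spec, rng)


def phantom(spec: PhantomSpec) -> GrayImage:
    """Dispatch on ``spec.kind``."""
    return filament_phantom(spec) if spec.kind == "filament" else dot_phantom(spec)


def degraded_pair(
    spec: PhantomSpec, lr_sigma_px: float, lr_frames: int = 25
) -> tuple[GrayImage, GrayImage]:
    """(low-resolution, high-resolution) pair sharing one object geometry.

    The two renders use the same structure but PSF widths ``lr_sigma_px``
    and ``spec.psf_sigma_px`` respectively, with independent Poisson
    draws derived from the same seed.  The low-resolution image emulates
    a frame-averaged diffraction-limited acquisition: ``lr_frames``
    exposures are averaged, so its relative shot noise is lower by
    ``sqrt(lr_frames)`` while the high-resolution image is a single
    exposure.
    """
    if not lr_sigma_px > spec.psf_sigma_px:
        raise InvalidInputError("lr_sigma_px must exceed spec.psf_sigma_px")
    if lr_frames < 1:
        raise InvalidInputError("lr_frames must be at least 1")
    ss = np.random.SeedSequence(spec.seed)
    geom_seed, hr_seed, lr_seed = ss.spawn(3)
    rng_geom = np.random.default_rng(geom_seed)
    base = replace(spec, psf_sigma_px=0.0)
    if spec.kind == "filament":
        struct = _filament_structure(base, rng_geom)
    else:
        struct = _dot_structure(base, rng_geom)

    def render(sigma: float, seed, frames: int) -> GrayImage:
        blurred = gaussian_filter(struct, sigma) if sigma > 0 else struct
        expected = spec.background + spec.photon_budget * blurred
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected * frames) / frames
        return GrayImage(
            np.clip(counts, 0, 65535), bit_depth=16, pixel_size_nm=spec.pixel_size_nm
        )

    hr = render(spec.psf_sigma_px, hr_seed, 1)
    lr = render(lr_sigma_px, lr_seed, lr_frames)
    return lr, hr
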