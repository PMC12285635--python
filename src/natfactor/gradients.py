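"""Gradient statistics, hyper-Laplace fitting and the naturalness factor.

Natural-scene images have heavy-tailed gradient distributions.  Their
cumulative gradient distribution (CGD) and cumulative Laplacian
distribution (CLD) are well described by a one-parameter arctan-shaped
(hyper-Laplace) law,

    F(g; T) = 1/2 + arctan(T * g) / pi,

where larger ``T`` means the mass concentrates near zero (fewer large
gradients).  Fitting ``T`` to the first-order gradients gives ``T1``, to
the Laplacian ``T2``.  The published natural-scene reference values are
``T1_prior = 0.38`` and ``T2_prior = 0.14``.

The naturalness factor of an image is the prior-normalized mixture

    N_f = (1 - theta) * T1 / T1_prior + theta * T2 / T2_prior,

with ``theta`` weighting first- against second-order statistics
(``theta = 0.5`` by default).  ``N_f = 1`` means the image's gradient
statistics match the natural-scene reference; ``N_f > 1`` means the image
has more small gradients than a natural scene (typically blur), ``N_f < 1``
more large gradients (typically sharp structure or noise).

Images are converted to 8-bit (min-max rescale) before the statistics are
computed so that the fitted parameters are comparable with the published
8-bit reference values regardless of acquisition bit depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import (
    DegenerateDistributionError,
    InsufficientDataError,
    InvalidImageError,
    InvalidInputError,
)
from .image import GrayImage, as_gray_image, to_gray8

#: Published natural-scene reference parameters (8-bit grayscale corpus).
T1_PRIOR_DEFAULT = 0.38
T2_PRIOR_DEFAULT = 0.14

#: Bounds of the scalar search for T.
T_BOUNDS = (1e-4, 1e4)

_MIN_SAMPLES = 100


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True, eq=False)
class GradientField:
    """Forward-difference gradient components plus the Laplacian raster.

    All three rasters cover the same valid region of the source image
    (the interior, where every stencil neighbor exists).
    """

    gx: np.ndarray
    gy: np.ndarray
    laplacian: np.ndarray

    def __post_init__(self) -> None:
        gx = np.asarray(self.gx, dtype=np.float64)
        gy = np.asarray(self.gy, dtype=np.float64)
        lap = np.asarray(self.laplacian, dtype=np.float64)
        object.__setattr__(self, "gx", gx)
        object.__setattr__(self, "gy", gy)
        object.__setattr__(self, "laplacian", lap)
        if not (gx.shape == gy.shape == lap.shape):
            raise InvalidInputError("gx, gy and laplacian must share one shape")
        for name, arr in (("gx", gx), ("gy", gy), ("laplacian", lap)):
            if not np.all(np.isfinite(arr)):
                raise InvalidInputError(f"{name} contains non-finite entries")


@dataclass(frozen=True, eq=False)
class EmpiricalCumulative:
    """Empirical CDF evaluated at the sorted unique sample values."""

    support: np.ndarray
    cdf: np.ndarray

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=np.float64)
        cdf = np.asarray(self.cdf, dtype=np.float64)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "cdf", cdf)
        if support.ndim != 1 or support.shape != cdf.shape:
            raise InvalidInputError("support and cdf must be equal-length 1D")
        if np.any(np.diff(support) <= 0):
            raise InvalidInputError("support must be strictly increasing")
        if np.any(np.diff(cdf) < 0) or cdf[0] < 0 or cdf[-1] > 1 + 1e-12:
            raise InvalidInputError("cdf must be non-decreasing within [0, 1]")
        if abs(cdf[-1] - 1.0) > 1e-9:
            raise InvalidInputError("last cdf value must equal 1")


@dataclass(frozen=True)
class HyperLaplaceParams:
    """Fitted scale parameter of the arctan-form cumulative distribution."""

    t: float
    order: str  # "first" (gradients) or "second" (Laplacian)
    fit_residual: float

    def __post_init__(self) -> None:
        if not self.t > 0:
            raise InvalidInputError("t must be positive")
        if self.order not in ("first", "second"):
            raise InvalidInputError("order must be 'first' or 'second'")
        if not (np.isfinite(self.fit_residual) and self.fit_residual >= 0):
            raise InvalidInputError("fit_residual must be finite and >= 0")


@dataclass(frozen=True)
class NaturalnessPrior:
    """Natural-scene reference parameters for the CGD and CLD."""

    t1_prior: float = T1_PRIOR_DEFAULT
    t2_prior: float = T2_PRIOR_DEFAULT

    def __post_init__(self) -> None:
        if not (self.t1_prior > 0 and self.t2_prior > 0):
            raise InvalidInputError("prior parameters must be positive")


@dataclass(frozen=True)
class NaturalnessResult:
    """Per-image fitted parameters and the naturalness factor."""

    t1: float
    t2: float
    theta: float
    nf: float


# ---------------------------------------------------------------------------
# gradient statistics


def gradient_field(image) -> GradientField:
    """Forward-difference gradients and 5-point Laplacian of an image.

    Both are evaluated only on the interior valid region (all stencil
    neighbors inside the frame); no padding is applied, so no fabricated
    edge gradients enter the statistics.
    """
    px = as_gray_image(image).pixels if isinstance(image, GrayImage) else np.asarray(image, dtype=np.float64)
    if px.ndim != 2 or min(px.shape) < 3:
        raise InvalidImageError("gradient field requires a 2D image of at least 3x3")
    c = px[1:-1, 1:-1]
    gx = px[1:-1, 2:] - c
    gy = px[2:, 1:-1] - c
    lap = px[1:-1, 2:] + px[1:-1, :-2] + px[2:, 1:-1] + px[:-2, 1:-1] - 4.0 * c
    return GradientField(gx=gx, gy=gy, laplacian=lap)


def empirical_cumulative(samples) -> EmpiricalCumulative:
    """Empirical CDF of a sample set, evaluated at the unique values.

    Right-continuous convention: ``cdf[i] = P(X <= support[i])``.
    """
    x = np.asarray(samples, dtype=np.float64).ravel()
    if x.size < _MIN_SAMPLES:
        raise InsufficientDataError(
            f"need at least {_MIN_SAMPLES} samples, got {x.size}"
        )
    support, counts = np.unique(x, return_counts=True)
    cdf = np.cumsum(counts) / x.size
    cdf[-1] = 1.0  # guard against accumulated rounding
    return EmpiricalCumulative(support=support, cdf=cdf)


# ---------------------------------------------------------------------------
# hyper-Laplace fitting


def hyper_laplace_cdf(x, t: float):
    """Model CDF ``F(x; T) = 1/2 + arctan(T x) / pi``."""
    return 0.5 + np.arctan(t * np.asarray(x, dtype=np.float64)) / np.pi


def hyper_laplace_ppf(q, t: float):
    """Inverse of :func:`hyper_laplace_cdf` (for inverse-transform sampling)."""
    return np.tan(np.pi * (np.asarray(q, dtype=np.float64) - 0.5)) / t


def _check_not_degenerate(cdfs: Iterable[EmpiricalCumulative]) -> None:
    for c in cdfs:
        if c.support.size > 1 or c.support[0] != 0.0:
            return
    raise DegenerateDistributionError(
        "all sample mass at zero; scale parameter is undefined"
    )


def _fit_t(cdfs: Sequence[EmpiricalCumulative], order: str) -> HyperLaplaceParams:
    """Least-squares fit of T against one or more empirical CDFs (stacked).

    A coarse log-spaced grid brackets the optimum, then a bounded scalar
    minimization over log10(T) refines it.  Deterministic by construction.
    """
    _check_not_degenerate(cdfs)
    support = np.concatenate([c.support for c in cdfs])
    target = np.concatenate([c.cdf for c in cdfs])

    def objective(t: float) -> float:
        return float(np.sum((hyper_laplace_cdf(support, t) - target) ** 2))

    lo, hi = T_BOUNDS
    grid = np.logspace(np.log10(lo), np.log10(hi), 161)
    vals = np.array([objective(t) for t in grid])
    i = int(np.argmin(vals))
    blo = grid[max(i - 1, 0)]
    bhi = grid[min(i + 1, grid.size - 1)]
    res = minimize_scalar(
        lambda u: objective(10.0**u),
        bounds=(np.log10(blo), np.log10(bhi)),
        method="bounded",
        options={"xatol": 1e-10, "maxiter": 500},
    )
    t_hat = float(10.0**res.x)
    return HyperLaplaceParams(t=t_hat, order=order, fit_residual=float(res.fun))


def fit_cgd_param(
    gx_cdf: EmpiricalCumulative, gy_cdf: EmpiricalCumulative
) -> HyperLaplaceParams:
    """Fit the first-order parameter T1 to the two gradient marginals.

    The model CGD is a product of identical arctan marginals sharing one
    T1, so the fit is performed against the two stacked empirical
    marginal CDFs with an unweighted least-squares objective.
    """
    return _fit_t([gx_cdf, gy_cdf], order="first")


def fit_cld_param(lap_cdf: EmpiricalCumulative) -> HyperLaplaceParams:
    """Fit the second-order parameter T2 to the Laplacian CDF."""
    return _fit_t([lap_cdf], order="second")


def image_params(image) -> tuple[HyperLaplaceParams, HyperLaplaceParams]:
    """(T1, T2) of one image: 8-bit conversion, field, CDFs, fits."""
    img8 = to_gray8(as_gray_image(image))
    field = gradient_field(img8)
    gx_cdf = empirical_cumulative(field.gx)
    gy_cdf = empirical_cumulative(field.gy)
    lap_cdf = empirical_cumulative(field.laplacian)
    return fit_cgd_param(gx_cdf, gy_cdf), fit_cld_param(lap_cdf)


def estimate_prior(images: Sequence) -> NaturalnessPrior:
    """Arithmetic mean of per-image (T1, T2) across a corpus."""
    images = list(images)
    if not images:
        raise InvalidInputError("need at least one image to estimate a prior")
    t1s, t2s = [], []
    for img in images:
        p1, p2 = image_params(img)
        t1s.append(p1.t)
        t2s.append(p2.t)
    return NaturalnessPrior(
        t1_prior=float(np.mean(t1s)), t2_prior=float(np.mean(t2s))
    )


def naturalness_factor(
    image,
    prior: NaturalnessPrior | None = None,
    theta: float = 0.5,
) -> NaturalnessResult:
    """Naturalness factor N_f of one image.

    Parameters
    ----------
    image
        Any grayscale image (converted to 8-bit internally).
    prior
        Natural-scene reference; defaults to the published constants
        (0.38, 0.14).
    theta
        Weight of the second-order (Laplacian) term, in [0, 1].
    """
    if not 0.0 <= theta <= 1.0:
        raise InvalidInputError(f"theta must be in [0, 1], got {theta}")
    if prior is None:
        prior = NaturalnessPrior()
    p1, p2 = image_params(image)
    nf = (1.0 - theta) * p1.t / prior.t1_prior + theta * p2.t / prior.t2_prior
    return NaturalnessResult(t1=p1.t, t2=p2.t, theta=theta, nf=nf)
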