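"""Compression of a scattering image into two characterizing parameters.

A transmitted scattering pattern is summarized by

* the **transmitted power** ``p`` — the gray intensity integrated over all
  pixels, and
* the **scaled Gaussian width** ``σ`` — the standard deviation of the
  normalized, symmetrized radial intensity profile divided by ``p``.

The width is extracted in five steps: (1) low-pass filter the image with a
Gaussian kernel in the frequency domain; (2) angularly average the
intensity into a radial profile; (3) mirror the profile to negative radii
and rescale it to unit area, so it approximates a zero-mean probability
density; (4) fit a one-dimensional Gaussian-process regressor with an
adaptive nugget to denoise and enrich the profile; (5) take the standard
deviation of the enriched density and divide by ``p``.

Dividing by the power deliberately couples the two features: heavily
scattering samples transmit less power *and* spread it wider, so ``p`` and
``σ`` are negatively correlated across any design of slab settings, which
sharpens the contrast between weakly and strongly scattering samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .gp import fit_gp
from .simulator import ScatterImage

__all__ = [
    "RadialCurve",
    "PatternFeatures",
    "lowpass_filter",
    "total_power",
    "radial_density",
    "enrich_curve",
    "scaled_gaussian_width",
    "characterize",
]

#: conversion from a full-width-at-half-maximum to a Gaussian std
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class RadialCurve:
    """Symmetric radial intensity density.

    ``radii`` are signed distances in pixels (the profile is mirrored about
    zero); ``values`` are intensity densities per unit radius.  When
    ``normalized``, the trapezoidal integral over the support is 1.
    """

    radii: np.ndarray
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.radii.shape != self.values.shape:
            raise ValueError("radii and values must have equal shapes")

    @property
    def area(self) -> float:
        return float(np.trapezoid(self.values, self.radii))


@dataclass(frozen=True)
class PatternFeatures:
    """The two-parameter characterization [p, σ] of a scattering image."""

    p: float
    sigma: float
    nugget_1d: float = float("nan")  # noise level estimated by the curve smoother

    def __post_init__(self) -> None:
        if self.p < 0 or self.sigma < 0:
            raise ValueError("features must be nonnegative")


def _as_array(image: ScatterImage | np.ndarray) -> np.ndarray:
    if isinstance(image, ScatterImage):
        return image.intensity
    return np.asarray(image, dtype=float)


def lowpass_filter(
    image: ScatterImage | np.ndarray, kernel_width: float = 7.0
) -> ScatterImage | np.ndarray:
    """Gaussian low-pass filter applied in the frequency domain.

    ``kernel_width`` is the kernel's full width at half maximum in pixels
    (default 7).  The kernel has unit sum, so the total intensity is
    conserved; boundaries wrap periodically (FFT-native), which is benign
    for patterns that decay toward the detector edge.
    """
    arr = _as_array(image)
    if kernel_width < 1:
        raise ValueError("kernel width must be at least 1 pixel")
    if kernel_width > min(arr.shape):
        raise ValueError("kernel wider than the image")
    sigma = kernel_width * _FWHM_TO_SIGMA
    spec = np.fft.rfft2(arr)
    spec = ndimage.fourier_gaussian(spec, sigma, n=arr.shape[1])
    out = np.fft.irfft2(spec, s=arr.shape)
    out = np.maximum(out, 0.0)  # clip FFT ringing; kernel itself is positive
    if isinstance(image, ScatterImage):
        return ScatterImage(out, image.pixel_pitch, dict(image.meta))
    return out


def total_power(image: ScatterImage | np.ndarray) -> float:
    """Transmitted power p: the gray intensity summed over all pixels."""
    return float(_as_array(image).sum())


def radial_density(
    image: ScatterImage | np.ndarray,
    center: tuple[float, float] | None = None,
) -> RadialCurve:
    """Angularly averaged radial profile, mirrored and scaled to unit area.

    Pixels are binned by their integer-rounded distance (in pixels) from
    ``center`` — by default the geometric center of the grid, where the
    beam axis sits — and averaged per annulus.  The profile is mirrored to
    negative radii and rescaled so its trapezoidal integral equals one,
    yielding an approximate zero-mean probability density.
    """
    arr = _as_array(image)
    power = arr.sum()
    if power <= 0:
        raise ValueError("radial density undefined for a zero-power image")
    ny, nx = arr.shape
    if center is None:
        center = ((ny - 1) / 2.0, (nx - 1) / 2.0)
    cy, cx = center
    if not (0 <= cy <= ny - 1 and 0 <= cx <= nx - 1):
        raise ValueError("center must lie inside the image")
    yy, xx = np.indices(arr.shape)
    r = np.hypot(yy - cy, xx - cx)
    k = np.rint(r).astype(int)
    counts = np.bincount(k.ravel())
    sums = np.bincount(k.ravel(), weights=arr.ravel())
    present = counts > 0
    radii = np.nonzero(present)[0].astype(float)
    values = sums[present] / counts[present]

    if radii[0] == 0.0:
        # keep the on-axis sample single so the mirrored curve stays a function
        mr = np.concatenate([-radii[:0:-1], radii])
        mv = np.concatenate([values[:0:-1], values])
    else:
        mr = np.concatenate([-radii[::-1], radii])
        mv = np.concatenate([values[::-1], values])
    area = np.trapezoid(mv, mr)
    return RadialCurve(mr, mv / area, normalized=True)


def enrich_curve(
    curve: RadialCurve, grid_factor: int = 5, n_starts: int = 4
) -> tuple[RadialCurve, float]:
    """Denoise and enrich a radial profile with a 1-D GP regressor.

    Fits a Gaussian-process regressor with an adaptive nugget to the
    (radius, density) pairs and evaluates its posterior mean on a grid
    ``grid_factor`` times finer than the input.  Returns the enriched curve
    together with the estimated nugget — near zero for clean profiles
    (the regressor almost interpolates) and growing with the noise level of
    heavily scattered, photon-starved images.
    """
    if not curve.normalized:
        raise ValueError("enrich_curve expects a normalized curve")
    if curve.radii.size < 4:
        raise ValueError("need at least 4 curve points")
    model = fit_gp(
        curve.radii[:, None], curve.values, mode="single", n_starts=n_starts
    )
    step = np.median(np.diff(curve.radii)) / grid_factor
    dense_r = np.arange(curve.radii[0], curve.radii[-1] + 0.5 * step, step)
    mean = model.predict(dense_r[:, None]).mean[:, 0]
    enriched = RadialCurve(dense_r, mean, normalized=True)
    return enriched, float(model.nugget[0])


def scaled_gaussian_width(enriched: RadialCurve, p: float) -> float:
    """Standard deviation of the enriched zero-mean density, divided by p.

    The width is the second moment ``sqrt(∫ r² f(r) dr / ∫ f(r) dr)`` of
    the symmetric density rather than a parametric Gaussian fit, so it is
    well defined even for patterns that are not exactly Gaussian.  Negative
    regressor excursions are clipped to zero before the moments are taken.
    """
    if p <= 0:
        raise ValueError("power must be positive")
    f = np.maximum(enriched.values, 0.0)
    mass = np.trapezoid(f, enriched.radii)
    if mass <= 0:
        raise ValueError("enriched curve has no positive mass")
    second = np.trapezoid(enriched.radii**2 * f, enriched.radii)
    return float(np.sqrt(second / mass) / p)


def gaussian_fit_width(enriched: RadialCurve, p: float) -> float:
    """Alternative width: least-squares fit of a zero-mean Gaussian PDF."""
    from scipy.optimize import curve_fit

    if p <= 0:
        raise ValueError("power must be positive")

    def pdf(r, s):
        return np.exp(-0.5 * (r / s) ** 2) / (s * np.sqrt(2 * np.pi))

    s0 = max(scaled_gaussian_width(enriched, 1.0), 1e-6)
    popt, _ = curve_fit(pdf, enriched.radii, enriched.values, p0=[s0])
    return float(abs(popt[0]) / p)


def characterize(
    image: ScatterImage | np.ndarray,
    kernel_width: float = 7.0,
    width_method: str = "moment",
) -> PatternFeatures:
    """Full image → [p, σ] pipeline.

    ``p`` comes from the raw (unfiltered) image; ``σ`` from the filtered
    image via radial averaging, GP enrichment and the second moment (or a
    parametric Gaussian fit when ``width_method="gaussian"``).
    """
    arr = _as_array(image)
    p = total_power(arr)
    if p <= 0:
        raise ValueError("cannot characterize a zero-power image")
    border = np.concatenate([arr[0], arr[-1], arr[1:-1, 0], arr[1:-1, -1]])
    if border.sum() > 0.02 * p:
        warnings.warn(
            "pattern does not decay at the detector edge; periodic filtering "
            "and the radial moment may be biased"
        )
    filtered = lowpass_filter(arr, kernel_width)
    curve = radial_density(filtered)
    enriched, nugget = enrich_curve(curve)
    if width_method == "moment":
        sigma = scaled_gaussian_width(enriched, p)
    elif width_method == "gaussian":
        sigma = gaussian_fit_width(enriched, p)
    else:
        raise ValueError(f"unknown width method {width_method!r}")
    return PatternFeatures(p=p, sigma=sigma, nugget_1d=nugget)
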