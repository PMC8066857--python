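"""Seeded generator of synthetic circle phantoms with ground-truth edges.

The phantoms emulate the two classes of cardiac-MRI-like training images
used to optimize the detector:

* ``low`` intensity class  — dark background (~10) with a bright disk
  (~200): dark, high-contrast images;
* ``high`` intensity class — brighter background (~120) with a slightly
  brighter disk (~180): bright, low-contrast images.

Each sample is a filled circle (optionally distorted into an ellipse with
a sinusoidal radial perturbation) on a uniform background.  The ground
truth is the one-pixel-thick rasterized boundary of the clean shape,
captured *before* Gaussian blur and additive Gaussian noise degrade the
image.  All randomness is driven by explicit seeds, so any sample or set
is bit-reproducible.

The class intensity levels, radius, blur, and noise ranges below are
calibrated so that the two classes' global SNR distributions are well
separated (low class clearly noisier relative to its mean), mirroring the
low/high split such generators are meant to emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, NamedTuple

import numpy as np
from scipy import ndimage

INTENSITY_LEVELS = {
    # (background, foreground) on the 0-255 scale
    "low": (10.0, 200.0),
    "high": (120.0, 180.0),
}


class LabeledSample(NamedTuple):
    """A grayscale image paired with its ground-truth binary edge map."""

    image: np.ndarray
    truth: np.ndarray


@dataclass(frozen=True)
class PhantomSpec:
    """Full recipe for one synthetic circle phantom.

    radius is in pixels; center_jitter shifts the circle center uniformly
    within +/- that many pixels on both axes; sigma_blur and sigma_noise
    are the Gaussian degradation parameters; distortion_amplitude is the
    sinusoidal radial perturbation as a fraction of the radius.
    """

    size: int = 128
    intensity_class: str = "low"
    radius: float = 35.0
    center_jitter: float = 0.0
    sigma_blur: float = 0.0
    sigma_noise: float = 0.0
    distort: bool = False
    distortion_amplitude: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intensity_class not in INTENSITY_LEVELS:
            raise ValueError(
                f"intensity_class must be one of {sorted(INTENSITY_LEVELS)}, "
                f"got {self.intensity_class!r}"
            )
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")
        max_extent = self.radius * (1.0 + (self.distortion_amplitude if self.distort else 0.0))
        if max_extent + self.center_jitter >= self.size / 2 - 1:
            raise ValueError(
                f"circle of radius {self.radius} (extent {max_extent:.1f}) with jitter "
                f"{self.center_jitter} does not fit in a {self.size}x{self.size} frame"
            )


def _shape_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask of the clean (pre-degradation) shape."""
    c = (spec.size - 1) / 2.0
    if spec.center_jitter > 0:
        cy, cx = c + rng.uniform(-spec.center_jitter, spec.center_jitter, size=2)
    else:
        cy, cx = c, c
    yy, xx = np.mgrid[0:spec.size, 0:spec.size]
    dy = yy - cy
    dx = xx - cx
    if not spec.distort:
        return dy**2 + dx**2 <= spec.radius**2
    # Ellipse eccentricity plus a sinusoidal radial perturbation.
    axis_ratio = rng.uniform(0.85, 1.0)
    lobes = int(rng.integers(2, 5))
    phase = rng.uniform(0, 2 * np.pi)
    theta = np.arctan2(dy, dx * axis_ratio)
    r_local = spec.radius * (1.0 + spec.distortion_amplitude * np.sin(lobes * theta + phase))
    return np.hypot(dy, dx / axis_ratio) <= r_local


def _boundary(mask: np.ndarray) -> np.ndarray:
    """One-pixel-thick inner boundary of a filled shape (8-connected curve)."""
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return (mask & ~eroded).astype(np.uint8)


def make_circle_image(spec: PhantomSpec) -> LabeledSample:
    """Generate one phantom and its ground-truth edge map.

    The truth is rasterized from the clean shape before blur and noise are
    applied, so it stays a closed one-pixel curve however degraded the
    image is.  Fully determined by ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    background, foreground = INTENSITY_LEVELS[spec.intensity_class]
    mask = _shape_mask(spec, rng)
    truth = _boundary(mask)
    image = np.where(mask, foreground, background).astype(float)
    if spec.sigma_blur > 0:
        image = ndimage.gaussian_filter(image, sigma=spec.sigma_blur, mode="reflect")
    if spec.sigma_noise > 0:
        image = image + rng.normal(0.0, spec.sigma_noise, size=image.shape)
    image = np.clip(image, 0.0, 255.0)
    return LabeledSample(image=image, truth=truth)


def make_optimization_set(
    n: int = 20,
    intensity_class: str = "low",
    master_seed: int = 0,
    *,
    size: int = 128,
    radius_range: tuple[float, float] = (20.0, 50.0),
    blur_range: tuple[float, float] = (0.5, 1.5),
    noise_range: tuple[float, float] = (2.0, 8.0),
    distort_fraction: float = 0.5,
) -> List[LabeledSample]:
    """Generate a set of n phantoms with varied geometry and degradation.

    Radii, centers, blur and noise sigmas are drawn uniformly from their
    ranges; roughly ``distort_fraction`` of the shapes are distorted.
    Per-sample seeds derive from ``master_seed``, so the whole set is
    reproducible.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(master_seed)
    samples = []
    for _ in range(n):
        spec = PhantomSpec(
            size=size,
            intensity_class=intensity_class,
            radius=float(rng.uniform(*radius_range)),
            center_jitter=5.0,
            sigma_blur=float(rng.uniform(*blur_range)),
            sigma_noise=float(rng.uniform(*noise_range)),
            distort=bool(rng.random() < distort_fraction),
            distortion_amplitude=0.1,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        samples.append(make_circle_image(spec))
    return samples


def inject_noise(image: np.ndarray, sigma_noise: float, seed: int = 0) -> np.ndarray:
    """Add zero-mean Gaussian noise of the given std, clipped to [0, 255]."""
    if sigma_noise < 0:
        raise ValueError(f"sigma_noise must be non-negative, got {sigma_noise}")
    image = np.asarray(image, dtype=float)
    if sigma_noise == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    return np.clip(image + rng.normal(0.0, sigma_noise, size=image.shape), 0.0, 255.0)
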