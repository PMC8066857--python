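"""Pre/post-processing pipelines and the Canny baseline.

Three scenario pipelines wrap the CA detector:

* ``plain``     — the raw CA edge map, no extra processing;
* ``post``      — CA map, then Zhang–Suen thinning and removal of small
                  8-connected components (disconnected edge fragments);
* ``pre_post``  — Gaussian smoothing of the input first, then the post path.

Both post-processing operators only ever remove edge pixels.  The Canny
baseline uses hysteresis thresholds at 10% / 20% of the 8-bit maximum
(25.5 / 51 on the 0–255 scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import canny
from skimage.morphology import skeletonize

from caedge.ca_core import DetectorParams, apply_detector

SCENARIOS = ("plain", "post", "pre_post")


@dataclass(frozen=True)
class ScenarioConfig:
    """Which pipeline to run and its knobs.

    sigma_smooth is the Gaussian pre-filter standard deviation (0 = no
    smoothing; only used by pre_post); min_component_size is the smallest
    8-connected edge fragment kept by the post-processing step.
    """

    scenario: str = "plain"
    sigma_smooth: float = 0.0
    min_component_size: int = 8

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}")
        if self.sigma_smooth < 0:
            raise ValueError(f"sigma_smooth must be non-negative, got {self.sigma_smooth}")
        if self.min_component_size < 1:
            raise ValueError(f"min_component_size must be >= 1, got {self.min_component_size}")


def gaussian_prefilter(image: np.ndarray, sigma_smooth: float) -> np.ndarray:
    """2-D Gaussian smoothing with reflective boundary; sigma 0 is identity."""
    if sigma_smooth < 0:
        raise ValueError(f"sigma_smooth must be non-negative, got {sigma_smooth}")
    image = np.asarray(image, dtype=float)
    if sigma_smooth == 0:
        return image.copy()
    return ndimage.gaussian_filter(image, sigma=sigma_smooth, mode="reflect")


def thin_edges(edges: np.ndarray) -> np.ndarray:
    """Zhang–Suen thinning to one-pixel-wide curves.

    The output edge set is a subset of the input's and the operator is
    idempotent.
    """
    edges = np.asarray(edges).astype(bool)
    return skeletonize(edges, method="zhang").astype(np.uint8)


def remove_disconnected(edges: np.ndarray, min_component_size: int) -> np.ndarray:
    """Delete 8-connected components with fewer than min_component_size pixels."""
    if min_component_size < 1:
        raise ValueError(f"min_component_size must be >= 1, got {min_component_size}")
    edges = np.asarray(edges).astype(bool)
    # 8-connectivity, matching the detector's Moore neighborhood.
    labels, n = ndimage.label(edges, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return edges.astype(np.uint8)
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_component_size
    keep[0] = False
    return keep[labels].astype(np.uint8)


def run_scenario(image: np.ndarray, params: DetectorParams, cfg: ScenarioConfig) -> np.ndarray:
    """Run one of the three detector pipelines on a grayscale image."""
    if cfg.scenario == "pre_post":
        image = gaussian_prefilter(image, cfg.sigma_smooth)
    edges = apply_detector(image, params)
    if cfg.scenario in ("post", "pre_post"):
        edges = thin_edges(edges)
        edges = remove_disconnected(edges, cfg.min_component_size)
    return edges


def canny_baseline(image: np.ndarray, sigma: float) -> np.ndarray:
    """Canny edge detection with hysteresis thresholds 25.5 / 51 (0–255 scale).

    Weak edges survive only when connected to a strong edge.  Returns a
    uint8 map with values in {0, 1}.
    """
    image = np.asarray(image, dtype=float)
    edges = canny(
        image / 255.0,
        sigma=sigma,
        low_threshold=0.1,
        high_threshold=0.2,
    )
    return edges.astype(np.uint8)
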