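import numpy as np
import pytest

from caedge.ca_core import DetectorParams, decode_rule
from caedge.image_synthesis import LabeledSample, inject_noise


def naive_detector(image: np.ndarray, params: DetectorParams) -> np.ndarray:
    """Independent per-pixel reference for the CA detector.

    Literal double loop over pixels and neighbor offsets with
    edge-replicate clamping; shares no code with the vectorized path.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    mask = decode_rule(params.rule)
    out = np.zeros((h, w), dtype=np.uint8)
    for i in range(h):
        for j in range(w):
            phi = 0.0
            for k, l in mask:
                ni = min(max(i + k, 0), h - 1)
                nj = min(max(j + l, 0), w - 1)
                phi += abs(image[i, j] - image[ni, nj])
            denom = params.delta + phi
            mu = phi / denom if denom > 0 else 0.0
            out[i, j] = 1 if mu > params.tau else 0
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20210414)


@pytest.fixture
def step_sample():
    """16x16 noisy vertical step with the two step-adjacent columns as truth."""
    image = np.full((16, 16), 50.0)
    image[:, 8:] = 200.0
    image = inject_noise(image, 5.0, seed=123)
    truth = np.zeros((16, 16), dtype=np.uint8)
    truth[:, 7:9] = 1
    return LabeledSample(image=image, truth=truth)
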