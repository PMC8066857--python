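"""The cellular-automaton edge detector.

A grayscale image is treated as a lattice of cells whose neighborhoods are
the radius-1 Moore neighborhood (the 3x3 block around each pixel).  A
*linear rule* is a 9-bit integer selecting which of the nine neighbor
offsets participate in the local difference sum

    phi(X_ij) = sum over selected offsets (k, l) of |X_ij - X_{i+k, j+l}|.

The edge membership of a pixel is the saturating ratio

    mu(X_ij) = phi / (delta + phi),        delta in {0, ..., 255},

and the binary edge decision is mu > tau with tau in [0, 1).  One
synchronous pass of this two-step transition rule maps the image to its
edge map.

Bit-to-offset convention: bit ``b`` of the rule integer selects offset
number ``b`` in the row-major enumeration of the Moore neighborhood,

    (-1,-1) (-1,0) (-1,+1) (0,-1) (0,0) (0,+1) (+1,-1) (+1,0) (+1,+1)

so bit 0 is the upper-left neighbor and bit 4 the (algebraically neutral)
center.  Any bijection between bits and offsets yields the same detector
family; only the numeric label of each rule changes.

Out-of-bounds neighbors take the value of the nearest in-bounds pixel
(edge-replicate padding), so border pixels see zero difference toward the
outside and no spurious frame edges appear.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import FrozenSet, Iterable, Tuple

import numpy as np
import yaml

#: Row-major enumeration of the radius-1 Moore neighborhood; bit b of a
#: rule integer selects MOORE_OFFSETS[b].
MOORE_OFFSETS: Tuple[Tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 0), (0, 1),
    (1, -1), (1, 0), (1, 1),
)

N_RULES = 1 << len(MOORE_OFFSETS)  # 512 linear rules

Offset = Tuple[int, int]
NeighborMask = FrozenSet[Offset]


@dataclass(frozen=True)
class DetectorParams:
    """The CA rule triplet: damping constant, threshold, linear rule.

    delta : int in {0, ..., 255}
        Damping constant of the membership ratio; larger delta detects
        fewer edges.
    tau : float in [0, 1)
        Membership threshold; a pixel is an edge iff mu > tau.
    rule : int in {0, ..., 511}
        9-bit linear rule selecting the participating Moore neighbors.
    """

    delta: int
    tau: float
    rule: int

    def __post_init__(self) -> None:
        if not (0 <= self.delta <= 255):
            raise ValueError(f"delta must be in [0, 255], got {self.delta}")
        if not (0.0 <= self.tau < 1.0):
            raise ValueError(f"tau must be in [0, 1), got {self.tau}")
        if not (0 <= self.rule < N_RULES):
            raise ValueError(f"rule must be in [0, 511], got {self.rule}")

    def to_dict(self) -> dict:
        return {"delta": int(self.delta), "tau": float(self.tau), "rule": int(self.rule)}

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorParams":
        return cls(delta=int(d["delta"]), tau=float(d["tau"]), rule=int(d["rule"]))

    def save(self, path: str | Path) -> None:
        """Serialize to YAML or JSON depending on the file suffix."""
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "DetectorParams":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)


def decode_rule(rule: int) -> NeighborMask:
    """Decode a 9-bit linear rule into its set of selected Moore offsets.

    Bit ``b`` (b = 0..8) of ``rule`` selects ``MOORE_OFFSETS[b]``.
    """
    if not (0 <= rule < N_RULES):
        raise ValueError(f"rule must be in [0, 511], got {rule}")
    return frozenset(off for b, off in enumerate(MOORE_OFFSETS) if rule >> b & 1)


def encode_rule(mask: Iterable[Offset]) -> int:
    """Encode a set of Moore offsets as a 9-bit linear rule (inverse of decode)."""
    mask = frozenset(mask)
    invalid = mask - set(MOORE_OFFSETS)
    if invalid:
        raise ValueError(f"offsets outside the Moore neighborhood: {sorted(invalid)}")
    return sum(1 << b for b, off in enumerate(MOORE_OFFSETS) if off in mask)


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"image must be 2-D, got shape {image.shape}")
    return image


def difference_sum(image: np.ndarray, i: int, j: int, mask: Iterable[Offset]) -> float:
    """phi at one pixel: sum of |X(i,j) - X(i+k,j+l)| over the mask offsets.

    Out-of-bounds neighbors replicate the nearest in-bounds pixel.  The
    center offset (0, 0) contributes exactly zero.
    """
    image = _check_image(image)
    h, w = image.shape
    if not (0 <= i < h and 0 <= j < w):
        raise IndexError(f"pixel ({i}, {j}) outside image of shape {image.shape}")
    x = image[i, j]
    phi = 0.0
    for k, l in frozenset(mask):
        ni = min(max(i + k, 0), h - 1)
        nj = min(max(j + l, 0), w - 1)
        phi += abs(x - image[ni, nj])
    return phi


def edge_membership(phi: float, delta: int) -> float:
    """Membership mu = phi / (delta + phi); defined as 0 at the 0/0 limit.

    A flat neighborhood (phi = 0) is never an edge, even at delta = 0.
    """
    if phi < 0:
        raise ValueError(f"phi must be non-negative, got {phi}")
    denom = delta + phi
    if denom == 0:
        return 0.0
    return phi / denom


def threshold_membership(mu: float, tau: float) -> int:
    """Binary edge decision: 1 iff mu > tau (mu == tau maps to 0)."""
    if not (0.0 <= tau < 1.0):
        raise ValueError(f"tau must be in [0, 1), got {tau}")
    return 1 if mu > tau else 0


def _phi_stack(image: np.ndarray) -> np.ndarray:
    """Per-offset absolute-difference planes, shape (9, H, W).

    Plane b holds |X - X shifted by MOORE_OFFSETS[b]| with edge-replicate
    padding, so phi for any rule is the sum of its selected planes.
    """
    padded = np.pad(image, 1, mode="edge")
    h, w = image.shape
    planes = np.empty((len(MOORE_OFFSETS), h, w))
    for b, (k, l) in enumerate(MOORE_OFFSETS):
        planes[b] = np.abs(image - padded[1 + k:1 + k + h, 1 + l:1 + l + w])
    return planes


def apply_detector(image: np.ndarray, params: DetectorParams) -> np.ndarray:
    """One synchronous CA pass: per-pixel phi -> mu -> binary edge state.

    Returns a uint8 array of the same shape with values in {0, 1}.
    """
    image = _check_image(image)
    if image.shape[0] < 3 or image.shape[1] < 3:
        raise ValueError(f"image must be at least 3x3, got {image.shape}")
    planes = _phi_stack(image)
    bits = [b for b in range(len(MOORE_OFFSETS)) if params.rule >> b & 1]
    if bits:
        phi = planes[bits].sum(axis=0)
    else:
        phi = np.zeros(image.shape)
    denom = params.delta + phi
    mu = np.divide(phi, denom, out=np.zeros_like(phi), where=denom > 0)
    return (mu > params.tau).astype(np.uint8)
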