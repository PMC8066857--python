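"""Reading and writing 8-bit grayscale images and binary edge maps.

Images travel as float arrays on the 0–255 scale; edge maps are {0, 1}
arrays serialized as PNG with values {0, 255}.  PNG and TIFF are
supported through Pillow.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image


def read_gray(path: str | Path) -> np.ndarray:
    """Load an image as a 2-D float array in [0, 255] (converts to grayscale)."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=float)


def write_gray(path: str | Path, image: np.ndarray) -> None:
    """Write a 2-D array (0–255 scale, clipped and rounded) as 8-bit grayscale."""
    arr = np.clip(np.asarray(image, dtype=float), 0, 255).round().astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def write_edge_map(path: str | Path, edges: np.ndarray) -> None:
    """Write a binary edge map as an 8-bit image with values {0, 255}."""
    arr = (np.asarray(edges).astype(bool).astype(np.uint8)) * 255
    Image.fromarray(arr, mode="L").save(path)


def read_edge_map(path: str | Path) -> np.ndarray:
    """Load an edge-map image; any nonzero pixel counts as an edge."""
    with Image.open(path) as im:
        return (np.asarray(im.convert("L")) > 127).astype(np.uint8)
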