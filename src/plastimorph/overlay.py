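"""PNG overlays: detected features drawn over the grey micrograph."""

from __future__ import annotations

import os

import numpy as np
from PIL import Image, ImageDraw
from skimage import segmentation

__all__ = ["edge_overlay", "label_overlay", "save_overlay"]

EDGE_COLOUR = (255, 64, 64)
OUTLINE_COLOUR = (64, 200, 255)


def edge_overlay(pixels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Edges in red over the greyscale image."""
    rgb = np.stack([pixels] * 3, axis=-1).astype(np.uint8)
    rgb[mask] = EDGE_COLOUR
    return rgb


def label_overlay(pixels: np.ndarray, labels: np.ndarray, number: bool = True) -> np.ndarray:
    """Object boundaries outlined and (optionally) numbered by label."""
    rgb = np.stack([pixels] * 3, axis=-1).astype(np.uint8)
    boundaries = segmentation.find_boundaries(labels, mode="outer")
    rgb[boundaries] = OUTLINE_COLOUR
    if not number or labels.max() == 0:
        return rgb
    im = Image.fromarray(rgb)
    draw = ImageDraw.Draw(im)
    for lab in range(1, int(labels.max()) + 1):
        rows, cols = np.nonzero(labels == lab)
        if rows.size == 0:
            continue
        draw.text((float(cols.mean()), float(rows.mean())), str(lab), fill=EDGE_COLOUR)
    return np.asarray(im)


def save_overlay(rgb: np.ndarray, path: str | os.PathLike) -> None:
    Image.fromarray(rgb, mode="RGB").save(path)
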