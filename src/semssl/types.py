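"""Core domain objects shared across the pipeline.

An SEM biofilm scene is a grayscale micrograph plus a dense tri-class
annotation: every pixel is exactly one of *Surface* (non-occluded metal),
*Cell* (bacterium or cell cluster) or *Byproduct* (corrosion products and
other microbial material without canonical shape). Annotations travel as a
small integer class map in memory and as an exact-color RGB image on disk
(cells blue, byproducts pink, surface green).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Dict, Tuple

import numpy as np


class ClassLabel(IntEnum):
    SURFACE = 0
    CELL = 1
    BYPRODUCT = 2


#: Exact RGB encodings used in annotation files.
CLASS_COLORS: Dict[ClassLabel, Tuple[int, int, int]] = {
    ClassLabel.CELL: (0, 0, 255),        # blue
    ClassLabel.BYPRODUCT: (255, 105, 180),  # pink
    ClassLabel.SURFACE: (0, 255, 0),     # green
}

#: Canonical class order for multi-label vectors and report columns.
CLASS_ORDER = (ClassLabel.BYPRODUCT, ClassLabel.CELL, ClassLabel.SURFACE)
CLASS_NAMES = ("byproduct", "cell", "surface")


@dataclass
class ImageMeta:
    """Acquisition metadata carried with every image."""

    magnification_label: float = 436.0
    scale_um: float = 10.0
    meta_strip_height: int = 0

    def validate(self) -> None:
        if self.magnification_label <= 0:
            raise ValueError("magnification_label must be > 0")
        if self.scale_um <= 0:
            raise ValueError("scale_um must be > 0")
        if self.meta_strip_height < 0:
            raise ValueError("meta_strip_height must be >= 0")


@dataclass
class AnnotatedImage:
    """Grayscale pixels with a per-pixel class map of identical shape."""

    pixels: np.ndarray          # uint8, (H, W)
    annotation: np.ndarray      # uint8 class codes, (H, W)
    meta: ImageMeta = field(default_factory=ImageMeta)
    source_id: str = "image"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        self.annotation = np.asarray(self.annotation, dtype=np.uint8)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grayscale array")
        if self.pixels.shape != self.annotation.shape:
            raise ValueError(
                f"pixels {self.pixels.shape} and annotation "
                f"{self.annotation.shape} must have identical dimensions")
        valid = np.isin(self.annotation, [int(c) for c in ClassLabel])
        if not valid.all():
            raise ValueError("annotation contains codes outside the three classes")
        self.meta.validate()

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    def class_counts(self) -> Dict[ClassLabel, int]:
        return {c: int((self.annotation == int(c)).sum()) for c in ClassLabel}


def annotation_to_rgb(annotation: np.ndarray) -> np.ndarray:
    """Render a class map as the exact blue/pink/green RGB encoding."""
    annotation = np.asarray(annotation)
    rgb = np.zeros((*annotation.shape, 3), dtype=np.uint8)
    for label, color in CLASS_COLORS.items():
        rgb[annotation == int(label)] = color
    return rgb


def rgb_to_annotation(rgb: np.ndarray) -> np.ndarray:
    """Invert :func:`annotation_to_rgb`; reject any off-palette pixel."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise ValueError("annotation image must be RGB")
    rgb = rgb[..., :3]
    out = np.full(rgb.shape[:2], 255, dtype=np.uint8)
    for label, color in CLASS_COLORS.items():
        out[(rgb == color).all(axis=2)] = int(label)
    if (out == 255).any():
        raise ValueError("annotation image contains colors outside the palette")
    return out
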