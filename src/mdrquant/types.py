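"""Core in-memory containers: intensity images and tissue label masks.

Conventions
-----------
* Pixel intensities live on the normalized ``[0, 1]`` scale, where *higher
  means radiographically denser* (brighter on a processed mammogram).
  Ingestion is responsible for inverting MONOCHROME1 sources so this holds.
* Label masks use the fixed palette

  ====  ================
  0     background
  1     fat (adipose)
  2     gland
  3     pectoral muscle
  ====  ================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ShapeError

BACKGROUND, FAT, GLAND, PECTORAL = 0, 1, 2, 3
LABELS = (BACKGROUND, FAT, GLAND, PECTORAL)
TISSUE_LABELS = (FAT, GLAND, PECTORAL)
LABEL_NAMES = {BACKGROUND: "background", FAT: "fat", GLAND: "gland", PECTORAL: "pectoral"}
N_CLASSES = 4


@dataclass
class IntensityImage:
    """A 2-D grayscale image with intensities normalized to [0, 1].

    Parameters
    ----------
    pixels:
        ``(H, W)`` float array in ``[0, 1]``.
    source_bit_depth:
        Bit depth of the file the image was read from (8 or 16); phantoms
        generated in memory default to 16.
    laterality:
        ``"left"``, ``"right"`` or ``"unknown"``.
    """

    pixels: np.ndarray
    source_bit_depth: int = 16
    laterality: str = "unknown"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ShapeError(f"expected a 2-D grayscale image, got shape {self.pixels.shape}")
        lo, hi = float(self.pixels.min(initial=0.0)), float(self.pixels.max(initial=0.0))
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"intensities must lie in [0, 1]; got range [{lo}, {hi}]")
        np.clip(self.pixels, 0.0, 1.0, out=self.pixels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class LabelMask:
    """A per-pixel tissue label grid over the fixed palette {0, 1, 2, 3}."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ShapeError(f"expected a 2-D label mask, got shape {self.labels.shape}")
        if not np.isin(self.labels, LABELS).all():
            bad = sorted(set(np.unique(self.labels)) - set(LABELS))
            raise ValueError(f"mask contains out-of-palette values {bad}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def class_counts(self) -> dict[int, int]:
        return {c: int((self.labels == c).sum()) for c in LABELS}


def as_pixels(image: "IntensityImage | np.ndarray") -> np.ndarray:
    """Accept an :class:`IntensityImage` or a bare array; return the array."""
    return image.pixels if isinstance(image, IntensityImage) else np.asarray(image, dtype=np.float64)


def as_labels(mask: "LabelMask | np.ndarray") -> np.ndarray:
    """Accept a :class:`LabelMask` or a bare array; return the label array."""
    return mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)


def check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ShapeError(f"shape mismatch: {a.shape} vs {b.shape}")
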