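"""Mammographic dense rate (MDR): pectoral-referenced density thresholding.

The statistic at the core of the pipeline. Given a grayscale MLO image and
its tissue mask, the mean intensity of the pectoralis-major region, D_mj,
serves as the per-image dense-tissue threshold: glandular pixels brighter
than D_mj are counted as dense (A_d), and

    MDR = A_d / A_gl

where A_gl is the total glandular pixel count. Because the threshold is
internal to each image, MDR is invariant under any strictly monotone
increasing intensity transform applied jointly to the whole image — no
cross-image intensity calibration is needed, which is what makes the
statistic applicable to vendor-processed mammograms.

The Japanese breast-composition atlas maps the resulting percentage to four
categories (cut-offs at 10 / 50 / 80 %); heterogeneous and extreme-dense
together constitute "dense breasts". The atlas counts pixels *at or above*
the pectoral reference, while the MDR definition used here is strictly
above; the ``inequality`` switch selects between the two conventions
(default strict).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import EmptyRegionError
from .types import GLAND, PECTORAL, as_labels, as_pixels, check_same_shape

__all__ = [
    "CompositionCategory",
    "DensityResult",
    "pectoral_mean_intensity",
    "compute_mdr",
    "classify_composition",
    "is_dense_breast",
]


class CompositionCategory(str, Enum):
    """Four-category breast composition (quantitative atlas cut-offs)."""

    FATTY = "fatty"
    SCATTERED = "scattered"
    HETEROGENEOUS = "heterogeneous"
    EXTREME_DENSE = "extreme_dense"


@dataclass(frozen=True)
class DensityResult:
    """MDR and its ingredients for one image (one breast side)."""

    d_mj: float      # mean pectoral intensity, [0, 1]
    a_gl: int        # glandular pixel count
    a_d: int         # dense glandular pixel count
    mdr: float       # A_d / A_gl, [0, 1]
    category: CompositionCategory

    @property
    def mdr_percent(self) -> float:
        return 100.0 * self.mdr

    @property
    def dense_breast(self) -> bool:
        return is_dense_breast(self.category)


def pectoral_mean_intensity(image, mask) -> float:
    """Mean image intensity over pectoral-labeled pixels (D_mj)."""
    px = as_pixels(image)
    lab = as_labels(mask)
    check_same_shape(px, lab)
    pec = px[lab == PECTORAL]
    if pec.size == 0:
        raise EmptyRegionError("mask contains no pectoral pixels; cannot derive threshold")
    return float(pec.mean())


def compute_mdr(image, mask, inequality: str = "gt") -> DensityResult:
    """Compute the dense rate of one image from its tissue mask.

    ``inequality='gt'`` counts glandular pixels strictly brighter than D_mj
    as dense (the MDR definition); ``'ge'`` counts pixels at or above the
    threshold (the visual-atlas convention). Comparisons are done on the
    normalized [0, 1] scale at native float precision, no epsilon.
    """
    if inequality not in ("gt", "ge"):
        raise ValueError(f"inequality must be 'gt' or 'ge', got {inequality!r}")
    px = as_pixels(image)
    lab = as_labels(mask)
    check_same_shape(px, lab)
    d_mj = pectoral_mean_intensity(px, lab)
    gland = px[lab == GLAND]
    if gland.size == 0:
        raise EmptyRegionError("mask contains no gland pixels; MDR undefined")
    a_gl = int(gland.size)
    a_d = int((gland > d_mj).sum() if inequality == "gt" else (gland >= d_mj).sum())
    mdr = a_d / a_gl
    return DensityResult(d_mj=d_mj, a_gl=a_gl, a_d=a_d, mdr=mdr,
                         category=classify_composition(mdr))


def classify_composition(mdr: float) -> CompositionCategory:
    """Atlas composition category for an MDR on the [0, 1] scale.

    [0, 0.10) fatty; [0.10, 0.50) scattered; [0.50, 0.80) heterogeneous;
    [0.80, 1] extreme dense.
    """
    if not 0.0 <= mdr <= 1.0:
        raise ValueError(f"mdr must be in [0, 1], got {mdr}")
    if mdr < 0.10:
        return CompositionCategory.FATTY
    if mdr < 0.50:
        return CompositionCategory.SCATTERED
    if mdr < 0.80:
        return CompositionCategory.HETEROGENEOUS
    return CompositionCategory.EXTREME_DENSE


def is_dense_breast(category: CompositionCategory) -> bool:
    """Heterogeneous and extreme-dense compositions count as dense breasts."""
    if not isinstance(category, CompositionCategory):
        raise ValueError(f"not a CompositionCategory: {category!r}")
    return category in (CompositionCategory.HETEROGENEOUS, CompositionCategory.EXTREME_DENSE)
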