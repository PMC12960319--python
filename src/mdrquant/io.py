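"""Readers/writers for images, masks and result tables, plus the end-to-end
pipeline runner.

Contracts
---------
* Grayscale PNG/TIFF is the baseline image format; 8- or 16-bit, normalized
  on read to [0, 1] by the bit depth's maximum. RGB input is rejected, never
  silently converted.
* DICOM is optional (requires ``pydicom``): MONOCHROME1 images are inverted
  on ingestion so that higher always means denser; laterality is taken from
  the Image Laterality / Laterality tags when present.
* Masks are 8-bit indexed PNG over the palette {0 background, 1 fat,
  2 gland, 3 pectoral}; out-of-palette values raise ``MaskFormatError``.
* Result CSVs carry a ``# mdrquant config_hash=...`` comment header so any
  output can be traced to the configuration that produced it; percentages
  are printed with one decimal.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .density import compute_mdr
from .errors import DataError, EmptyRegionError, MaskFormatError, MdrQuantError
from .segmentation import UNetSegmenter, predict_mask, resample_pair
from .types import LABELS, IntensityImage, LabelMask

__all__ = [
    "PipelineConfig",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_pairs",
    "run_pipeline",
    "write_results_csv",
]

log = logging.getLogger("mdrquant")

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}
_DICOM_SUFFIXES = {".dcm", ".dicom"}

#: fixed RGB palette for mask PNGs (background, fat, gland, pectoral)
_MASK_PALETTE = [0, 0, 0, 80, 80, 80, 170, 170, 170, 255, 255, 255]


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline settings; hashed into every output file header."""

    target_size: tuple[int, int] = (320, 384)   # (width, height)
    dense_inequality: str = "gt"                # 'gt' (MDR definition) or 'ge' (atlas)
    moving_average_window: int = 5
    histogram_bin_width: float = 10.0
    rapid_slope: float = -1.0
    persistent_slope: float = -0.5
    dense_level: float = 50.0
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def read_image(path: str | Path) -> IntensityImage:
    """Read a grayscale PNG/TIFF (or DICOM) into a normalized image.

    Intensities are divided by the source bit depth's maximum so the result
    lies in [0, 1] with higher = denser.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in _DICOM_SUFFIXES:
        return _read_dicom(path)
    if suffix not in _IMAGE_SUFFIXES:
        raise MdrQuantError(f"unsupported image format: {path.name}")
    with Image.open(path) as im:
        if im.mode in ("RGB", "RGBA", "P"):
            raise MdrQuantError(
                f"{path.name}: color image; grayscale input required (no silent conversion)"
            )
        arr = np.asarray(im)
    if arr.ndim != 2:
        raise MdrQuantError(f"{path.name}: expected a single-channel image, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        depth, denom = 8, 255.0
    elif arr.dtype in (np.uint16, np.int32):  # PIL reads 16-bit PNG as I;16 or I
        depth, denom = 16, 65535.0
    else:
        raise MdrQuantError(f"{path.name}: unsupported pixel dtype {arr.dtype}")
    return IntensityImage(arr.astype(np.float64) / denom, source_bit_depth=depth,
                          meta={"path": str(path)})


def _read_dicom(path: Path) -> IntensityImage:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise MdrQuantError("DICOM support requires the 'pydicom' extra") from exc
    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(np.float64)
    if arr.ndim != 2:
        raise MdrQuantError(f"{path.name}: expected single-frame grayscale DICOM")
    bits = int(getattr(ds, "BitsStored", 16))
    denom = float(2**bits - 1)
    arr = arr / denom
    if str(getattr(ds, "PhotometricInterpretation", "MONOCHROME2")) == "MONOCHROME1":
        arr = 1.0 - arr  # invert so higher = denser
    lat = str(getattr(ds, "ImageLaterality", getattr(ds, "Laterality", ""))).upper()
    laterality = {"L": "left", "R": "right"}.get(lat, "unknown")
    return IntensityImage(np.clip(arr, 0.0, 1.0), source_bit_depth=bits,
                          laterality=laterality, meta={"path": str(path)})


def write_image(image: IntensityImage, path: str | Path) -> Path:
    """Write a normalized image as 16-bit grayscale PNG (lossless for the
    quantized intensities phantoms emit)."""
    path = Path(path)
    arr = np.round(image.pixels * 65535.0).astype(np.uint16)
    Image.fromarray(arr).save(path)  # uint16 -> 16-bit grayscale PNG
    return path


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def write_mask(mask: LabelMask, path: str | Path) -> Path:
    """Write a label mask as 8-bit indexed PNG with the fixed 4-entry palette."""
    path = Path(path)
    im = Image.fromarray(mask.labels, mode="P")
    im.putpalette(_MASK_PALETTE + [0] * (768 - len(_MASK_PALETTE)))
    im.save(path)
    return path


def read_mask(path: str | Path) -> LabelMask:
    """Read an indexed/grayscale PNG mask; values must be within {0,1,2,3}."""
    path = Path(path)
    with Image.open(path) as im:
        if im.mode not in ("P", "L"):
            raise MaskFormatError(f"{path.name}: mask must be indexed or 8-bit grayscale PNG")
        arr = np.asarray(im)
    if not np.isin(arr, LABELS).all():
        bad = sorted(set(np.unique(arr)) - set(LABELS))
        raise MaskFormatError(f"{path.name}: out-of-palette mask values {bad}")
    return LabelMask(arr)


def read_pairs(image_dir: str | Path, mask_dir: str | Path) -> list[tuple[IntensityImage, LabelMask]]:
    """Load (image, mask) pairs matched by file stem from two directories."""
    image_dir, mask_dir = Path(image_dir), Path(mask_dir)
    pairs = []
    for img_path in sorted(p for p in image_dir.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES):
        mask_path = mask_dir / f"{img_path.stem}.png"
        if not mask_path.exists():
            raise DataError(f"no mask for {img_path.name} in {mask_dir}")
        pairs.append((read_image(img_path), read_mask(mask_path)))
    if not pairs:
        raise DataError(f"no images found in {image_dir}")
    return pairs


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    image_dir: str | Path,
    model: UNetSegmenter,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Segment every readable image in a directory and compute its MDR.

    Returns ``(results, skips)``: one result row per successfully processed
    image (``image_id, d_mj, a_gl, a_d, mdr_percent, category``) and one
    skip entry (``image_id, reason``) per file that could not be processed.
    Rows + skips always account for every candidate file; nothing is
    silently dropped. Raises ``DataError`` if no image yields a result.
    """
    config = config or PipelineConfig()
    image_dir = Path(image_dir)
    candidates = sorted(
        p for p in image_dir.iterdir()
        if p.is_file() and p.suffix.lower() in (_IMAGE_SUFFIXES | _DICOM_SUFFIXES)
    )
    rows: list[dict] = []
    skips: list[dict] = []
    for path in candidates:
        try:
            image = read_image(path)
            px, _ = resample_pair(image, None, config.target_size)
            mask = predict_mask(model, px)
            res = compute_mdr(px, mask, inequality=config.dense_inequality)
        except (MdrQuantError, EmptyRegionError, OSError) as exc:
            log.info("skip %s: %s", path.name, exc)
            skips.append({"image_id": path.name, "reason": str(exc)})
            continue
        log.info("ok %s: mdr=%.3f", path.name, res.mdr)
        rows.append({
            "image_id": path.name,
            "d_mj": res.d_mj,
            "a_gl": res.a_gl,
            "a_d": res.a_d,
            "mdr_percent": res.mdr_percent,
            "category": res.category.value,
        })
    if not rows:
        raise DataError(f"no readable images in {image_dir}")
    return pd.DataFrame(rows), skips


def write_results_csv(df: pd.DataFrame, path: str | Path,
                      config: PipelineConfig | None = None) -> Path:
    """Write a result table as CSV with the config-hash comment header."""
    config = config or PipelineConfig()
    path = Path(path)
    df = df.copy()
    for col in df.columns:
        if col.endswith("_percent"):
            df[col] = df[col].map(lambda v: f"{v:.1f}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# mdrquant config_hash={config.config_hash()}\n")
        df.to_csv(fh, index=False)
    return path


def read_results_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
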