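"""Synthetic MLO-like phantoms and longitudinal cohorts.

Every downstream stage of the pipeline (segmentation, density, cohort
analytics) is exercised on data from this module, so it is first-class,
seeded and bit-reproducible.

Image phantoms
--------------
A phantom mimics the layout of a mediolateral-oblique (MLO) mammogram with
minimal geometry:

* a half-ellipse *breast* of fat against the chest-wall edge,
* a triangular *pectoral* wedge in the upper chest-wall corner,
* an elliptical *gland* region embedded in the breast,
* dark *background* elsewhere, plus clipped Gaussian noise.

Gland texture is a two-mode mixture straddling the realized pectoral mean
intensity: a chosen fraction ``dense_fraction`` of gland pixels is placed
strictly above that mean and the rest strictly below, so ``dense_fraction``
is directly the ground-truth mammographic dense rate (MDR) of the emitted
image/mask pair.

Cohorts
-------
:func:`generate_cohort` emulates longitudinal per-subject MDR series with
two latent subpopulations — a rapidly declining majority and a persistently
dense minority — mirroring the dichotomy seen in screening populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegeneratePhantomError
from .types import BACKGROUND, FAT, GLAND, PECTORAL, IntensityImage, LabelMask

__all__ = [
    "PhantomParams",
    "CohortParams",
    "PhantomSet",
    "Cohort",
    "generate_phantom",
    "generate_phantom_set",
    "generate_cohort",
]

#: intensities are snapped to this grid so that a 16-bit PNG round trip is lossless
_QUANTUM = 65535
#: clearance between gland modes' clip bound and the pectoral mean, in intensity
#: units; much larger than one 16-bit quantum so strict comparisons survive I/O
_MARGIN = 0.005


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and intensity parameters of one synthetic MLO phantom.

    ``width``/``height`` must be divisible by 16 (the segmenter's maximum
    downsampling factor). ``dense_fraction`` is the target fraction of gland
    pixels strictly above the realized pectoral mean intensity, i.e. the
    ground-truth MDR.
    """

    width: int = 160
    height: int = 192
    pectoral_intensity_mean: float = 0.75
    pectoral_fraction: float = 0.08
    gland_fraction: float = 0.35
    dense_fraction: float = 0.40
    fat_intensity_mean: float = 0.35
    noise_sd: float = 0.02
    laterality: str = "left"
    gland_contrast: float = 0.12
    background_intensity: float = 0.04

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ConfigurationError("width and height must be positive")
        if self.width % 16 or self.height % 16:
            raise ConfigurationError(
                f"width and height must be divisible by 16, got {self.width}x{self.height}"
            )
        for name in ("pectoral_fraction", "gland_fraction", "dense_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.fat_intensity_mean <= 1.0 or not 0.0 <= self.pectoral_intensity_mean <= 1.0:
            raise ConfigurationError("intensity means must be in [0, 1]")
        if self.fat_intensity_mean >= self.pectoral_intensity_mean:
            raise ConfigurationError("fat must be darker than pectoral muscle (radiolucent)")
        if self.pectoral_intensity_mean + _MARGIN >= 1.0:
            raise ConfigurationError("pectoral_intensity_mean too close to 1 for dense contrast")
        if self.noise_sd < 0 or self.gland_contrast <= _MARGIN:
            raise ConfigurationError("noise_sd must be >= 0 and gland_contrast > margin")
        if self.laterality not in ("left", "right"):
            raise ConfigurationError(f"laterality must be 'left' or 'right', got {self.laterality!r}")


def _geometry(params: PhantomParams) -> tuple[np.ndarray, dict[str, int]]:
    """Rasterize the label mask in left-laterality frame (chest wall at x=0)."""
    h, w = params.height, params.width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    # pectoral wedge: right triangle in the upper chest-wall corner with
    # height twice its base, area = pectoral_fraction * image area
    wt = np.sqrt(params.pectoral_fraction * w * h)
    hs = 2.0 * wt
    if hs > h:  # cap and widen to preserve area
        hs = float(h)
        wt = 2.0 * params.pectoral_fraction * w * h / hs
    wedge = (xx / max(wt, 1e-9) + yy / max(hs, 1e-9)) < 1.0 if params.pectoral_fraction > 0 else np.zeros((h, w), bool)

    # breast: half-ellipse centred on the chest-wall edge
    rx, ry, cy = 0.82 * w, 0.46 * h, 0.5 * h
    breast = (xx / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0

    # gland: ellipse inside the breast, scaled so its in-breast pixel count
    # approximates gland_fraction of the non-pectoral breast area
    breast_only = breast & ~wedge
    n_breast = int(breast_only.sum())
    target = params.gland_fraction * n_breast
    gx, gy = 0.50 * rx, 0.55 * ry
    s = np.sqrt(max(target, 1.0) / (np.pi * gx * gy))
    cxg, cyg = 0.40 * rx, cy + 0.04 * h
    gland = ((xx - cxg) / max(s * gx, 1e-9)) ** 2 + ((yy - cyg) / max(s * gy, 1e-9)) ** 2 <= 1.0
    gland &= breast_only
    if params.gland_fraction == 0:
        gland[:] = False

    labels = np.full((h, w), BACKGROUND, dtype=np.uint8)
    labels[breast_only] = FAT
    labels[gland] = GLAND
    labels[wedge] = PECTORAL

    counts = {
        "area_fat": int((labels == FAT).sum()),
        "area_gland": int((labels == GLAND).sum()),
        "area_pectoral": int((labels == PECTORAL).sum()),
    }
    if params.gland_fraction > 0 and counts["area_gland"] < 16:
        raise DegeneratePhantomError(
            f"gland region rasterized to {counts['area_gland']} px (< 16); "
            "increase gland_fraction or image size"
        )
    if counts["area_pectoral"] < 1 and params.pectoral_fraction > 0:
        raise DegeneratePhantomError("pectoral wedge rasterized to zero pixels")
    return labels, counts


def generate_phantom(
    params: PhantomParams | None = None, seed: int = 0
) -> tuple[IntensityImage, LabelMask]:
    """Generate one seeded image/mask phantom pair.

    Returns an :class:`IntensityImage` (intensities quantized to the 16-bit
    grid, so PNG round trips are lossless) and the matching
    :class:`LabelMask`. Same ``(params, seed)`` gives bit-identical output.
    """
    params = params or PhantomParams()
    params.validate()
    labels, _counts = _geometry(params)
    rng = np.random.default_rng(seed)
    h, w = labels.shape

    img = np.full((h, w), params.background_intensity, dtype=np.float64)
    img += rng.normal(0.0, params.noise_sd, size=(h, w))

    fat_px = labels == FAT
    img[fat_px] = params.fat_intensity_mean + rng.normal(0.0, params.noise_sd, int(fat_px.sum()))

    pec_px = labels == PECTORAL
    n_pec = int(pec_px.sum())
    if n_pec:
        pec_vals = np.clip(
            params.pectoral_intensity_mean + rng.normal(0.0, params.noise_sd, n_pec), 0.0, 1.0
        )
        img[pec_px] = pec_vals
        d_mj = float(pec_vals.mean())
    else:
        d_mj = params.pectoral_intensity_mean

    # gland: exactly round(p * n) pixels strictly above the realized pectoral
    # mean, the rest strictly below; clip keeps each mode on its side of the
    # threshold with a safety margin much larger than the 16-bit quantum
    gl_px = np.flatnonzero(labels.ravel() == GLAND)
    n_gl = gl_px.size
    if n_gl:
        n_dense = int(round(params.dense_fraction * n_gl))
        order = rng.permutation(n_gl)
        dense_idx = gl_px[order[:n_dense]]
        lucent_idx = gl_px[order[n_dense:]]
        flat = img.ravel()
        flat[dense_idx] = np.clip(
            d_mj + params.gland_contrast + rng.normal(0.0, params.noise_sd, n_dense),
            d_mj + _MARGIN,
            1.0,
        )
        flat[lucent_idx] = np.clip(
            d_mj - params.gland_contrast + rng.normal(0.0, params.noise_sd, n_gl - n_dense),
            0.0,
            d_mj - _MARGIN,
        )

    np.clip(img, 0.0, 1.0, out=img)
    img = np.round(img * _QUANTUM) / _QUANTUM

    if params.laterality == "right":
        img = img[:, ::-1].copy()
        labels = labels[:, ::-1].copy()

    image = IntensityImage(img, source_bit_depth=16, laterality=params.laterality)
    return image, LabelMask(labels)


@dataclass
class PhantomSet:
    """A generated collection of phantoms with its manifest.

    ``manifest`` has one row per item: ``item_id``, ``seed``, every
    :class:`PhantomParams` field, realized region areas, the ground-truth
    MDR of the emitted pair and, when a split was requested, a ``split``
    column (``train``/``test``).
    """

    items: list[tuple[IntensityImage, LabelMask]]
    manifest: pd.DataFrame

    def subset(self, split: str) -> "PhantomSet":
        idx = self.manifest.index[self.manifest["split"] == split]
        return PhantomSet(
            [self.items[i] for i in idx], self.manifest.loc[idx].reset_index(drop=True)
        )

    def split_manifests(self) -> dict[str, pd.DataFrame]:
        return {s: g.reset_index(drop=True) for s, g in self.manifest.groupby("split")}

    def write(self, out_dir: str | Path) -> Path:
        """Write images (16-bit PNG), masks (8-bit PNG) and manifest CSV.

        With a split, items go to ``<out>/train/{images,masks}`` and
        ``<out>/test/{images,masks}`` with one manifest per split;
        otherwise to ``<out>/{images,masks}``.
        """
        from . import io as _io  # local import to avoid a cycle at import time

        out = Path(out_dir)
        splits = self.manifest["split"] if "split" in self.manifest.columns else None
        for i, (img, mask) in enumerate(self.items):
            sub = out / splits.iloc[i] if splits is not None else out
            (sub / "images").mkdir(parents=True, exist_ok=True)
            (sub / "masks").mkdir(parents=True, exist_ok=True)
            stem = self.manifest["item_id"].iloc[i]
            _io.write_image(img, sub / "images" / f"{stem}.png")
            _io.write_mask(mask, sub / "masks" / f"{stem}.png")
        self.manifest.to_csv(out / "manifest.csv", index=False)
        if splits is not None:
            for s, g in self.split_manifests().items():
                g.to_csv(out / s / "manifest.csv", index=False)
        return out


def default_params_sampler(rng: np.random.Generator, width: int = 160,
                           height: int = 192) -> PhantomParams:
    """Per-item parameter draw used when no sampler is given: uniform dense
    fraction in [0.05, 0.95], random laterality, default geometry."""
    return PhantomParams(
        width=width,
        height=height,
        dense_fraction=float(rng.uniform(0.05, 0.95)),
        laterality="left" if rng.random() < 0.5 else "right",
    )


def generate_phantom_set(
    n: int,
    params_sampler: PhantomParams | Callable[[np.random.Generator], PhantomParams] | None = None,
    seed: int = 0,
    split: tuple[int, int] | None = None,
) -> PhantomSet:
    """Generate ``n`` independent phantoms with a deterministic manifest.

    Parameters
    ----------
    params_sampler:
        Either fixed :class:`PhantomParams` for every item, or a callable
        ``sampler(rng) -> PhantomParams`` drawing per-item parameters, or
        ``None`` for package defaults with alternating laterality.
    split:
        Optional ``(n_train, n_test)`` with ``n_train + n_test == n``; adds a
        ``split`` column to the manifest (first block train, rest test).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if split is not None and split[0] + split[1] != n:
        raise ValueError(f"split {split} does not sum to n={n}")

    master = np.random.default_rng(seed)
    item_seeds = master.integers(0, 2**31, size=n)

    items: list[tuple[IntensityImage, LabelMask]] = []
    rows: list[dict] = []
    for i in range(n):
        rng_i = np.random.default_rng(int(item_seeds[i]))
        if params_sampler is None:
            p = default_params_sampler(rng_i)
        elif callable(params_sampler):
            p = params_sampler(rng_i)
        else:
            p = params_sampler
        img, mask = generate_phantom(p, seed=int(item_seeds[i]))
        row = {"item_id": f"phantom_{i:04d}", "seed": int(item_seeds[i]), **asdict(p)}
        _, counts = _geometry(p)
        row.update(counts)
        row["truth_mdr"] = _ground_truth_mdr(img, mask)
        rows.append(row)
        items.append((img, mask))

    manifest = pd.DataFrame(rows)
    if split is not None:
        manifest["split"] = ["train"] * split[0] + ["test"] * split[1]
    return PhantomSet(items, manifest)


def _ground_truth_mdr(image: IntensityImage, mask: LabelMask) -> float:
    """Brute-force MDR from an emitted pair (kept local and loop-free on purpose:
    the reference implementation with full error handling lives in ``density``)."""
    px, lab = image.pixels, mask.labels
    pec = px[lab == PECTORAL]
    gl = px[lab == GLAND]
    if pec.size == 0 or gl.size == 0:
        return float("nan")
    return float((gl > pec.mean()).sum() / gl.size)


# ---------------------------------------------------------------------------
# longitudinal cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortParams:
    """Conditions for a synthetic longitudinal screening cohort.

    Two latent groups: a *rapidly declining* majority whose MDR falls by
    ``decline_rate_fast`` percentage points per year, and a *persistently
    dense* minority (fraction ``frac_persistent``) declining at
    ``decline_rate_slow``. Each subject enters at ``age_range[0]`` (screening
    entry) and is examined every ``exam_interval_years`` years. Start values
    are drawn per group from Gaussians ``start_mdr_* = (mean, sd)`` in
    percent; observed MDR adds Gaussian noise ``noise_sd`` and is clamped to
    [0, 100].
    """

    n_subjects: int = 200
    age_range: tuple[int, int] = (40, 79)
    exams_per_subject: int = 5
    exam_interval_years: int = 5
    frac_persistent: float = 0.2
    decline_rate_fast: float = 1.33
    decline_rate_slow: float = 0.1
    start_mdr_fast: tuple[float, float] = (36.2, 7.0)
    start_mdr_persistent: tuple[float, float] = (70.0, 10.0)
    noise_sd: float = 2.0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.age_range[1] <= self.age_range[0]:
            raise ValueError(f"age_range inverted or empty: {self.age_range}")
        if not 0.0 <= self.frac_persistent <= 1.0:
            raise ValueError("frac_persistent must be in [0, 1]")
        if self.decline_rate_fast < 0 or self.decline_rate_slow < 0:
            raise ValueError("decline rates must be >= 0")
        if self.exams_per_subject < 1 or self.exam_interval_years < 1:
            raise ValueError("exams_per_subject and exam_interval_years must be >= 1")
        span = self.exam_interval_years * (self.exams_per_subject - 1)
        if self.age_range[0] + span > self.age_range[1]:
            raise ValueError(
                f"exam schedule spans {span} years, exceeding age_range {self.age_range}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class Cohort:
    """Generated exam records plus the hidden group truth.

    ``exams``: columns ``subject_id, age, laterality, mdr_percent``.
    ``truth`` (sidecar, not an input to any estimator): ``subject_id, group,
    start_mdr, decline_rate`` with group in {rapidly_decreasing,
    persistently_dense}.
    """

    exams: pd.DataFrame
    truth: pd.DataFrame

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.exams.to_csv(out / "cohort.csv", index=False)
        self.truth.to_csv(out / "cohort_truth.csv", index=False)
        return out


def generate_cohort(params: CohortParams | None = None, seed: int = 0) -> Cohort:
    """Simulate per-subject longitudinal MDR series with two latent groups.

    Group assignment is deterministic in size: exactly
    ``round(frac_persistent * n_subjects)`` subjects are persistent, chosen by
    a seeded permutation.
    """
    params = params or CohortParams()
    params.validate()
    rng = np.random.default_rng(seed)

    n = params.n_subjects
    n_persistent = int(round(params.frac_persistent * n))
    persistent = np.zeros(n, dtype=bool)
    persistent[rng.permutation(n)[:n_persistent]] = True

    entry_age = params.age_range[0]
    ages = entry_age + params.exam_interval_years * np.arange(params.exams_per_subject)

    mu_f, sd_f = params.start_mdr_fast
    mu_p, sd_p = params.start_mdr_persistent
    starts = np.where(
        persistent,
        mu_p + sd_p * rng.standard_normal(n),
        mu_f + sd_f * rng.standard_normal(n),
    )
    starts = np.clip(starts, 0.0, 100.0)
    rates = np.where(persistent, params.decline_rate_slow, params.decline_rate_fast)

    exam_rows = []
    for i in range(n):
        noise = rng.normal(0.0, params.noise_sd, size=ages.size) if params.noise_sd > 0 else 0.0
        values = np.clip(starts[i] - rates[i] * (ages - entry_age) + noise, 0.0, 100.0)
        lats = rng.choice(["left", "right"], size=ages.size)
        for a, v, lat in zip(ages, values, lats):
            exam_rows.append(
                {"subject_id": f"S{i:05d}", "age": int(a), "laterality": lat,
                 "mdr_percent": float(v)}
            )

    truth = pd.DataFrame(
        {
            "subject_id": [f"S{i:05d}" for i in range(n)],
            "group": np.where(persistent, "persistently_dense", "rapidly_decreasing"),
            "start_mdr": starts,
            "decline_rate": rates,
        }
    )
    return Cohort(pd.DataFrame(exam_rows), truth)
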