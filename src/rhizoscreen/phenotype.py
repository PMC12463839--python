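"""Image-based shoot phenotyping: segmentation, traits, weight calibration.

Multi-view RGB photographs of a plant on a rotating platform are reduced
to three traits per view — pixel-based biomass (foreground pixel count),
shoot width (horizontal foreground extent), and occupancy ratio
(foreground fraction of the frame) — via a green-channel grayscale,
intensity thresholding (Otsu by default), and a center-anchored distance
mask that replaces manual cropping by discarding everything outside a
stated radius.  Per-view traits are aggregated over the view series
(mean for areas, maximum for width) and the aggregated pixel biomass is
calibrated against destructive dry shoot weights by Pearson correlation
and a least-squares line.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import remove_small_objects


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholding and masking configuration.

    ``mask_radius_fraction`` scales the inscribed image radius
    ``min(H, W) / 2``; foreground outside that disk is discarded.
    ``min_object_px`` removes connected components smaller than the given
    pixel count (0 disables the cleanup).  ``invert`` flips the threshold
    direction for light backgrounds.
    """

    threshold_mode: Literal["otsu", "fixed"] = "otsu"
    fixed_threshold: float | None = None
    mask_radius_fraction: float = 0.9
    min_object_px: int = 0
    invert: bool = False

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("otsu", "fixed"):
            raise ValueError("threshold_mode must be 'otsu' or 'fixed'")
        if self.threshold_mode == "fixed":
            if self.fixed_threshold is None or not \
                    0.0 <= self.fixed_threshold <= 1.0:
                raise ValueError("fixed mode needs fixed_threshold in [0, 1]")
        elif self.fixed_threshold is not None:
            raise ValueError("fixed_threshold is only valid in fixed mode")
        if not 0.0 < self.mask_radius_fraction <= 1.0:
            raise ValueError("mask_radius_fraction must be in (0, 1]")
        if self.min_object_px < 0:
            raise ValueError("min_object_px must be >= 0")


@dataclass(frozen=True)
class PlantTraits:
    """Shoot traits for one view (or the aggregate when ``view`` is None)."""

    plant_id: str
    view: int | None
    pixel_biomass: float
    shoot_width: float
    occupancy_ratio: float


def green_grayscale(view: np.ndarray) -> np.ndarray:
    """Grayscale as the green channel of an H x W x 3 image in [0, 1]."""
    view = np.asarray(view)
    if view.ndim != 3 or view.shape[2] != 3:
        raise ValueError("expected an H x W x 3 image")
    return view[:, :, 1]


def binarize(gray: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Threshold a grayscale image into a boolean foreground mask."""
    gray = np.asarray(gray, dtype=float)
    if gray.min() < 0 or gray.max() > 1:
        raise ValueError("intensities must lie in [0, 1]")
    if params.threshold_mode == "otsu":
        if np.ptp(gray) == 0:
            raise ValueError(
                "constant image: Otsu threshold undefined, use fixed mode")
        thr = threshold_otsu(gray)
    else:
        thr = float(params.fixed_threshold)  # type: ignore[arg-type]
    mask = (gray < thr) if params.invert else (gray > thr)
    if params.min_object_px > 0:
        # removes components of size <= max_size, i.e. < min_object_px
        mask = remove_small_objects(label(mask),
                                    max_size=params.min_object_px - 1) > 0
    return mask


def apply_distance_mask(mask: np.ndarray,
                        mask_radius_fraction: float) -> np.ndarray:
    """Zero out foreground farther than the given fraction of the
    inscribed radius from the image center."""
    h, w = mask.shape
    radius = mask_radius_fraction * min(h, w) / 2.0
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    rr = np.hypot(yy - (h - 1) / 2.0, xx - (w - 1) / 2.0)
    return mask & (rr <= radius)


def extract_traits(mask: np.ndarray, plant_id: str = "",
                   view: int | None = None) -> PlantTraits:
    """Traits from a (masked) binary image; empty masks yield zeros.

    Shoot width is the horizontal extent of the foreground boundary:
    rightmost minus leftmost occupied column plus one.
    """
    h, w = mask.shape
    count = int(mask.sum())
    if count == 0:
        return PlantTraits(plant_id, view, 0.0, 0.0, 0.0)
    cols = np.flatnonzero(mask.any(axis=0))
    width = int(cols[-1] - cols[0] + 1)
    return PlantTraits(plant_id, view, float(count), float(width),
                       count / (h * w))


def segment_view(view: np.ndarray, params: SegmentationParams,
                 plant_id: str = "", view_index: int | None = None,
                 ) -> PlantTraits:
    """Full per-view chain: green channel -> threshold -> mask -> traits."""
    mask = binarize(green_grayscale(view), params)
    mask = apply_distance_mask(mask, params.mask_radius_fraction)
    return extract_traits(mask, plant_id, view_index)


def aggregate_views(traits: Sequence[PlantTraits],
                    agg: Literal["mean", "sum"] = "mean") -> PlantTraits:
    """Combine per-view traits: mean (or sum) for pixel biomass and
    occupancy, maximum across views for shoot width."""
    if not traits:
        raise ValueError("no view traits to aggregate")
    plant_ids = {t.plant_id for t in traits}
    if len(plant_ids) != 1:
        raise ValueError("traits from multiple plants")
    combine = np.mean if agg == "mean" else np.sum
    return PlantTraits(
        plant_id=traits[0].plant_id, view=None,
        pixel_biomass=float(combine([t.pixel_biomass for t in traits])),
        shoot_width=float(max(t.shoot_width for t in traits)),
        occupancy_ratio=float(combine([t.occupancy_ratio for t in traits])),
    )


def phenotype_plants(images: Mapping[str, Iterable[np.ndarray]],
                     params: SegmentationParams | None = None,
                     agg: Literal["mean", "sum"] = "mean",
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-view and aggregate trait tables for a set of plants."""
    params = params or SegmentationParams()
    per_view, aggregates = [], []
    for plant_id in sorted(images):
        traits = [segment_view(img, params, plant_id, k)
                  for k, img in enumerate(images[plant_id])]
        per_view.extend(traits)
        aggregates.append(aggregate_views(traits, agg=agg))
    cols = ["plant_id", "view", "pixel_biomass", "shoot_width",
            "occupancy_ratio"]
    pv = pd.DataFrame([t.__dict__ for t in per_view], columns=cols)
    ag = pd.DataFrame([t.__dict__ for t in aggregates], columns=cols
                      ).drop(columns="view")
    return pv, ag


def load_view_images(image_dir: str | Path) -> dict[str, list[np.ndarray]]:
    """Load ``<plant_id>_<view>.png`` images as float arrays in [0, 1]."""
    image_dir = Path(image_dir)
    grouped: dict[str, dict[int, np.ndarray]] = {}
    for path in sorted(image_dir.glob("*.png")):
        stem, _, view = path.stem.rpartition("_")
        arr = np.asarray(Image.open(path).convert("RGB"), dtype=float) / 255.0
        grouped.setdefault(stem, {})[int(view)] = arr
    return {pid: [views[k] for k in sorted(views)]
            for pid, views in grouped.items()}


@dataclass(frozen=True)
class CalibrationResult:
    """Pixel-biomass vs dry-weight calibration (weight regressed on pixels)."""

    n_plants: int
    pearson_r: float
    slope: float
    intercept: float

    def predict(self, pixels: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(pixels, dtype=float)


def calibrate(aggregate_traits: pd.DataFrame,
              dry_weights: pd.DataFrame) -> CalibrationResult:
    """Correlate aggregated pixel biomass with dry shoot weight.

    ``dry_weights`` needs columns ``plant_id`` and ``weight_g``; plant ids
    must match the aggregate trait table one-to-one and at least three
    plants with nonzero variance on both axes are required.
    """
    merged = aggregate_traits.merge(dry_weights, on="plant_id", how="inner",
                                    validate="one_to_one")
    if len(merged) != len(aggregate_traits) or \
            len(merged) != len(dry_weights):
        raise ValueError("plant ids in traits and weights do not match")
    if len(merged) < 3:
        raise ValueError("calibration needs at least 3 plants")
    x = merged["pixel_biomass"].to_numpy(float)
    y = merged["weight_g"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in pixels or weights")
    r = float(stats.pearsonr(x, y).statistic)
    fit = stats.linregress(x, y)
    return CalibrationResult(n_plants=len(merged), pearson_r=r,
                             slope=float(fit.slope),
                             intercept=float(fit.intercept))
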