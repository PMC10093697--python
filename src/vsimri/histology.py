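"""Vessel morphometry on stained-slide ROI images.

Positively stained vessel profiles are segmented from a single-channel
stain-intensity image (Otsu threshold, light morphological clean-up,
hole filling, connected components) and quantified per object:

* area and equivalent radius ``sqrt(area / pi)`` in micrometres,
* roundness ``perimeter**2 / (4 * pi * area)`` — 1 for a circle, larger for
  elongated or crenated profiles (inverse circularity).

Per-ROI summaries are vessel density (stained area as a percentage of ROI
area, pooled over ROIs by total areas) and unweighted means of radius and
roundness over all objects. Perimeters use the Crofton line-intercept
estimator (4 directions), which is unbiased enough that a rasterized disk
scores roundness 1.00 within 1%; naive pixel-edge counting overestimates a
disk's perimeter by ~11% and would bias roundness upward by ~27%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import disk, opening

__all__ = [
    "VesselTable",
    "segment_vessels",
    "measure_vessels",
    "vessel_density",
    "mean_radius",
    "mean_roundness",
    "pool_rois",
]


@dataclass
class VesselTable:
    """Per-object metrics plus pooled per-ROI summary values."""

    objects: pd.DataFrame  # area_um2, perimeter_um, equivalent_radius_um, roundness
    vessel_density_percent: float
    mean_radius_um: float
    mean_roundness: float
    n_objects: int
    pixel_size: float


def segment_vessels(
    stain_image: np.ndarray,
    pixel_size: float = 1.0,
    min_object_area: float = 20.0,
) -> np.ndarray:
    """Label stained vessel profiles in a single-channel intensity image.

    Otsu thresholding separates stain from background, a one-pixel opening
    removes speckle, holes are filled, and objects smaller than
    ``min_object_area`` (um^2) are dropped. A perfectly uniform image yields
    zero objects.

    Returns an int label image (0 = background).
    """
    img = np.asarray(stain_image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("stain_image must be a non-empty 2D array")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=np.int32)
    fg = img > threshold_otsu(img)
    fg = opening(fg, disk(1))
    fg = ndimage.binary_fill_holes(fg)
    labels = cc_label(fg, connectivity=2)
    min_px = max(1, int(round(min_object_area / pixel_size**2)))
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts >= min_px)
    keep = keep[keep != 0]
    relabel = np.zeros(counts.size, dtype=np.int32)
    relabel[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
    return relabel[labels]


def measure_vessels(labels: np.ndarray, pixel_size: float = 1.0) -> pd.DataFrame:
    """Per-object area, perimeter, equivalent radius and roundness.

    Zero-area objects are excluded. Lengths are in micrometres via
    ``pixel_size`` (um/px).
    """
    records = []
    for prop in regionprops(labels):
        area_px = prop.area
        if area_px <= 0:
            continue
        perim_px = prop.perimeter_crofton
        area = area_px * pixel_size**2
        perim = perim_px * pixel_size
        records.append(
            {
                "label": prop.label,
                "area_um2": area,
                "perimeter_um": perim,
                "equivalent_radius_um": float(np.sqrt(area / np.pi)),
                "roundness": float(perim**2 / (4.0 * np.pi * area)),
            }
        )
    return pd.DataFrame(
        records,
        columns=["label", "area_um2", "perimeter_um", "equivalent_radius_um", "roundness"],
    )


def vessel_density(
    labels: np.ndarray,
    roi_area_um2: float | None = None,
    pixel_size: float = 1.0,
) -> float:
    """Stained area as a percentage of the ROI area.

    By default the ROI is the full label image.
    """
    stained = float((labels > 0).sum()) * pixel_size**2
    if roi_area_um2 is None:
        roi_area_um2 = labels.size * pixel_size**2
    if roi_area_um2 <= 0:
        raise ValueError("ROI area must be positive")
    return 100.0 * stained / roi_area_um2


def mean_radius(objects: pd.DataFrame) -> float:
    """Unweighted mean equivalent radius over objects (um)."""
    if len(objects) == 0:
        raise ValueError("no objects to average")
    return float(objects["equivalent_radius_um"].mean())


def mean_roundness(objects: pd.DataFrame) -> float:
    """Unweighted mean roundness over objects."""
    if len(objects) == 0:
        raise ValueError("no objects to average")
    return float(objects["roundness"].mean())


def pool_rois(
    rois: list[tuple[np.ndarray, float | None]],
    pixel_size: float = 1.0,
) -> VesselTable:
    """Pool morphometry over several ROIs of one tissue sample.

    ``rois`` is a list of ``(label_image, roi_area_um2)`` pairs (area None
    means the full image). Density pools total stained and ROI areas; radius
    and roundness are averaged over all objects from all ROIs.
    """
    if not rois:
        raise ValueError("at least one ROI is required")
    tables = []
    stained_total = 0.0
    roi_total = 0.0
    for labels, roi_area in rois:
        stained_total += float((labels > 0).sum()) * pixel_size**2
        roi_total += (
            labels.size * pixel_size**2 if roi_area is None else float(roi_area)
        )
        tables.append(measure_vessels(labels, pixel_size=pixel_size))
    objects = pd.concat(tables, ignore_index=True)
    if roi_total <= 0:
        raise ValueError("total ROI area must be positive")
    density = 100.0 * stained_total / roi_total
    return VesselTable(
        objects=objects,
        vessel_density_percent=density,
        mean_radius_um=mean_radius(objects) if len(objects) else float("nan"),
        mean_roundness=mean_roundness(objects) if len(objects) else float("nan"),
        n_objects=int(len(objects)),
        pixel_size=pixel_size,
    )
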