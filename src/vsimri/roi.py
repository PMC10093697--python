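"""Tumor-ROI summaries: mean, median and hot-spot values per map.

The hot spot pools every valid tumor voxel whose value is at or above the
90th percentile of the within-tumor distribution and averages them across
all supra-threshold clusters together; the number of 26-connected clusters
is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preprocess import ValidityMask

__all__ = ["ROISummary", "summarize"]


@dataclass
class ROISummary:
    parameter: str
    mean: float
    median: float
    hotspot: float
    n_valid_voxels: int
    n_hotspot_voxels: int
    n_clusters: int

    def as_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "mean": self.mean,
            "median": self.median,
            "hotspot": self.hotspot,
            "n_valid_voxels": self.n_valid_voxels,
            "n_hotspot_voxels": self.n_hotspot_voxels,
            "n_clusters": self.n_clusters,
        }


def summarize(
    value_map: np.ndarray,
    tumor_mask: np.ndarray,
    validity: ValidityMask | None = None,
    hotspot_percentile: float = 90.0,
    min_voxels: int = 10,
    parameter: str = "",
) -> ROISummary:
    """Mean, median and hot-spot summary of one map over the tumor mask.

    Only valid, finite voxels enter the statistics. The percentile uses
    linear interpolation between order statistics, and the supra-threshold
    set is inclusive (values >= the percentile). Clusters are connected
    components of that set under 26-connectivity; their count is reported
    but the hot-spot value pools all supra-threshold voxels.
    """
    sel = tumor_mask.astype(bool)
    if validity is not None:
        sel = sel & validity.valid
    sel = sel & np.isfinite(value_map)
    values = value_map[sel]
    if values.size < min_voxels:
        raise ValueError(
            f"only {values.size} valid tumor voxels; need at least {min_voxels}"
        )
    threshold = np.percentile(values, hotspot_percentile)
    hot = values >= threshold
    hot_volume = sel & (value_map >= threshold)
    _, n_clusters = ndimage.label(hot_volume, structure=np.ones((3, 3, 3)))
    return ROISummary(
        parameter=parameter,
        mean=float(values.mean()),
        median=float(np.median(values)),
        hotspot=float(values[hot].mean()),
        n_valid_voxels=int(values.size),
        n_hotspot_voxels=int(hot.sum()),
        n_clusters=int(n_clusters),
    )
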