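"""Normalized CBV / uCBV maps and the Kiselev vessel-size map.

Raw bolus integrals are normalized to the contralateral normal-appearing
white matter (NAWM) mean, the CBV entering the vessel-size model is rescaled
so its NAWM median equals 3.2% blood volume, and mean vessel size per voxel
follows the Kiselev model

    VS = 0.867 * sqrt(CBV * ADC) * dR2*max / dR2max**(3/2)

with CBV as a unitless fraction, ADC in um^2/s and the peak rate changes in
1/s, which yields micrometres. No contrast-leakage correction is applied.
Invalid voxels carry NaN and are excluded from all region statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import (
    REASON_NEGATIVE_CBV_ADC,
    REASON_NONPOSITIVE_PEAK_RATE,
    ValidityMask,
)
from .relaxometry import PeakRates

__all__ = [
    "KISELEV_CONSTANT",
    "ParamMaps",
    "normalize_to_nawm",
    "scale_to_nawm_median",
    "vessel_size_map",
]

KISELEV_CONSTANT = 0.867

NAWM_CBV_TARGET_PERCENT = 3.2


@dataclass
class ParamMaps:
    """The per-subject quantitative maps, on one shared grid.

    ``cbv_norm`` and ``ucbv_norm`` are NAWM-relative (NAWM mean = 1);
    ``cbv_scaled`` is in percent blood volume (NAWM median = 3.2);
    ``vessel_size`` is in micrometres; ``adc`` in um^2/s. Invalid voxels are
    NaN in every map.
    """

    cbv_norm: np.ndarray
    ucbv_norm: np.ndarray
    cbv_scaled: np.ndarray
    vessel_size: np.ndarray
    adc: np.ndarray
    validity: ValidityMask

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "cbv": self.cbv_norm,
            "ucbv": self.ucbv_norm,
            "cbv_scaled": self.cbv_scaled,
            "vessel_size": self.vessel_size,
            "adc": self.adc,
        }


def _valid_region_values(
    raw_map: np.ndarray, region_mask: np.ndarray, validity: ValidityMask | None
) -> np.ndarray:
    sel = region_mask.astype(bool)
    if validity is not None:
        sel = sel & validity.valid
    vals = raw_map[sel]
    return vals[np.isfinite(vals)]


def normalize_to_nawm(
    raw_map: np.ndarray,
    nawm_mask: np.ndarray,
    validity: ValidityMask | None = None,
    min_voxels: int = 50,
) -> np.ndarray:
    """Divide every voxel by the mean over valid NAWM voxels.

    The output is unitless with NAWM mean exactly 1.
    """
    vals = _valid_region_values(raw_map, nawm_mask, validity)
    if vals.size < min_voxels:
        raise ValueError(
            f"only {vals.size} valid NAWM voxels; need at least {min_voxels}"
        )
    ref = vals.mean()
    if not np.isfinite(ref) or ref == 0:
        raise ValueError("NAWM mean is zero or non-finite; cannot normalize")
    return raw_map / ref


def scale_to_nawm_median(
    raw_cbv: np.ndarray,
    nawm_mask: np.ndarray,
    validity: ValidityMask | None = None,
    target_percent: float = NAWM_CBV_TARGET_PERCENT,
    min_voxels: int = 50,
) -> np.ndarray:
    """Rescale raw CBV so the valid-NAWM median equals ``target_percent``.

    The result is in percent blood volume; dividing by 100 gives the
    fraction the vessel-size model expects.
    """
    vals = _valid_region_values(raw_cbv, nawm_mask, validity)
    if vals.size < min_voxels:
        raise ValueError(
            f"only {vals.size} valid NAWM voxels; need at least {min_voxels}"
        )
    med = np.median(vals)
    if med <= 0:
        raise ValueError(f"NAWM median CBV is {med}; must be positive to scale")
    if target_percent == 0:
        warnings.warn("target_percent is 0: the scaled map is identically zero")
    return raw_cbv * (target_percent / med)


def vessel_size_map(
    cbv_fraction: np.ndarray,
    adc: np.ndarray,
    peaks: PeakRates,
    validity: ValidityMask | None = None,
) -> tuple[np.ndarray, ValidityMask]:
    """Mean vessel size per voxel from the Kiselev model, in micrometres.

    ``cbv_fraction`` must be the scaled CBV expressed as a fraction
    (3.2% -> 0.032). Voxels with a nonpositive spin-echo peak rate or a
    negative CBV*ADC product are invalidated with a reason code rather than
    producing a value.
    """
    validity = (
        validity.copy()
        if validity is not None
        else ValidityMask.all_valid(np.shape(cbv_fraction))
    )
    dr2s = np.asarray(peaks.delta_r2star_max, dtype=float)
    dr2 = np.asarray(peaks.delta_r2_max, dtype=float)
    product = np.asarray(cbv_fraction, dtype=float) * np.asarray(adc, dtype=float)

    with np.errstate(invalid="ignore"):
        bad_peak = ~(dr2 > 0)  # catches NaN too
        bad_product = product < 0
    validity.invalidate(bad_peak & validity.valid, REASON_NONPOSITIVE_PEAK_RATE)
    validity.invalidate(bad_product & validity.valid, REASON_NEGATIVE_CBV_ADC)

    with np.errstate(invalid="ignore", divide="ignore"):
        vs = KISELEV_CONSTANT * np.sqrt(product) * dr2s / dr2**1.5
    vs = np.where(validity.valid, vs, np.nan)
    return vs, validity
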