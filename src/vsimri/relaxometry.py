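"""Signal-to-relaxation-rate conversion and bolus-passage integration.

The dual-echo signals are converted to transverse relaxation-rate changes

    dR2*(t) = -(1/TE_GRE) * ln(S_GRE(t) / S_GRE(0))
    dR2(t)  = -(1/TE_SE)  * ln(S_SE(t)  / S_SE(0))

with ``S(0)`` the pre-bolus baseline mean. The bolus passage window
``[t0, t1]`` is located on the mask-averaged dR2* curve, and raw CBV / uCBV
follow by trapezoidal integration of dR2*(t) / dR2(t) over that window; the
peak rate changes within the window feed the vessel-size model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import (
    BaselineEstimate,
    DualEchoSeries,
    REASON_NONPOSITIVE,
    ValidityMask,
)

__all__ = [
    "RelaxationCurves",
    "BolusWindow",
    "PeakRates",
    "to_relaxation",
    "detect_bolus_window",
    "integrate_cbv",
    "integrate_ucbv",
    "peak_rates",
]


@dataclass
class RelaxationCurves:
    """Per-voxel dR2*(t) and dR2(t) curves in 1/s.

    Invalid voxels are NaN throughout; ``baseline_end`` marks the first
    post-injection frame and ``time_axis`` is frame index times TR.
    """

    delta_r2star: np.ndarray
    delta_r2: np.ndarray
    time_axis: np.ndarray
    baseline_end: int
    validity: ValidityMask

    @property
    def tr(self) -> float:
        return float(self.time_axis[1] - self.time_axis[0])


@dataclass(frozen=True)
class BolusWindow:
    """Entrance (t0) and exit (t1) frame indices of the bolus, inclusive."""

    t0: int
    t1: int

    def __post_init__(self) -> None:
        if self.t1 <= self.t0:
            raise ValueError("bolus window requires t1 > t0")

    @property
    def n_frames(self) -> int:
        return self.t1 - self.t0 + 1


@dataclass
class PeakRates:
    """Per-voxel maxima of dR2*(t) and dR2(t) within the bolus window."""

    delta_r2star_max: np.ndarray
    delta_r2_max: np.ndarray


def to_relaxation(
    series: DualEchoSeries,
    baseline: BaselineEstimate,
    validity: ValidityMask | None = None,
) -> RelaxationCurves:
    """Convert both echoes to relaxation-rate change curves.

    Voxels with a nonpositive signal ratio anywhere on the time axis are
    marked invalid (never clamped); their curves are NaN.
    """
    validity = (
        validity.copy()
        if validity is not None
        else ValidityMask.all_valid(series.grid_shape)
    )
    bad_ratio = (
        (series.gre_signal.min(axis=-1) <= 0)
        | (series.se_signal.min(axis=-1) <= 0)
        | (baseline.gre_mean <= 0)
        | (baseline.se_mean <= 0)
    )
    validity.invalidate(bad_ratio & validity.valid, REASON_NONPOSITIVE)

    with np.errstate(divide="ignore", invalid="ignore"):
        dr2s = -np.log(series.gre_signal / baseline.gre_mean[..., None]) / series.te_gre
        dr2 = -np.log(series.se_signal / baseline.se_mean[..., None]) / series.te_se
    dr2s[~validity.valid] = np.nan
    dr2[~validity.valid] = np.nan

    time_axis = np.arange(series.n_frames, dtype=float) * series.tr
    return RelaxationCurves(
        delta_r2star=dr2s,
        delta_r2=dr2,
        time_axis=time_axis,
        baseline_end=series.injection_index,
        validity=validity,
    )


def mean_curve(curves: RelaxationCurves, mask: np.ndarray) -> np.ndarray:
    """dR2*(t) averaged over valid voxels inside ``mask``."""
    sel = mask & curves.validity.valid
    if not sel.any():
        raise ValueError("no valid voxels inside the mask")
    return curves.delta_r2star[sel].mean(axis=0)


def detect_bolus_window(
    curves: RelaxationCurves,
    mask: np.ndarray,
    threshold_fraction: float = 0.1,
) -> BolusWindow:
    """Locate the bolus passage on the mask-averaged dR2* curve.

    The window is the contiguous run of frames around the global peak whose
    mean curve stays at or above ``threshold_fraction`` of the peak value,
    clipped to start no earlier than the end of the baseline. One shared
    window is used for all voxels.
    """
    curve = mean_curve(curves, mask)
    peak = np.nanmax(curve)
    if not np.isfinite(peak) or peak <= 0:
        raise ValueError("flat or nonpositive mean curve: no bolus detected")
    thr = threshold_fraction * peak
    above = curve >= thr
    if not above.any():
        raise ValueError("no frame exceeds the detection threshold")
    peak_idx = int(np.nanargmax(curve))
    t0 = peak_idx
    while t0 > 0 and above[t0 - 1]:
        t0 -= 1
    t1 = peak_idx
    while t1 < curve.size - 1 and above[t1 + 1]:
        t1 += 1
    t0 = max(t0, curves.baseline_end)
    if t1 <= t0:
        raise ValueError("detected bolus window collapsed to a single frame")
    return BolusWindow(t0=t0, t1=t1)


def _trapz_window(curve4d: np.ndarray, window: BolusWindow, dt: float) -> np.ndarray:
    return np.trapezoid(curve4d[..., window.t0 : window.t1 + 1], dx=dt, axis=-1)


def integrate_cbv(curves: RelaxationCurves, window: BolusWindow) -> np.ndarray:
    """Raw CBV: trapezoidal integral of dR2*(t) over [t0, t1], spacing TR.

    Negative excursions within the window are integrated as-is (no
    clipping); units are (1/s)*s, removed later by NAWM normalization.
    """
    return _trapz_window(curves.delta_r2star, window, curves.tr)


def integrate_ucbv(curves: RelaxationCurves, window: BolusWindow) -> np.ndarray:
    """Raw microvascular CBV: trapezoidal integral of dR2(t) over [t0, t1]."""
    return _trapz_window(curves.delta_r2, window, curves.tr)


def peak_rates(curves: RelaxationCurves, window: BolusWindow) -> PeakRates:
    """Per-voxel maximum rate change of each echo within the window."""
    sl = slice(window.t0, window.t1 + 1)
    return PeakRates(
        delta_r2star_max=curves.delta_r2star[..., sl].max(axis=-1),
        delta_r2_max=curves.delta_r2[..., sl].max(axis=-1),
    )
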