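"""Per-subject vessel-size-imaging model and its results object.

:class:`VesselSizeModel` bundles one subject's co-registered inputs (the
dual-echo DSC series, ADC map and tumor / NAWM masks) with the pipeline
constants; :meth:`VesselSizeModel.fit` runs trimming, baseline estimation,
quality control, relaxometry, bolus-window detection, integration,
normalization and the Kiselev vessel-size model, returning a
:class:`VesselSizeResults` that carries the quantitative maps, ROI
summaries, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import maps as maps_mod
from . import relaxometry as rel
from . import roi as roi_mod
from .preprocess import (
    BaselineEstimate,
    DualEchoSeries,
    ValidityMask,
    estimate_baseline,
    qc_filter,
    trim_initial,
)

__all__ = ["PipelineConfig", "VesselSizeModel", "VesselSizeResults"]

_ADC_TO_UM2_S = {"um2/s": 1.0, "mm2/s": 1e6}


@dataclass(frozen=True)
class PipelineConfig:
    """Pipeline constants.

    Defaults are the study conditions: discard the first 4 frames, exclude
    voxels dropping less than 2 baseline SDs, rescale CBV so the NAWM median
    is 3.2% blood volume, hot spots at the 90th percentile, alpha = 0.05.
    ``adc_units`` must be declared by the caller ("um2/s" or "mm2/s").
    """

    n_discard: int = 4
    qc_sd_threshold: float = 2.0
    nawm_cbv_target_percent: float = 3.2
    hotspot_percentile: float = 90.0
    alpha: float = 0.05
    min_nawm_voxels: int = 50
    min_tumor_voxels: int = 10
    bolus_threshold_fraction: float = 0.1
    adc_units: str = "um2/s"

    def __post_init__(self) -> None:
        if self.n_discard < 0:
            raise ValueError("n_discard must be >= 0")
        for name in (
            "qc_sd_threshold",
            "nawm_cbv_target_percent",
            "hotspot_percentile",
            "alpha",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.adc_units not in _ADC_TO_UM2_S:
            raise ValueError(
                f"adc_units must be one of {sorted(_ADC_TO_UM2_S)}"
            )


class VesselSizeModel:
    """Vessel-size imaging estimation for one subject.

    Parameters
    ----------
    series : DualEchoSeries
        Untrimmed dual-echo DSC acquisition.
    adc : ndarray
        3D apparent-diffusion-coefficient map on the same grid, in the units
        declared by ``config.adc_units``.
    tumor_mask, nawm_mask : ndarray
        Binary 3D masks on the same grid (pre-registered).
    config : PipelineConfig, optional
    """

    def __init__(
        self,
        series: DualEchoSeries,
        adc: np.ndarray,
        tumor_mask: np.ndarray,
        nawm_mask: np.ndarray,
        config: PipelineConfig | None = None,
    ):
        config = config or PipelineConfig()
        adc = np.asarray(adc, dtype=float)
        tumor_mask = np.asarray(tumor_mask).astype(bool)
        nawm_mask = np.asarray(nawm_mask).astype(bool)
        grid = series.grid_shape
        for name, vol in (("adc", adc), ("tumor_mask", tumor_mask), ("nawm_mask", nawm_mask)):
            if vol.shape != grid:
                raise ValueError(
                    f"{name} grid {vol.shape} does not match the series grid {grid}"
                )
        if np.any(tumor_mask & nawm_mask):
            raise ValueError("tumor and NAWM masks overlap")
        self.series = series
        self.adc = adc * _ADC_TO_UM2_S[config.adc_units]
        self.tumor_mask = tumor_mask
        self.nawm_mask = nawm_mask
        self.config = config

    @classmethod
    def from_phantom(cls, phantom, config: PipelineConfig | None = None):
        """Build the model directly from a digital-phantom output."""
        return cls(
            series=DualEchoSeries.from_phantom(phantom),
            adc=phantom.adc_map,
            tumor_mask=phantom.tumor_mask,
            nawm_mask=phantom.nawm_mask,
            config=config,
        )

    def fit(self) -> "VesselSizeResults":
        """Run the full per-subject pipeline. Deterministic given inputs."""
        cfg = self.config
        trimmed = trim_initial(self.series, cfg.n_discard)
        baseline = estimate_baseline(trimmed)
        validity = qc_filter(trimmed, baseline, sd_threshold=cfg.qc_sd_threshold)
        curves = rel.to_relaxation(trimmed, baseline, validity)
        window = rel.detect_bolus_window(
            curves,
            self.tumor_mask | self.nawm_mask,
            threshold_fraction=cfg.bolus_threshold_fraction,
        )
        raw_cbv = rel.integrate_cbv(curves, window)
        raw_ucbv = rel.integrate_ucbv(curves, window)
        peaks = rel.peak_rates(curves, window)

        cbv_norm = maps_mod.normalize_to_nawm(
            raw_cbv, self.nawm_mask, curves.validity, min_voxels=cfg.min_nawm_voxels
        )
        ucbv_norm = maps_mod.normalize_to_nawm(
            raw_ucbv, self.nawm_mask, curves.validity, min_voxels=cfg.min_nawm_voxels
        )
        cbv_scaled = maps_mod.scale_to_nawm_median(
            raw_cbv,
            self.nawm_mask,
            curves.validity,
            target_percent=cfg.nawm_cbv_target_percent,
            min_voxels=cfg.min_nawm_voxels,
        )
        vessel_size, validity = maps_mod.vessel_size_map(
            cbv_scaled / 100.0, self.adc, peaks, curves.validity
        )

        nan = np.where(validity.valid, 1.0, np.nan)
        param_maps = maps_mod.ParamMaps(
            cbv_norm=cbv_norm * nan,
            ucbv_norm=ucbv_norm * nan,
            cbv_scaled=cbv_scaled * nan,
            vessel_size=vessel_size,
            adc=self.adc,
            validity=validity,
        )
        return VesselSizeResults(
            model=self,
            maps=param_maps,
            baseline=baseline,
            window=window,
            peaks=peaks,
            raw_cbv=raw_cbv,
            raw_ucbv=raw_ucbv,
        )


@dataclass
class VesselSizeResults:
    """Fitted maps, diagnostics and ROI summaries for one subject."""

    model: VesselSizeModel
    maps: maps_mod.ParamMaps
    baseline: BaselineEstimate
    window: rel.BolusWindow
    peaks: rel.PeakRates
    raw_cbv: np.ndarray
    raw_ucbv: np.ndarray
    _roi_cache: pd.DataFrame | None = field(default=None, repr=False)

    # parameters summarized over the tumor ROI, in reporting order
    ROI_PARAMETERS = ("cbv", "ucbv", "vessel_size")

    @property
    def validity(self) -> ValidityMask:
        return self.maps.validity

    def roi_summary(self) -> pd.DataFrame:
        """Tumor-ROI mean / median / hot-spot table for CBV, uCBV and VS."""
        if self._roi_cache is None:
            cfg = self.model.config
            maps_by_name = {
                "cbv": self.maps.cbv_norm,
                "ucbv": self.maps.ucbv_norm,
                "vessel_size": self.maps.vessel_size,
            }
            rows = []
            for name in self.ROI_PARAMETERS:
                summary = roi_mod.summarize(
                    maps_by_name[name],
                    self.model.tumor_mask,
                    self.validity,
                    hotspot_percentile=cfg.hotspot_percentile,
                    min_voxels=cfg.min_tumor_voxels,
                    parameter=name,
                )
                rows.append(summary.as_dict())
            self._roi_cache = pd.DataFrame(rows)
        return self._roi_cache

    def summary(self) -> str:
        """Human-readable fit report."""
        cfg = self.model.config
        counts = self.validity.exclusion_counts()
        roi = self.roi_summary()
        lines = [
            "Vessel size imaging fit",
            "=======================",
            f"grid: {self.model.series.grid_shape}, "
            f"frames after trim: {self.model.series.n_frames - cfg.n_discard}",
            f"bolus window: frames [{self.window.t0}, {self.window.t1}] "
            f"({self.window.n_frames} frames x TR {self.model.series.tr} s)",
            f"valid voxels: {self.validity.n_valid} / {self.validity.valid.size}",
            "exclusions: "
            + ", ".join(f"{k}={v}" for k, v in counts.items() if v),
            "",
            "Tumor ROI summaries (CBV/uCBV NAWM-relative, vessel size in um):",
            roi.to_string(
                index=False,
                float_format=lambda v: f"{v:.3f}",
                columns=[
                    "parameter",
                    "mean",
                    "median",
                    "hotspot",
                    "n_valid_voxels",
                    "n_clusters",
                ],
            ),
        ]
        return "\n".join(lines)
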