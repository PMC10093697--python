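"""Steady-state trimming, baseline estimation and voxel quality control.

The dual-echo series is trimmed of its first frames (signal not yet at
steady state), per-voxel baselines are estimated over the pre-bolus window,
and voxels whose bolus-induced signal drop is smaller than twice the
baseline standard deviation — on either echo — are excluded from all
downstream maps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "DualEchoSeries",
    "BaselineEstimate",
    "ValidityMask",
    "REASON_DROP_GRE",
    "REASON_DROP_SE",
    "REASON_NONPOSITIVE",
    "REASON_NONPOSITIVE_PEAK_RATE",
    "REASON_NEGATIVE_CBV_ADC",
    "trim_initial",
    "estimate_baseline",
    "qc_filter",
]

# reason-code bits for excluded voxels
REASON_DROP_GRE = 1  # signal drop < 2 SD on the gradient echo
REASON_DROP_SE = 2  # signal drop < 2 SD on the spin echo
REASON_NONPOSITIVE = 4  # nonpositive signal (log undefined)
REASON_NONPOSITIVE_PEAK_RATE = 8  # dR2 peak <= 0 in the vessel-size model
REASON_NEGATIVE_CBV_ADC = 16  # negative CBV*ADC product under the square root


@dataclass
class DualEchoSeries:
    """Paired 4D gradient-echo / spin-echo DSC signal series.

    Arrays are ``(x, y, z, t)`` in arbitrary signal units. Echo times and the
    repetition time are in seconds; ``injection_index`` is the frame at which
    the contrast bolus is administered.
    """

    gre_signal: np.ndarray
    se_signal: np.ndarray
    tr: float
    te_gre: float
    te_se: float
    injection_index: int

    def __post_init__(self) -> None:
        self.gre_signal = np.asarray(self.gre_signal, dtype=float)
        self.se_signal = np.asarray(self.se_signal, dtype=float)
        if self.gre_signal.ndim != 4:
            raise ValueError("signal arrays must be 4D (x, y, z, t)")
        if self.gre_signal.shape != self.se_signal.shape:
            raise ValueError("GRE and SE series must share one shape")
        if not (self.tr > 0 and self.te_gre > 0 and self.te_se > 0):
            raise ValueError("tr, te_gre and te_se must be positive")
        if self.te_gre >= self.te_se:
            raise ValueError("gradient-echo TE must be shorter than spin-echo TE")
        if not 0 <= self.injection_index < self.n_frames:
            raise ValueError("injection_index outside the time axis")

    @property
    def n_frames(self) -> int:
        return self.gre_signal.shape[-1]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.gre_signal.shape[:3]

    @classmethod
    def from_phantom(cls, phantom) -> "DualEchoSeries":
        """Wrap a :class:`~vsimri.phantom.PhantomOutput` as an acquisition."""
        return cls(
            gre_signal=phantom.gre_series,
            se_signal=phantom.se_series,
            tr=phantom.tr,
            te_gre=phantom.te_gre,
            te_se=phantom.te_se,
            injection_index=phantom.injection_index,
        )


@dataclass
class BaselineEstimate:
    """Per-voxel, per-echo pre-bolus signal mean and standard deviation.

    The window is ``[0, injection_index)`` on the trimmed series; the SD uses
    the n-1 divisor.
    """

    gre_mean: np.ndarray
    gre_sd: np.ndarray
    se_mean: np.ndarray
    se_sd: np.ndarray
    window: tuple[int, int]


@dataclass
class ValidityMask:
    """3D validity map with per-voxel reason codes for exclusions.

    ``reason`` is a bitmask of the ``REASON_*`` constants; a voxel is valid
    only when it passed every check on both echoes.
    """

    valid: np.ndarray
    reason: np.ndarray

    @classmethod
    def all_valid(cls, grid_shape) -> "ValidityMask":
        return cls(
            valid=np.ones(grid_shape, dtype=bool),
            reason=np.zeros(grid_shape, dtype=np.uint8),
        )

    def invalidate(self, where: np.ndarray, reason_bit: int) -> None:
        self.valid &= ~where
        self.reason[where] |= np.uint8(reason_bit)

    def copy(self) -> "ValidityMask":
        return ValidityMask(valid=self.valid.copy(), reason=self.reason.copy())

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def exclusion_counts(self) -> dict[str, int]:
        return {
            "insufficient_drop_gre": int((self.reason & REASON_DROP_GRE > 0).sum()),
            "insufficient_drop_se": int((self.reason & REASON_DROP_SE > 0).sum()),
            "nonpositive_signal": int((self.reason & REASON_NONPOSITIVE > 0).sum()),
            "nonpositive_peak_rate": int(
                (self.reason & REASON_NONPOSITIVE_PEAK_RATE > 0).sum()
            ),
            "negative_cbv_adc": int((self.reason & REASON_NEGATIVE_CBV_ADC > 0).sum()),
        }


def trim_initial(series: DualEchoSeries, n_discard: int = 4) -> DualEchoSeries:
    """Drop the first ``n_discard`` frames of both echoes (steady state).

    The injection index shifts by the same amount. Rejects a trim that would
    consume the whole series or reach past the injection.
    """
    if n_discard < 0:
        raise ValueError("n_discard must be >= 0")
    if n_discard >= series.n_frames:
        raise ValueError(
            f"cannot discard {n_discard} of {series.n_frames} frames"
        )
    if series.injection_index < n_discard:
        raise ValueError(
            "injection_index precedes the discarded frames; nothing of the "
            "baseline would remain"
        )
    if n_discard == 0:
        return replace(series)
    return DualEchoSeries(
        gre_signal=series.gre_signal[..., n_discard:],
        se_signal=series.se_signal[..., n_discard:],
        tr=series.tr,
        te_gre=series.te_gre,
        te_se=series.te_se,
        injection_index=series.injection_index - n_discard,
    )


def estimate_baseline(
    series: DualEchoSeries, min_frames: int = 5
) -> BaselineEstimate:
    """Per-voxel baseline mean and SD over the pre-bolus frames.

    The window is every frame strictly before the injection index.
    """
    n_base = series.injection_index
    if n_base < min_frames:
        raise ValueError(
            f"only {n_base} pre-bolus frames; need at least {min_frames}"
        )
    gre = series.gre_signal[..., :n_base]
    se = series.se_signal[..., :n_base]
    return BaselineEstimate(
        gre_mean=gre.mean(axis=-1),
        gre_sd=gre.std(axis=-1, ddof=1),
        se_mean=se.mean(axis=-1),
        se_sd=se.std(axis=-1, ddof=1),
        window=(0, n_base),
    )


def qc_filter(
    series: DualEchoSeries,
    baseline: BaselineEstimate,
    sd_threshold: float = 2.0,
) -> ValidityMask:
    """Exclude voxels without a clear bolus-induced signal drop.

    A voxel is kept only if, on BOTH echoes, the baseline mean minus the
    post-injection signal minimum is at least ``sd_threshold`` baseline
    standard deviations. Voxels with nonpositive signal anywhere in the
    series are excluded as well (the log-ratio conversion is undefined
    there). The filter is total and idempotent.
    """
    if baseline.gre_mean.shape != series.grid_shape:
        raise ValueError("baseline grid does not match the series grid")
    post = slice(series.injection_index, None)
    drop_gre = baseline.gre_mean - series.gre_signal[..., post].min(axis=-1)
    drop_se = baseline.se_mean - series.se_signal[..., post].min(axis=-1)

    mask = ValidityMask.all_valid(series.grid_shape)
    mask.invalidate(drop_gre < sd_threshold * baseline.gre_sd, REASON_DROP_GRE)
    mask.invalidate(drop_se < sd_threshold * baseline.se_sd, REASON_DROP_SE)
    nonpos = (series.gre_signal.min(axis=-1) <= 0) | (
        series.se_signal.min(axis=-1) <= 0
    )
    nonpos |= (baseline.gre_mean <= 0) | (baseline.se_mean <= 0)
    mask.invalidate(nonpos, REASON_NONPOSITIVE)
    return mask
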