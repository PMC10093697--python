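"""Digital phantom for dual-echo DSC-MRI and stained-slide morphometry.

The phantom synthesizes everything the downstream pipeline consumes, with
known ground truth per tissue class:

* paired 4D gradient-echo / spin-echo signal series generated by the exact
  exponential forward model ``S(t) = S(0) * exp(-TE * dR2(t))``, where the
  relaxation-rate change follows a unit-peak gamma-variate bolus scaled by
  the class blood-volume fraction;
* a 3D ADC map, disjoint tumor / normal-appearing-white-matter (NAWM) masks,
  and 3D truth volumes for CBV, microvascular CBV and vessel size;
* 2D stained-slide images of elliptical vessel profiles with exact
  per-object geometry for morphometry oracles.

Geometry is deliberately simple: tissue classes occupy rectangular slabs
along the first axis of a 15-slice grid, so masks and per-class statistics
are trivially verifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gamma as gamma_fn, gammainc
from skimage.draw import ellipse as draw_ellipse

__all__ = [
    "REFERENCE_NAWM_CBV",
    "TissueClassSpec",
    "BolusModel",
    "PhantomOutput",
    "SlideOutput",
    "gamma_variate",
    "gamma_variate_integral",
    "ucbv_for_vessel_size",
    "default_classes",
    "default_bolus",
    "simulate_dsc",
    "simulate_slide",
]

# Reference blood-volume fraction of normal-appearing white matter. The
# forward model expresses relaxation-rate amplitudes relative to this value,
# so a class with true_cbv_fraction == REFERENCE_NAWM_CBV peaks exactly at
# the bolus amplitude. 3.2% is the conventional white-matter CBV.
REFERENCE_NAWM_CBV = 0.032

KISELEV_CONSTANT = 0.867


@dataclass(frozen=True)
class TissueClassSpec:
    """Ground-truth parameters of one homogeneous tissue class.

    Parameters
    ----------
    label : str
        Class name, e.g. ``"NAWM"`` or ``"tumor-A"``. Labels starting with
        ``"tumor"`` are pooled into the tumor mask.
    true_cbv_fraction : float
        Blood volume fraction (unitless, in (0, 0.2]).
    true_ucbv_fraction : float
        Microvascular blood volume fraction; must not exceed the total.
    true_vessel_size : float
        Mean vessel size in micrometres.
    adc_value : float
        Apparent diffusion coefficient in um^2/s.
    baseline_signal : float
        Pre-bolus signal level in arbitrary units.
    """

    label: str
    true_cbv_fraction: float
    true_ucbv_fraction: float
    true_vessel_size: float
    adc_value: float
    baseline_signal: float = 1000.0

    def __post_init__(self) -> None:
        if not 0.0 < self.true_cbv_fraction <= 0.2:
            raise ValueError(
                f"{self.label}: true_cbv_fraction must be in (0, 0.2], "
                f"got {self.true_cbv_fraction}"
            )
        if not 0.0 < self.true_ucbv_fraction <= self.true_cbv_fraction:
            raise ValueError(
                f"{self.label}: true_ucbv_fraction must be in "
                f"(0, true_cbv_fraction]"
            )
        if self.true_vessel_size <= 0:
            raise ValueError(f"{self.label}: true_vessel_size must be > 0")
        if self.adc_value <= 0:
            raise ValueError(f"{self.label}: adc_value must be > 0")
        if self.baseline_signal <= 0:
            raise ValueError(f"{self.label}: baseline_signal must be > 0")


@dataclass(frozen=True)
class BolusModel:
    """Gamma-variate contrast bolus, normalized to unit peak.

    ``C(t) = ((t - ta) / (alpha * beta))**alpha * exp(alpha - (t - ta)/beta)``
    for ``t > ta`` (arrival), zero before; the peak value 1 is reached at
    ``ta + alpha * beta``. An optional recirculation term adds a delayed,
    scaled copy of the first passage.

    `amplitude` is the peak dR2* (in 1/s) produced in tissue whose blood
    volume fraction equals :data:`REFERENCE_NAWM_CBV`.
    """

    arrival_index: int = 20
    amplitude: float = 10.0
    shape_alpha: float = 3.0
    scale_beta: float = 2.0
    recirculation_fraction: float = 0.0
    recirculation_delay: float = 20.0

    def __post_init__(self) -> None:
        if self.arrival_index < 1:
            raise ValueError("arrival_index must leave at least one baseline frame")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.shape_alpha <= 0 or self.scale_beta <= 0:
            raise ValueError("shape_alpha and scale_beta must be > 0")
        if not 0.0 <= self.recirculation_fraction < 1.0:
            raise ValueError("recirculation_fraction must be in [0, 1)")

    def concentration(self, frames: np.ndarray) -> np.ndarray:
        """Unit-peak bolus curve sampled at (fractional) frame indices."""
        c = gamma_variate(frames, self.arrival_index, self.shape_alpha, self.scale_beta)
        if self.recirculation_fraction > 0:
            c = c + self.recirculation_fraction * gamma_variate(
                frames,
                self.arrival_index + self.recirculation_delay,
                self.shape_alpha,
                self.scale_beta,
            )
        return c


def gamma_variate(t, arrival, alpha, beta):
    """Unit-peak gamma-variate ``((t-ta)/(a*b))**a * exp(a - (t-ta)/b)``."""
    t = np.asarray(t, dtype=float)
    dt = t - arrival
    out = np.zeros_like(dt)
    pos = dt > 0
    s = dt[pos] / beta
    out[pos] = (s / alpha) ** alpha * np.exp(alpha - s)
    return out


def gamma_variate_integral(alpha, beta, s0=None, s1=None):
    """Closed-form integral of the unit-peak gamma-variate over time.

    With ``s = (t - ta)/beta``, the full integral is
    ``beta * exp(alpha) * Gamma(alpha + 1) / alpha**alpha``. If ``s0``/``s1``
    (in the same scaled coordinate) are given, the integral is truncated to
    that interval using the regularized lower incomplete gamma function.
    """
    total = beta * np.exp(alpha) * gamma_fn(alpha + 1.0) / alpha**alpha
    lo = 0.0 if s0 is None else gammainc(alpha + 1.0, max(s0, 0.0))
    hi = 1.0 if s1 is None else gammainc(alpha + 1.0, max(s1, 0.0))
    return total * (hi - lo)


def ucbv_for_vessel_size(
    cbv_fraction: float,
    vessel_size_um: float,
    adc_um2_s: float,
    amplitude: float = 10.0,
    nawm_cbv: float = REFERENCE_NAWM_CBV,
    target_percent: float = 3.2,
) -> float:
    """Microvascular fraction consistent with the Kiselev vessel-size model.

    Inverts ``VS = 0.867 * sqrt(CBV_scaled * ADC) * dR2*max / dR2max**1.5``
    under the phantom forward model (peak rates proportional to the blood
    volume fractions), so that a class built with the returned ucbv yields
    exactly ``vessel_size_um`` when pushed through the full pipeline on
    noiseless data. ``CBV_scaled`` accounts for the NAWM-median rescaling to
    ``target_percent``.
    """
    dr2s_max = amplitude * cbv_fraction / REFERENCE_NAWM_CBV
    cbv_scaled = (target_percent / 100.0) * cbv_fraction / nawm_cbv
    dr2_max = (
        KISELEV_CONSTANT * np.sqrt(cbv_scaled * adc_um2_s) * dr2s_max / vessel_size_um
    ) ** (2.0 / 3.0)
    return float(dr2_max * REFERENCE_NAWM_CBV / amplitude)


def default_classes(amplitude: float = 10.0) -> list[TissueClassSpec]:
    """Five-class study condition: NAWM, grey matter, three tumor classes.

    Tumor blood volumes are expressed relative to NAWM (ratios 1.43, 0.96,
    1.20) with distinct vessel sizes (12.5, 15.5, 10.3 um), emulating the
    contrast between glioma subtypes; the microvascular fractions are derived
    from the vessel-size relation so the forward model is self-consistent.
    """

    def make(label, cbv, vs, adc):
        return TissueClassSpec(
            label=label,
            true_cbv_fraction=cbv,
            true_ucbv_fraction=ucbv_for_vessel_size(cbv, vs, adc, amplitude=amplitude),
            true_vessel_size=vs,
            adc_value=adc,
        )

    nawm = REFERENCE_NAWM_CBV
    return [
        make("NAWM", nawm, 7.0, 800.0),
        make("GM", 0.055, 10.0, 900.0),
        make("tumor-A", 1.43 * nawm, 12.5, 1100.0),
        make("tumor-B", 0.96 * nawm, 15.5, 1200.0),
        make("tumor-C", 1.20 * nawm, 10.3, 1150.0),
    ]


def default_bolus() -> BolusModel:
    """Bolus arriving 20 frames into the acquisition (the study condition)."""
    return BolusModel()


@dataclass
class PhantomOutput:
    """Everything the phantom produced, on one shared voxel grid."""

    gre_series: np.ndarray
    se_series: np.ndarray
    adc_map: np.ndarray
    tumor_mask: np.ndarray
    nawm_mask: np.ndarray
    class_map: np.ndarray
    truth_maps: dict[str, np.ndarray]
    classes: list[TissueClassSpec]
    bolus: BolusModel
    tr: float
    te_gre: float
    te_se: float
    injection_index: int
    seed: int

    def truth_table(self) -> pd.DataFrame:
        """Per-class ground truth as a tidy table."""
        return pd.DataFrame(
            [
                {
                    "label": c.label,
                    "true_cbv_fraction": c.true_cbv_fraction,
                    "true_ucbv_fraction": c.true_ucbv_fraction,
                    "true_vessel_size_um": c.true_vessel_size,
                    "adc_um2_s": c.adc_value,
                    "baseline_signal": c.baseline_signal,
                }
                for c in self.classes
            ]
        )


def simulate_dsc(
    classes: list[TissueClassSpec],
    bolus: BolusModel,
    grid_shape: tuple[int, int, int] = (64, 64, 15),
    n_frames: int = 120,
    tr: float = 1.5,
    te_gre: float = 0.0186,
    te_se: float = 0.069,
    noise_sd: float = 0.0,
    seed: int = 0,
    noise_model: str = "gaussian",
) -> PhantomOutput:
    """Simulate a dual-echo DSC acquisition over a block phantom.

    Each tissue class occupies a slab along the first grid axis. Per voxel,

    ``dR2*(t) = amplitude * (cbv / 0.032) * C(t)`` and
    ``dR2(t)  = amplitude * (ucbv / 0.032) * C(t)``,

    with ``C(t)`` the unit-peak gamma-variate bolus, and signals follow the
    exact single-exponential decay for each echo time. Noise is additive
    Gaussian on the signal magnitude by default (``noise_model="rician"``
    applies the noise to quadrature channels instead).

    Deterministic for a fixed seed; with ``noise_sd == 0`` the relaxometry
    inverse recovers the injected rate curves exactly.
    """
    if not classes:
        raise ValueError("at least one tissue class is required")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if bolus.arrival_index >= n_frames:
        raise ValueError(
            f"bolus arrival_index {bolus.arrival_index} outside the "
            f"{n_frames}-frame time axis"
        )
    if noise_model not in ("gaussian", "rician"):
        raise ValueError("noise_model must be 'gaussian' or 'rician'")
    nx, ny, nz = grid_shape
    if nx < len(classes):
        raise ValueError("grid too small to hold all tissue classes")

    frames = np.arange(n_frames, dtype=float)
    conc = bolus.concentration(frames)  # (t,)

    class_map = np.zeros(grid_shape, dtype=np.int32)
    edges = np.linspace(0, nx, len(classes) + 1).astype(int)
    for i in range(len(classes)):
        class_map[edges[i] : edges[i + 1]] = i

    cbv = np.array([c.true_cbv_fraction for c in classes])
    ucbv = np.array([c.true_ucbv_fraction for c in classes])
    base = np.array([c.baseline_signal for c in classes])
    adc = np.array([c.adc_value for c in classes])
    vs = np.array([c.true_vessel_size for c in classes])

    # class-wise rate curves (class, t), then broadcast to voxels
    dr2s = bolus.amplitude * (cbv / REFERENCE_NAWM_CBV)[:, None] * conc[None, :]
    dr2 = bolus.amplitude * (ucbv / REFERENCE_NAWM_CBV)[:, None] * conc[None, :]
    sig_gre = base[:, None] * np.exp(-te_gre * dr2s)
    sig_se = base[:, None] * np.exp(-te_se * dr2)

    gre = sig_gre[class_map]  # (x, y, z, t)
    se = sig_se[class_map]

    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        if noise_model == "gaussian":
            gre = gre + rng.normal(0.0, noise_sd, gre.shape)
            se = se + rng.normal(0.0, noise_sd, se.shape)
        else:
            gre = np.hypot(
                gre + rng.normal(0.0, noise_sd, gre.shape),
                rng.normal(0.0, noise_sd, gre.shape),
            )
            se = np.hypot(
                se + rng.normal(0.0, noise_sd, se.shape),
                rng.normal(0.0, noise_sd, se.shape),
            )

    labels = [c.label for c in classes]
    tumor_idx = [i for i, lab in enumerate(labels) if lab.lower().startswith("tumor")]
    nawm_idx = [i for i, lab in enumerate(labels) if lab.upper() == "NAWM"]
    tumor_mask = np.isin(class_map, tumor_idx)
    nawm_mask = np.isin(class_map, nawm_idx)

    truth_maps = {
        "cbv": cbv[class_map],
        "ucbv": ucbv[class_map],
        "vessel_size": vs[class_map],
    }
    return PhantomOutput(
        gre_series=gre,
        se_series=se,
        adc_map=adc[class_map],
        tumor_mask=tumor_mask,
        nawm_mask=nawm_mask,
        class_map=class_map,
        truth_maps=truth_maps,
        classes=list(classes),
        bolus=bolus,
        tr=tr,
        te_gre=te_gre,
        te_se=te_se,
        injection_index=bolus.arrival_index,
        seed=seed,
    )


@dataclass
class SlideOutput:
    """Synthetic stained slide with exact per-object geometry."""

    stain_image: np.ndarray  # 2D float, stain intensity
    label_image: np.ndarray  # 2D int, true object labels
    truth: pd.DataFrame  # per-object analytic geometry
    seed: int = 0
    pixel_size: float = 1.0


def simulate_slide(
    vessels: list[tuple[tuple[float, float], tuple[float, float], float]],
    image_shape: tuple[int, int] = (512, 512),
    background: float = 40.0,
    vessel_intensity: float = 200.0,
    background_noise: float = 0.0,
    seed: int = 0,
    pixel_size: float = 1.0,
) -> SlideOutput:
    """Render non-overlapping elliptical vessel profiles on a slide.

    Each vessel is ``(center_rc, (semi_major, semi_minor), orientation_rad)``
    in pixel units. Returns the stain-intensity image, a labeled truth image,
    and a table with the analytic area ``pi*a*b``, the rasterized pixel area,
    and the axes as given — the oracle for segmentation and morphometry.

    Raises if any vessel leaves the image bounds or overlaps another.
    """
    rows, cols = image_shape
    label_image = np.zeros(image_shape, dtype=np.int32)
    records = []
    for k, (center, axes, theta) in enumerate(vessels, start=1):
        r0, c0 = center
        a, b = axes
        if a <= 0 or b <= 0:
            raise ValueError(f"vessel {k}: semi-axes must be positive")
        reach = max(a, b)
        if not (reach <= r0 <= rows - 1 - reach and reach <= c0 <= cols - 1 - reach):
            raise ValueError(f"vessel {k} does not fit inside the image bounds")
        rr, cc = draw_ellipse(r0, c0, a, b, shape=image_shape, rotation=theta)
        if np.any(label_image[rr, cc] != 0):
            raise ValueError(f"vessel {k} overlaps an earlier vessel")
        label_image[rr, cc] = k
        records.append(
            {
                "label": k,
                "center_row": r0,
                "center_col": c0,
                "semi_major_px": a,
                "semi_minor_px": b,
                "orientation_rad": theta,
                "area_true_px": np.pi * a * b,
                "area_raster_px": rr.size,
            }
        )
    rng = np.random.default_rng(seed)
    stain = np.full(image_shape, background, dtype=float)
    stain[label_image > 0] = vessel_intensity
    if background_noise > 0:
        stain = stain + rng.normal(0.0, background_noise, image_shape)
    truth = pd.DataFrame(
        records,
        columns=[
            "label",
            "center_row",
            "center_col",
            "semi_major_px",
            "semi_minor_px",
            "orientation_rad",
            "area_true_px",
            "area_raster_px",
        ],
    )
    return SlideOutput(
        stain_image=stain,
        label_image=label_image,
        truth=truth,
        seed=seed,
        pixel_size=pixel_size,
    )
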