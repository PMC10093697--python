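# vsimri

Vessel size imaging (VSI) from dual-echo dynamic susceptibility contrast
(DSC) MRI, for researchers studying tumor microvasculature — in particular
the perfusion contrast between adult-type diffuse glioma subtypes. The
package turns paired gradient-echo (GRE) / spin-echo (SE) bolus-passage
time series into quantitative maps of cerebral blood volume (CBV),
microvascular CBV (µCBV) and mean vessel size, summarizes them over a tumor
ROI, quantifies vessel morphometry on stained histology slides, and compares
parameters across three groups with a normality-gated decision tree. A
digital phantom with known ground truth makes every stage testable without
any patient data.

## Model

Per voxel, the two echoes are converted to transverse relaxation-rate
changes using the pre-bolus baseline signal S(0):

    ΔR2*(t) = −(1/TE_GRE) · ln(S_GRE(t) / S_GRE(0))
    ΔR2(t)  = −(1/TE_SE)  · ln(S_SE(t)  / S_SE(0))

Raw CBV and µCBV are trapezoidal integrals of ΔR2*(t) and ΔR2(t) over the
bolus window [t0, t1] (detected on the mask-averaged ΔR2* curve at 10% of
peak). Both are normalized to the mean over contralateral normal-appearing
white matter (NAWM); the CBV entering the vessel-size model is instead
rescaled so its NAWM median equals 3.2% blood volume. Mean vessel size
follows the Kiselev model,

    VS = 0.867 · (CBV · ADC)^(1/2) · ΔR2*max / (ΔR2max)^(3/2)

with CBV as a unitless fraction, the apparent diffusion coefficient ADC in
µm²/s and the window-restricted peak rates in s⁻¹, giving micrometres.
Voxels whose bolus-induced signal drop is under 2 baseline standard
deviations on either echo are excluded throughout. Histology morphometry
reports vessel density (% stained area), equivalent radius √(area/π), and
roundness perimeter²/(4π·area) (1 = circle). Group comparison: Shapiro–Wilk
per group, then one-way ANOVA + Tukey HSD if all groups look normal,
otherwise Kruskal–Wallis + Dunn–Bonferroni.

## Worked example

```python
import vsimri as v

phantom = v.simulate_dsc(
    v.default_classes(), v.default_bolus(),
    grid_shape=(40, 40, 6), noise_sd=20.0, seed=1,
)
results = v.VesselSizeModel.from_phantom(phantom).fit()
print(results.summary())
```

```
Vessel size imaging fit
=======================
grid: (40, 40, 6), frames after trim: 116
bolus window: frames [18, 32] (15 frames x TR 1.5 s)
valid voxels: 9600 / 9600
exclusions: 

Tumor ROI summaries (CBV/uCBV NAWM-relative, vessel size in um):
  parameter   mean  median  hotspot  n_valid_voxels  n_clusters
        cbv  1.195   1.198    1.514            5760           3
       ucbv  0.926   1.023    1.158            5760          64
vessel_size 12.294  11.934   17.855            5760          36
```

The phantom's three tumor classes are programmed with NAWM-relative CBV
ratios 1.43, 0.96 and 1.20 and vessel sizes 12.5, 15.5 and 10.3 µm; the
tumor-ROI mean CBV of 1.195 and mean vessel size of 12.29 µm recover the
across-class averages (1.197 and 12.77 µm) at SNR 50, with the hot-spot
column pooling voxels at or above the within-tumor 90th percentile. At zero
noise the recovery is exact to six digits.

There is also a CLI: `vsimri phantom dsc`, `vsimri maps`, `vsimri histo`,
`vsimri stats`, `vsimri all` (see `vsimri --help`).

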