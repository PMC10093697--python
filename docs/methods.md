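# Methods

## Pipeline

One subject's inputs are a paired 4D GRE/SE DSC acquisition (TR 1.5 s,
TE(GRE)/TE(SE) = 18.6/69 ms, 120 time points, contrast arriving 20 frames
in), a co-registered 3D ADC map, and binary tumor and contralateral-NAWM
masks. `VesselSizeModel.fit()` runs, in order:

1. **Trim** — the first 4 frames are discarded (signal not yet at steady
   state); the injection index shifts accordingly.
2. **Baseline** — per-voxel, per-echo mean and SD over all frames strictly
   before the injection index (sample SD, n−1 divisor).
3. **Quality filter** — a voxel is kept only if, on both echoes, the
   baseline mean minus the post-injection signal minimum is at least
   2 baseline SDs; voxels with nonpositive signal are excluded because the
   log-ratio is undefined. Exclusions carry per-voxel reason codes
   (bitmask) and propagate as NaN, never as zero, so they drop out of every
   ROI statistic.
4. **Relaxometry** — exact inversion of the single-exponential signal
   model; no clamping of negative rates.
5. **Bolus window** — the tumor+NAWM-averaged ΔR2* curve is thresholded at
   10% of its global peak; the window is the contiguous supra-threshold run
   around the peak, shared by all voxels. A flat or nonpositive mean curve
   is an error.
6. **Integration and peaks** — trapezoidal rule with spacing TR over
   [t0, t1], inclusive; negative excursions are integrated as-is. Peak
   rates are window-restricted maxima.
7. **Maps** — CBV and µCBV normalized by the valid-NAWM mean (NAWM mean
   = 1); a second CBV copy rescaled so the valid-NAWM *median* equals 3.2%
   blood volume; vessel size from the Kiselev formula with that CBV as a
   fraction, ADC in µm²/s and rates in s⁻¹. This unit convention is the
   only one that yields micrometres on dimensional grounds, consistent with
   vessel-size color scales of 0–100 µm. No contrast-leakage correction is
   applied anywhere.

Tumor summaries are mean, median and hot spot over valid voxels; the hot
spot averages all voxels at or above the 90th percentile (linear
interpolation between order statistics, inclusive threshold), pooled over
all 26-connected clusters; the cluster count is reported but does not
affect the value.

## Digital phantom

The phantom is the package's study condition, not a tunable benchmark. Five
rectangular tissue slabs (NAWM, grey matter, three tumor classes) fill a
64×64×15 grid — matching partial-brain coverage with 15 slices — with 120
time points at TR 1.5 s. The bolus is a unit-peak gamma-variate
C(t) = ((t−ta)/(αβ))^α·exp(α−(t−ta)/β) with α = 3, β = 2 frames, arriving
at frame 20; an optional recirculation term adds a delayed scaled copy
(off by default). Rates scale with the blood-volume fractions relative to
the conventional 3.2% NAWM reference:

    ΔR2*(t) = A · (CBV_true / 0.032) · C(t),   A = 10 s⁻¹
    ΔR2(t)  = A · (µCBV_true / 0.032) · C(t)

and signals follow S(t) = S₀·exp(−TE·ΔR2(t)), S₀ = 1000 a.u. The default
tumor classes carry NAWM-relative CBV ratios 1.43/0.96/1.20 and vessel
sizes 12.5/15.5/10.3 µm, emulating the reported ordering among glioma
subtypes; each class's µCBV is derived by inverting the Kiselev relation
(`ucbv_for_vessel_size`), which makes the forward model self-consistent:
the full pipeline recovers the programmed vessel sizes exactly on noiseless
data, so recovery tests check the pipeline, not a coincidence of constants.
The proportionality constants linking blood volume to relaxation rates are
conventions chosen here; no acquisition-derived values exist for them.

Noise is additive Gaussian on signal magnitude (default SD 20, i.e. SNR 50
at baseline), keeping the log-ratio inversion unbiased to first order at
high SNR; a Rician option exists. What the phantom does *not* emulate:
anatomy, partial-volume mixing, motion, B0 inhomogeneity, bolus dispersion
or delay differences between tissues, and contrast leakage. Passing
recovery tests therefore demonstrates correctness of the numerics and the
estimation chain, not robustness to those real-data effects.

Slide phantoms rasterize non-overlapping rotated ellipses (high stain
intensity on a noisy background) and record each object's analytic area
πab and exact rasterized pixel count, which is the oracle for segmentation
and morphometry.

## Numerical choices

- **Baseline window** is every trimmed frame before the known injection
  index; no bolus-arrival estimation is attempted on the baseline side.
- **QC "drop"** is baseline mean minus the post-injection raw-signal
  minimum. Note the rule's limited power against pure noise: with ~100
  post-injection frames the expected noise minimum sits ≈2.5 SD below the
  mean, so a bolus-free noisy voxel is excluded only ~10% of the time. The
  filter is a guard against *erroneous* (weak-drop, nonpositive) voxels,
  not a bolus detector.
- **Window threshold** at 10% of peak captures ≈94–96% of the
  gamma-variate's mass — the supra-threshold crossings of any unimodal
  curve leave a few percent in the tails (3.2% in the Gaussian limit).
  This truncation cancels exactly in NAWM-normalized ratios, which is why
  CBV/µCBV ratio recovery is window-independent; tests that check the
  integral against the closed form use the truncated (regularized
  incomplete gamma) expression over the detected window.
- **Percentile convention** is linear interpolation between order
  statistics, threshold inclusive (≥), so top-decile examples are
  reproducible bit-exactly.
- **Perimeter estimation** uses the Crofton line-intercept formula
  (4 directions). On a rasterized disk of radius 50 px it yields roundness
  0.991 and, for a 2:1 ellipse, 1.178 against the Ramanujan-perimeter value
  1.189 — both within the 0.02 discretization tolerance this package
  quotes for objects ≥40 px across. Weighted boundary-step counting was
  rejected: it overestimates a disk's perimeter enough to bias roundness
  to ≈1.08.
- **Segmentation** is Otsu thresholding, a 1-px opening, hole filling and
  connected components with a minimum-area filter — deliberately simple and
  fully documented, sufficient for well-separated stained profiles; it is
  not a nuclei-vs-vessel classifier and will count any stained object.
- **Statistics** — the normality gate requires *all* groups to pass
  Shapiro–Wilk at α = 0.05 (the conservative reading); a constant-valued
  group routes the parameter to the Kruskal–Wallis branch with a note.
  Dunn's z uses the tie-corrected rank variance and Bonferroni multiplies
  by the number of pairs (3), capped at 1. No correction is applied across
  parameters. The null type-I error of the full decision tree is calibrated
  at 0.05 ± 0.02 in the test suite (1000 seeded replicates of 3×12
  Gaussians).
- **ADC units** must be declared by the caller (`um2/s` or `mm2/s`);
  scanner-exported maps do not state them reliably. Slice gaps are ignored
  for volume statistics.

## Problem sizes in the test suite

Recovery tests run on a 25×20×4 noiseless phantom (exact recovery) and a
40×40×6 phantom at SNR 50; one end-to-end check uses the full 64×64×15×120
grid. Study-level tests use 3 subjects per subtype on 20×16×3 grids —
enough for every statistic to be well-defined while keeping the default
suite around a minute.

## Known limitations

- The bolus window is global (one window for all voxels); per-voxel
  windows would track delay/dispersion but are not needed for the phantom
  and were not part of the estimation design.
- Vessel-size recovery is exact only for forward models consistent with
  the Kiselev relation; for arbitrary (CBV, µCBV, VS) triples the class
  *ranking* is still preserved, which is what the recovery test asserts in
  general.
- Group statistics on phantom-derived cohorts exercise the machinery; they
  say nothing about effect sizes in patients.
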