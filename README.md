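# adchist

Fast quantification of age-dependent brain volume loss from routine
diffusion-weighted MRI, via apparent-diffusion-coefficient (ADC) histograms.

Brain atrophy — loss of brain tissue with a matching enlargement of the
cerebrospinal-fluid (CSF) spaces — is part of normal aging, and deciding
whether an individual brain is "atrophic for its age" normally requires
high-resolution 3-D T1 imaging plus segmentation. A standard clinical DWI
acquisition already contains the needed contrast: CSF has a much higher ADC
(~3 × 10⁻³ mm²/s) than brain tissue (~0.75 × 10⁻³ mm²/s), so the whole-head
ADC histogram splits into a tissue peak and a CSF tail. `adchist` turns a
b0/diffusion-weighted volume pair into a single per-subject statistic — the
**brain-tissue pixel percentage** — and fits its decline across a cohort
with a quadratic normative aging trajectory.

## Method

For each subject with volumes *S*₀ (b = 0) and *S*ᵈʷ (b = 1000 s/mm²):

1. **Self-scaling.** The mode of the smoothed dw-intensity histogram is
   mapped to 250; both volumes are multiplied by the same factor
   (clinical exports are arbitrarily scaled).
2. **Masking.** Noise and skull voxels are excluded with a combined
   threshold (default: b0 > 50 and dw > 1 in scaled units). The mask count
   *N* normalizes everything downstream, compensating for head size.
3. **ADC histogram.** ADC = ln(*S*₀/*S*ᵈʷ)/b per masked voxel, binned on
   [0, 4 × 10⁻³] mm²/s (bin width 0.02 × 10⁻³) in percent of *N*.
4. **Characteristic value.** On the cohort-average histogram, the tissue
   peak's left 1%-of-maximum point (the *basis*) is mirrored about the
   peak: a_char = peak + (peak − basis). This single partition point
   (≈ 1.15 × 10⁻³ mm²/s) separates tissue-dominated from CSF-dominated
   voxels.
5. **Brain fraction.** y = percent of masked voxels with ADC ≤ a_char.
6. **Cohort statistics.** Age-group means and adjacent-group pooled-variance
   t-tests (Bonferroni-corrected), and an OLS quadratic fit
   y = c₀ + c₁x + c₂x² with slope c₁ + 2c₂x evaluated at chosen ages.

No clinical data ship with the package. The `phantom` module generates
synthetic head volumes (ellipsoidal head, ventricle + sulcal CSF,
partial-volume shell, Rician noise, arbitrary per-subject global scaling)
with known ground-truth tissue share following a configurable age
trajectory, so the whole pipeline is testable end to end.

## Worked example

Simulate an 8-subject phantom cohort (fast mode: flat voxel arrays instead
of full 224 × 224 × 30 volumes), run the pipeline, and fit the trajectory:

```sh
adchist simulate --n 8 --seed 11 --fast --out-dir demo/sim
adchist cohort --manifest demo/sim/manifest.csv --out-dir demo/out
adchist fit --results demo/out/results.csv --stratum all --slopes 20,50,80
```

which prints

```json
{
  "c0": 83.72032893285133,
  "c1": -0.06781912118565682,
  "c2": -0.003070955361565817,
  "n": 8,
  "rmse": 0.8475940845774335,
  "slopes": {
    "20.0": -0.19065733564828952,
    "50.0": -0.3749146573422385,
    "80.0": -0.5591719790361875
  },
  "stratum": "all"
}
```

The generator's trajectory was 83.5 − 0.068x − 0.0027x²; even with 8 noisy
subjects the fit recovers the intercept (83.7%) and an accelerating decline
(≈ −0.19 %/year at age 20 steepening to ≈ −0.56 %/year at 80).
`demo/out/characteristic.json` records the derived partition point — tissue
peak at 0.75 × 10⁻³ mm²/s, left basis 0.33 × 10⁻³, characteristic value
1.17 × 10⁻³ mm²/s — and `adchist report --results-dir demo/out` renders the
average histogram and the age-trajectory scatter as PNGs.

The same analysis runs on real data: point the manifest CSV
(`subject_id, age, sex, b0_path, dw_path, ...`) at NIfTI volume pairs
(two 3-D files, or one 4-D file with frame 0 = b0, frame 1 = dw).

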