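# Methods

## The statistic

The pipeline reduces a subject's b0/dw volume pair to one number: the
percentage of suprathreshold voxels whose ADC lies at or below a
characteristic partition value. Because CSF ADC (~3.1 × 10⁻³ mm²/s) is
roughly four times the brain-tissue ADC (~0.75 × 10⁻³ mm²/s), that
percentage tracks the tissue/CSF volume balance without any segmentation,
registration or atlas normalization — the only spatial operation is voxel
counting, and head-size differences cancel because the count is normalized
to the subject's own masked-voxel total. The statistic deliberately
excludes partial-volume voxels from the "brain" side (their mixed ADC falls
above the partition), so it is not a literal tissue-volume fraction; it is
a monotone surrogate whose *age trend* is the quantity of interest.

## Self-scaling and masking

MR intensities have no absolute units, so each subject is first
self-calibrated: the mode of the dw-intensity histogram (dominated by brain
tissue, the most common compartment) is mapped to 250. The mode is found on
a 256-bin histogram over (floor, max], floor = 0.05 × the 99th-percentile
intensity — the floor removes the background-noise spike near zero — with a
centered 5-bin moving average (shrunk at the edges) for stability, ties
resolved toward the lowest bin. Masking then uses fixed thresholds *in
scaled units*: a voxel is kept iff b0 > 50 and dw > 1. The b0 gate removes
background and skull (everything inside the head, including CSF, is bright
in b0); the dw floor only guarantees the logarithm is defined. `or` and
`sum` combiners are available as config options. The original thresholds
behind the clinical analysis are not recoverable, so these defaults are
validated by self-consistency: on noise-free phantoms the mask reproduces
the in-head label set exactly, and the final statistic changes by
< 0.1 percentage points when both raw volumes are multiplied by any factor
in [0.1, 10].

One reading ambiguity is resolved here deliberately: the scaling rule is
described in the source material both as using a "median" and as the
"maximum of the smoothed histogram". We implement the histogram mode (that
is what a smoothed-histogram maximum estimates) and orient the quotient as
250/mode, the only direction that actually normalizes.

## ADC histogram

ADC = ln(b0/dw)/b per masked voxel. Noise can push dw above b0 in dark
voxels; those ADCs are clamped to 0 rather than discarded so the voxel
count stays equal to the mask count (the normalization denominator).
Histograms use uniform bins of width 0.02 × 10⁻³ mm²/s on
[0, 4 × 10⁻³] — fine enough to resolve the basis search (~20 bins between
basis and peak), coarse enough for stable per-bin counts at ~10⁵–10⁶
voxels per subject. Bins are half-open [lo, hi); mass at or above the last
edge is kept in a separate overflow term that stays in the denominator
(those are real high-ADC voxels, all on the CSF side of any partition).
Per-bin percent + overflow = 100 is enforced at construction to 10⁻⁹. The
cohort-average histogram is the unweighted per-bin mean of the subjects'
percent histograms: each subject is already normalized to its own head
size, so equal weighting is the consistent choice.

## Characteristic value

The tissue peak is the argmax of the lightly smoothed (3-bin moving
average) average histogram inside a search window of
[0.3, 1.2] × 10⁻³ mm²/s; the window excludes both the zero-clamp spike and
the CSF tail, and ties break toward lower ADC. Scanning left from the peak,
the basis is the center of the first bin whose smoothed value drops to
≤ 1% of the (smoothed) peak height; mirroring gives
a_char = 2·peak − basis, an identity that holds exactly by construction.
Peak and basis use bin centers without sub-bin interpolation — binning
dominates the uncertainty anyway — and smoothing is applied only for
peak/basis *detection*; all mass sums use the raw histogram. The
characteristic value is computed once from the cohort average and applied
to every subject; a per-subject mode
(`characteristic.per_subject`) exists for sensitivity analysis. For a
Gaussian tissue peak the 1% point sits at μ − σ√(−2 ln 0.01) ≈ μ − 3.03σ,
so with tissue ADC N(0.75, 0.13) × 10⁻³ the basis lands near
0.35 × 10⁻³ and a_char near 1.15 × 10⁻³ mm²/s.

## Cohort statistics

Age classes are [0, 20), [20, 40), [40, 60), [60, 90] years (the boundary
convention — half-open, last closed — is our choice; ages are decimal).
Adjacent classes are compared with two-sided pooled-variance two-sample
t-tests, Bonferroni-corrected for the family of 3 comparisons. Trajectory
fits are ordinary least squares on y = c₀ + c₁x + c₂x² (numpy polynomial
fit; verified in tests against the closed-form normal-equations solution to
10⁻⁹ relative error), overall and per sex; slopes are c₁ + 2c₂x.

## The phantom generator

The generator emulates the study conditions, not anatomy. A subject is an
axis-aligned ellipsoid (semi-axes 0.42/0.45/0.47 of the grid) in a
224 × 224 × 30 grid of 1.03 × 1.03 × 4.8 mm voxels. In-head voxels are
ranked by a CSF-affinity score that is large near the center (a ventricle
blob, normalized radius < 0.35) and near the surface (a sulcal rim,
radius > 0.8); exactly enough top-ranked voxels are labelled CSF that the
pure-tissue share equals the subject's true brain fraction (to within half
a voxel). CSF voxels within `partial_volume_shell` (default 1) dilation
steps of tissue become the partial-volume shell with linear mixing weights
w = d/(shell+1) — interior points of the tissue→CSF ramp, so with the
default shell the mixed ADC (≈ 1.9 × 10⁻³) lies clearly on the CSF side of
a_char and the measured brain fraction stays within 1 percentage point of
the generated tissue share.

Signals: b0 = 300 (tissue) / 900 (CSF, "bright") arbitrary units, mixed
linearly in the shell; dw = b0·exp(−b·ADC) with per-voxel ADC ~
N(compartment mean, sd) truncated at 0 (tissue sd 0.13 × 10⁻³ mm²/s, CSF
sd 0.25 × 10⁻³); Rician noise (magnitude of a complex Gaussian,
σ = 2.5 units, i.e. b0-SNR ≈ 120) added to both volumes *before* the
per-subject global intensity scale. The CSF ADC mean (3.1 × 10⁻³ mm²/s, the
free-water literature value) and the noise level are free parameters of the
simulation — the clinical description pins neither — chosen so that the
background spike stays below the 5%-of-p99 histogram floor used by the
mode estimator. Cohort sampling draws ages uniformly, sexes
Bernoulli(1/2), per-subject fractions from the trajectory plus
N(0, subject_sd) clipped to [1, 99]%, and global scales uniform on
[0.2, 5]; everything is deterministic given the seed (per-subject seeds are
spawned from the cohort seed, and identical (subject, config) inputs yield
bit-identical volumes). Both sexes share one trajectory unless two are
supplied: the sex difference in decline is an empirical finding, not a
generative law we should bake in.

`fast` mode skips the geometry and emits the same compartment mixture as a
flat array (default 60 000 voxels: 60% in-head, 15% of the CSF budget in
the shell, 40% background), reshaped to a thin 3-D grid so the files remain
valid NIfTI. It exercises every numerical step of the pipeline at ~25× less
cost; what it does not test is the spatial dilation logic, which the
geometric mode's tests cover.

### What the phantoms do not emulate

Gray/white-matter distinction (the real tissue peak is a two-tissue
overlap), EPI distortion and motion, spatially varying coil sensitivity,
skull/fat signal (our background is dark), and pathology. Passing tests
therefore demonstrate the *estimator's* correctness and invariances, not
clinical accuracy of the thresholds on real scanners.

## Problem sizes in the tests

The default suite and the acceptance script use fast-mode cohorts of 60
subjects × 60 000 voxels for recovery experiments, and reduced geometric
grids (96 × 96 × 20 and smaller) where the spatial generator itself is
under test; the physics and all thresholds are identical to the full-size
defaults. With 60 subjects and 1.5% scatter the standard error of the
recovered slope at age 50 is ≈ 0.01 %/year, comfortably inside the ±0.05
acceptance band.

## Known limitations

- The characteristic value is quantized to the bin grid (0.02 × 10⁻³);
  cohorts whose average histogram is noisy near the 1% level can shift the
  basis by a bin, moving a_char by 0.04 × 10⁻³.
- The brain fraction saturates near 100% for very low CSF content; the
  quadratic trajectory is only meaningful where the cohort spans enough
  atrophy range.
- Group comparisons require ≥ 2 subjects in all four age classes; the
  cohort report omits them (with a None) otherwise, while the low-level
  function raises.
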