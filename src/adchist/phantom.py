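"""Synthetic DWI head phantoms with known brain/CSF composition.

Every downstream stage of the pipeline is exercised against phantoms whose
tissue share, compartment ADC distributions, intensity scaling and noise are
all known exactly.  A phantom subject is an ellipsoidal "head" inside a
224 × 224 × 30 grid, partitioned into pure brain tissue, pure CSF (a central
ventricle blob plus a peripheral sulcal rim) and a thin partial-volume shell
with linear mixing weights.  Signals follow the two-point DWI relation
``dw = b0 · exp(−b · ADC)`` with per-voxel ADC drawn from the compartment's
Gaussian (truncated at 0), Rician noise added to both magnitude volumes, and
an arbitrary per-subject global intensity scale applied last — the feature
the self-scaling preprocessing step exists to undo.

A ``fast`` mode emits flat voxel-value arrays (no spatial geometry) with the
same compartment mixture, for quick cohort-scale tests.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import VolumePair

# fast-mode composition: share of voxels inside the head, and the share of
# the CSF budget placed in the partial-volume shell
FAST_HEAD_SHARE = 0.6
FAST_PV_FRACTION = 0.15

# normalized-radius geometry of the CSF compartments
_VENTRICLE_RADIUS = 0.35
_SULCAL_RADIUS = 0.80
_SEMIAXES_FRACTION = (0.42, 0.45, 0.47)


@dataclass(frozen=True)
class PhantomConfig:
    """Acquisition-and-anatomy parameters of the synthetic head.

    Defaults emulate a 224 × 224 axial matrix (230 mm FOV), 30 slices of
    4 mm with a 0.8 mm gap, and b-values 0/1000 s/mm².  Tissue ADC is
    N(0.75 × 10⁻³, 0.13 × 10⁻³) mm²/s; CSF ADC centers on the free-water
    value 3.1 × 10⁻³ mm²/s.  CSF is much brighter than tissue in b0
    (T2-like contrast), and both must dominate the Rician noise floor.
    """

    grid_shape: tuple[int, int, int] = (224, 224, 30)
    voxel_size: tuple[float, float, float] = (230 / 224, 230 / 224, 4.8)
    b_value: float = 1000.0
    tissue_adc_mean: float = 0.75e-3
    tissue_adc_sd: float = 0.13e-3
    csf_adc_mean: float = 3.1e-3
    csf_adc_sd: float = 0.25e-3
    s0_tissue: float = 300.0
    s0_csf: float = 900.0
    noise_sigma: float = 2.5
    partial_volume_shell: int = 1
    fast_n_voxels: int = 60_000

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(
            not isinstance(n, numbers.Integral) or n <= 0 for n in self.grid_shape
        ):
            raise ValueError("grid_shape must be three positive integers")
        if min(self.tissue_adc_mean, self.tissue_adc_sd,
               self.csf_adc_mean, self.csf_adc_sd) <= 0:
            raise ValueError("all ADC parameters must be strictly positive")
        if self.csf_adc_mean <= self.tissue_adc_mean:
            raise ValueError("csf_adc_mean must exceed tissue_adc_mean")
        if not (self.s0_csf > self.s0_tissue > self.noise_sigma):
            raise ValueError("require s0_csf > s0_tissue > noise_sigma")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.b_value <= 0:
            raise ValueError("b_value must be positive")
        if self.partial_volume_shell < 0:
            raise ValueError("partial_volume_shell must be >= 0")
        if self.fast_n_voxels < 1000 or self.fast_n_voxels % 100:
            raise ValueError(
                "fast_n_voxels must be a multiple of 100 and >= 1000"
            )


@dataclass(frozen=True)
class AgeTrajectory:
    """Quadratic brain-fraction-versus-age law used on the generating side.

    ``c0`` percent, ``c1`` percent/year, ``c2`` percent/year²;
    ``subject_sd`` is the between-subject scatter in percent.  The curve must
    stay inside (0, 100) over the supported age range 0–90 years.
    """

    c0: float
    c1: float = 0.0
    c2: float = 0.0
    subject_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be non-negative")
        ages = np.linspace(0.0, 90.0, 181)
        y = self(ages)
        if np.any(y <= 0) or np.any(y >= 100):
            raise ValueError(
                "trajectory leaves (0, 100) percent over ages 0-90"
            )

    def __call__(self, age):
        age = np.asarray(age, dtype=float)
        out = self.c0 + self.c1 * age + self.c2 * age * age
        return float(out) if out.ndim == 0 else out


def true_fraction(trajectory: AgeTrajectory, age: float) -> float:
    """Noise-free trajectory value c0 + c1·age + c2·age² at one age."""
    if age < 0:
        raise ValueError("age must be non-negative")
    return float(trajectory(age))


@dataclass
class SubjectGroundTruth:
    subject_id: str
    age: float
    sex: str
    true_brain_fraction: float
    global_scale: float = 1.0
    seed: int = 0
    b0_path: str | None = None
    dw_path: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.true_brain_fraction < 100:
            raise ValueError("true_brain_fraction must be in (0, 100)")
        if not 0 <= self.age <= 90:
            raise ValueError("age must be in [0, 90]")
        if self.global_scale <= 0:
            raise ValueError("global_scale must be positive")
        if self.sex not in ("female", "male"):
            raise ValueError("sex must be 'female' or 'male'")


_MANIFEST_COLUMNS = [
    "subject_id", "age", "sex", "b0_path", "dw_path",
    "true_brain_fraction", "global_scale", "seed",
]


@dataclass
class CohortManifest:
    """Ordered subject list with ground truth and (optional) file paths."""

    subjects: list[SubjectGroundTruth]

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject_ids must be unique")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subject_id": s.subject_id,
                    "age": s.age,
                    "sex": s.sex,
                    "b0_path": s.b0_path or "",
                    "dw_path": s.dw_path or "",
                    "true_brain_fraction": s.true_brain_fraction,
                    "global_scale": s.global_scale,
                    "seed": s.seed,
                }
                for s in self.subjects
            ],
            columns=_MANIFEST_COLUMNS,
        )

    def to_csv(self, path: str | Path) -> None:
        # %.17g keeps float64 columns exactly round-trippable
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortManifest":
        df = pd.read_csv(path, dtype={"subject_id": str},
                         float_precision="round_trip")
        missing = set(_MANIFEST_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        subjects = [
            SubjectGroundTruth(
                subject_id=row.subject_id,
                age=float(row.age),
                sex=str(row.sex),
                true_brain_fraction=float(row.true_brain_fraction),
                global_scale=float(row.global_scale),
                seed=int(row.seed),
                b0_path=str(row.b0_path) or None,
                dw_path=str(row.dw_path) or None,
            )
            for row in df.itertuples(index=False)
        ]
        return cls(subjects)


def sample_cohort(
    n: int,
    age_range: tuple[float, float],
    trajectory: AgeTrajectory,
    seed: int,
    scale_range: tuple[float, float] = (0.2, 5.0),
) -> CohortManifest:
    """Draw a synthetic cohort of ``n`` subjects.

    Ages are uniform over ``age_range``, sexes Bernoulli(1/2), and each
    subject's true brain fraction is the trajectory value at their age plus
    N(0, subject_sd) scatter, clipped to [1, 99] percent.  Per-subject
    global intensity scales are uniform over ``scale_range`` — mimicking the
    inconsistent export scaling of clinical data.  Fully deterministic given
    ``seed``.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    lo, hi = age_range
    if not (0 <= lo < hi <= 90):
        raise ValueError("age_range must be a non-empty interval within [0, 90]")
    if not (0 < scale_range[0] <= scale_range[1]):
        raise ValueError("scale_range must be positive and ordered")
    rng = np.random.default_rng(seed)
    ages = rng.uniform(lo, hi, n)
    sexes = np.where(rng.random(n) < 0.5, "female", "male")
    fractions = np.clip(
        trajectory(ages) + rng.normal(0.0, trajectory.subject_sd, n),
        1.0, 99.0,
    )
    scales = rng.uniform(scale_range[0], scale_range[1], n)
    seeds = rng.integers(0, 2**31 - 1, n)
    width = max(4, len(str(n)))
    subjects = [
        SubjectGroundTruth(
            subject_id=f"sub-{i + 1:0{width}d}",
            age=float(ages[i]),
            sex=str(sexes[i]),
            true_brain_fraction=float(fractions[i]),
            global_scale=float(scales[i]),
            seed=int(seeds[i]),
        )
        for i in range(n)
    ]
    return CohortManifest(subjects)


def _pv_weights(shell: int) -> np.ndarray:
    """Interior CSF-mixing weights of the linear partial-volume ramp."""
    return np.arange(1, shell + 1, dtype=float) / (shell + 1)


def _label_field_geometric(subject: SubjectGroundTruth, config: PhantomConfig):
    """Compartment labels on the full 3-D grid.

    The head is an axis-aligned ellipsoid.  CSF voxels are the in-head
    voxels with the highest "CSF affinity" — large near the center
    (ventricle) and near the head boundary (sulcal rim) — taken in exact
    number so the pure-tissue share equals the requested fraction.  CSF
    voxels within ``partial_volume_shell`` dilation steps of tissue become
    the partial-volume shell with linear mixing weights.
    """
    nx, ny, nz = config.grid_shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    ax, ay, az = (f * n for f, n in zip(_SEMIAXES_FRACTION, config.grid_shape))
    u = (ii - (nx - 1) / 2) / ax
    v = (jj - (ny - 1) / 2) / ay
    w = (kk - (nz - 1) / 2) / az
    r = np.sqrt(u * u + v * v + w * w)
    head = r <= 1.0
    n_head = int(np.count_nonzero(head))

    n_tissue = int(round(subject.true_brain_fraction / 100.0 * n_head))
    n_csf = n_head - n_tissue
    if n_tissue < 1 or n_csf < 0:
        raise ValueError("brain fraction infeasible for this geometry")

    r_head = r[head]
    ventricle_score = 1.0 - r_head / _VENTRICLE_RADIUS
    sulcal_score = (r_head - _SULCAL_RADIUS) / (1.0 - _SULCAL_RADIUS)
    score = np.maximum(ventricle_score, sulcal_score)
    order = np.argsort(-score, kind="stable")  # ties -> lowest flat index

    head_flat = np.flatnonzero(head.ravel())
    csf_mask = np.zeros(head.size, dtype=bool)
    csf_mask[head_flat[order[:n_csf]]] = True
    csf_mask = csf_mask.reshape(head.shape)
    tissue_mask = head & ~csf_mask

    csf_weight = np.zeros(head.shape)
    csf_weight[csf_mask] = 1.0
    pv_mask = np.zeros(head.shape, dtype=bool)
    shell = config.partial_volume_shell
    if shell > 0 and n_csf > 0:
        struct = ndimage.generate_binary_structure(3, 1)
        weights = _pv_weights(shell)
        reached = tissue_mask
        assigned = np.zeros(head.shape, dtype=bool)
        for d in range(1, shell + 1):
            reached = ndimage.binary_dilation(reached, structure=struct)
            layer = csf_mask & reached & ~assigned
            csf_weight[layer] = weights[d - 1]
            assigned |= layer
        pv_mask = assigned
    return {
        "head": head,
        "tissue": tissue_mask,
        "csf": csf_mask & ~pv_mask,
        "pv": pv_mask,
        "csf_weight": csf_weight,
    }


def _label_field_fast(subject: SubjectGroundTruth, config: PhantomConfig,
                      rng: np.random.Generator):
    """Flat compartment labels (no geometry) for quick cohort tests.

    Voxels are laid out in raveled order — in-head first (pure tissue, then
    partial volume, then pure CSF), background zeros last — and reshaped to
    a thin 3-D grid so the volumes stay NIfTI-writable.  Compartment
    proportions match the geometric generator's intent; partial-volume
    voxels take a fixed share of the CSF budget with weights drawn from the
    same linear ramp.
    """
    n = config.fast_n_voxels
    n_head = int(round(FAST_HEAD_SHARE * n))
    n_tissue = int(round(subject.true_brain_fraction / 100.0 * n_head))
    n_csf_total = n_head - n_tissue
    if n_tissue < 1 or n_csf_total < 0:
        raise ValueError("brain fraction infeasible for fast mode")
    shell = config.partial_volume_shell
    n_pv = int(round(FAST_PV_FRACTION * n_csf_total)) if shell > 0 else 0

    shape = (100, n // 100, 1)
    head = np.zeros(shape, dtype=bool)
    head.ravel()[:n_head] = True
    tissue = np.zeros(shape, dtype=bool)
    tissue.ravel()[:n_tissue] = True
    pv = np.zeros(shape, dtype=bool)
    pv.ravel()[n_tissue:n_tissue + n_pv] = True
    csf = head & ~tissue & ~pv

    csf_weight = np.zeros(shape)
    csf_weight[csf] = 1.0
    if n_pv > 0:
        csf_weight.ravel()[n_tissue:n_tissue + n_pv] = rng.choice(
            _pv_weights(shell), size=n_pv
        )
    return {"head": head, "tissue": tissue, "csf": csf, "pv": pv,
            "csf_weight": csf_weight}


def synthesize_with_truth(
    subject: SubjectGroundTruth,
    config: PhantomConfig | None = None,
    fast: bool = False,
):
    """Synthesize a subject's b0/dw pair plus its ground-truth fields.

    Returns ``(VolumePair, truth)`` where ``truth`` holds the boolean
    compartment masks, the per-voxel CSF mixing weight, and the assigned
    noise-free ADC field.  Deterministic: the same (subject, config) always
    yields bit-identical volumes.
    """
    config = config or PhantomConfig()
    rng = np.random.default_rng(subject.seed)
    if fast:
        labels = _label_field_fast(subject, config, rng)
    else:
        labels = _label_field_geometric(subject, config)

    head = labels["head"]
    w = labels["csf_weight"]
    shape = head.shape
    n_head = int(np.count_nonzero(head))

    tissue_draw = np.maximum(
        rng.normal(config.tissue_adc_mean, config.tissue_adc_sd, n_head), 0.0
    )
    csf_draw = np.maximum(
        rng.normal(config.csf_adc_mean, config.csf_adc_sd, n_head), 0.0
    )
    w_head = w[head]
    adc = np.zeros(shape)
    adc[head] = (1.0 - w_head) * tissue_draw + w_head * csf_draw

    b0 = np.zeros(shape)
    b0[head] = (1.0 - w_head) * config.s0_tissue + w_head * config.s0_csf
    dw = b0 * np.exp(-config.b_value * adc)

    if config.noise_sigma > 0:
        sigma = config.noise_sigma
        b0 = np.hypot(b0 + rng.normal(0.0, sigma, shape),
                      rng.normal(0.0, sigma, shape))
        dw = np.hypot(dw + rng.normal(0.0, sigma, shape),
                      rng.normal(0.0, sigma, shape))
    b0 *= subject.global_scale
    dw *= subject.global_scale

    truth = dict(labels)
    truth["adc"] = adc
    return VolumePair(b0=b0, dw=dw, b_value=config.b_value), truth


def synthesize_volumes(
    subject: SubjectGroundTruth,
    config: PhantomConfig | None = None,
    fast: bool = False,
) -> VolumePair:
    """Synthesize a subject's b0/dw volume pair (see synthesize_with_truth)."""
    pair, _ = synthesize_with_truth(subject, config, fast=fast)
    return pair
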