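"""Intensity self-scaling and noise/skull masking for b0/dw volume pairs.

Clinical DWI exports carry arbitrary per-study intensity scaling, so all
downstream thresholds are defined in self-calibrated units: the mode of the
(smoothed) dw-intensity histogram is mapped to a fixed target value (250 by
default) and both volumes of the pair are multiplied by the same factor.
Background/skull voxels are then removed with a combined b0/dw threshold;
the surviving voxel count is the normalization denominator for every ADC
histogram built later.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import moving_average

DEFAULT_TARGET = 250.0
DEFAULT_TAU_B0 = 50.0
DEFAULT_DW_FLOOR = 1.0

_MASK_RULES = ("and", "or", "sum")


@dataclass(frozen=True)
class VolumePair:
    """A subject's co-registered b0 and diffusion-weighted volumes.

    Intensities are in arbitrary scanner units; ``b_value`` is the diffusion
    weighting of the dw member in s/mm² (the b0 member has b = 0).
    """

    b0: np.ndarray
    dw: np.ndarray
    b_value: float = 1000.0

    def __post_init__(self) -> None:
        b0 = np.asarray(self.b0, dtype=float)
        dw = np.asarray(self.dw, dtype=float)
        if b0.shape != dw.shape:
            raise ValueError(
                f"b0 and dw shapes differ: {b0.shape} vs {dw.shape}"
            )
        if self.b_value <= 0:
            raise ValueError("b_value must be positive")
        object.__setattr__(self, "b0", b0)
        object.__setattr__(self, "dw", dw)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.b0.shape

    def scaled_by(self, k: float) -> "VolumePair":
        """Return a copy with both volumes multiplied by ``k`` (> 0)."""
        if k <= 0:
            raise ValueError("scale must be positive")
        return VolumePair(self.b0 * k, self.dw * k, self.b_value)


@dataclass(frozen=True)
class ScaledVolumePair(VolumePair):
    """VolumePair after intensity self-scaling.

    ``dw_mode`` is the estimated mode of the raw dw-intensity histogram and
    ``scale_factor`` the multiplier (target / dw_mode) that was applied to
    both volumes.
    """

    scale_factor: float = 1.0
    dw_mode: float = float("nan")


@dataclass(frozen=True)
class VoxelMask:
    """Boolean voxel-inclusion mask; ``count`` is the denominator for
    percent-normalized ADC histograms."""

    included: np.ndarray

    def __post_init__(self) -> None:
        inc = np.asarray(self.included, dtype=bool)
        object.__setattr__(self, "included", inc)

    @property
    def count(self) -> int:
        return int(np.count_nonzero(self.included))


def dw_intensity_mode(
    dw: np.ndarray,
    n_bins: int = 256,
    smooth_window: int = 5,
    floor_fraction: float = 0.05,
) -> float:
    """Mode of the smoothed dw-intensity histogram.

    A histogram with ``n_bins`` uniform bins is built over ``(floor, max]``
    where ``floor = floor_fraction ×`` the 99th-percentile intensity; the
    floor excludes the large background-noise spike near zero that would
    otherwise capture the mode.  The counts are smoothed with a centered
    moving average of odd width ``smooth_window`` (shrunk at the edges) and
    the center of the maximal smoothed bin is returned, ties broken toward
    the lowest bin.
    """
    if n_bins < 16:
        raise ValueError("n_bins must be at least 16")
    if not 0 <= floor_fraction < 1:
        raise ValueError("floor_fraction must be in [0, 1)")
    flat = np.asarray(dw, dtype=float).ravel()
    if flat.size == 0:
        raise ValueError("empty volume")
    floor = floor_fraction * np.percentile(flat, 99)
    sel = flat[flat > floor]
    if sel.size == 0:
        raise ValueError("no dw intensities above the background floor")
    top = sel.max()
    if top <= floor:
        raise ValueError("degenerate dw intensity range")
    edges = np.linspace(floor, top, n_bins + 1)
    counts, _ = np.histogram(sel, bins=edges)
    smoothed = moving_average(counts, smooth_window)
    imax = int(np.argmax(smoothed))  # argmax returns the first (lowest) tie
    return float(0.5 * (edges[imax] + edges[imax + 1]))


def rescale(
    pair: VolumePair,
    target: float = DEFAULT_TARGET,
    n_bins: int = 256,
    smooth_window: int = 5,
    floor_fraction: float = 0.05,
) -> ScaledVolumePair:
    """Self-scale a volume pair so its dw histogram mode maps to ``target``.

    Both members are multiplied by ``target / dw_mode``; the factor and the
    estimated mode are recorded on the returned pair so every applied
    parameter can be echoed into run reports.
    """
    if target <= 0:
        raise ValueError("target intensity must be positive")
    mode = dw_intensity_mode(
        pair.dw,
        n_bins=n_bins,
        smooth_window=smooth_window,
        floor_fraction=floor_fraction,
    )
    if mode <= 0:
        raise ValueError("dw intensity mode is non-positive; cannot rescale")
    factor = target / mode
    return ScaledVolumePair(
        b0=pair.b0 * factor,
        dw=pair.dw * factor,
        b_value=pair.b_value,
        scale_factor=factor,
        dw_mode=mode,
    )


def combined_mask(
    pair: ScaledVolumePair,
    tau_b0: float = DEFAULT_TAU_B0,
    dw_floor: float = DEFAULT_DW_FLOOR,
    rule: str = "and",
) -> VoxelMask:
    """Exclude background and skull with a combined b0/dw threshold.

    Thresholds are in self-calibrated units (dw mode = 250).  The default
    ``and`` rule keeps a voxel iff ``b0 > tau_b0`` and ``dw > dw_floor``:
    every in-head voxel — tissue and CSF alike — is bright in b0, whereas
    background and skull are dark, so the b0 gate does the anatomical work;
    the low dw floor only guarantees the ADC logarithm is defined and keeps
    the dark-in-dw CSF.  ``or`` and ``sum`` (b0 + dw > tau_b0) are provided
    as alternatives.
    """
    if tau_b0 < 0 or dw_floor < 0:
        raise ValueError("thresholds must be non-negative")
    if rule not in _MASK_RULES:
        raise ValueError(f"rule must be one of {_MASK_RULES}")
    if rule == "and":
        included = (pair.b0 > tau_b0) & (pair.dw > dw_floor)
    elif rule == "or":
        included = (pair.b0 > tau_b0) | (pair.dw > dw_floor)
    else:
        included = (pair.b0 + pair.dw) > tau_b0
    mask = VoxelMask(included)
    if mask.count == 0:
        raise ValueError("combined threshold excluded every voxel "
                         "(empty or corrupt input)")
    return mask
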