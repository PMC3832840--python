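"""Characteristic ADC value and the brain-tissue pixel percentage.

The cohort-average ADC histogram shows a clear brain-tissue peak (near
0.75 × 10⁻³ mm²/s) and a high-ADC CSF tail.  The partition point between
tissue-dominated and CSF-dominated voxels is constructed from the peak's
left flank: find the point left of the maximum where the histogram first
drops to 1% of the peak height (the "basis"), then mirror it about the peak:

    a_char = peak + (peak − basis)

Each subject's brain fraction is then the percent of masked voxels with
ADC at or below a_char.  Peak and basis are detected on a lightly smoothed
histogram; mass sums always use the raw histogram.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from ._util import moving_average
from .histogram import ADCHistogram

DEFAULT_PEAK_WINDOW = (0.3e-3, 1.2e-3)
DEFAULT_LEVEL = 0.01
DEFAULT_SMOOTH_WINDOW = 3


@dataclass(frozen=True)
class PeakDescriptor:
    """Location and (smoothed) height of the brain-tissue histogram peak."""

    peak_adc: float
    peak_height: float
    peak_index: int

    def __post_init__(self) -> None:
        if self.peak_height <= 0:
            raise ValueError("peak height must be positive")


@dataclass(frozen=True)
class CharacteristicValue:
    """Tissue/CSF partition point with its construction record.

    The mirror identity a_char − peak = peak − left_basis holds exactly by
    construction.
    """

    left_basis: float
    peak_adc: float
    a_char: float
    level: float

    def __post_init__(self) -> None:
        if not self.left_basis < self.peak_adc < self.a_char:
            raise ValueError("require left_basis < peak_adc < a_char")


def find_tissue_peak(
    avg: ADCHistogram,
    window: tuple[float, float] = DEFAULT_PEAK_WINDOW,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> PeakDescriptor:
    """Argmax of the smoothed average histogram within the search window.

    The window (default 0.3–1.2 × 10⁻³ mm²/s) excludes the zero-clamp noise
    spike on the left and the CSF tail on the right, so the windowed argmax
    is the brain-tissue mode.  Ties break toward the lowest ADC.
    """
    centers = avg.bin_centers
    smoothed = moving_average(avg.percent, smooth_window)
    in_window = (centers >= window[0]) & (centers <= window[1])
    if not np.any(in_window):
        raise ValueError("peak search window contains no histogram bins")
    if np.all(smoothed[in_window] <= 0):
        raise ValueError("histogram is empty within the peak search window")
    idx_window = np.flatnonzero(in_window)
    best = idx_window[int(np.argmax(smoothed[in_window]))]
    return PeakDescriptor(
        peak_adc=float(centers[best]),
        peak_height=float(smoothed[best]),
        peak_index=int(best),
    )


def find_left_basis(
    avg: ADCHistogram,
    peak: PeakDescriptor,
    level: float = DEFAULT_LEVEL,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> float:
    """Leftward scan from the peak for the first bin at <= level × height.

    Returns the bin center of the first (smoothed) bin at or below
    ``level × peak_height`` when walking from the peak toward ADC = 0.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    smoothed = moving_average(avg.percent, smooth_window)
    threshold = level * peak.peak_height
    centers = avg.bin_centers
    for i in range(peak.peak_index - 1, -1, -1):
        if smoothed[i] <= threshold:
            return float(centers[i])
    raise ValueError(
        "histogram never descends to the basis level left of the peak "
        "(malformed histogram)"
    )


def characteristic_value(
    peak: PeakDescriptor,
    basis: float,
    level: float = DEFAULT_LEVEL,
) -> CharacteristicValue:
    """Mirror the left basis about the peak: a_char = 2·peak − basis."""
    if basis >= peak.peak_adc:
        raise ValueError("basis must lie left of the peak")
    return CharacteristicValue(
        left_basis=float(basis),
        peak_adc=peak.peak_adc,
        a_char=float(2.0 * peak.peak_adc - basis),
        level=level,
    )


def characteristic_from_histogram(
    avg: ADCHistogram,
    window: tuple[float, float] = DEFAULT_PEAK_WINDOW,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    level: float = DEFAULT_LEVEL,
) -> tuple[PeakDescriptor, CharacteristicValue]:
    """Peak detection, basis search and mirroring in one step."""
    peak = find_tissue_peak(avg, window=window, smooth_window=smooth_window)
    basis = find_left_basis(avg, peak, level=level, smooth_window=smooth_window)
    return peak, characteristic_value(peak, basis, level=level)


def brain_fraction(hist: ADCHistogram, a_char: float) -> float:
    """Percent of masked voxels with ADC at or below the partition point.

    Sums the (unsmoothed) per-bin percent over bins whose center is
    <= a_char; the complement — including overflow mass — is the CSF-side
    percentage, 100 minus this value.  A partition at or beyond the last
    bin edge includes the overflow mass, so brain_fraction(hist, inf) = 100.
    """
    centers = hist.bin_centers
    if a_char < centers[0]:
        warnings.warn(
            "characteristic value below the first bin center; "
            "brain fraction is 0", stacklevel=2,
        )
        return 0.0
    total = float(hist.percent[centers <= a_char].sum())
    if a_char >= hist.bin_edges[-1]:
        total += hist.overflow_percent
    return total
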