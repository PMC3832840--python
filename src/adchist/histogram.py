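"""Per-voxel ADC computation and percent-normalized ADC histograms.

ADC = ln(S_b0 / S_dw) / b per masked voxel (mm²/s); values are binned on a
uniform grid (default 0 to 4 × 10⁻³ mm²/s, bin width 0.02 × 10⁻³) and
expressed as percent of the masked-voxel count, so histograms from heads of
different sizes are directly comparable.  Mass at or above the last edge is
kept in a separate overflow term; per-bin percent plus overflow always sums
to 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .preprocess import ScaledVolumePair, VoxelMask

DEFAULT_ADC_MAX = 4.0e-3
DEFAULT_N_BINS = 200


def default_bin_edges(adc_max: float = DEFAULT_ADC_MAX,
                      n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    return np.linspace(0.0, adc_max, n_bins + 1)


@dataclass(frozen=True)
class ADCMap:
    """Flat ADC values (mm²/s) over the masked voxels of one subject."""

    values: np.ndarray
    b_value: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        object.__setattr__(self, "values", v)

    @property
    def n_voxels(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class ADCHistogram:
    """Percent-normalized ADC histogram for one subject or a cohort average.

    ``percent`` holds per-bin mass in percent of ``total_count`` masked
    voxels; ``overflow_percent`` is the mass at or above the last edge.
    Normalization (sum + overflow = 100) is enforced at construction.
    """

    bin_edges: np.ndarray
    percent: np.ndarray
    overflow_percent: float
    total_count: int

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        pct = np.asarray(self.percent, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("bin_edges must be a 1-D array of >= 2 edges")
        if pct.size != edges.size - 1:
            raise ValueError("percent length must equal number of bins")
        widths = np.diff(edges)
        if np.any(widths <= 0) or not np.allclose(widths, widths[0]):
            raise ValueError("bin edges must be uniform and increasing")
        if np.any(pct < 0) or self.overflow_percent < 0:
            raise ValueError("histogram mass must be non-negative")
        total = pct.sum() + self.overflow_percent
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"histogram mass sums to {total!r}, not 100")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "percent", pct)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


def compute_adc(pair: ScaledVolumePair, mask: VoxelMask) -> ADCMap:
    """Per-voxel ADC = ln(b0/dw)/b over the mask, negatives clamped to 0.

    Noise can push dw above b0 in dark voxels, which would give a negative
    ADC; clamping (rather than discarding) keeps the map's voxel count equal
    to the mask count, the denominator of the percent normalization.
    """
    if mask.count == 0:
        raise ValueError("empty mask")
    if mask.included.shape != pair.shape:
        raise ValueError("mask shape does not match volumes")
    b0 = pair.b0[mask.included]
    dw = pair.dw[mask.included]
    if np.any(dw <= 0):
        raise ValueError(
            "non-positive dw intensity inside the mask; "
            "the dw floor should have excluded these voxels"
        )
    with np.errstate(divide="ignore"):
        adc = np.log(b0 / dw) / pair.b_value
    adc = np.maximum(adc, 0.0)
    return ADCMap(values=adc, b_value=pair.b_value)


def build_histogram(adc_map: ADCMap,
                    bin_edges: np.ndarray | None = None) -> ADCHistogram:
    """Bin an ADC map into a percent-normalized histogram.

    Bins are half-open [lo, hi); values at or above the last edge accumulate
    in the overflow term (they are real CSF/noise voxels above range and
    stay in the normalization denominator).
    """
    if adc_map.n_voxels == 0:
        raise ValueError("empty ADC map")
    edges = default_bin_edges() if bin_edges is None else np.asarray(bin_edges,
                                                                     dtype=float)
    values = adc_map.values
    if np.any(values < edges[0]):
        raise ValueError("ADC values below the first bin edge")
    in_range = values[values < edges[-1]]
    counts, _ = np.histogram(in_range, bins=edges)
    n_over = values.size - in_range.size
    total = values.size
    return ADCHistogram(
        bin_edges=edges,
        percent=100.0 * counts / total,
        overflow_percent=100.0 * n_over / total,
        total_count=total,
    )


def average_histogram(histograms: list[ADCHistogram]) -> ADCHistogram:
    """Cohort-average histogram: per-bin arithmetic mean of percent values.

    Each subject is weighted equally — their histograms are already
    normalized to their own masked-voxel count, which is what compensates
    for head-size differences.  ``total_count`` becomes the summed count.
    """
    if not histograms:
        raise ValueError("need at least one histogram")
    ref = histograms[0]
    for h in histograms[1:]:
        if h.bin_edges.shape != ref.bin_edges.shape or not np.allclose(
            h.bin_edges, ref.bin_edges
        ):
            raise ValueError("histograms have mismatched binning")
    pct = np.mean([h.percent for h in histograms], axis=0)
    over = float(np.mean([h.overflow_percent for h in histograms]))
    # re-balance float rounding so the normalization invariant stays exact
    drift = pct.sum() + over - 100.0
    over -= drift
    return ADCHistogram(
        bin_edges=ref.bin_edges,
        percent=pct,
        overflow_percent=over,
        total_count=int(sum(h.total_count for h in histograms)),
    )


def histogram_to_tsv(hist: ADCHistogram, path: str | Path) -> None:
    """Write bin_lo / bin_hi / percent rows, with a final overflow row."""
    with open(path, "w") as fh:
        fh.write("bin_lo\tbin_hi\tpercent\n")
        for lo, hi, p in zip(hist.bin_edges[:-1], hist.bin_edges[1:],
                             hist.percent):
            fh.write(f"{lo:.6e}\t{hi:.6e}\t{p:.10g}\n")
        fh.write(f"{hist.bin_edges[-1]:.6e}\tinf\t{hist.overflow_percent:.10g}\n")
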