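"""End-to-end orchestration: per-subject analysis and cohort reports.

The per-subject chain is rescale → mask → ADC → histogram.  At cohort level
the per-subject histograms are averaged, the characteristic ADC value is
derived once from the average and applied to every subject, and the
resulting brain fractions feed the age-group summaries, adjacent-group
tests and quadratic fits.  Every tunable parameter lives in RunConfig and
is echoed (with a content hash) into all reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

from . import characteristic as chr_mod
from . import cohort as cohort_mod
from . import io as io_mod
from .histogram import (ADCHistogram, average_histogram, build_histogram,
                        compute_adc, default_bin_edges, histogram_to_tsv)
from .phantom import CohortManifest
from .preprocess import (VolumePair, combined_mask, rescale)


@dataclass(frozen=True)
class NormalizeConfig:
    target: float = 250.0
    n_bins: int = 256
    smooth_window: int = 5
    floor_fraction: float = 0.05


@dataclass(frozen=True)
class MaskConfig:
    rule: str = "and"
    tau_b0: float = 50.0
    dw_floor: float = 1.0


@dataclass(frozen=True)
class HistogramConfig:
    adc_max: float = 4.0e-3
    n_bins: int = 200

    def edges(self) -> np.ndarray:
        return default_bin_edges(self.adc_max, self.n_bins)


@dataclass(frozen=True)
class CharacteristicConfig:
    window_lo: float = 0.3e-3
    window_hi: float = 1.2e-3
    smooth_window: int = 3
    level: float = 0.01
    per_subject: bool = False  # sensitivity mode: a_char per subject


@dataclass(frozen=True)
class RunConfig:
    normalize: NormalizeConfig = field(default_factory=NormalizeConfig)
    mask: MaskConfig = field(default_factory=MaskConfig)
    histogram: HistogramConfig = field(default_factory=HistogramConfig)
    characteristic: CharacteristicConfig = field(
        default_factory=CharacteristicConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, flat: Mapping) -> "RunConfig":
        """Build from flat dotted keys, e.g. ``normalize.target: 250``."""
        sections = {
            "normalize": {}, "mask": {}, "histogram": {}, "characteristic": {},
        }
        seed = 0
        for key, value in flat.items():
            if key == "seed":
                seed = int(value)
                continue
            if "." not in key:
                raise ValueError(f"unknown config key: {key}")
            section, name = key.split(".", 1)
            if section not in sections:
                raise ValueError(f"unknown config section: {section}")
            sections[section][name] = value
        return cls(
            normalize=NormalizeConfig(**sections["normalize"]),
            mask=MaskConfig(**sections["mask"]),
            histogram=HistogramConfig(**sections["histogram"]),
            characteristic=CharacteristicConfig(**sections["characteristic"]),
            seed=seed,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            flat = yaml.safe_load(fh) or {}
        return cls.from_dict(flat)


@dataclass
class CohortResult:
    """Everything the cohort analysis produces."""

    peak: chr_mod.PeakDescriptor
    characteristic: chr_mod.CharacteristicValue
    avg_histogram: ADCHistogram
    subject_results: list[cohort_mod.SubjectResult]
    summaries: list[cohort_mod.AgeGroupSummary]
    comparisons: list[cohort_mod.GroupComparison] | None
    fits: dict[str, cohort_mod.QuadraticFit | None]


def analyze_subject(pair: VolumePair,
                    config: RunConfig | None = None
                    ) -> tuple[ADCHistogram, dict]:
    """Rescale → mask → ADC → histogram for one subject.

    Returns the percent-normalized histogram plus metadata (scale factor,
    dw mode, mask count) for the run log.
    """
    config = config or RunConfig()
    scaled = rescale(
        pair,
        target=config.normalize.target,
        n_bins=config.normalize.n_bins,
        smooth_window=config.normalize.smooth_window,
        floor_fraction=config.normalize.floor_fraction,
    )
    mask = combined_mask(
        scaled,
        tau_b0=config.mask.tau_b0,
        dw_floor=config.mask.dw_floor,
        rule=config.mask.rule,
    )
    adc = compute_adc(scaled, mask)
    hist = build_histogram(adc, config.histogram.edges())
    meta = {
        "scale_factor": scaled.scale_factor,
        "dw_mode": scaled.dw_mode,
        "mask_count": mask.count,
    }
    return hist, meta


def analyze_cohort(
    subjects: Iterable[tuple[Mapping, VolumePair]],
    config: RunConfig | None = None,
    fit: bool = True,
) -> CohortResult:
    """Full cohort analysis from (metadata, VolumePair) records.

    Metadata mappings must carry ``subject_id``, ``age`` and ``sex``.  The
    characteristic ADC value is derived once from the cohort-average
    histogram and applied to every subject (set
    ``characteristic.per_subject`` for the sensitivity variant).  With
    ``fit=True`` a cohort of fewer than 3 subjects is refused; sex strata
    that are too small yield ``None`` fits.  Adjacent-group comparisons are
    reported only when all four age groups have >= 2 members.
    """
    config = config or RunConfig()
    histograms: list[ADCHistogram] = []
    metas: list[dict] = []
    infos: list[Mapping] = []
    for info, pair in subjects:
        try:
            hist, meta = analyze_subject(pair, config)
        except Exception as exc:
            raise RuntimeError(
                f"subject {info.get('subject_id', '?')}: {exc}"
            ) from exc
        histograms.append(hist)
        metas.append(meta)
        infos.append(info)
    if not histograms:
        raise ValueError("empty cohort")

    avg = average_histogram(histograms)
    cc = config.characteristic
    window = (cc.window_lo, cc.window_hi)
    peak, char = chr_mod.characteristic_from_histogram(
        avg, window=window, smooth_window=cc.smooth_window, level=cc.level
    )

    results = []
    for info, hist, meta in zip(infos, histograms, metas):
        if cc.per_subject:
            _, subj_char = chr_mod.characteristic_from_histogram(
                hist, window=window, smooth_window=cc.smooth_window,
                level=cc.level,
            )
            a_char = subj_char.a_char
        else:
            a_char = char.a_char
        results.append(
            cohort_mod.SubjectResult(
                subject_id=str(info["subject_id"]),
                age=float(info["age"]),
                sex=str(info["sex"]),
                brain_fraction=chr_mod.brain_fraction(hist, a_char),
                mask_count=meta["mask_count"],
                scale_factor=meta["scale_factor"],
            )
        )

    summaries = cohort_mod.group_summary(results)
    comparisons = None
    if all(s.n >= 2 for s in summaries):
        comparisons = cohort_mod.compare_adjacent_groups(results)

    fits: dict[str, cohort_mod.QuadraticFit | None] = {}
    if fit:
        fits["all"] = cohort_mod.fit_quadratic(results, "all")  # raises if n < 3
        for stratum in ("female", "male"):
            try:
                fits[stratum] = cohort_mod.fit_quadratic(results, stratum)
            except ValueError:
                fits[stratum] = None
    return CohortResult(
        peak=peak,
        characteristic=char,
        avg_histogram=avg,
        subject_results=results,
        summaries=summaries,
        comparisons=comparisons,
        fits=fits,
    )


def iter_manifest_pairs(
    manifest: CohortManifest,
) -> Iterator[tuple[dict, VolumePair]]:
    """Load each manifest subject's volumes, failing fast with its id."""
    for s in manifest:
        if not s.b0_path or not s.dw_path:
            raise FileNotFoundError(
                f"subject {s.subject_id}: manifest has no volume paths"
            )
        try:
            pair = io_mod.read_volume_pair(s.b0_path, s.dw_path)
        except Exception as exc:
            raise RuntimeError(
                f"subject {s.subject_id}: cannot read volumes ({exc})"
            ) from exc
        yield {"subject_id": s.subject_id, "age": s.age, "sex": s.sex}, pair


def run_manifest(manifest: CohortManifest,
                 config: RunConfig | None = None,
                 fit: bool = True) -> CohortResult:
    """Manifest-driven end-to-end cohort analysis."""
    return analyze_cohort(iter_manifest_pairs(manifest), config, fit=fit)


def _fit_record(fit: cohort_mod.QuadraticFit | None) -> dict | None:
    if fit is None:
        return None
    rec = asdict(fit)
    rec["slopes"] = {
        str(age): cohort_mod.slope_at_age(fit, age) for age in (20, 50, 80)
    }
    return rec


def write_report(result: CohortResult, out_dir: str | Path,
                 config: RunConfig | None = None) -> None:
    """Write CSV/JSON/TSV reports; every file embeds the config hash."""
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()

    pd.DataFrame([asdict(r) for r in result.subject_results]).to_csv(
        out / "results.csv", index=False
    )
    pd.DataFrame([asdict(s) for s in result.summaries]).to_csv(
        out / "group_summary.csv", index=False
    )
    if result.comparisons is not None:
        pd.DataFrame([asdict(c) for c in result.comparisons]).to_csv(
            out / "comparisons.csv", index=False
        )
    histogram_to_tsv(result.avg_histogram, out / "avg_histogram.tsv")

    char_report = {
        "config_hash": cfg_hash,
        "peak_adc": result.peak.peak_adc,
        "peak_height": result.peak.peak_height,
        "left_basis": result.characteristic.left_basis,
        "a_char": result.characteristic.a_char,
        "level": result.characteristic.level,
        "bin_width": result.avg_histogram.bin_width,
        "n_subjects": len(result.subject_results),
    }
    with open(out / "characteristic.json", "w") as fh:
        json.dump(char_report, fh, indent=2, sort_keys=True)

    fits_report = {
        "config_hash": cfg_hash,
        "fits": {k: _fit_record(v) for k, v in result.fits.items()},
    }
    with open(out / "fits.json", "w") as fh:
        json.dump(fits_report, fh, indent=2, sort_keys=True)

    with open(out / "run_config.json", "w") as fh:
        json.dump({"config_hash": cfg_hash, "config": config.to_dict()},
                  fh, indent=2, sort_keys=True)
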