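"""Preprocessing pipelines turning raw records into model-ready vectors.

Three pipelines, one per modality:

* **TGA** — clip the thermogram to 40-760 °C (readings above ~760 °C are
  dominated by instrument noise) and average the mass signal in 1 °C bins,
  reducing ~22,000 points to one value per integer °C.
* **FT-IR** — per wavenumber: average the replicates, clip at 100%
  transmittance (noise overshoots), subtract from 101, floor at 1e-6 and
  take log₁₀.  The result is a bounded absorbance-like vector:
  ``D = log₁₀(max(101 − min(mean(D_i), 100), 1e-6))``.
* **GC-MS** — sum detected derivative percentages per group and close the
  composition with an "Other" class holding the undetected shortfall, so
  the ten fractions always sum to one.

A Wasserstein-1 audit quantifies the information the TGA resampling
discards (it should be tiny — order 1e-3 on the mass-fraction scale).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datatypes import (
    GROUP_LABELS,
    CompositionVector,
    CoverageError,
    DerivativeTable,
    GridError,
    IRPreprocessed,
    IRSpectrumRaw,
    ThermogramRaw,
    ThermogramResampled,
    ValidationError,
    ftir_wavenumber_grid,
)

__all__ = [
    "PreprocessConfig",
    "clip_resample_tga",
    "preprocess_ftir",
    "aggregate_gcms",
    "preprocessing_information_loss",
    "process_bundle",
]


@dataclass
class PreprocessConfig:
    """Tunables of the three pipelines (defaults are the standard procedure)."""

    tga_clip_low_c: int = 40
    tga_clip_high_c: int = 760
    ftir_clip_pct: float = 100.0
    ftir_offset: float = 101.0
    ftir_floor: float = 1e-6
    log_base: float = 10.0

    def __post_init__(self) -> None:
        if self.tga_clip_low_c >= self.tga_clip_high_c:
            raise ValidationError("PreprocessConfig: clip_low must be < clip_high")
        if self.ftir_floor <= 0:
            raise ValidationError("PreprocessConfig: ftir_floor must be > 0")
        if self.log_base <= 1:
            raise ValidationError("PreprocessConfig: log_base must be > 1")


def clip_resample_tga(
    raw: ThermogramRaw, cfg: PreprocessConfig | None = None
) -> ThermogramResampled:
    """Clip to the configured window and average mass in centered 1 °C bins.

    Bin *t* collects raw points with temperature in [t-0.5, t+0.5); empty
    bins (possible only on sparse inputs) are filled by linear
    interpolation between the nearest non-empty bins.
    """
    cfg = cfg or PreprocessConfig()
    lo, hi = cfg.tga_clip_low_c, cfg.tga_clip_high_c
    t, m = raw.temperature_c, raw.mass_pct
    if t.min() > lo or t.max() < hi:
        raise CoverageError(
            f"thermogram spans [{t.min():.2f}, {t.max():.2f}] °C; "
            f"cannot cover clip window [{lo}, {hi}]"
        )
    keep = (t >= lo) & (t <= hi)
    t, m = t[keep], m[keep]
    bins = np.rint(t).astype(int) - lo
    n_bins = hi - lo + 1
    bins = np.clip(bins, 0, n_bins - 1)
    counts = np.bincount(bins, minlength=n_bins)
    sums = np.bincount(bins, weights=m, minlength=n_bins)
    values = np.full(n_bins, np.nan)
    nonempty = counts > 0
    values[nonempty] = sums[nonempty] / counts[nonempty]
    if not nonempty.all():
        grid = np.arange(n_bins, dtype=float)
        values[~nonempty] = np.interp(grid[~nonempty], grid[nonempty], values[nonempty])
    return ThermogramResampled(mass_pct=values, grid_start_c=lo, grid_end_c=hi)


def preprocess_ftir(
    replicates: Sequence[IRSpectrumRaw], cfg: PreprocessConfig | None = None
) -> IRPreprocessed:
    """Merge replicates and apply the clip / offset / floor / log transform.

    Off-grid replicates are first linearly interpolated onto the canonical
    3476-point wavenumber grid.  With the default config the output is
    bounded in [0, log₁₀(101)] for any non-negative transmittance.
    """
    cfg = cfg or PreprocessConfig()
    if len(replicates) == 0:
        raise ValueError("preprocess_ftir: need at least one replicate")
    grid = ftir_wavenumber_grid()
    stack = []
    for rep in replicates:
        wn = rep.wavenumber_cm1
        if wn.size == grid.size and np.allclose(wn, grid, atol=1e-9):
            stack.append(rep.transmittance_pct)
        else:
            if wn.max() < grid[0] or wn.min() > grid[-1]:
                raise GridError(
                    "replicate wavenumber range does not overlap the canonical grid"
                )
            stack.append(np.interp(grid, wn, rep.transmittance_pct))
    mean = np.mean(np.stack(stack), axis=0)
    clipped = np.minimum(mean, cfg.ftir_clip_pct)
    arg = np.maximum(cfg.ftir_offset - clipped, cfg.ftir_floor)
    values = np.log(arg) / np.log(cfg.log_base)
    return IRPreprocessed(values=values)


def aggregate_gcms(table: DerivativeTable) -> CompositionVector:
    """Sum detected derivatives per group and close with the Other class."""
    violations = table.validate()
    if violations:
        raise ValidationError("aggregate_gcms: " + "; ".join(violations))
    sums = {g: 0.0 for g in GROUP_LABELS}
    for row in table.rows:
        if row.detected:
            sums[row.group] += row.proportion_pct
    fracs = np.array([sums[g] / 100.0 for g in GROUP_LABELS])
    other = 1.0 - fracs.sum()
    # guard against float dust when the detected total is exactly 100
    other = max(other, 0.0)
    return CompositionVector(np.concatenate([fracs, [other]]))


def preprocessing_information_loss(
    raw: ThermogramRaw,
    resampled: ThermogramResampled,
    cfg: PreprocessConfig | None = None,
) -> float:
    """Wasserstein-1 distance between raw and resampled mass distributions.

    Both samples are taken on the mass-fraction scale (values / 100), with
    the raw record restricted to the clip window, quantifying how much of
    the original distribution the 1 °C resampling discards.
    """
    from .evaluation import wasserstein1

    cfg = cfg or PreprocessConfig()
    keep = (raw.temperature_c >= cfg.tga_clip_low_c) & (
        raw.temperature_c <= cfg.tga_clip_high_c
    )
    p = raw.mass_pct[keep] / 100.0
    q = resampled.mass_pct / 100.0
    return wasserstein1(p, q)


def process_bundle(bundle: dict, cfg: PreprocessConfig | None = None) -> list:
    """Turn a raw study bundle into one :class:`SampleTriplet` per condition.

    Also returns the per-condition resampling audit when requested via the
    tuple form — see :func:`lignosense.workflow.run_full_experiment`.
    """
    from .datatypes import SampleTriplet

    cfg = cfg or PreprocessConfig()
    spectra_by_temp: dict[float, list[IRSpectrumRaw]] = {}
    for rep in bundle.get("spectra", []):
        spectra_by_temp.setdefault(rep.htl_temperature_c, []).append(rep)
    gcms_by_temp = {t.htl_temperature_c: t for t in bundle.get("gcms_tables", [])}
    triplets = []
    for raw in bundle.get("thermograms", []):
        temp = raw.htl_temperature_c
        triplets.append(
            SampleTriplet(
                htl_temperature_c=temp,
                tga=clip_resample_tga(raw, cfg),
                ftir=preprocess_ftir(spectra_by_temp[temp], cfg),
                gcms=aggregate_gcms(gcms_by_temp[temp]),
            )
        )
    return triplets
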