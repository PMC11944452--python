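"""Domain types and validation for TGA / FT-IR / GC-MS records.

Every downstream stage (preprocessing, generation, prediction, evaluation)
consumes these validated containers rather than raw files.  Validation is
*total*: :func:`validate_triplet` and the per-type ``validate`` helpers never
raise on bad data — they return a list of human-readable violation messages,
each naming the offending field and rule.  Constructors that *must* refuse
garbage (e.g. mismatched lengths that would make arrays unusable) raise
:class:`ValidationError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GROUP_LABELS",
    "COMPOSITION_LABELS",
    "LignosenseError",
    "SchemaError",
    "ParseError",
    "ValidationError",
    "CoverageError",
    "DomainError",
    "StateError",
    "GridError",
    "ThermogramRaw",
    "ThermogramResampled",
    "IRSpectrumRaw",
    "IRPreprocessed",
    "DerivativeTable",
    "CompositionVector",
    "SampleTriplet",
    "validate_triplet",
    "FTIR_GRID_POINTS",
    "FTIR_WAVENUMBER_MIN",
    "FTIR_WAVENUMBER_MAX",
    "ftir_wavenumber_grid",
]

#: The nine GC-MS compound groups observed among lignin depolymerization
#: products, in canonical column order.
GROUP_LABELS: tuple[str, ...] = (
    "Syringyl",
    "Guaiacyl",
    "PolyAromatics_C10_C21",
    "OtherAromatics_C6_C20",
    "Alkanes",
    "Cyclic",
    "FattyAcids",
    "Alcohol",
    "GlycerolDerived",
)

#: The nine groups plus the "Other" closure class holding undetected mass.
COMPOSITION_LABELS: tuple[str, ...] = GROUP_LABELS + ("Other",)

FTIR_GRID_POINTS = 3476
FTIR_WAVENUMBER_MIN = 649.8934
FTIR_WAVENUMBER_MAX = 4000.6047


def ftir_wavenumber_grid() -> np.ndarray:
    """Canonical 3476-point FT-IR wavenumber grid (cm^-1, ascending)."""
    return np.linspace(FTIR_WAVENUMBER_MIN, FTIR_WAVENUMBER_MAX, FTIR_GRID_POINTS)


class LignosenseError(Exception):
    """Base class for package errors."""


class SchemaError(LignosenseError):
    """A table is missing a required column or carries an unknown kind."""


class ParseError(LignosenseError):
    """A cell could not be parsed; the message carries the row index."""


class ValidationError(LignosenseError):
    """A typed record violates one of its invariants."""


class CoverageError(LignosenseError):
    """A raw thermogram does not span the requested clip window."""


class DomainError(LignosenseError):
    """A requested condition lies outside the supported domain."""


class StateError(LignosenseError):
    """An operation was invoked on a model in the wrong state (e.g. untrained)."""


class GridError(LignosenseError):
    """Spectra live on incompatible wavenumber grids."""


def _as1d(x: Sequence[float] | np.ndarray) -> np.ndarray:
    return np.asarray(x, dtype=float).ravel()


@dataclass
class ThermogramRaw:
    """A raw TGA record: % of initial mass vs. furnace temperature (°C)."""

    temperature_c: np.ndarray
    mass_pct: np.ndarray
    htl_temperature_c: float

    def __post_init__(self) -> None:
        self.temperature_c = _as1d(self.temperature_c)
        self.mass_pct = _as1d(self.mass_pct)
        self.htl_temperature_c = float(self.htl_temperature_c)
        if self.temperature_c.shape != self.mass_pct.shape:
            raise ValidationError(
                "ThermogramRaw: temperature_c and mass_pct lengths differ "
                f"({self.temperature_c.size} vs {self.mass_pct.size})"
            )

    def validate(self) -> list[str]:
        out: list[str] = []
        t, m = self.temperature_c, self.mass_pct
        if t.size == 0:
            out.append("ThermogramRaw.temperature_c: empty record")
            return out
        if np.any(np.diff(t) <= 0):
            out.append("ThermogramRaw.temperature_c: not strictly increasing")
        if t.min() < 30.0 or t.max() > 800.0:
            out.append("ThermogramRaw.temperature_c: out of range [30, 800]")
        if np.any(~np.isfinite(m)) or np.any(m <= 0.0) or np.any(m > 110.0):
            out.append("ThermogramRaw.mass_pct: out of range (0, 110]")
        return out


@dataclass
class ThermogramResampled:
    """TGA thermogram averaged onto a fixed 1 °C grid (the TGA modality vector)."""

    mass_pct: np.ndarray
    grid_start_c: int = 40
    grid_end_c: int = 760

    def __post_init__(self) -> None:
        self.mass_pct = _as1d(self.mass_pct)
        self.grid_start_c = int(self.grid_start_c)
        self.grid_end_c = int(self.grid_end_c)

    @property
    def grid_c(self) -> np.ndarray:
        return np.arange(self.grid_start_c, self.grid_end_c + 1, dtype=float)

    def validate(self) -> list[str]:
        out: list[str] = []
        expected = self.grid_end_c - self.grid_start_c + 1
        if self.mass_pct.size != expected:
            out.append(
                "ThermogramResampled.mass_pct: length "
                f"{self.mass_pct.size} != grid length {expected}"
            )
        if np.any(~np.isfinite(self.mass_pct)):
            out.append("ThermogramResampled.mass_pct: non-finite values")
        return out


@dataclass
class IRSpectrumRaw:
    """One FT-IR replicate: % transmittance vs. wavenumber (cm^-1).

    Instrument noise occasionally pushes recorded transmittance slightly
    above 100%; such values are legal here and handled by preprocessing.
    """

    wavenumber_cm1: np.ndarray
    transmittance_pct: np.ndarray
    replicate_id: int
    htl_temperature_c: float

    def __post_init__(self) -> None:
        self.wavenumber_cm1 = _as1d(self.wavenumber_cm1)
        self.transmittance_pct = _as1d(self.transmittance_pct)
        self.replicate_id = int(self.replicate_id)
        self.htl_temperature_c = float(self.htl_temperature_c)
        if self.wavenumber_cm1.shape != self.transmittance_pct.shape:
            raise ValidationError(
                "IRSpectrumRaw: wavenumber_cm1 and transmittance_pct lengths differ"
            )

    def validate(self) -> list[str]:
        out: list[str] = []
        w = self.wavenumber_cm1
        if w.size == 0:
            out.append("IRSpectrumRaw.wavenumber_cm1: empty record")
            return out
        if np.any(np.diff(w) <= 0):
            out.append("IRSpectrumRaw.wavenumber_cm1: not strictly increasing")
        if not (1 <= self.replicate_id <= 3):
            out.append("IRSpectrumRaw.replicate_id: not in 1..3")
        if np.any(~np.isfinite(self.transmittance_pct)):
            out.append("IRSpectrumRaw.transmittance_pct: non-finite values")
        return out


@dataclass
class IRPreprocessed:
    """Log-transformed absorbance-like FT-IR vector on the canonical grid."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _as1d(self.values)

    def validate(self) -> list[str]:
        out: list[str] = []
        if self.values.size != FTIR_GRID_POINTS:
            out.append(
                f"IRPreprocessed.values: length {self.values.size} != {FTIR_GRID_POINTS}"
            )
        if np.any(~np.isfinite(self.values)):
            out.append("IRPreprocessed.values: non-finite values")
        return out


@dataclass
class DerivativeRow:
    compound_name: str
    group: str
    proportion_pct: float
    detected: bool


@dataclass
class DerivativeTable:
    """Per-compound GC-MS record: 114 derivatives in nine groups.

    ``detected=False`` rows are compounds the GC-MS run failed to quantify
    (insufficient volatility, thermal degradation, poor ionization); their
    mass is what the "Other" closure class absorbs.
    """

    rows: list[DerivativeRow]
    htl_temperature_c: float = float("nan")

    def detected_total_pct(self) -> float:
        return float(sum(r.proportion_pct for r in self.rows if r.detected))

    def validate(self) -> list[str]:
        out: list[str] = []
        for i, r in enumerate(self.rows):
            if r.group not in GROUP_LABELS:
                out.append(f"DerivativeTable.rows[{i}].group: unknown label {r.group!r}")
            if not np.isfinite(r.proportion_pct) or r.proportion_pct < 0:
                out.append(f"DerivativeTable.rows[{i}].proportion_pct: negative or non-finite")
        if self.detected_total_pct() > 100.0 + 1e-6:
            out.append("DerivativeTable: detected proportion_pct sum exceeds 100")
        return out


@dataclass
class CompositionVector:
    """Ten non-negative group fractions (9 groups + Other) summing to one."""

    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.fractions = _as1d(self.fractions)

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "CompositionVector":
        return cls(np.array([d[k] for k in COMPOSITION_LABELS], dtype=float))

    def as_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in zip(COMPOSITION_LABELS, self.fractions)}

    def validate(self) -> list[str]:
        out: list[str] = []
        f = self.fractions
        if f.size != len(COMPOSITION_LABELS):
            out.append(
                f"CompositionVector.fractions: length {f.size} != {len(COMPOSITION_LABELS)}"
            )
            return out
        if np.any(~np.isfinite(f)):
            out.append("CompositionVector.fractions: non-finite values")
            return out
        if np.any(f < -1e-12):
            out.append("CompositionVector.fractions: negative fraction")
        if abs(float(f.sum()) - 1.0) > 1e-6:
            out.append("CompositionVector.fractions: sum-to-one violated "
                       f"(sum={float(f.sum()):.9f})")
        return out


@dataclass
class SampleTriplet:
    """One HTL condition's aligned, model-ready TGA / FT-IR / GC-MS data."""

    htl_temperature_c: float
    tga: ThermogramResampled
    ftir: IRPreprocessed
    gcms: CompositionVector


def validate_triplet(t: SampleTriplet) -> list[str]:
    """Collect every invariant violation of a triplet; empty list means valid."""
    out: list[str] = []
    out.extend(t.tga.validate())
    out.extend(t.ftir.validate())
    out.extend(t.gcms.validate())
    if not np.isfinite(t.htl_temperature_c):
        out.append("SampleTriplet.htl_temperature_c: non-finite")
    return out
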