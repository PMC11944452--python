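"""Readers and writers for the package's delimited-table conventions.

All tables are comma-separated UTF-8 with one header row and dot decimals
(the common instrument-export dialect).  Floats are written with ``%.17g``
so that a write→read round trip is bit-stable well below the 1e-12
tolerance the rest of the package assumes.

Table kinds and their columns:

``thermogram``
    temperature_c, mass_pct, htl_temperature_c
``spectrum``
    wavenumber_cm1, transmittance_pct, replicate_id, htl_temperature_c
``gcms``
    compound, group, proportion_pct, detected, htl_temperature_c
``composition``
    htl_temperature_c + the ten fraction columns
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .datatypes import (
    COMPOSITION_LABELS,
    CompositionVector,
    DerivativeRow,
    DerivativeTable,
    IRSpectrumRaw,
    ParseError,
    SchemaError,
    ThermogramRaw,
    ValidationError,
)

__all__ = ["load_bundle", "save_bundle", "TABLE_SCHEMAS", "FLOAT_FORMAT"]

FLOAT_FORMAT = "%.17g"

TABLE_SCHEMAS: dict[str, tuple[str, ...]] = {
    "thermogram": ("temperature_c", "mass_pct", "htl_temperature_c"),
    "spectrum": ("wavenumber_cm1", "transmittance_pct", "replicate_id", "htl_temperature_c"),
    "gcms": ("compound", "group", "proportion_pct", "detected", "htl_temperature_c"),
    "composition": ("htl_temperature_c",) + COMPOSITION_LABELS,
}

_NUMERIC_COLS: dict[str, tuple[str, ...]] = {
    "thermogram": ("temperature_c", "mass_pct", "htl_temperature_c"),
    "spectrum": ("wavenumber_cm1", "transmittance_pct", "htl_temperature_c"),
    "gcms": ("proportion_pct", "htl_temperature_c"),
    "composition": ("htl_temperature_c",) + COMPOSITION_LABELS,
}


def _read_table(path: Path, kind: str) -> pd.DataFrame:
    if kind not in TABLE_SCHEMAS:
        raise SchemaError(f"unknown table kind {kind!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in TABLE_SCHEMAS[kind]:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing column {col!r} for kind {kind!r}")
    for col in _NUMERIC_COLS[kind]:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce")
            row = int(bad[bad.isna()].index[0])
            raise ParseError(
                f"{path.name}: non-numeric value in column {col!r} at row {row}"
            ) from None
    return df


def _raise_on_violations(violations: list[str], path: Path) -> None:
    if violations:
        raise ValidationError(f"{path.name}: " + "; ".join(violations))


def _thermogram_from_df(df: pd.DataFrame, path: Path) -> ThermogramRaw:
    rec = ThermogramRaw(
        temperature_c=df["temperature_c"].to_numpy(float),
        mass_pct=df["mass_pct"].to_numpy(float),
        htl_temperature_c=float(df["htl_temperature_c"].iloc[0]) if len(df) else float("nan"),
    )
    _raise_on_violations(rec.validate(), path)
    return rec


def _spectra_from_df(df: pd.DataFrame, path: Path) -> list[IRSpectrumRaw]:
    out = []
    for rid, sub in df.groupby("replicate_id", sort=True):
        rec = IRSpectrumRaw(
            wavenumber_cm1=sub["wavenumber_cm1"].to_numpy(float),
            transmittance_pct=sub["transmittance_pct"].to_numpy(float),
            replicate_id=int(rid),
            htl_temperature_c=float(sub["htl_temperature_c"].iloc[0]),
        )
        _raise_on_violations(rec.validate(), path)
        out.append(rec)
    return out


def _gcms_from_df(df: pd.DataFrame, path: Path) -> DerivativeTable:
    rows = [
        DerivativeRow(
            compound_name=str(r.compound),
            group=str(r.group),
            proportion_pct=float(r.proportion_pct),
            detected=str(r.detected).strip().lower() in ("true", "1", "yes"),
        )
        for r in df.itertuples()
    ]
    rec = DerivativeTable(
        rows=rows,
        htl_temperature_c=float(df["htl_temperature_c"].iloc[0]) if len(df) else float("nan"),
    )
    _raise_on_violations(rec.validate(), path)
    return rec


def _compositions_from_df(df: pd.DataFrame, path: Path) -> list[tuple[float, CompositionVector]]:
    out = []
    for _, r in df.iterrows():
        cv = CompositionVector.from_dict({k: float(r[k]) for k in COMPOSITION_LABELS})
        _raise_on_violations(cv.validate(), path)
        out.append((float(r["htl_temperature_c"]), cv))
    return out


def load_bundle(path: str | Path, schema: str | None = None) -> dict:
    """Load validated records from a bundle directory (or a single table file).

    Parameters
    ----------
    path
        Either a directory written by :func:`save_bundle` (contains
        ``manifest.json``) or a single CSV file, in which case ``schema``
        must name its table kind.
    schema
        Table-kind tag (``thermogram`` / ``spectrum`` / ``gcms`` /
        ``composition``); required for single files, ignored for bundles.

    Returns
    -------
    dict
        ``{"thermograms": [...], "spectra": [...], "gcms_tables": [...],
        "compositions": [...]}`` with validated typed records.
    """
    path = Path(path)
    out: dict = {"thermograms": [], "spectra": [], "gcms_tables": [], "compositions": []}
    if path.is_file():
        if schema is None:
            raise SchemaError("schema tag required when loading a single file")
        entries = [(path, schema)]
    else:
        manifest_path = path / "manifest.json"
        if not manifest_path.exists():
            raise SchemaError(f"{path}: no manifest.json; not a bundle directory")
        manifest = json.loads(manifest_path.read_text())
        entries = [(path / e["file"], e["kind"]) for e in manifest["tables"]]
    for fpath, kind in entries:
        df = _read_table(fpath, kind)
        if kind == "thermogram":
            out["thermograms"].append(_thermogram_from_df(df, fpath))
        elif kind == "spectrum":
            out["spectra"].extend(_spectra_from_df(df, fpath))
        elif kind == "gcms":
            out["gcms_tables"].append(_gcms_from_df(df, fpath))
        elif kind == "composition":
            out["compositions"].extend(_compositions_from_df(df, fpath))
    return out


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def save_bundle(
    records: dict,
    path: str | Path,
    *,
    validate: bool = True,
) -> dict:
    """Write typed records as canonical CSVs plus a JSON manifest.

    ``records`` uses the same keys :func:`load_bundle` returns.  File names
    encode kind and HTL temperature (e.g. ``tga_300.csv``).  Returns the
    manifest dict (also written to ``manifest.json``).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    tables: list[dict] = []

    def _temp_tag(t: float) -> str:
        return f"{t:g}".replace(".", "p")

    for rec in records.get("thermograms", []):
        if validate:
            _raise_on_violations(rec.validate(), Path("thermogram"))
        name = f"tga_{_temp_tag(rec.htl_temperature_c)}.csv"
        _write_csv(
            pd.DataFrame(
                {
                    "temperature_c": rec.temperature_c,
                    "mass_pct": rec.mass_pct,
                    "htl_temperature_c": rec.htl_temperature_c,
                }
            ),
            path / name,
        )
        tables.append({"file": name, "kind": "thermogram"})

    by_temp: dict[float, list[IRSpectrumRaw]] = {}
    for rec in records.get("spectra", []):
        if validate:
            _raise_on_violations(rec.validate(), Path("spectrum"))
        by_temp.setdefault(rec.htl_temperature_c, []).append(rec)
    for temp, reps in by_temp.items():
        name = f"ftir_{_temp_tag(temp)}.csv"
        frames = [
            pd.DataFrame(
                {
                    "wavenumber_cm1": r.wavenumber_cm1,
                    "transmittance_pct": r.transmittance_pct,
                    "replicate_id": r.replicate_id,
                    "htl_temperature_c": r.htl_temperature_c,
                }
            )
            for r in sorted(reps, key=lambda r: r.replicate_id)
        ]
        _write_csv(pd.concat(frames, ignore_index=True), path / name)
        tables.append({"file": name, "kind": "spectrum"})

    for rec in records.get("gcms_tables", []):
        if validate:
            _raise_on_violations(rec.validate(), Path("gcms"))
        name = f"gcms_{_temp_tag(rec.htl_temperature_c)}.csv"
        _write_csv(
            pd.DataFrame(
                {
                    "compound": [r.compound_name for r in rec.rows],
                    "group": [r.group for r in rec.rows],
                    "proportion_pct": [r.proportion_pct for r in rec.rows],
                    "detected": [r.detected for r in rec.rows],
                    "htl_temperature_c": rec.htl_temperature_c,
                }
            ),
            path / name,
        )
        tables.append({"file": name, "kind": "gcms"})

    comps = records.get("compositions")
    if comps is not None:
        rows = []
        for temp, cv in comps:
            if validate:
                _raise_on_violations(cv.validate(), Path("composition"))
            row = {"htl_temperature_c": temp}
            row.update(cv.as_dict())
            rows.append(row)
        name = "compositions.csv"
        _write_csv(pd.DataFrame(rows, columns=list(TABLE_SCHEMAS["composition"])), path / name)
        tables.append({"file": name, "kind": "composition"})

    manifest = {"tables": tables}
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
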