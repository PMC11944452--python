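"""Evaluation metrics and the interpolation-based reference protocol.

No measured data exist at the intermediate HTL temperatures, so references
there are built by linear interpolation between the two bracketing anchor
conditions.  Generated / predicted vectors are then scored against those
references with MAE, R² and the Pearson correlation, all computed
elementwise across the vector's components (each spectral point or group
fraction is one observation).  A one-dimensional Wasserstein-1 distance
audits distribution shifts (e.g. information lost in resampling).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import wasserstein_distance

from .datatypes import CompositionVector, DomainError

__all__ = [
    "MetricRow",
    "linear_interpolate",
    "mae",
    "r_squared",
    "pearson",
    "wasserstein1",
    "evaluate_generation",
    "evaluate_prediction",
    "make_report",
]


@dataclass
class MetricRow:
    """One evaluation row: a temperature and its MAE / R² / Pearson scores."""

    temperature_c: float
    mae: float
    r2: float
    pearson: float


def linear_interpolate(
    x1: float,
    y1: np.ndarray | Sequence[float],
    x2: float,
    y2: np.ndarray | Sequence[float],
    x: float,
) -> np.ndarray:
    """Elementwise linear interpolation y1 + (x-x1)/(x2-x1) · (y2-y1)."""
    if x1 == x2:
        raise ValueError("linear_interpolate: degenerate interval (x1 == x2)")
    lo, hi = min(x1, x2), max(x1, x2)
    if not (lo <= x <= hi):
        raise DomainError(f"linear_interpolate: x={x} outside [{lo}, {hi}]")
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if y1.shape != y2.shape:
        raise ValueError("linear_interpolate: y1 and y2 shapes differ")
    t = (x - x1) / (x2 - x1)
    return y1 + t * (y2 - y1)


def _pair(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("metric: vector lengths differ")
    if y.size == 0:
        raise ValueError("metric: empty vectors")
    return y, yhat


def mae(y, yhat) -> float:
    """Mean absolute error (1/n) Σ|yᵢ − ŷᵢ|."""
    y, yhat = _pair(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


def r_squared(y, yhat) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot (may be negative)."""
    y, yhat = _pair(y, yhat)
    if y.size < 2:
        raise ValueError("r_squared: need at least 2 observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("r_squared: y is constant (undefined denominator)")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def pearson(y, yhat) -> float:
    """Pearson correlation Cov(y, ŷ)/(σ_y σ_ŷ), population moments."""
    y, yhat = _pair(y, yhat)
    if y.size < 2:
        raise ValueError("pearson: need at least 2 observations")
    yc = y - y.mean()
    hc = yhat - yhat.mean()
    denom = np.sqrt(np.mean(yc**2)) * np.sqrt(np.mean(hc**2))
    if denom == 0.0:
        raise ValueError("pearson: zero variance (undefined correlation)")
    return float(np.mean(yc * hc) / denom)


def wasserstein1(p_samples, q_samples) -> float:
    """W₁ between the empirical distributions of two 1-D samples.

    For equal sizes this is the mean absolute difference of the sorted
    samples; for unequal sizes the ECDF-difference integral (delegated to
    scipy's optimal-transport routine).
    """
    p = np.asarray(p_samples, dtype=float).ravel()
    q = np.asarray(q_samples, dtype=float).ravel()
    if p.size == 0 or q.size == 0:
        raise ValueError("wasserstein1: empty sample")
    if p.size == q.size:
        return float(np.mean(np.abs(np.sort(p) - np.sort(q))))
    return float(wasserstein_distance(p, q))


def _bracketing_anchors(temp: float, anchor_temps: Sequence[float]) -> tuple[float, float]:
    anchors = sorted(anchor_temps)
    for lo, hi in zip(anchors[:-1], anchors[1:]):
        if lo <= temp <= hi:
            return lo, hi
    raise DomainError(
        f"temperature {temp} °C is not bracketed by anchors {anchors}"
    )


def evaluate_generation(
    generated: Mapping[float, np.ndarray],
    anchors: Mapping[float, np.ndarray],
    temps: Sequence[float] | None = None,
) -> list[MetricRow]:
    """Score generated vectors against interpolated anchor references.

    For each requested temperature the reference is the linear
    interpolation between the nearest bracketing anchor vectors; the row
    carries MAE / R² / Pearson over the vector's elements.
    """
    temps = sorted(generated.keys()) if temps is None else list(temps)
    rows = []
    for t in temps:
        lo, hi = _bracketing_anchors(t, list(anchors.keys()))
        ref = linear_interpolate(lo, anchors[lo], hi, anchors[hi], t)
        gen = np.asarray(generated[t], dtype=float).ravel()
        rows.append(
            MetricRow(
                temperature_c=float(t),
                mae=mae(ref, gen),
                r2=r_squared(ref, gen),
                pearson=pearson(ref, gen),
            )
        )
    return rows


def evaluate_prediction(
    predictions: Mapping[float, CompositionVector],
    references: Mapping[float, CompositionVector],
) -> list[MetricRow]:
    """Score predicted compositions against references, per temperature."""
    if set(predictions.keys()) != set(references.keys()):
        raise ValueError(
            "evaluate_prediction: prediction and reference temperature keys differ"
        )
    rows = []
    for t in sorted(predictions.keys()):
        p = predictions[t].fractions
        r = references[t].fractions
        try:
            pr = pearson(r, p)
        except ValueError:  # constant prediction: correlation undefined
            pr = float("nan")
        rows.append(
            MetricRow(
                temperature_c=float(t),
                mae=mae(r, p),
                r2=r_squared(r, p),
                pearson=pr,
            )
        )
    return rows


def _rows_frame(rows: Sequence[MetricRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "temperature_c": r.temperature_c,
                "mae": r.mae,
                "r2": r.r2,
                "pearson": r.pearson,
            }
            for r in rows
        ],
        columns=["temperature_c", "mae", "r2", "pearson"],
    )


def make_report(
    generation_rows: Mapping[str, Sequence[MetricRow]],
    prediction_rows: Sequence[MetricRow],
    audit: Mapping[float, float],
    path: str | Path,
) -> list[Path]:
    """Write the evaluation tables (CSV) and a JSON summary; deterministic.

    ``generation_rows`` maps modality name → rows; ``audit`` maps anchor
    temperature → resampling Wasserstein-1 loss.  Returns written paths.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary: dict = {"generation": {}, "prediction": [], "tga_resampling_audit": {}}
    for modality, rows in sorted(generation_rows.items()):
        p = path / f"generation_{modality.lower()}.csv"
        _rows_frame(rows).to_csv(p, index=False, float_format="%.17g")
        written.append(p)
        summary["generation"][modality] = [vars(r) for r in rows]
    p = path / "prediction.csv"
    _rows_frame(prediction_rows).to_csv(p, index=False, float_format="%.17g")
    written.append(p)
    summary["prediction"] = [vars(r) for r in prediction_rows]
    p = path / "tga_resampling_audit.csv"
    pd.DataFrame(
        [{"temperature_c": t, "wasserstein1": w} for t, w in sorted(audit.items())],
        columns=["temperature_c", "wasserstein1"],
    ).to_csv(p, index=False, float_format="%.17g")
    written.append(p)
    summary["tga_resampling_audit"] = {str(t): w for t, w in sorted(audit.items())}
    p = path / "summary.json"
    p.write_text(json.dumps(summary, indent=2, sort_keys=True))
    written.append(p)
    return written
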