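"""Metric correctness against independent brute-force implementations."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lignosense.datatypes import CompositionVector, DomainError
from lignosense.evaluation import (
    evaluate_generation,
    evaluate_prediction,
    linear_interpolate,
    mae,
    make_report,
    pearson,
    r_squared,
    wasserstein1,
)

# -- independent oracles (naive loops, no numpy vectorization) ----------------


def mae_naive(y, yhat):
    total = 0.0
    for a, b in zip(y, yhat):
        total += abs(a - b)
    return total / len(y)


def r2_naive(y, yhat):
    ybar = sum(y) / len(y)
    ss_res = sum((a - b) ** 2 for a, b in zip(y, yhat))
    ss_tot = sum((a - ybar) ** 2 for a in y)
    return 1.0 - ss_res / ss_tot


def pearson_naive(y, yhat):
    n = len(y)
    my = sum(y) / n
    mh = sum(yhat) / n
    cov = sum((a - my) * (b - mh) for a, b in zip(y, yhat)) / n
    sy = (sum((a - my) ** 2 for a in y) / n) ** 0.5
    sh = (sum((b - mh) ** 2 for b in yhat) / n) ** 0.5
    return cov / (sy * sh)


def w1_exhaustive(p, q):
    """Minimal mean |aᵢ − b_π(i)| over all permutations (equal sizes, n ≤ 6)."""
    best = float("inf")
    for perm in itertools.permutations(range(len(q))):
        cost = sum(abs(p[i] - q[j]) for i, j in enumerate(perm)) / len(p)
        best = min(best, cost)
    return best


# -- hand-computed examples ----------------------------------------------------


@pytest.mark.parametrize(
    "fn,y,yhat,expected",
    [
        (mae, [0.0, 0.0], [1.0, -1.0], 1.0),
        (mae, [2.0], [5.0], 3.0),
        (r_squared, [1.0, 2.0, 3.0], [1.0, 2.0, 4.0], 0.5),
        (pearson, [1.0, 2.0, 3.0], [1.0, 3.0, 2.0], 0.5),
        (wasserstein1, [2.0], [5.0], 3.0),
        (wasserstein1, [0.0, 1.0], [0.0, 3.0], 1.0),
    ],
)
def test_metric_examples(fn, y, yhat, expected):
    assert fn(y, yhat) == pytest.approx(expected, abs=1e-12)


def test_metric_identities(rng):
    y = rng.normal(size=20)
    assert mae(y, y) == 0.0
    assert r_squared(y, y) == pytest.approx(1.0)
    assert pearson(y, y) == pytest.approx(1.0)
    assert pearson(y, -y) == pytest.approx(-1.0)
    assert wasserstein1(y, y) == 0.0
    # predicting the mean gives exactly R² = 0
    assert r_squared(y, np.full_like(y, y.mean())) == pytest.approx(0.0)


def test_metrics_match_bruteforce_on_random_pairs(rng):
    for _ in range(300):
        n = int(rng.integers(2, 40))
        y = rng.normal(size=n)
        yhat = y + rng.normal(scale=rng.uniform(0.01, 2.0), size=n)
        assert mae(y, yhat) == pytest.approx(mae_naive(y, yhat), abs=1e-9)
        assert r_squared(y, yhat) == pytest.approx(r2_naive(y, yhat), abs=1e-9)
        assert pearson(y, yhat) == pytest.approx(pearson_naive(y, yhat), abs=1e-9)


def test_wasserstein_matches_exhaustive_matching(rng):
    for _ in range(100):
        n = int(rng.integers(1, 7))
        p = rng.normal(size=n)
        q = rng.normal(size=n)
        assert wasserstein1(p, q) == pytest.approx(w1_exhaustive(p, q), abs=1e-9)


def test_wasserstein_unequal_sizes_and_symmetry(rng):
    p = rng.normal(size=17)
    q = rng.normal(size=5)
    assert wasserstein1(p, q) == pytest.approx(wasserstein1(q, p), abs=1e-12)
    # triangle inequality on sampled triples
    for _ in range(20):
        a, b, c = (rng.normal(size=8) for _ in range(3))
        assert wasserstein1(a, c) <= wasserstein1(a, b) + wasserstein1(b, c) + 1e-12


@given(
    scale=st.floats(0.1, 10.0),
    shift=st.floats(-5.0, 5.0),
)
@settings(max_examples=50, deadline=None)
def test_pearson_invariant_under_positive_affine(scale, shift):
    rng = np.random.default_rng(7)
    y = rng.normal(size=15)
    yhat = rng.normal(size=15)
    base = pearson(y, yhat)
    assert pearson(y, scale * yhat + shift) == pytest.approx(base, abs=1e-8)


def test_r_squared_never_exceeds_one(rng):
    for _ in range(100):
        y = rng.normal(size=10)
        yhat = rng.normal(size=10)
        assert r_squared(y, yhat) <= 1.0


def test_metric_error_conditions():
    with pytest.raises(ValueError):
        mae([1.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        r_squared([3.0, 3.0], [1.0, 2.0])  # constant y
    with pytest.raises(ValueError):
        pearson([1.0, 2.0], [5.0, 5.0])  # zero variance
    with pytest.raises(ValueError):
        wasserstein1([], [1.0])


# -- interpolation --------------------------------------------------------------


def test_linear_interpolate_identities():
    y1, y2 = np.array([0.2]), np.array([0.4])
    assert linear_interpolate(250, y1, 300, y2, 250) == pytest.approx([0.2])
    assert linear_interpolate(250, y1, 300, y2, 275) == pytest.approx([0.3])
    assert linear_interpolate(250, y1, 300, y2, 260) == pytest.approx([0.24])


def test_linear_interpolate_errors():
    y = np.array([1.0])
    with pytest.raises(ValueError):
        linear_interpolate(250, y, 250, y, 250)
    with pytest.raises(DomainError):
        linear_interpolate(250, y, 300, y, 310)


# -- evaluation protocols -------------------------------------------------------


def test_evaluate_generation_perfect_and_offset(rng):
    anchors = {250.0: rng.normal(size=30), 300.0: rng.normal(size=30)}
    ref260 = linear_interpolate(250, anchors[250.0], 300, anchors[300.0], 260)
    rows = evaluate_generation({260.0: ref260}, anchors, [260.0])
    assert rows[0].mae == pytest.approx(0.0, abs=1e-12)
    assert rows[0].r2 == pytest.approx(1.0)
    assert rows[0].pearson == pytest.approx(1.0)
    # constant offset: mae = c, pearson stays 1
    rows = evaluate_generation({260.0: ref260 + 0.5}, anchors, [260.0])
    assert rows[0].mae == pytest.approx(0.5, abs=1e-6)
    assert rows[0].pearson == pytest.approx(1.0, abs=1e-6)


def test_evaluate_generation_unbracketed_temp_raises(rng):
    anchors = {250.0: rng.normal(size=5), 300.0: rng.normal(size=5)}
    with pytest.raises(DomainError):
        evaluate_generation({310.0: rng.normal(size=5)}, anchors, [310.0])


def test_evaluate_prediction_uniform_vs_reference(rng):
    f = rng.dirichlet(np.ones(10))
    ref = {300.0: CompositionVector(f)}
    uni = {300.0: CompositionVector(np.full(10, 0.1))}
    rows = evaluate_prediction(uni, ref)
    assert rows[0].mae == pytest.approx(np.mean(np.abs(f - 0.1)), abs=1e-9)
    assert np.isnan(rows[0].pearson)  # constant prediction: undefined correlation
    with pytest.raises(ValueError):
        evaluate_prediction(uni, {350.0: ref[300.0]})


def test_make_report_deterministic(tmp_path, rng):
    from lignosense.evaluation import MetricRow

    rows = {"TGA": [MetricRow(260.0, 0.01, 0.99, 0.995)]}
    pred = [MetricRow(260.0, 0.02, 0.9, 0.95)]
    audit = {250.0: 1.5e-3}
    w1 = make_report(rows, pred, audit, tmp_path / "a")
    w2 = make_report(rows, pred, audit, tmp_path / "b")
    for p1, p2 in zip(w1, w2):
        assert p1.read_bytes() == p2.read_bytes()
    names = {p.name for p in w1}
    assert {"generation_tga.csv", "prediction.csv", "tga_resampling_audit.csv",
            "summary.json"} <= names
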