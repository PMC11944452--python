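"""TGA resampling, FT-IR log transform and GC-MS closure."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lignosense.datatypes import (
    CoverageError,
    DerivativeRow,
    DerivativeTable,
    IRSpectrumRaw,
    ThermogramRaw,
    ValidationError,
    ftir_wavenumber_grid,
)
from lignosense.preprocessing import (
    PreprocessConfig,
    aggregate_gcms,
    clip_resample_tga,
    preprocess_ftir,
    preprocessing_information_loss,
)
from lignosense.synthetic import SimulatorParams, simulate_tga_raw


def _thermo(t, m, htl=300.0):
    return ThermogramRaw(temperature_c=t, mass_pct=m, htl_temperature_c=htl)


# -- TGA -----------------------------------------------------------------------


def test_resample_constant_mass_gives_constant_bins():
    t = np.arange(39.0, 761.5, 0.25)
    out = clip_resample_tga(_thermo(t, np.full_like(t, 100.0)))
    assert out.mass_pct.size == 721
    assert np.allclose(out.mass_pct, 100.0)


def test_resample_linear_mass_matches_bin_means():
    t = np.arange(39.6, 787.6, 0.034)
    w = 100.0 - 0.05 * t
    out = clip_resample_tga(_thermo(t, w))
    grid = np.arange(40, 761)
    # interior bins are full [t-0.5, t+0.5) windows; the two edge bins are
    # half-windows whose means sit 0.0125 off the line by construction
    interior = slice(1, -1)
    assert np.max(np.abs(out.mass_pct[interior] - (100.0 - 0.05 * grid[interior]))) < 0.002
    # brute-force bin means at a few bins
    for tb in (40, 123, 500, 760):
        mask = (t >= max(tb - 0.5, 40.0)) & (t < tb + 0.5) & (t <= 760.0)
        assert out.mass_pct[tb - 40] == pytest.approx(w[mask].mean(), abs=1e-9)


def test_resample_default_window_is_721_bins(default_params):
    raw = simulate_tga_raw(300, default_params, seed=0)
    out = clip_resample_tga(raw)
    assert out.mass_pct.size == 721
    assert out.grid_start_c == 40 and out.grid_end_c == 760


def test_resample_is_idempotent_on_binned_data(default_params):
    raw = simulate_tga_raw(300, default_params, seed=0)
    once = clip_resample_tga(raw)
    again = clip_resample_tga(
        _thermo(once.grid_c, once.mass_pct), PreprocessConfig()
    )
    assert np.max(np.abs(again.mass_pct - once.mass_pct)) < 1e-12


def test_resample_fills_empty_bins_by_interpolation():
    # sparse record: nothing between 100 and 200 °C
    t = np.concatenate([np.arange(39.0, 100.0, 0.5), np.arange(200.0, 761.0, 0.5)])
    m = np.where(t < 150, 100.0, 50.0)
    out = clip_resample_tga(_thermo(t, m))
    assert np.all(np.isfinite(out.mass_pct))
    mid = out.mass_pct[(out.grid_c > 100) & (out.grid_c < 200)]
    assert np.all((mid >= 50.0) & (mid <= 100.0))


def test_resample_requires_window_coverage():
    t = np.arange(100.0, 500.0, 0.5)
    with pytest.raises(CoverageError):
        clip_resample_tga(_thermo(t, np.full_like(t, 90.0)))


# -- FT-IR (log-transform path) -------------------------------------------------


def _replicates(values):
    grid = ftir_wavenumber_grid()
    return [
        IRSpectrumRaw(
            wavenumber_cm1=grid,
            transmittance_pct=np.full(grid.size, v),
            replicate_id=i + 1,
            htl_temperature_c=300.0,
        )
        for i, v in enumerate(values)
    ]


@pytest.mark.parametrize(
    "mean_pct,expected",
    [
        (91.0, 1.0),     # log10(101 - 91) = log10(10)
        (100.0, 0.0),    # log10(1)
        (105.0, 0.0),    # clipped to 100 first
        (1.0, 2.0),      # log10(100)
    ],
)
def test_ftir_transform_branches(mean_pct, expected):
    out = preprocess_ftir(_replicates([mean_pct] * 3))
    assert np.allclose(out.values, expected, atol=1e-12)


def test_ftir_replicate_averaging():
    out = preprocess_ftir(_replicates([88.0, 91.0, 94.0]))  # mean 91
    assert np.allclose(out.values, 1.0, atol=1e-12)


def test_ftir_output_bounded_for_random_transmittance(rng):
    grid = ftir_wavenumber_grid()
    reps = [
        IRSpectrumRaw(
            wavenumber_cm1=grid,
            transmittance_pct=rng.uniform(0.0, 110.0, size=grid.size),
            replicate_id=i + 1,
            htl_temperature_c=300.0,
        )
        for i in range(3)
    ]
    out = preprocess_ftir(reps)
    assert out.values.min() >= 0.0
    assert out.values.max() <= np.log10(101.0)


def test_ftir_off_grid_replicate_is_interpolated():
    grid = ftir_wavenumber_grid()
    coarse = np.linspace(grid[0], grid[-1], 500)
    rep = IRSpectrumRaw(
        wavenumber_cm1=coarse,
        transmittance_pct=np.full(500, 91.0),
        replicate_id=1,
        htl_temperature_c=300.0,
    )
    out = preprocess_ftir([rep])
    assert np.allclose(out.values, 1.0, atol=1e-9)


def test_ftir_empty_replicate_group_raises():
    with pytest.raises(ValueError):
        preprocess_ftir([])


# -- GC-MS -----------------------------------------------------------------------


def _table(rows):
    return DerivativeTable(
        rows=[DerivativeRow(f"c{i}", g, p, d) for i, (g, p, d) in enumerate(rows)],
        htl_temperature_c=300.0,
    )


def test_aggregate_other_closes_detected_shortfall():
    # detected total 91.16% -> Other = 0.0884
    rows = [("Syringyl", 45.58, True), ("Guaiacyl", 45.58, True), ("Alkanes", 5.0, False)]
    comp = aggregate_gcms(_table(rows))
    assert comp.fractions[-1] == pytest.approx(0.0884, abs=1e-9)
    assert comp.fractions.sum() == pytest.approx(1.0, abs=1e-12)


def test_aggregate_full_detection_gives_zero_other():
    rows = [("Syringyl", 60.0, True), ("Guaiacyl", 40.0, True)]
    comp = aggregate_gcms(_table(rows))
    assert comp.fractions[-1] == pytest.approx(0.0, abs=1e-9)


def test_aggregate_single_detected_group():
    rows = [("Cyclic", 50.0, True), ("Syringyl", 30.0, False)]
    comp = aggregate_gcms(_table(rows))
    d = comp.as_dict()
    assert d["Cyclic"] == pytest.approx(0.5)
    assert d["Other"] == pytest.approx(0.5)
    assert sum(v for k, v in d.items() if k not in ("Cyclic", "Other")) == 0.0


def test_aggregate_rejects_overfull_table():
    rows = [("Syringyl", 80.0, True), ("Guaiacyl", 30.0, True)]
    with pytest.raises(ValidationError):
        aggregate_gcms(_table(rows))


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None)
def test_aggregate_always_on_simplex(seed):
    from lignosense.synthetic import simulate_gcms_table

    table = simulate_gcms_table(250 + (seed % 151), SimulatorParams(), seed)
    comp = aggregate_gcms(table)
    assert comp.fractions.min() >= 0.0
    assert comp.fractions.sum() == pytest.approx(1.0, abs=1e-9)


# -- information-loss audit ------------------------------------------------------


def test_information_loss_zero_for_identical_distributions():
    t = np.arange(40.0, 760.0 + 1e-9, 1.0)
    m = np.linspace(100.0, 45.0, t.size)
    rec = _thermo(t, m)
    out = clip_resample_tga(rec)
    assert preprocessing_information_loss(rec, out) == pytest.approx(0.0, abs=1e-12)


def test_information_loss_hand_example():
    from lignosense.evaluation import wasserstein1

    assert wasserstein1([0.2, 0.4], [0.2, 0.6]) == pytest.approx(0.1)


def test_information_loss_small_on_noiseless_simulation(default_params):
    raw = simulate_tga_raw(300, default_params.noiseless(), seed=0)
    out = clip_resample_tga(raw)
    assert preprocessing_information_loss(raw, out) < 5e-3


def test_information_loss_vanishes_as_spacing_approaches_grid():
    # bin-center-aligned raw grids: at 1 °C spacing resampling is lossless
    losses = []
    for spacing in (0.034, 0.5, 1.0):
        t = np.arange(40.0, 760.0 + 2 * spacing, spacing)
        m = 100.0 - 0.06 * t
        rec = _thermo(t, m)
        losses.append(preprocessing_information_loss(rec, clip_resample_tga(rec)))
    assert losses[0] > losses[1] > losses[2]
    assert losses[2] == pytest.approx(0.0, abs=1e-12)
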