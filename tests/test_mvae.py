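"""Latent fusion, reparameterization, losses and predictor mechanics."""

from __future__ import annotations

import numpy as np
import pytest

from lignosense.datatypes import StateError, ValidationError
from lignosense.generators import TrainConfig
from lignosense.mvae import (
    GaussianLatent,
    LossBreakdown,
    MVAEMoE,
    MVAEMoEConfig,
    compute_losses,
    decode_modality,
    encode_modality,
    fuse_experts,
    kl_divergence,
    predict_composition,
    predict_gcms,
    reparameterize,
    train_predictor,
)


@pytest.fixture(scope="module")
def model():
    return MVAEMoE(MVAEMoEConfig(seed=0))


@pytest.fixture(scope="module")
def short_trained(anchor_triplets):
    """A briefly trained predictor shared by the mechanics tests."""
    cfg = TrainConfig(epochs=10, seed=0)
    return train_predictor(anchor_triplets, cfg, MVAEMoEConfig(seed=0))


# -- encoding -------------------------------------------------------------------


def test_encode_modality_shapes_and_determinism(model, anchor_triplets):
    x = anchor_triplets[0].tga.mass_pct / 100.0
    g1 = encode_modality(x, "TGA", model)
    g2 = encode_modality(x, "TGA", model)
    assert g1.mu.shape == (16,) and g1.logvar.shape == (16,)
    assert np.isfinite(g1.mu).all() and np.isfinite(g1.logvar).all()
    assert np.array_equal(g1.mu, g2.mu)
    with pytest.raises(ValidationError):
        encode_modality(np.ones(10), "TGA", model)


# -- product-of-experts fusion ----------------------------------------------------


def test_fusion_closed_forms():
    unit = GaussianLatent(np.zeros(4), np.zeros(4))
    # one unit expert + prior: precision 2 -> var 1/2
    f1 = fuse_experts([unit])
    assert np.allclose(np.exp(f1.logvar), 0.5, atol=1e-12)
    assert np.allclose(f1.mu, 0.0)
    # two unit experts + prior: var 1/3
    f2 = fuse_experts([unit, GaussianLatent(np.zeros(4), np.zeros(4))])
    assert np.allclose(np.exp(f2.logvar), 1.0 / 3.0, atol=1e-12)


def test_fusion_symmetric_means_cancel():
    a = GaussianLatent(np.full(3, 0.7), np.full(3, -0.2))
    b = GaussianLatent(np.full(3, -0.7), np.full(3, -0.2))
    f = fuse_experts([a, b])
    assert np.allclose(f.mu, 0.0, atol=1e-12)


def test_fusion_precision_weighted_mean():
    # hand-computed: mu = (1*e^0 + 2*e^1)/(1 + e^0 + e^1)
    a = GaussianLatent(np.array([1.0]), np.array([0.0]))
    b = GaussianLatent(np.array([2.0]), np.array([-1.0]))
    f = fuse_experts([a, b])
    expected = (1.0 + 2.0 * np.e) / (1.0 + 1.0 + np.e)
    assert f.mu[0] == pytest.approx(expected, abs=1e-12)
    with pytest.raises(ValueError):
        fuse_experts([])


# -- reparameterization -----------------------------------------------------------


def test_reparameterize_deterministic_limit_and_unit_case():
    g = GaussianLatent(np.array([0.3, -0.2]), np.array([0.0, 0.0]))
    assert np.array_equal(reparameterize(g, np.zeros(2)), g.mu)
    g1 = GaussianLatent(np.array([0.0]), np.array([0.0]))
    assert reparameterize(g1, np.array([1.0]))[0] == pytest.approx(1.0)
    with pytest.raises(ValidationError):
        reparameterize(g, np.zeros(3))


def test_reparameterize_monte_carlo_mean(rng):
    g = GaussianLatent(np.array([0.5]), np.array([np.log(0.25)]))
    n = 100_000
    draws = np.array([reparameterize(g, e)[0] for e in rng.standard_normal((n, 1))])
    assert draws.mean() == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(n))
    assert draws.std() == pytest.approx(0.5, rel=0.02)


# -- KL divergence -----------------------------------------------------------------


@pytest.mark.parametrize(
    "mu,logvar,expected",
    [
        (0.0, 0.0, 0.0),
        (1.0, 0.0, 0.5),
        (0.0, 1.0, (np.e - 2.0) / 2.0),
    ],
)
def test_kl_closed_forms(mu, logvar, expected):
    assert kl_divergence(np.array([mu]), np.array([logvar])) == pytest.approx(
        expected, abs=1e-12
    )


def test_kl_matches_rearranged_form(rng):
    mu = rng.normal(size=(6, 16))
    logvar = rng.normal(size=(6, 16))
    alt = np.mean(
        0.5 * np.sum(mu**2 + np.exp(logvar) - 1.0 - logvar, axis=1)
    )
    assert kl_divergence(mu, logvar) == pytest.approx(alt, abs=1e-12)


def test_kl_nonnegative_on_random_inputs(rng):
    for _ in range(50):
        assert kl_divergence(rng.normal(size=8), rng.normal(size=8)) >= 0.0


# -- decoding and MoE head ----------------------------------------------------------


def test_decode_shapes_and_determinism(model, rng):
    z = rng.normal(size=16)
    assert decode_modality(z, "TGA", model).shape == (721,)
    assert decode_modality(z, "FTIR", model).shape == (3476,)
    assert np.array_equal(
        decode_modality(z, "TGA", model), decode_modality(z, "TGA", model)
    )


def test_moe_output_is_convex_mixture(model, rng):
    z = rng.normal(size=(5, 16))
    comp, gate = predict_composition(z, model)
    assert comp.shape == (5, 10) and gate.shape == (5, model.cfg.n_experts)
    assert np.allclose(gate.sum(axis=1), 1.0, atol=1e-6)
    assert np.allclose(comp.sum(axis=1), 1.0, atol=1e-6)
    assert comp.min() >= 0.0
    # hand mixture: recompute from expert outputs and gate
    outs = np.stack([ex.forward(z.astype(np.float32)) for ex in model.experts], axis=1)
    manual = np.einsum("be,bej->bj", gate, outs)
    assert np.allclose(comp, manual, atol=1e-6)


def test_single_expert_moe_passthrough(rng):
    m1 = MVAEMoE(MVAEMoEConfig(n_experts=1, seed=0))
    z = rng.normal(size=(1, 16))
    comp, gate = predict_composition(z, m1)
    assert gate == pytest.approx(1.0)
    assert np.allclose(comp, m1.experts[0].forward(z.astype(np.float32))[0], atol=1e-7)


# -- losses --------------------------------------------------------------------------


def test_loss_breakdown_additivity_and_finiteness(model, anchor_triplets):
    b = compute_losses(anchor_triplets, model)
    assert b.total == pytest.approx(b.recon_tga + b.recon_ftir + b.pred + b.kl, abs=1e-9)
    assert b.kl >= 0.0
    assert min(b.recon_tga, b.recon_ftir, b.pred) >= 0.0
    assert np.isfinite(b.total)


def test_losses_reject_empty_or_invalid_batches(model, anchor_triplets):
    from lignosense.datatypes import CompositionVector, SampleTriplet

    with pytest.raises(ValueError):
        compute_losses([], model)
    bad = SampleTriplet(
        htl_temperature_c=300.0,
        tga=anchor_triplets[0].tga,
        ftir=anchor_triplets[0].ftir,
        gcms=CompositionVector(np.full(10, 0.05)),
    )
    with pytest.raises(ValidationError):
        compute_losses([bad], model)


# -- training & inference -------------------------------------------------------------


def test_train_history_mechanics(short_trained):
    _, history = short_trained
    assert len(history) == 10
    for b in history:
        assert isinstance(b, LossBreakdown)
        assert b.total == pytest.approx(
            b.recon_tga + b.recon_ftir + b.pred + b.kl, abs=1e-9
        )
    assert history[-1].total < history[0].total


def test_training_seed_determinism(anchor_triplets):
    cfg = TrainConfig(epochs=4, seed=9)
    h1 = train_predictor(anchor_triplets, cfg, MVAEMoEConfig(seed=9))[1]
    h2 = train_predictor(anchor_triplets, cfg, MVAEMoEConfig(seed=9))[1]
    assert [b.total for b in h1] == [b.total for b in h2]


def test_training_requires_two_triplets(anchor_triplets):
    with pytest.raises(ValueError):
        train_predictor(anchor_triplets[:1], TrainConfig(epochs=2), MVAEMoEConfig())


def test_predict_gcms_simplex_and_determinism(short_trained, anchor_triplets):
    mdl, _ = short_trained
    t = anchor_triplets[0]
    c1 = predict_gcms(mdl, t.tga, t.ftir)
    c2 = predict_gcms(mdl, t.tga, t.ftir)
    assert np.array_equal(c1.fractions, c2.fractions)
    assert c1.validate() == []


def test_predict_requires_trained_model(model, anchor_triplets):
    t = anchor_triplets[0]
    with pytest.raises(StateError):
        predict_gcms(model, t.tga, t.ftir)


def test_model_save_load_roundtrip(tmp_path, short_trained, anchor_triplets):
    mdl, _ = short_trained
    mdl.save(tmp_path / "m")
    back = MVAEMoE.load(tmp_path / "m")
    t = anchor_triplets[0]
    assert np.array_equal(
        predict_gcms(mdl, t.tga, t.ftir).fractions,
        predict_gcms(back, t.tga, t.ftir).fractions,
    )


def test_concat_fusion_alternative_trains(anchor_triplets):
    cfg = TrainConfig(epochs=3, seed=0)
    mdl, hist = train_predictor(
        anchor_triplets, cfg, MVAEMoEConfig(fusion="concat", seed=0)
    )
    assert len(hist) == 3
    t = anchor_triplets[0]
    assert predict_gcms(mdl, t.tga, t.ftir).validate() == []
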