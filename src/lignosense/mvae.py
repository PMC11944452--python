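"""Multimodal VAE + mixture-of-experts GC-MS prediction model.

Two convolutional encoders map the TGA vector (mass fraction, 721 points)
and the FT-IR vector (log-absorbance, 3476 points) to diagonal-Gaussian
posteriors (μ, log σ²).  The posteriors are fused into a shared latent by a
product of experts that includes a standard-normal prior expert:

    precision = 1 + Σᵢ 1/σᵢ²,   μ_fused = (Σᵢ μᵢ/σᵢ²) / precision,

so the fused log-variance is −log(precision).  A latent sample
``z = μ + σ ⊙ ε`` (reparameterization trick) feeds two decoders that
reconstruct each modality and a mixture-of-experts head that predicts the
10-dimensional GC-MS group composition: each expert emits a simplex point
(softmax) and a gating network mixes them convexly, so the prediction is
always on the simplex.

Training minimizes the unweighted composite loss

    L_total = L_recon^TGA + L_recon^FT-IR + L_pred + L_KL,

with sample-indexed MSE data terms ``(1/n) Σᵢ ‖yᵢ − ŷᵢ‖²`` (squared error
summed over a vector's components, averaged over the n samples) and the
Gaussian KL ``−½ Σ (1 + log σ² − μ² − σ²)`` summed over latent dimensions
and averaged over the batch.  The matching sum-over-dimensions convention
in the data and KL terms is the standard VAE balance: dividing the
reconstruction by the vector length instead would let the KL overwhelm
the data terms and collapse the posterior to the prior within the short
fixed training budget.  Inference is deterministic: the fused posterior
mean is used, no sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import json
from pathlib import Path

import numpy as np

from . import nn
from .datatypes import (
    CompositionVector,
    IRPreprocessed,
    SampleTriplet,
    StateError,
    ThermogramResampled,
    ValidationError,
    validate_triplet,
)
from .generators import TrainConfig, TrainHistory, modality_target

__all__ = [
    "GaussianLatent",
    "MVAEMoEConfig",
    "LossBreakdown",
    "MVAEMoE",
    "encode_modality",
    "fuse_experts",
    "reparameterize",
    "decode_modality",
    "predict_composition",
    "compute_losses",
    "train_predictor",
    "predict_gcms",
    "kl_divergence",
    "sample_mse",
]

_LV_CLIP = 12.0  # |log variance| bound for numerical stability


@dataclass
class GaussianLatent:
    """(μ, log σ²) of a diagonal-Gaussian latent posterior; batched or flat."""

    mu: np.ndarray
    logvar: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.logvar = np.asarray(self.logvar, dtype=float)
        if self.mu.shape != self.logvar.shape:
            raise ValidationError("GaussianLatent: mu and logvar shapes differ")


@dataclass
class MVAEMoEConfig:
    tga_dim: int = 721
    ftir_dim: int = 3476
    gcms_dim: int = 10
    latent_dim: int = 16
    encoder_conv_channels: tuple[int, ...] = (16, 32)
    encoder_pool: int = 4  # average-pool window after each encoder conv block
    encoder_hidden: int = 256
    decoder_hidden: int = 1024
    n_experts: int = 4
    expert_hidden: int = 64
    gating_hidden: int = 32
    fusion: str = "poe"  # "poe" (product of experts + prior) or "concat"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.tga_dim, self.ftir_dim, self.gcms_dim, self.latent_dim,
               self.encoder_hidden, self.n_experts, self.expert_hidden,
               self.gating_hidden) <= 0:
            raise ValidationError("MVAEMoEConfig: all dimensions must be positive")
        if self.fusion not in ("poe", "concat"):
            raise ValidationError("MVAEMoEConfig: fusion must be 'poe' or 'concat'")


@dataclass
class LossBreakdown:
    recon_tga: float
    recon_ftir: float
    pred: float
    kl: float
    total: float

    @classmethod
    def make(cls, recon_tga: float, recon_ftir: float, pred: float, kl: float):
        return cls(recon_tga, recon_ftir, pred, kl, recon_tga + recon_ftir + pred + kl)


def sample_mse(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Sample-indexed MSE: (1/n) Σᵢ ‖yᵢ − ŷᵢ‖², with gradient wrt ``pred``.

    Squared error is summed over each vector's components and averaged
    over the n samples, mirroring the latent KL's sum-over-dimensions.
    """
    pred = np.atleast_2d(pred)
    target = np.atleast_2d(target)
    diff = pred - target
    n = diff.shape[0]
    return float(np.sum(diff**2) / n), 2.0 * diff / n


def kl_divergence(mu: np.ndarray, logvar: np.ndarray) -> float:
    """Gaussian-vs-N(0, I) KL: −½ Σ(1 + log σ² − μ² − σ²), batch-averaged."""
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    logvar = np.atleast_2d(np.asarray(logvar, dtype=float))
    per_sample = -0.5 * np.sum(1.0 + logvar - mu**2 - np.exp(logvar), axis=1)
    return float(np.mean(per_sample))


class MVAEMoE:
    """The full predictor; all sub-networks built with seeded initialization."""

    def __init__(self, cfg: MVAEMoEConfig | None = None, seed: int | None = None) -> None:
        self.cfg = cfg or MVAEMoEConfig()
        seed = self.cfg.seed if seed is None else int(seed)
        ss = np.random.SeedSequence(seed)
        rngs = iter(np.random.default_rng(s) for s in ss.spawn(64))
        c = self.cfg

        def encoder(dim: int) -> nn.Sequential:
            layers: list[nn.Layer] = []
            cin, length = 1, dim
            for cout in c.encoder_conv_channels:
                layers.append(nn.Conv1d(cin, cout, rng=next(rngs)))
                layers.append(nn.ReLU())
                if c.encoder_pool > 1:
                    layers.append(nn.AvgPool1d(c.encoder_pool))
                    length = -(-length // c.encoder_pool)
                cin = cout
            layers.append(nn.Flatten())
            layers.append(nn.Linear(cin * length, c.encoder_hidden, rng=next(rngs)))
            layers.append(nn.ReLU())
            layers.append(nn.Linear(c.encoder_hidden, 2 * c.latent_dim, rng=next(rngs)))
            return nn.Sequential(layers)

        def decoder(dim: int) -> nn.Sequential:
            return nn.Sequential(
                [
                    nn.Linear(c.latent_dim, c.decoder_hidden, rng=next(rngs)),
                    nn.ReLU(),
                    nn.Linear(c.decoder_hidden, dim, rng=next(rngs)),
                ]
            )

        self.enc_tga = encoder(c.tga_dim)
        self.enc_ftir = encoder(c.ftir_dim)
        self.dec_tga = decoder(c.tga_dim)
        self.dec_ftir = decoder(c.ftir_dim)
        self.experts = [
            nn.Sequential(
                [
                    nn.Linear(c.latent_dim, c.expert_hidden, rng=next(rngs)),
                    nn.ReLU(),
                    nn.Linear(c.expert_hidden, c.gcms_dim, rng=next(rngs)),
                    nn.Softmax(),
                ]
            )
            for _ in range(c.n_experts)
        ]
        self.gating = nn.Sequential(
            [
                nn.Linear(c.latent_dim, c.gating_hidden, rng=next(rngs)),
                nn.ReLU(),
                nn.Linear(c.gating_hidden, c.n_experts, rng=next(rngs)),
                nn.Softmax(),
            ]
        )
        self.fuse_net = (
            nn.Sequential([nn.Linear(4 * c.latent_dim, 2 * c.latent_dim, rng=next(rngs))])
            if c.fusion == "concat"
            else None
        )
        # per-feature z-scoring of encoder inputs, fitted on the training set;
        # identity until then.  Decoders always reconstruct the raw scale.
        self.norm: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self.trained = False

    def normalize(self, x: np.ndarray, modality: str) -> np.ndarray:
        if modality not in self.norm:
            return x
        mean, std = self.norm[modality]
        return (x - mean) / std

    def fit_normalization(self, xt: np.ndarray, xf: np.ndarray) -> None:
        for key, arr in (("TGA", xt), ("FTIR", xf)):
            std = arr.std(axis=0)
            self.norm[key] = (arr.mean(axis=0), np.maximum(std, 1e-6))

    # -- sub-network surfaces -------------------------------------------------

    def all_nets(self) -> list[nn.Sequential]:
        nets = [self.enc_tga, self.enc_ftir, self.dec_tga, self.dec_ftir,
                self.gating, *self.experts]
        if self.fuse_net is not None:
            nets.append(self.fuse_net)
        return nets

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays: dict[str, np.ndarray] = {}
        for i, net in enumerate(self.all_nets()):
            for k, v in net.state_arrays().items():
                arrays[f"net{i}.{k}"] = v
        for key, (mean, std) in self.norm.items():
            arrays[f"norm.{key}.mean"] = mean
            arrays[f"norm.{key}.std"] = std
        np.savez(path / "weights.npz", **arrays)
        meta = {"config": vars(self.cfg).copy(), "trained": self.trained}
        meta["config"]["encoder_conv_channels"] = list(self.cfg.encoder_conv_channels)
        (path / "model.json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "MVAEMoE":
        path = Path(path)
        meta = json.loads((path / "model.json").read_text())
        cfg_d = meta["config"]
        cfg_d["encoder_conv_channels"] = tuple(cfg_d["encoder_conv_channels"])
        model = cls(MVAEMoEConfig(**cfg_d))
        with np.load(path / "weights.npz") as data:
            nets = model.all_nets()
            for i, net in enumerate(nets):
                prefix = f"net{i}."
                state = {
                    k[len(prefix):]: data[k] for k in data.files if k.startswith(prefix)
                }
                net.load_state_arrays(state)
            for key in ("TGA", "FTIR"):
                if f"norm.{key}.mean" in data.files:
                    model.norm[key] = (data[f"norm.{key}.mean"], data[f"norm.{key}.std"])
        model.trained = bool(meta["trained"])
        return model


# -- functional operations ----------------------------------------------------


def _split(h: np.ndarray, d: int) -> tuple[np.ndarray, np.ndarray]:
    return h[:, :d], np.clip(h[:, d:], -_LV_CLIP, _LV_CLIP)


def encode_modality(x: np.ndarray, modality: str, model: MVAEMoE) -> GaussianLatent:
    """Run one modality's encoder; returns the (μ, log σ²) posterior."""
    modality = modality.upper()
    dim = model.cfg.tga_dim if modality == "TGA" else model.cfg.ftir_dim
    enc = model.enc_tga if modality == "TGA" else model.enc_ftir
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != dim:
        raise ValidationError(f"encode_modality: {modality} input length {x.shape[1]} != {dim}")
    h = enc.forward(model.normalize(x, modality)[:, None, :], train=False)
    mu, lv = _split(h, model.cfg.latent_dim)
    if mu.shape[0] == 1:
        mu, lv = mu[0], lv[0]
    return GaussianLatent(mu, lv)


def fuse_experts(posteriors: Sequence[GaussianLatent]) -> GaussianLatent:
    """Product-of-experts fusion including a standard-normal prior expert.

    precision = 1 + Σ 1/σᵢ²;  μ = (Σ μᵢ/σᵢ²)/precision;  logvar = −log precision.
    """
    if len(posteriors) == 0:
        raise ValueError("fuse_experts: need at least one posterior")
    mus = [np.atleast_2d(p.mu) for p in posteriors]
    lvs = [np.atleast_2d(p.logvar) for p in posteriors]
    if len({m.shape for m in mus}) != 1:
        raise ValidationError("fuse_experts: posteriors have mismatched latent dims")
    precisions = [np.exp(-lv) for lv in lvs]
    p = 1.0 + sum(precisions)
    mu = sum(m * r for m, r in zip(mus, precisions)) / p
    lv = -np.log(p)
    if posteriors[0].mu.ndim == 1:
        return GaussianLatent(mu[0], lv[0])
    return GaussianLatent(mu, lv)


def reparameterize(g: GaussianLatent, noise: np.ndarray) -> np.ndarray:
    """z = μ + exp(logvar/2) ⊙ ε."""
    noise = np.asarray(noise, dtype=float)
    if noise.shape != g.mu.shape:
        raise ValidationError("reparameterize: noise shape != latent shape")
    return g.mu + np.exp(g.logvar / 2.0) * noise


def decode_modality(z: np.ndarray, modality: str, model: MVAEMoE) -> np.ndarray:
    """Reconstruct one modality vector from a latent point."""
    modality = modality.upper()
    dec = model.dec_tga if modality == "TGA" else model.dec_ftir
    flat = np.asarray(z, dtype=float).ndim == 1
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.shape[1] != model.cfg.latent_dim:
        raise ValidationError("decode_modality: latent length mismatch")
    out = dec.forward(z, train=False)
    return out[0] if flat else out


def predict_composition(
    z: np.ndarray, model: MVAEMoE
) -> tuple[np.ndarray, np.ndarray]:
    """MoE head: convex gate-weighted mixture of expert simplex points.

    Returns ``(composition, gate_weights)``; both rows sum to one.
    """
    flat = np.asarray(z, dtype=float).ndim == 1
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.shape[1] != model.cfg.latent_dim:
        raise ValidationError("predict_composition: latent length mismatch")
    gate = model.gating.forward(z, train=False)
    outs = np.stack([ex.forward(z, train=False) for ex in model.experts], axis=1)
    comp = np.einsum("be,bej->bj", gate, outs)
    if flat:
        return comp[0], gate[0]
    return comp, gate


# -- training ------------------------------------------------------------------


def _batch_arrays(batch: Sequence[SampleTriplet]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    xt = np.stack([modality_target(t, "TGA") for t in batch])
    xf = np.stack([modality_target(t, "FTIR") for t in batch])
    y = np.stack([modality_target(t, "GCMS") for t in batch])
    return xt, xf, y


def _fuse_forward(model: MVAEMoE, mu_t, lv_t, mu_f, lv_f):
    """Fusion forward pass; returns (muF, lvF, cache-for-backward)."""
    if model.cfg.fusion == "concat":
        h = np.concatenate([mu_t, lv_t, mu_f, lv_f], axis=1)
        out = model.fuse_net.forward(h, train=True)
        muF, lvF = _split(out, model.cfg.latent_dim)
        return muF, lvF, {"mode": "concat", "lvF_raw": out[:, model.cfg.latent_dim:]}
    r_t, r_f = np.exp(-lv_t), np.exp(-lv_f)
    p = 1.0 + r_t + r_f
    muF = (mu_t * r_t + mu_f * r_f) / p
    lvF = -np.log(p)
    return muF, lvF, {"mode": "poe", "r_t": r_t, "r_f": r_f, "p": p}


def _fuse_backward(model: MVAEMoE, cache, dmuF, dlvF, mu_t, mu_f, muF):
    if cache["mode"] == "concat":
        raw = cache["lvF_raw"]
        dlvF = dlvF * (np.abs(raw) < _LV_CLIP)
        g = np.concatenate([dmuF, dlvF], axis=1)
        gh = model.fuse_net.backward(g)
        d = model.cfg.latent_dim
        return gh[:, :d], gh[:, d:2*d], gh[:, 2*d:3*d], gh[:, 3*d:]
    r_t, r_f, p = cache["r_t"], cache["r_f"], cache["p"]
    dmu_t = dmuF * r_t / p
    dmu_f = dmuF * r_f / p
    dr_t = dmuF * (mu_t - muF) / p - dlvF / p
    dr_f = dmuF * (mu_f - muF) / p - dlvF / p
    return dmu_t, -r_t * dr_t, dmu_f, -r_f * dr_f


def _forward_backward(
    model: MVAEMoE,
    xt: np.ndarray,
    xf: np.ndarray,
    y: np.ndarray,
    noise: np.ndarray | None,
    train: bool,
) -> LossBreakdown:
    """One pass over a batch; accumulates gradients when ``train``."""
    B = xt.shape[0]
    d = model.cfg.latent_dim

    h_t = model.enc_tga.forward(model.normalize(xt, "TGA")[:, None, :], train=train)
    h_f = model.enc_ftir.forward(model.normalize(xf, "FTIR")[:, None, :], train=train)
    mu_t, lv_t = _split(h_t, d)
    mu_f, lv_f = _split(h_f, d)
    muF, lvF, fcache = _fuse_forward(model, mu_t, lv_t, mu_f, lv_f)

    eps = np.zeros_like(muF) if noise is None else noise
    sig = np.exp(lvF / 2.0)
    z = muF + sig * eps

    rec_t = model.dec_tga.forward(z, train=train)
    rec_f = model.dec_ftir.forward(z, train=train)
    gate = model.gating.forward(z, train=train)
    outs = np.stack([ex.forward(z, train=train) for ex in model.experts], axis=1)
    pred = np.einsum("be,bej->bj", gate, outs)

    loss_t, grad_t = sample_mse(rec_t, xt)
    loss_f, grad_f = sample_mse(rec_f, xf)
    loss_p, grad_p = sample_mse(pred, y)
    loss_kl = kl_divergence(muF, lvF)
    breakdown = LossBreakdown.make(loss_t, loss_f, loss_p, loss_kl)

    if not train:
        return breakdown

    dz = model.dec_tga.backward(grad_t)
    dz = dz + model.dec_ftir.backward(grad_f)
    for e, ex in enumerate(model.experts):
        dz = dz + ex.backward(gate[:, e, None] * grad_p)
    gate_up = np.einsum("bej,bj->be", outs, grad_p)
    dz = dz + model.gating.backward(gate_up)

    dmuF = dz + muF / B
    dlvF = dz * eps * 0.5 * sig + (np.exp(lvF) - 1.0) / (2.0 * B)

    dmu_t, dlv_t, dmu_f, dlv_f = _fuse_backward(model, fcache, dmuF, dlvF, mu_t, mu_f, muF)
    # clip gate on raw log-variances
    dlv_t = dlv_t * (np.abs(h_t[:, d:]) < _LV_CLIP)
    dlv_f = dlv_f * (np.abs(h_f[:, d:]) < _LV_CLIP)
    model.enc_tga.backward(np.concatenate([dmu_t, dlv_t], axis=1))
    model.enc_ftir.backward(np.concatenate([dmu_f, dlv_f], axis=1))
    return breakdown


def compute_losses(
    batch: Sequence[SampleTriplet],
    model: MVAEMoE,
    noise: np.ndarray | None = None,
) -> LossBreakdown:
    """Composite loss on a batch; ``noise=None`` uses the deterministic μ path.

    ``noise`` may be a fixed (batch, latent_dim) array of standard-normal
    draws; gradients are *not* accumulated (evaluation only).
    """
    if len(batch) == 0:
        raise ValueError("compute_losses: empty batch")
    for t in batch:
        v = validate_triplet(t)
        if v:
            raise ValidationError("compute_losses: invalid triplet: " + "; ".join(v))
    xt, xf, y = _batch_arrays(batch)
    return _forward_backward(model, xt, xf, y, noise, train=False)


def train_predictor(
    data: Sequence[SampleTriplet],
    cfg: TrainConfig | None = None,
    mcfg: MVAEMoEConfig | None = None,
) -> tuple[MVAEMoE, list[LossBreakdown]]:
    """Jointly optimize encoders, decoders, experts and gating.

    Adam with the step learning-rate schedule; per-epoch loss breakdowns
    are returned (components averaged over the epoch's batches, total
    recomputed as their exact sum).  Fully reproducible under fixed seeds.
    """
    cfg = cfg or TrainConfig()
    mcfg = mcfg or MVAEMoEConfig()
    if len(data) < 2:
        raise ValueError("train_predictor: need at least 2 training triplets")
    for t in data:
        v = validate_triplet(t)
        if v:
            raise ValidationError("train_predictor: invalid triplet: " + "; ".join(v))
    model = MVAEMoE(mcfg)
    xt, xf, y = _batch_arrays(data)
    model.fit_normalization(xt, xf)

    # output-prior initialization: every expert starts at the training-mean
    # composition, so learning budgets go to condition dependence
    mean_logit = np.log(np.maximum(y.mean(axis=0), 1e-8))
    mean_logit = mean_logit - mean_logit.mean()
    for ex in model.experts:
        final = [l for l in ex.layers if isinstance(l, nn.Linear)][-1]
        final.params["b"] = mean_logit.astype(nn.DTYPE)

    opt = nn.Adam(model.all_nets())
    rng = np.random.default_rng(cfg.seed)
    n = len(data)
    history: list[LossBreakdown] = []
    for epoch in range(1, cfg.epochs + 1):
        lr = nn.step_lr(epoch, cfg.learning_rate, cfg.lr_step_epoch, cfg.lr_factor)
        order = rng.permutation(n)
        comps = np.zeros(4)
        weights = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            eps = rng.standard_normal((len(idx), mcfg.latent_dim))
            opt.zero_grad()
            b = _forward_backward(model, xt[idx], xf[idx], y[idx], eps, train=True)
            opt.step(lr)
            comps += len(idx) * np.array([b.recon_tga, b.recon_ftir, b.pred, b.kl])
            weights += len(idx)
        comps /= weights
        history.append(LossBreakdown.make(*comps))
    model.trained = True
    return model, history


def predict_gcms(
    model: MVAEMoE, tga: ThermogramResampled, ftir: IRPreprocessed
) -> CompositionVector:
    """Deterministic composition prediction from one TGA + FT-IR pair.

    Encodes both modalities, fuses the posteriors and pushes the fused
    *mean* (no sampling) through the mixture-of-experts head.
    """
    if not model.trained:
        raise StateError("predict_gcms: model has not been trained")
    xt = tga.mass_pct / 100.0
    xf = ftir.values
    g_t = encode_modality(xt, "TGA", model)
    g_f = encode_modality(xf, "FTIR", model)
    if model.cfg.fusion == "concat":
        h = np.concatenate(
            [np.atleast_2d(g_t.mu), np.atleast_2d(g_t.logvar),
             np.atleast_2d(g_f.mu), np.atleast_2d(g_f.logvar)], axis=1
        )
        mu = model.fuse_net.forward(h)[:, : model.cfg.latent_dim]
    else:
        mu = np.atleast_2d(fuse_experts([g_t, g_f]).mu)
    comp, _ = predict_composition(mu, model)
    return CompositionVector(np.asarray(comp).ravel())
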