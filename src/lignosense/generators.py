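"""Conditional CNN generation models for the three analytical modalities.

Each modality gets its own decoder-style 1-D CNN that maps the scalar
normalized HTL temperature τ = (T − 250)/150 to a full modality vector:

* **TGA** — Conv(1→16)+ReLU, Conv(16→32)+ReLU, Flatten,
  Linear(32·L→1024)+ReLU, Linear(1024→output).
* **FT-IR** — Conv(1→16)+ReLU, Conv(16→32)+ReLU, Conv(32→64)+ReLU,
  Flatten, Linear(64·L→1024)+ReLU, Dropout(0.3), Linear(1024→3476).
* **GC-MS** — Conv(1→64)+ReLU ×3, Global Average Pooling,
  Linear(64→128)+ReLU, Linear(128→10), Softmax (simplex output).

The generators are deterministic (no noise channel): one vector per
queried temperature.  Trained on the (few) anchor conditions with MSE,
Adam (lr 1e-3, ×0.1 after 75 epochs), batch 32, 100 epochs, they
synthesize modality vectors at unseen temperatures, which augment the
training set of the downstream GC-MS predictor.

Training targets are scale-matched across modalities: TGA mass % is
divided by 100 and FT-IR log-absorbance values are used as-is.  Before
optimization the output layer's bias is initialized to the training-target
mean (log-mean for the softmax head) — an output-prior initialization that
lets the short fixed training budget be spent on the condition dependence
rather than on finding the mean curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import nn
from .datatypes import (
    CompositionVector,
    IRPreprocessed,
    SampleTriplet,
    StateError,
    ThermogramResampled,
    ValidationError,
)
from .synthetic import normalized_condition

__all__ = [
    "GeneratorSpec",
    "TrainConfig",
    "TrainHistory",
    "GeneratorModel",
    "build_generator",
    "encode_condition",
    "train_generator",
    "generate_at_temperature",
    "augment_dataset",
    "modality_target",
    "DEFAULT_AUGMENT_TEMPS",
]

MODALITIES = ("TGA", "FTIR", "GCMS")
DEFAULT_AUGMENT_TEMPS: tuple[float, ...] = (260.0, 280.0, 315.0, 345.0, 365.0, 390.0)

_DEFAULT_CHANNELS = {"TGA": (16, 32), "FTIR": (16, 32, 64), "GCMS": (64, 64, 64)}
_DEFAULT_OUTPUT = {"TGA": 721, "FTIR": 3476, "GCMS": 10}


@dataclass
class GeneratorSpec:
    """Architecture description of one modality's generation model."""

    modality: str
    output_dim: int
    conv_channels: tuple[int, ...]
    kernel_size: int = 3
    stride: int = 1
    padding: int = 1
    hidden: int = 1024
    dropout: float = 0.0
    gcms_hidden: int = 128
    input_length: int = 1
    input_channels: int = 1

    @classmethod
    def for_modality(cls, modality: str, output_dim: int | None = None) -> "GeneratorSpec":
        modality = modality.upper()
        if modality not in MODALITIES:
            raise ValueError(f"unknown modality {modality!r}")
        return cls(
            modality=modality,
            output_dim=int(output_dim or _DEFAULT_OUTPUT[modality]),
            conv_channels=_DEFAULT_CHANNELS[modality],
            dropout=0.3 if modality == "FTIR" else 0.0,
        )


@dataclass
class TrainConfig:
    """The fixed training regime: Adam, StepLR, small-batch, 100 epochs."""

    optimizer: str = "adam"
    learning_rate: float = 0.001
    lr_step_epoch: int = 75
    lr_factor: float = 0.1
    batch_size: int = 32
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.lr_step_epoch, self.batch_size, self.epochs) <= 0:
            raise ValidationError("TrainConfig: all quantities must be positive")
        if not (0.0 < self.lr_factor <= 1.0):
            raise ValidationError("TrainConfig: lr_factor must be in (0, 1]")


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)


@dataclass
class GeneratorModel:
    spec: GeneratorSpec
    net: nn.Sequential
    trained: bool = False


def build_generator(spec: GeneratorSpec, seed: int) -> GeneratorModel:
    """Instantiate the modality's layer stack with seeded initialization."""
    if spec.modality not in MODALITIES:
        raise ValueError(f"unknown modality {spec.modality!r}")
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(16)]
    ri = iter(rngs)
    layers: list[nn.Layer] = []
    cin = spec.input_channels
    for cout in spec.conv_channels:
        layers.append(nn.Conv1d(cin, cout, spec.kernel_size, spec.padding, rng=next(ri)))
        layers.append(nn.ReLU())
        cin = cout
    if spec.modality == "GCMS":
        layers.append(nn.GlobalAvgPool())
        layers.append(nn.Linear(cin, spec.gcms_hidden, rng=next(ri)))
        layers.append(nn.ReLU())
        layers.append(nn.Linear(spec.gcms_hidden, spec.output_dim, rng=next(ri)))
        layers.append(nn.Softmax())
    else:
        layers.append(nn.Flatten())
        layers.append(nn.Linear(cin * spec.input_length, spec.hidden, rng=next(ri)))
        layers.append(nn.ReLU())
        if spec.dropout > 0:
            layers.append(nn.Dropout(spec.dropout, rng=next(ri)))
        layers.append(nn.Linear(spec.hidden, spec.output_dim, rng=next(ri)))
    return GeneratorModel(spec=spec, net=nn.Sequential(layers))


def encode_condition(htl_temperature_c: float, input_length: int = 1) -> np.ndarray:
    """Normalized HTL temperature tiled to the generator's input length."""
    tau = normalized_condition(htl_temperature_c)
    return np.full(input_length, tau, dtype=float)


def _final_linear(net: nn.Sequential) -> nn.Linear:
    for layer in reversed(net.layers):
        if isinstance(layer, nn.Linear):
            return layer
    raise StateError("model has no Linear output layer")


def _init_output_bias(model: GeneratorModel, targets: np.ndarray) -> None:
    out = _final_linear(model.net)
    mean = targets.mean(axis=0)
    if model.spec.modality == "GCMS":
        logits = np.log(np.maximum(mean, 1e-8))
        out.params["b"] = (logits - logits.mean()).astype(nn.DTYPE)
    else:
        out.params["b"] = mean.astype(nn.DTYPE)


def train_generator(
    model: GeneratorModel,
    pairs: Sequence[tuple[float, np.ndarray]],
    cfg: TrainConfig | None = None,
) -> tuple[GeneratorModel, TrainHistory]:
    """Fit the generator to (HTL temperature, target vector) pairs with MSE."""
    cfg = cfg or TrainConfig()
    if len(pairs) < 2:
        raise ValidationError("train_generator: need at least 2 training pairs")
    X = np.stack(
        [encode_condition(t, model.spec.input_length) for t, _ in pairs]
    ).reshape(len(pairs), model.spec.input_channels, model.spec.input_length)
    Y = np.stack([np.asarray(y, dtype=float).ravel() for _, y in pairs])
    if Y.shape[1] != model.spec.output_dim:
        raise ValidationError(
            f"train_generator: target length {Y.shape[1]} != "
            f"spec output_dim {model.spec.output_dim}"
        )
    _init_output_bias(model, Y)
    opt = nn.Adam([model.net])
    rng = np.random.default_rng(cfg.seed)
    history = TrainHistory()
    n = len(pairs)
    for epoch in range(1, cfg.epochs + 1):
        lr = nn.step_lr(epoch, cfg.learning_rate, cfg.lr_step_epoch, cfg.lr_factor)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            opt.zero_grad()
            pred = model.net.forward(X[idx], train=True)
            loss, grad = nn.mse_loss(pred, Y[idx])
            model.net.backward(grad)
            opt.step(lr)
            losses.append(loss)
        history.loss.append(float(np.mean(losses)))
        history.lr.append(lr)
    model.trained = True
    return model, history


def generate_at_temperature(model: GeneratorModel, htl_temperature_c: float) -> np.ndarray:
    """Deterministic modality vector at the requested HTL temperature."""
    if not model.trained:
        raise StateError("generate_at_temperature: model has not been trained")
    x = encode_condition(htl_temperature_c, model.spec.input_length).reshape(
        1, model.spec.input_channels, model.spec.input_length
    )
    return model.net.forward(x, train=False)[0]


def modality_target(triplet: SampleTriplet, modality: str) -> np.ndarray:
    """Training-target vector for a modality, on the model's scale."""
    modality = modality.upper()
    if modality == "TGA":
        return triplet.tga.mass_pct / 100.0
    if modality == "FTIR":
        return triplet.ftir.values.copy()
    if modality == "GCMS":
        return triplet.gcms.fractions.copy()
    raise ValueError(f"unknown modality {modality!r}")


def augment_dataset(
    models: Mapping[str, GeneratorModel],
    temps: Sequence[float] | None = None,
) -> list[SampleTriplet]:
    """Assemble one generated :class:`SampleTriplet` per requested temperature."""
    temps = DEFAULT_AUGMENT_TEMPS if temps is None else tuple(temps)
    for key in MODALITIES:
        if key not in models or not models[key].trained:
            raise StateError(f"augment_dataset: generator for {key} missing or untrained")
    out = []
    for t in temps:
        tga_vec = generate_at_temperature(models["TGA"], t)
        ftir_vec = generate_at_temperature(models["FTIR"], t)
        gcms_vec = generate_at_temperature(models["GCMS"], t)
        out.append(
            SampleTriplet(
                htl_temperature_c=float(t),
                tga=ThermogramResampled(mass_pct=tga_vec * 100.0),
                ftir=IRPreprocessed(values=ftir_vec),
                gcms=CompositionVector(fractions=gcms_vec),
            )
        )
    return out
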