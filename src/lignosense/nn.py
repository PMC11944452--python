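"""Minimal 1-D neural-network core: layers, backprop, Adam, StepLR.

Supports exactly what the generation and prediction models need —
``Conv1d(k=3, s=1, p=1)``, ``ReLU``, ``Flatten``, ``Linear``, ``Dropout``,
``GlobalAvgPool``, ``Softmax`` — with hand-written backward passes.
Parameters and activations are float32 (the customary deep-learning
precision; it also halves the memory traffic of the optimizer, the cost
that dominates on the wide fully connected layers).  Weight initialization
follows the uniform ±1/sqrt(fan_in) convention; every source of
randomness (init, dropout masks, batch shuffling) is driven by explicit
seeded generators, so a fixed seed yields bit-identical training
trajectories.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32

__all__ = [
    "Layer",
    "Conv1d",
    "ReLU",
    "Flatten",
    "Linear",
    "AvgPool1d",
    "Dropout",
    "GlobalAvgPool",
    "Softmax",
    "Sequential",
    "Adam",
    "step_lr",
    "mse_loss",
]


class Layer:
    """Base layer: parameter dict, gradient dict, forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.params:
            if k in self.grads:
                self.grads[k].fill(0)
            else:
                self.grads[k] = np.zeros_like(self.params[k])

    def out_shape(self, shape: tuple[int, ...]) -> tuple[int, ...]:
        """Symbolic shape propagation (batch dimension omitted)."""
        raise NotImplementedError

    def describe(self) -> str:
        return type(self).__name__


class Conv1d(Layer):
    """1-D convolution, kernel 3, stride 1, padding 1 (length-preserving)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        padding: int = 1,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        self.cin, self.cout, self.k, self.pad = in_channels, out_channels, kernel_size, padding
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / np.sqrt(in_channels * kernel_size)
        self.params["W"] = rng.uniform(
            -bound, bound, size=(out_channels, in_channels, kernel_size)
        ).astype(DTYPE)
        self.params["b"] = rng.uniform(-bound, bound, size=out_channels).astype(DTYPE)
        self.zero_grad()
        self._cols: np.ndarray | None = None
        self._in_len = 0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, cin, L = x.shape
        self._in_len = L
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        cols = win.transpose(0, 2, 1, 3).reshape(B, -1, self.cin * self.k)
        self._cols = cols
        Wm = self.params["W"].reshape(self.cout, -1)
        y = cols @ Wm.T + self.params["b"]
        return y.transpose(0, 2, 1)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        B, _, Lo = gout.shape
        g = gout.transpose(0, 2, 1)  # (B, Lo, cout)
        cols = self._cols
        Wm = self.params["W"].reshape(self.cout, -1)
        self.grads["W"] += (
            g.reshape(-1, self.cout).T @ cols.reshape(-1, self.cin * self.k)
        ).reshape(self.params["W"].shape)
        self.grads["b"] += g.sum(axis=(0, 1))
        dcols = (g @ Wm).reshape(B, Lo, self.cin, self.k)
        gx_pad = np.zeros((B, self.cin, self._in_len + 2 * self.pad), dtype=gout.dtype)
        for kk in range(self.k):
            gx_pad[:, :, kk : kk + Lo] += dcols[:, :, :, kk].transpose(0, 2, 1)
        return gx_pad[:, :, self.pad : self.pad + self._in_len]

    def out_shape(self, shape):
        return (self.cout, shape[1])

    def describe(self) -> str:
        return f"Conv1d({self.cin}, {self.cout}, kernel={self.k}, stride=1, padding={self.pad})"


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout):
        return gout * self._mask

    def out_shape(self, shape):
        return shape


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout):
        return gout.reshape(self._shape)

    def out_shape(self, shape):
        return (int(np.prod(shape)),)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng=None) -> None:
        super().__init__()
        self.fin, self.fout = in_features, out_features
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / np.sqrt(in_features)
        self.params["W"] = rng.uniform(
            -bound, bound, size=(out_features, in_features)
        ).astype(DTYPE)
        self.params["b"] = rng.uniform(-bound, bound, size=out_features).astype(DTYPE)
        self.zero_grad()

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, gout):
        self.grads["W"] += gout.T @ self._x
        self.grads["b"] += gout.sum(axis=0)
        return gout @ self.params["W"]

    def out_shape(self, shape):
        return (self.fout,)

    def describe(self) -> str:
        return f"Linear({self.fin}, {self.fout})"


class Dropout(Layer):
    """Inverted dropout; active only when ``train=True``."""

    def __init__(self, p: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.p = p
        self.rng = rng or np.random.default_rng(0)
        self._mask: np.ndarray | float = 1.0

    def forward(self, x, train=False):
        if train and self.p > 0:
            self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        else:
            self._mask = 1.0
        return x * self._mask

    def backward(self, gout):
        return gout * self._mask

    def out_shape(self, shape):
        return shape

    def describe(self) -> str:
        return f"Dropout({self.p})"


class AvgPool1d(Layer):
    """Non-overlapping average pooling over the length axis (ceil mode)."""

    def __init__(self, window: int) -> None:
        super().__init__()
        self.w = int(window)

    def forward(self, x, train=False):
        B, C, L = x.shape
        self._L = L
        n_full, rem = divmod(L, self.w)
        self._rem = rem
        main = x[:, :, : n_full * self.w].reshape(B, C, n_full, self.w).mean(axis=3)
        if rem:
            tail = x[:, :, n_full * self.w :].mean(axis=2, keepdims=True)
            return np.concatenate([main, tail], axis=2)
        return main

    def backward(self, gout):
        B, C, _ = gout.shape
        gx = np.empty((B, C, self._L), dtype=gout.dtype)
        n_full = self._L // self.w
        g_main = gout[:, :, :n_full] / self.w
        gx[:, :, : n_full * self.w] = np.repeat(g_main, self.w, axis=2)
        if self._rem:
            gx[:, :, n_full * self.w :] = gout[:, :, -1:] / self._rem
        return gx

    def out_shape(self, shape):
        return (shape[0], -(-shape[1] // self.w))

    def describe(self) -> str:
        return f"AvgPool1d({self.w})"


class GlobalAvgPool(Layer):
    """Mean over the length axis: (B, C, L) → (B, C)."""

    def forward(self, x, train=False):
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, gout):
        return np.repeat(gout[:, :, None], self._L, axis=2) / self._L

    def out_shape(self, shape):
        return (shape[0],)

    def describe(self) -> str:
        return "GlobalAveragePooling"


class Softmax(Layer):
    def forward(self, x, train=False):
        e = np.exp(x - x.max(axis=-1, keepdims=True))
        self._y = e / e.sum(axis=-1, keepdims=True)
        return self._y

    def backward(self, gout):
        y = self._y
        return y * (gout - (gout * y).sum(axis=-1, keepdims=True))

    def out_shape(self, shape):
        return shape


class Sequential:
    """Ordered layer container with joint forward/backward."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        gout = np.asarray(gout, dtype=DTYPE)
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def parameters(self):
        """Yield (layer, name) pairs for every trainable array."""
        for layer in self.layers:
            for name in layer.params:
                yield layer, name

    def trace(self, input_shape: tuple[int, ...]) -> list[tuple[str, tuple[int, ...]]]:
        """Layer-by-layer (description, output shape) walk, batch omitted."""
        out = []
        shape = input_shape
        for layer in self.layers:
            shape = layer.out_shape(shape)
            out.append((layer.describe(), shape))
        return out

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {
            f"{i}.{name}": layer.params[name]
            for i, layer in enumerate(self.layers)
            for name in layer.params
        }

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for key, arr in state.items():
            idx, name = key.split(".", 1)
            self.layers[int(idx)].params[name] = np.array(arr, dtype=DTYPE)


class Adam:
    """Adam optimizer over one or more Sequential models."""

    def __init__(
        self,
        models: list[Sequential],
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.models = models
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[tuple[int, str], np.ndarray] = {}
        self._v: dict[tuple[int, str], np.ndarray] = {}
        self._scratch: dict[tuple[int, str], np.ndarray] = {}
        for model in models:
            for layer, name in model.parameters():
                key = (id(layer), name)
                self._m[key] = np.zeros_like(layer.params[name])
                self._v[key] = np.zeros_like(layer.params[name])
                self._scratch[key] = np.zeros_like(layer.params[name])

    def zero_grad(self) -> None:
        for model in self.models:
            model.zero_grad()

    def step(self, lr: float) -> None:
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for model in self.models:
            for layer, name in model.parameters():
                key = (id(layer), name)
                g = layer.grads[name]
                m, v, s = self._m[key], self._v[key], self._scratch[key]
                np.multiply(m, self.b1, out=m)
                np.multiply(g, 1.0 - self.b1, out=s)
                m += s
                np.multiply(v, self.b2, out=v)
                np.multiply(g, g, out=s)
                s *= 1.0 - self.b2
                v += s
                np.sqrt(v, out=s)
                s /= np.sqrt(c2)
                s += self.eps
                np.divide(m, s, out=s)
                s *= lr / c1
                layer.params[name] -= s


def step_lr(epoch: int, base_lr: float, step_epoch: int, factor: float) -> float:
    """Step learning-rate schedule; ``epoch`` is 1-indexed.

    Epochs 1..step_epoch run at ``base_lr``; the next ``step_epoch`` epochs
    at ``base_lr * factor``, and so on.
    """
    return base_lr * factor ** ((epoch - 1) // step_epoch)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all elements, and its gradient wrt ``pred``."""
    diff = pred - target
    loss = float(np.mean(diff**2))
    grad = 2.0 * diff / diff.size
    return loss, grad
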