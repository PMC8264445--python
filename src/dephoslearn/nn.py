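"""Minimal NumPy neural-network layers with exact backpropagation.

Implements exactly the layer set the sequence classifier needs:
embedding lookup, (bidirectional) LSTM with full backpropagation through
time, a time-distributed dense layer, flatten, inverted dropout, dense
layers, and a softmax/cross-entropy head.  Every layer exposes
``params`` / ``grads`` dictionaries keyed by parameter name so an
optimizer (or a layer-freezing policy) can address tensors by
``"<layer>/<param>"`` identifiers.

Gradients are verified against central finite differences in the test
suite; training is single-threaded and bit-reproducible for a fixed
seed.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.standard_normal((n, n))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


class Layer:
    """Base class: parameters, gradients, forward/backward."""

    def __init__(self, name: str):
        self.name = name
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grads(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}


class Embedding(Layer):
    """Integer token -> dense vector lookup table."""

    def __init__(self, name: str, vocab_size: int, dim: int,
                 rng: np.random.Generator):
        super().__init__(name)
        self.params["E"] = rng.uniform(-0.05, 0.05, size=(vocab_size, dim))
        self._x: np.ndarray | None = None

    def forward(self, x, training, rng=None):
        self._x = x
        return self.params["E"][x]

    def backward(self, dout):
        dE = np.zeros_like(self.params["E"])
        np.add.at(dE, self._x, dout)
        self.grads["E"] = dE
        return np.zeros(self._x.shape)  # integer input: no upstream gradient


class _LSTMDirection:
    """One direction of an LSTM; gate order is (input, forget, cell, output).

    Parameters: W (input kernel, D x 4U), R (recurrent kernel, U x 4U),
    b (bias, 4U).  The forget-gate bias starts at 1 so early training
    retains cell state.
    """

    def __init__(self, input_dim: int, units: int, rng: np.random.Generator):
        self.units = units
        self.W = glorot_uniform(rng, input_dim, units, (input_dim, 4 * units))
        self.R = np.concatenate([orthogonal(rng, units) for _ in range(4)], axis=1)
        self.b = np.zeros(4 * units)
        self.b[units : 2 * units] = 1.0
        self._cache: list[tuple] = []
        self._x_shape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, t, _ = x.shape
        u = self.units
        self._x_shape = x.shape
        h = np.zeros((n, u))
        c = np.zeros((n, u))
        self._cache = []
        out = np.empty((n, t, u))
        for step in range(t):
            xt = x[:, step, :]
            a = xt @ self.W + h @ self.R + self.b
            i = sigmoid(a[:, :u])
            f = sigmoid(a[:, u : 2 * u])
            g = np.tanh(a[:, 2 * u : 3 * u])
            o = sigmoid(a[:, 3 * u :])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            out[:, step, :] = h
            self._cache.append((xt, h_prev, c_prev, i, f, g, o, tc))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, t, _ = self._x_shape
        u = self.units
        dW = np.zeros_like(self.W)
        dR = np.zeros_like(self.R)
        db = np.zeros_like(self.b)
        dx = np.empty(self._x_shape)
        dh_next = np.zeros((n, u))
        dc_next = np.zeros((n, u))
        for step in reversed(range(t)):
            xt, h_prev, c_prev, i, f, g, o, tc = self._cache[step]
            dh = dout[:, step, :] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            da = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dW += xt.T @ da
            dR += h_prev.T @ da
            db += da.sum(axis=0)
            dx[:, step, :] = da @ self.W.T
            dh_next = da @ self.R.T
            dc_next = dc * f
        self.dW, self.dR, self.db = dW, dR, db
        return dx


class BiLSTM(Layer):
    """Bidirectional LSTM returning the full sequence of hidden states.

    The forward pass reads the window left-to-right, the backward pass
    right-to-left; per-timestep outputs are concatenated, so the output
    feature dimension is ``2 * units``.
    """

    def __init__(self, name: str, input_dim: int, units: int,
                 rng: np.random.Generator):
        super().__init__(name)
        self.fw = _LSTMDirection(input_dim, units, rng)
        self.bw = _LSTMDirection(input_dim, units, rng)
        self._sync_params()

    def _sync_params(self) -> None:
        self.params = {
            "fw_W": self.fw.W, "fw_R": self.fw.R, "fw_b": self.fw.b,
            "bw_W": self.bw.W, "bw_R": self.bw.R, "bw_b": self.bw.b,
        }

    def forward(self, x, training, rng=None):
        self.fw.W, self.fw.R, self.fw.b = (
            self.params["fw_W"], self.params["fw_R"], self.params["fw_b"])
        self.bw.W, self.bw.R, self.bw.b = (
            self.params["bw_W"], self.params["bw_R"], self.params["bw_b"])
        h_fw = self.fw.forward(x)
        h_bw = self.bw.forward(x[:, ::-1, :])[:, ::-1, :]
        return np.concatenate([h_fw, h_bw], axis=2)

    def backward(self, dout):
        u = self.fw.units
        dx_fw = self.fw.backward(dout[:, :, :u])
        dx_bw = self.bw.backward(dout[:, ::-1, u:])[:, ::-1, :]
        self.grads = {
            "fw_W": self.fw.dW, "fw_R": self.fw.dR, "fw_b": self.fw.db,
            "bw_W": self.bw.dW, "bw_R": self.bw.dR, "bw_b": self.bw.db,
        }
        return dx_fw + dx_bw


class TimeDistributedDense(Layer):
    """Dense layer applied identically at every timestep (ReLU)."""

    def __init__(self, name: str, input_dim: int, units: int,
                 rng: np.random.Generator):
        super().__init__(name)
        self.params["W"] = glorot_uniform(rng, input_dim, units, (input_dim, units))
        self.params["b"] = np.zeros(units)

    def forward(self, x, training, rng=None):
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        self._mask = z > 0
        return z * self._mask

    def backward(self, dout):
        dz = dout * self._mask
        n, t, d = self._x.shape
        x2 = self._x.reshape(n * t, d)
        dz2 = dz.reshape(n * t, -1)
        self.grads["W"] = x2.T @ dz2
        self.grads["b"] = dz2.sum(axis=0)
        return dz @ self.params["W"].T


class Flatten(Layer):
    def forward(self, x, training, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout: active only during training, identity at inference."""

    def __init__(self, name: str, rate: float):
        super().__init__(name)
        self.rate = rate

    def forward(self, x, training, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Dense(Layer):
    def __init__(self, name: str, input_dim: int, units: int,
                 rng: np.random.Generator, activation: str = "relu"):
        super().__init__(name)
        self.activation = activation
        self.params["W"] = glorot_uniform(rng, input_dim, units, (input_dim, units))
        self.params["b"] = np.zeros(units)

    def forward(self, x, training, rng=None):
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        if self.activation == "relu":
            self._mask = z > 0
            return z * self._mask
        self._mask = None
        return z

    def backward(self, dout):
        dz = dout if self._mask is None else dout * self._mask
        self.grads["W"] = self._x.T @ dz
        self.grads["b"] = dz.sum(axis=0)
        return dz @ self.params["W"].T


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y_onehot: np.ndarray,
                          eps: float = 1e-12) -> tuple[float, np.ndarray, np.ndarray]:
    """Softmax + cross-entropy; returns (mean loss, probabilities, dlogits).

    With a one-hot two-class target and a two-unit softmax this loss is
    identical to the per-output-averaged binary cross-entropy.
    """
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-(y_onehot * np.log(p + eps)).sum() / n)
    dlogits = (p - y_onehot) / n
    return loss, p, dlogits


class Network:
    """An ordered stack of layers with joint forward/backward passes."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def layer_names(self) -> list[str]:
        return [l.name for l in self.layers if l.params]

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        out = x
        for layer in self.layers:
            out = layer.forward(out, training, rng)
        return out

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def get_weights(self) -> dict[str, np.ndarray]:
        return {
            f"{l.name}/{k}": v.copy()
            for l in self.layers
            for k, v in l.params.items()
        }

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for layer in self.layers:
            for key in layer.params:
                full = f"{layer.name}/{key}"
                if full not in weights:
                    raise KeyError(f"missing weight tensor {full}")
                if weights[full].shape != layer.params[key].shape:
                    raise ValueError(
                        f"shape mismatch in layer {layer.name!r}: "
                        f"{weights[full].shape} vs {layer.params[key].shape}"
                    )
                layer.params[key] = weights[full].copy()
            if isinstance(layer, BiLSTM):
                layer.fw.W, layer.fw.R, layer.fw.b = (
                    layer.params["fw_W"], layer.params["fw_R"], layer.params["fw_b"])
                layer.bw.W, layer.bw.R, layer.bw.b = (
                    layer.params["bw_W"], layer.params["bw_R"], layer.params["bw_b"])


class Adam:
    """Adam optimizer with per-tensor state and an adjustable learning rate.

    ``frozen`` holds layer names whose parameters are excluded from
    updates (their gradients are simply ignored).
    """

    def __init__(self, network: Network, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7,
                 frozen: set[str] | None = None):
        self.network = network
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.frozen = set(frozen or ())
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for layer in self.network.layers:
            if layer.name in self.frozen:
                continue
            for key, grad in layer.grads.items():
                full = f"{layer.name}/{key}"
                if full not in self.m:
                    self.m[full] = np.zeros_like(grad)
                    self.v[full] = np.zeros_like(grad)
                self.m[full] = b1 * self.m[full] + (1 - b1) * grad
                self.v[full] = b2 * self.v[full] + (1 - b2) * grad * grad
                m_hat = self.m[full] / (1 - b1**self.t)
                v_hat = self.v[full] / (1 - b2**self.t)
                layer.params[key] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
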