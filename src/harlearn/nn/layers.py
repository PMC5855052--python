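"""Minimal numpy neural layers with explicit forward/backward passes.

Conventions: batches first; frame inputs are ``(B, T, S)``; convolutional
feature maps are ``(B, T, S', C)`` with valid (unpadded) convolutions over
the time axis and non-overlapping max pooling with floor division — the
arithmetic that makes the recurrent time-step counts of the hybrid presets
exact.  Weights use fan-in-scaled uniform initialization from an explicit
seeded generator, so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import SpecError


class Param:
    """A trainable array with a lazily-allocated gradient buffer."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = None

    def add_grad(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.value)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None


def _uniform_fan_in(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    limit = np.sqrt(1.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Param(_uniform_fan_in(rng, d_in, (d_in, d_out)))
        self.b = Param(np.zeros(d_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.add_grad(self._x.T @ dout)
        self.b.add_grad(dout.sum(axis=0))
        return dout @ self.W.value.T


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Flatten(Layer):
    """Collapse everything after the batch axis."""

    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class ExpandDims(Layer):
    """(B, T, S) -> (B, T, S, 1) single input feature map."""

    def forward(self, x, train):
        return x[..., None]

    def backward(self, dout):
        return dout[..., 0]


class TimeFlatten(Layer):
    """(B, T, S, C) -> (B, T, S*C): per-time-step slices for a recurrent layer."""

    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], x.shape[1], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class BatchNormChannels(Layer):
    """Batch normalization over each sensor channel, placed right after the input.

    Statistics are taken over the batch and time axes independently per
    channel; inference uses running averages so extracted features do not
    depend on batch composition.
    """

    def __init__(self, n_channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_channels))
        self.beta = Param(np.zeros(n_channels))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv_std
        self._n = x.shape[0] * x.shape[1]
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dout):
        xhat, n = self._xhat, self._n
        self.gamma.add_grad((dout * xhat).sum(axis=(0, 1)))
        self.beta.add_grad(dout.sum(axis=(0, 1)))
        dxhat = dout * self.gamma.value
        return (self._inv_std / n) * (
            n * dxhat
            - dxhat.sum(axis=(0, 1))
            - xhat * (dxhat * xhat).sum(axis=(0, 1))
        )


class Conv(Layer):
    """Valid 2-D convolution over (time, sensor) with stride 1.

    Kernel shape ``(f_T, f_S, C_in, n_kernels)``; per-channel convolutions
    use ``f_S=1`` (the kernel is shared across sensor positions) and
    cross-sensor ones ``f_S=S``.
    """

    def __init__(self, f_T: int, f_S: int, c_in: int, n_kernels: int,
                 rng: np.random.Generator):
        fan_in = f_T * f_S * c_in
        self.K = Param(_uniform_fan_in(rng, fan_in, (f_T, f_S, c_in, n_kernels)))
        self.b = Param(np.zeros(n_kernels))
        self.f_T, self.f_S = f_T, f_S

    def params(self):
        return [self.K, self.b]

    def forward(self, x, train):
        if x.shape[1] < self.f_T or x.shape[2] < self.f_S:
            raise SpecError(
                f"input ({x.shape[1]}x{x.shape[2]}) smaller than kernel "
                f"({self.f_T}x{self.f_S})"
            )
        # (B, T', S', C, f_T, f_S)
        win = np.lib.stride_tricks.sliding_window_view(
            x, (self.f_T, self.f_S), axis=(1, 2))
        self._win, self._xshape = win, x.shape
        return np.einsum("btscij,ijcn->btsn", win, self.K.value) + self.b.value

    def backward(self, dout):
        self.K.add_grad(np.einsum("btscij,btsn->ijcn", self._win, dout))
        self.b.add_grad(dout.sum(axis=(0, 1, 2)))
        dx = np.zeros(self._xshape)
        Tp, Sp = dout.shape[1], dout.shape[2]
        for i in range(self.f_T):
            for j in range(self.f_S):
                dx[:, i:i + Tp, j:j + Sp, :] += np.einsum(
                    "btsn,cn->btsc", dout, self.K.value[i, j])
        return dx


class MaxPoolTime(Layer):
    """Non-overlapping max pooling along time; partial trailing window dropped."""

    def __init__(self, p_T: int):
        if p_T < 1:
            raise SpecError("pool size must be >= 1")
        self.p_T = p_T

    def forward(self, x, train):
        B, T, S, C = x.shape
        Tp = T // self.p_T
        if Tp < 1:
            raise SpecError(f"time length {T} shorter than pool size {self.p_T}")
        self._T = T
        xt = x[:, :Tp * self.p_T].reshape(B, Tp, self.p_T, S, C)
        self._arg = xt.argmax(axis=2)
        return xt.max(axis=2)

    def backward(self, dout):
        B, Tp, S, C = dout.shape
        dxt = np.zeros((B, Tp, self.p_T, S, C))
        np.put_along_axis(dxt, self._arg[:, :, None], dout[:, :, None], axis=2)
        dx = np.zeros((B, self._T, S, C))
        dx[:, :Tp * self.p_T] = dxt.reshape(B, Tp * self.p_T, S, C)
        return dx


# ---------------------------------------------------------------------------
# LSTM
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class LSTMCellParams:
    """Weights of one recurrent layer's cell.

    The cell keeps an internal memory ``m_t`` and emits an output ``c_t``;
    input, forget and output gates are logistic functions of affine maps of
    the current input ``x_t`` and the previous output ``c_{t-1}``:

        y_i = logistic(W_i x_t + U_i c_{t-1} + b_i)        (input gate)
        y_f = logistic(W_f x_t + U_f c_{t-1} + b_f)        (forget gate)
        y_o = logistic(W_o x_t + U_o c_{t-1} + b_o)        (output gate)
        m_t = y_i * tanh(W x_t + U c_{t-1} + b) + y_f * m_{t-1}
        c_t = y_o * tanh(m_t)

    All weight matrices map inputs of dimension D (``W*``: D x H) or previous
    outputs of dimension H (``U*``: H x H).
    """

    W: np.ndarray
    U: np.ndarray
    b: np.ndarray
    W_i: np.ndarray
    U_i: np.ndarray
    b_i: np.ndarray
    W_f: np.ndarray
    U_f: np.ndarray
    b_f: np.ndarray
    W_o: np.ndarray
    U_o: np.ndarray
    b_o: np.ndarray

    @classmethod
    def init(cls, d_in: int, d_out: int, rng: np.random.Generator) -> "LSTMCellParams":
        def w():
            return _uniform_fan_in(rng, d_in + d_out, (d_in, d_out))

        def u():
            return _uniform_fan_in(rng, d_in + d_out, (d_out, d_out))

        # forget-gate bias starts at 1 so memories persist early in training
        return cls(W=w(), U=u(), b=np.zeros(d_out),
                   W_i=w(), U_i=u(), b_i=np.zeros(d_out),
                   W_f=w(), U_f=u(), b_f=np.ones(d_out),
                   W_o=w(), U_o=u(), b_o=np.zeros(d_out))


def lstm_cell_step(params: LSTMCellParams, x_t: np.ndarray,
                   c_prev: np.ndarray, m_prev: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """One forward step of the recurrent cell; returns ``(c_t, m_t)``.

    Accepts single vectors or batches (leading axes broadcast through the
    matrix products).
    """
    x_t, c_prev, m_prev = (np.asarray(a, dtype=float) for a in (x_t, c_prev, m_prev))
    if x_t.shape[-1] != params.W.shape[0]:
        raise SpecError(
            f"x_t dim {x_t.shape[-1]} incompatible with W ({params.W.shape})")
    if c_prev.shape[-1] != params.U.shape[0] or m_prev.shape != c_prev.shape:
        raise SpecError("c_prev/m_prev dims incompatible with U")
    y_i = _sigmoid(x_t @ params.W_i + c_prev @ params.U_i + params.b_i)
    y_f = _sigmoid(x_t @ params.W_f + c_prev @ params.U_f + params.b_f)
    y_o = _sigmoid(x_t @ params.W_o + c_prev @ params.U_o + params.b_o)
    g = np.tanh(x_t @ params.W + c_prev @ params.U + params.b)
    m_t = y_i * g + y_f * m_prev
    c_t = y_o * np.tanh(m_t)
    return c_t, m_t


class LSTMLayer(Layer):
    """A recurrent layer of the cells above, unrolled over the time axis.

    ``return_sequences=True`` wires the layer many-to-many (outputs at every
    step, ``(B, T, H)``); ``False`` wires it many-to-one (last output only,
    ``(B, H)``).  Backpropagation through time is exact over the full
    unrolled graph.
    """

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 return_sequences: bool):
        cp = LSTMCellParams.init(d_in, d_out, rng)
        self.p = {name: Param(getattr(cp, name)) for name in
                  ("W", "U", "b", "W_i", "U_i", "b_i", "W_f", "U_f", "b_f",
                   "W_o", "U_o", "b_o")}
        self.d_in, self.d_out = d_in, d_out
        self.return_sequences = return_sequences

    def params(self):
        return list(self.p.values())

    def cell_params(self) -> LSTMCellParams:
        return LSTMCellParams(**{k: v.value for k, v in self.p.items()})

    def forward(self, x, train):
        if x.ndim != 3 or x.shape[2] != self.d_in:
            raise SpecError(f"LSTM layer expects (B, T, {self.d_in}); got {x.shape}")
        B, T, _ = x.shape
        H = self.d_out
        p = {k: v.value for k, v in self.p.items()}
        c = np.zeros((B, H))
        m = np.zeros((B, H))
        cache = []
        outputs = np.empty((B, T, H))
        for t in range(T):
            x_t = x[:, t]
            y_i = _sigmoid(x_t @ p["W_i"] + c @ p["U_i"] + p["b_i"])
            y_f = _sigmoid(x_t @ p["W_f"] + c @ p["U_f"] + p["b_f"])
            y_o = _sigmoid(x_t @ p["W_o"] + c @ p["U_o"] + p["b_o"])
            g = np.tanh(x_t @ p["W"] + c @ p["U"] + p["b"])
            m_new = y_i * g + y_f * m
            tanh_m = np.tanh(m_new)
            c_new = y_o * tanh_m
            cache.append((x_t, c, m, y_i, y_f, y_o, g, tanh_m))
            c, m = c_new, m_new
            outputs[:, t] = c
        self._cache = cache
        self._x_shape = x.shape
        self._outputs = outputs
        return outputs if self.return_sequences else outputs[:, -1]

    def backward(self, dout):
        B, T, _ = self._x_shape
        H = self.d_out
        p = {k: v.value for k, v in self.p.items()}
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        if self.return_sequences:
            dout_seq = dout
        else:
            dout_seq = np.zeros((B, T, H))
            dout_seq[:, -1] = dout
        dx = np.zeros(self._x_shape)
        dc = np.zeros((B, H))
        dm = np.zeros((B, H))
        for t in reversed(range(T)):
            x_t, c_prev, m_prev, y_i, y_f, y_o, g, tanh_m = self._cache[t]
            dc = dc + dout_seq[:, t]
            dy_o = dc * tanh_m
            dm = dm + dc * y_o * (1.0 - tanh_m ** 2)
            dy_i = dm * g
            dg = dm * y_i
            dy_f = dm * m_prev
            dm_prev = dm * y_f
            da_i = dy_i * y_i * (1 - y_i)
            da_f = dy_f * y_f * (1 - y_f)
            da_o = dy_o * y_o * (1 - y_o)
            da_g = dg * (1 - g ** 2)
            for name, da in (("_i", da_i), ("_f", da_f), ("_o", da_o), ("", da_g)):
                grads["W" + name] += x_t.T @ da
                grads["U" + name] += c_prev.T @ da
                grads["b" + name] += da.sum(axis=0)
            dx[:, t] = (da_i @ p["W_i"].T + da_f @ p["W_f"].T
                        + da_o @ p["W_o"].T + da_g @ p["W"].T)
            dc = (da_i @ p["U_i"].T + da_f @ p["U_f"].T
                  + da_o @ p["U_o"].T + da_g @ p["U"].T)
            dm = dm_prev
        for k, g_ in grads.items():
            self.p[k].add_grad(g_)
        return dx


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

class SoftmaxCrossEntropy:
    """Categorical cross-entropy over softmax logits; mean over the batch."""

    def forward(self, logits: np.ndarray, y: np.ndarray) -> float:
        z = logits - logits.max(axis=1, keepdims=True)
        log_probs = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        self._probs = np.exp(log_probs)
        self._y = y
        return float(-log_probs[np.arange(len(y)), y].mean())

    def backward(self) -> np.ndarray:
        d = self._probs.copy()
        d[np.arange(len(self._y)), self._y] -= 1.0
        return d / len(self._y)


class MeanSquaredError:
    """Mean over all elements of the squared reconstruction error."""

    def forward(self, pred: np.ndarray, target: np.ndarray) -> float:
        self._diff = pred - target
        return float(np.mean(self._diff ** 2))

    def backward(self) -> np.ndarray:
        return 2.0 * self._diff / self._diff.size
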