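"""Minimal feed-forward layer engine used by the generative models and the classifier.

All arrays are float32. Each layer owns its parameters and, after a
``backward`` call, the matching gradients; ``Sequential`` chains layers and
caches whatever the backward pass needs. Convolutions are evaluated as a
single GEMM over an im2col patch matrix, which is where essentially all the
floating-point work of the package happens.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def trunc_normal(rng: np.random.Generator, shape, std: float) -> np.ndarray:
    """Normal(0, std) truncated at two standard deviations."""
    x = rng.standard_normal(shape)
    for _ in range(4):
        bad = np.abs(x) > 2.0
        if not bad.any():
            break
        x[bad] = rng.standard_normal(int(bad.sum()))
    return (std * np.clip(x, -2.0, 2.0)).astype(DTYPE)


def _he_std(fan_in: int) -> float:
    """He initialization scale for ReLU networks; these nets carry no
    normalization layers, so propagation-preserving init matters."""
    return float(np.sqrt(2.0 / fan_in))


def softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------- im2col

def _conv_out_size(n: int, k: int, s: int, p: int) -> int:
    return (n + 2 * p - k) // s + 1


try:  # strided gather/scatter is the runtime hot spot; JIT it when possible
    import numba as _numba

    @_numba.njit(cache=True)
    def _im2col_kernel(xp, k, s, Ho, Wo, cols):  # pragma: no cover - jitted
        B, C = xp.shape[0], xp.shape[1]
        for b in range(B):
            for c in range(C):
                for i in range(k):
                    for j in range(k):
                        for h in range(Ho):
                            row = xp[b, c, i + s * h]
                            dst = cols[b, c, i, j, h]
                            for w in range(Wo):
                                dst[w] = row[j + s * w]

    @_numba.njit(cache=True)
    def _col2im_kernel(cols, k, s, Ho, Wo, xp):  # pragma: no cover - jitted
        B, C = xp.shape[0], xp.shape[1]
        for b in range(B):
            for c in range(C):
                for i in range(k):
                    for j in range(k):
                        for h in range(Ho):
                            row = xp[b, c, i + s * h]
                            src = cols[b, c, i, j, h]
                            for w in range(Wo):
                                row[j + s * w] += src[w]

    _HAVE_NUMBA = True
except ImportError:  # pure-NumPy fallback
    _HAVE_NUMBA = False


def _pad(x: np.ndarray, p: int) -> np.ndarray:
    B, C, H, W = x.shape
    xp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=x.dtype)
    xp[:, :, p:p + H, p:p + W] = x
    return xp


def _im2col(x: np.ndarray, k: int, s: int, p: int) -> tuple[np.ndarray, int, int]:
    """(B,C,H,W) -> (B, C*k*k, Ho*Wo) patch matrix."""
    B, C, H, W = x.shape
    Ho, Wo = _conv_out_size(H, k, s, p), _conv_out_size(W, k, s, p)
    xp = _pad(x, p)
    cols = np.empty((B, C, k, k, Ho, Wo), dtype=x.dtype)
    if _HAVE_NUMBA:
        _im2col_kernel(xp, k, s, Ho, Wo, cols)
    else:
        for i in range(k):
            for j in range(k):
                cols[:, :, i, j] = xp[:, :, i:i + s * Ho:s, j:j + s * Wo:s]
    return cols.reshape(B, C * k * k, Ho * Wo), Ho, Wo


def _col2im(cols: np.ndarray, xshape, k: int, s: int, p: int) -> np.ndarray:
    """Adjoint of ``_im2col``: scatter-add patches back onto the image."""
    B, C, H, W = xshape
    Ho, Wo = _conv_out_size(H, k, s, p), _conv_out_size(W, k, s, p)
    cols = cols.reshape(B, C, k, k, Ho, Wo)
    xp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=cols.dtype)
    if _HAVE_NUMBA:
        _col2im_kernel(np.ascontiguousarray(cols), k, s, Ho, Wo, xp)
    else:
        for i in range(k):
            for j in range(k):
                xp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += cols[:, :, i, j]
    return xp[:, :, p:p + H, p:p + W]


# ----------------------------------------------------------------- layers

class Layer:
    """Base class: parameters in ``params``, gradients in ``grads``."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for name in self.params:
            self.grads[name] = np.zeros_like(self.params[name])


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 std: float | None = None, zero_init: bool = False):
        super().__init__()
        if zero_init:
            self.params["W"] = np.zeros((n_in, n_out), dtype=DTYPE)
        else:
            self.params["W"] = trunc_normal(rng, (n_in, n_out),
                                            _he_std(n_in) if std is None else std)
        self.params["b"] = np.zeros(n_out, dtype=DTYPE)
        self.zero_grad()

    def forward(self, x):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] += self._x.T @ dout
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"].T


class Conv2d(Layer):
    """5x5 stride-2 style convolution via im2col GEMM. Weight (cout, cin*k*k)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 k: int = 5, stride: int = 2, pad: int = 2,
                 std: float | None = None):
        super().__init__()
        self.cin, self.cout, self.k, self.s, self.p = cin, cout, k, stride, pad
        self.params["W"] = trunc_normal(rng, (cout, cin * k * k),
                                        _he_std(cin * k * k) if std is None else std)
        self.params["b"] = np.zeros(cout, dtype=DTYPE)
        self.zero_grad()

    def forward(self, x):
        self._xshape = x.shape
        cols, Ho, Wo = _im2col(x, self.k, self.s, self.p)
        self._cols = cols
        out = np.matmul(self.params["W"], cols) + self.params["b"][:, None]
        return out.reshape(x.shape[0], self.cout, Ho, Wo)

    def backward(self, dout):
        B = dout.shape[0]
        d = dout.reshape(B, self.cout, -1)
        self.grads["W"] += np.matmul(d, self._cols.transpose(0, 2, 1)).sum(axis=0)
        self.grads["b"] += d.sum(axis=(0, 2))
        dcols = np.matmul(self.params["W"].T, d)
        return _col2im(dcols, self._xshape, self.k, self.s, self.p)


class ConvTranspose2d(Layer):
    """Stride-2 transposed convolution (the adjoint map of Conv2d).

    With k=5, stride=2, pad=2, output_padding=1 the spatial size doubles
    exactly (4 -> 8 -> 16 -> 32). Weight (cin, cout*k*k).
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 k: int = 5, stride: int = 2, pad: int = 2, out_pad: int = 1,
                 std: float | None = None):
        super().__init__()
        self.cin, self.cout, self.k, self.s, self.p, self.op = cin, cout, k, stride, pad, out_pad
        # transposed conv spreads each input over k^2/s^2 output positions
        eff_fan = cin * k * k // (stride * stride)
        self.params["W"] = trunc_normal(rng, (cin, cout * k * k),
                                        _he_std(eff_fan) if std is None else std)
        self.params["b"] = np.zeros(cout, dtype=DTYPE)
        self.zero_grad()

    def _out_hw(self, H, W):
        return ((H - 1) * self.s - 2 * self.p + self.k + self.op,
                (W - 1) * self.s - 2 * self.p + self.k + self.op)

    def forward(self, x):
        B, cin, H, W = x.shape
        self._x = x
        Ho, Wo = self._out_hw(H, W)
        cols = np.matmul(self.params["W"].T, x.reshape(B, cin, H * W))
        out = _col2im(cols, (B, self.cout, Ho, Wo), self.k, self.s, self.p)
        return out + self.params["b"][None, :, None, None]

    def backward(self, dout):
        B, cin, H, W = self._x.shape
        dcols, _, _ = _im2col(dout, self.k, self.s, self.p)
        xr = self._x.reshape(B, cin, H * W)
        self.grads["W"] += np.matmul(xr, dcols.transpose(0, 2, 1)).sum(axis=0)
        self.grads["b"] += dout.sum(axis=(0, 2, 3))
        dx = np.matmul(self.params["W"], dcols)
        return dx.reshape(self._x.shape)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class Softplus(Layer):
    def forward(self, x):
        self._x = x
        return softplus(x)

    def backward(self, dout):
        return dout * _sigmoid(self._x)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape):
        super().__init__()
        self.shape = tuple(shape)

    def forward(self, x):
        self._in = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dout):
        return dout.reshape(self._in)


class BatchNorm(Layer):
    """Channel normalization with switchable statistics (AdaBN-style).

    For 4-D input statistics are taken over (batch, H, W) per channel, for
    2-D input over the batch per feature. In training mode the batch's own
    statistics are used (and exposed as ``last_stats``); in inference mode
    the statistics must be supplied via ``set_stats`` — recomputing them
    from a new domain's data is exactly adaptive batch normalization.
    """

    def __init__(self, n_channels: int, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(n_channels, dtype=DTYPE)
        self.params["beta"] = np.zeros(n_channels, dtype=DTYPE)
        self.eps = eps
        self.training = True
        self._stats: tuple[np.ndarray, np.ndarray] | None = None
        self.last_stats: tuple[np.ndarray, np.ndarray] | None = None
        self.zero_grad()

    def set_stats(self, mean: np.ndarray, var: np.ndarray) -> None:
        self._stats = (np.asarray(mean, dtype=DTYPE), np.asarray(var, dtype=DTYPE))

    def _axes(self, x):
        return (0, 2, 3) if x.ndim == 4 else (0,)

    def _bc(self, v, ndim):
        return v[None, :, None, None] if ndim == 4 else v[None, :]

    def forward(self, x):
        axes = self._axes(x)
        if self.training or self._stats is None:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.last_stats = (mean, var)
        else:
            mean, var = self._stats
        self._xhat = (x - self._bc(mean, x.ndim)) / np.sqrt(self._bc(var, x.ndim) + self.eps)
        self._var = var
        self._train_fwd = self.training or self._stats is None
        return self._bc(self.params["gamma"], x.ndim) * self._xhat + self._bc(self.params["beta"], x.ndim)

    def backward(self, dout):
        axes = self._axes(dout)
        xhat = self._xhat
        self.grads["gamma"] += (dout * xhat).sum(axis=axes)
        self.grads["beta"] += dout.sum(axis=axes)
        g = self._bc(self.params["gamma"], dout.ndim)
        istd = 1.0 / np.sqrt(self._bc(self._var, dout.ndim) + self.eps)
        dxhat = dout * g
        if not self._train_fwd:
            return dxhat * istd
        m = np.prod([dout.shape[a] for a in axes])
        t1 = dxhat.sum(axis=axes, keepdims=True)
        t2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
        return istd * (dxhat - t1 / m - xhat * t2 / m)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def param_items(self):
        for i, layer in enumerate(self.layers):
            for name, value in layer.params.items():
                yield (i, name), value, layer.grads[name]

    def set_training(self, flag: bool) -> None:
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.training = flag

    # -- flat (de)serialization used by the checkpoint format
    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"{i}.{name}": v for (i, name), v, _ in self.param_items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for (i, name), v, _ in self.param_items():
            v[...] = state[f"{i}.{name}"]


class Adam:
    """Adam over one or more Sequential models (joint step)."""

    def __init__(self, models, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.models = list(models)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict = {}
        self._v: dict = {}
        for mi, model in enumerate(self.models):
            for key, value, _ in model.param_items():
                self._m[(mi, key)] = np.zeros_like(value)
                self._v[(mi, key)] = np.zeros_like(value)

    def step(self) -> None:
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for mi, model in enumerate(self.models):
            for key, value, grad in model.param_items():
                m = self._m[(mi, key)]
                v = self._v[(mi, key)]
                m *= self.b1
                m += (1.0 - self.b1) * grad
                v *= self.b2
                v += (1.0 - self.b2) * grad * grad
                value -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)

    def zero_grad(self) -> None:
        for model in self.models:
            model.zero_grad()
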