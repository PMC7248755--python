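"""A small 1-D neural-network engine on numpy with manual backpropagation.

Conventions (chosen to match the Keras/DCGAN idiom the architectures
are described in):

* activations are stored as ``(batch, channels, length)`` arrays;
* weight initialization is Glorot-uniform, batch norm uses momentum
  0.99 and epsilon 1e-3, sigmoid/tanh/ReLU as usual;
* each layer caches what it needs during ``forward`` and returns the
  input gradient from ``backward``, accumulating parameter gradients
  into ``layer.grads`` (same structure as ``layer.params``).

Every differentiable layer here is verified against central finite
differences in the test suite, including the fixed (parameter-free)
signal transforms — FFT magnitude, envelope, DWT — whose adjoints are
needed so style-transfer gradients can flow from discriminator feature
maps back to the optimized signal.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..errors import ConfigurationError, InvalidArgumentError

__all__ = [
    "Layer", "Sequential", "Dense", "Conv1d", "ConvTranspose1d",
    "BatchNorm1d", "ReLU", "LeakyReLU", "Tanh", "Sigmoid", "Dropout",
    "Upsample1d", "Flatten", "Reshape", "MovingAverage1d",
    "FFTMagnitude", "Envelope", "DWT", "MinibatchDiscrimination",
    "ResidualBlock1d", "glorot_uniform",
]


def glorot_uniform(shape: tuple[int, ...], fan_in: int, fan_out: int,
                   rng: np.random.Generator) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base class: holds parallel lists of parameters and their gradients."""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for gr in self.grads:
            gr[...] = 0.0


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            if isinstance(layer, Sequential):
                out.extend(layer.parameters())
            else:
                out.extend(layer.params)
        return out

    def gradients(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            if isinstance(layer, Sequential):
                out.extend(layer.gradients())
            else:
                out.extend(layer.grads)
        return out

    # -- weight (de)serialization -------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"param_{i}": p for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ConfigurationError(
                f"checkpoint has {len(state)} arrays, model has {len(params)}")
        for i, p in enumerate(params):
            arr = state[f"param_{i}"]
            if arr.shape != p.shape:
                raise ConfigurationError(
                    f"param_{i} shape mismatch: checkpoint {arr.shape}, "
                    f"model {p.shape}")
            p[...] = arr


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        W = glorot_uniform((d_in, d_out), d_in, d_out, rng)
        b = np.zeros(d_out)
        self.params = [W, b]
        self.grads = [np.zeros_like(W), np.zeros_like(b)]

    def forward(self, x, train=False):
        self._x = x
        W, b = self.params
        return x @ W + b

    def backward(self, g):
        W, _ = self.params
        self.grads[0] += self._x.T @ g
        self.grads[1] += g.sum(axis=0)
        return g @ W.T


def _same_pad(length: int, kernel: int, stride: int) -> tuple[int, int, int]:
    out = -(-length // stride)            # ceil
    total = max((out - 1) * stride + kernel - length, 0)
    left = total // 2
    return out, left, total - left


class Conv1d(Layer):
    """1-D convolution (cross-correlation), 'same' padding, given stride."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1):
        super().__init__()
        if kernel < 1 or stride < 1:
            raise ConfigurationError("kernel and stride must be >= 1")
        self.kernel, self.stride = kernel, stride
        fan_in, fan_out = c_in * kernel, c_out * kernel
        W = glorot_uniform((c_out, c_in, kernel), fan_in, fan_out, rng)
        b = np.zeros(c_out)
        self.params = [W, b]
        self.grads = [np.zeros_like(W), np.zeros_like(b)]

    def out_length(self, length: int) -> int:
        return _same_pad(length, self.kernel, self.stride)[0]

    def forward(self, x, train=False):
        W, b = self.params
        n, c, L = x.shape
        out, pl, pr = _same_pad(L, self.kernel, self.stride)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        win = sliding_window_view(xp, self.kernel, axis=2)[:, :, ::self.stride, :]
        self._win, self._L, self._pl, self._pr = win, L, pl, pr
        y = np.einsum("nclk,fck->nfl", win, W, optimize=True)
        return y + b[None, :, None]

    def backward(self, g):
        W, _ = self.params
        win, L, pl, pr = self._win, self._L, self._pl, self._pr
        self.grads[0] += np.einsum("nfl,nclk->fck", g, win, optimize=True)
        self.grads[1] += g.sum(axis=(0, 2))
        n, _, out = g.shape
        t = np.einsum("nfl,fck->nclk", g, W, optimize=True)
        gxp = np.zeros((n, W.shape[1], L + pl + pr))
        s = self.stride
        for kk in range(self.kernel):
            gxp[:, :, kk:kk + s * out:s] += t[:, :, :, kk]
        return gxp[:, :, pl:pl + L]


class ConvTranspose1d(Layer):
    """1-D transposed convolution; output length is ``stride * input length``
    (the adjoint of a same-padded strided convolution).  Requires
    ``kernel >= stride``."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1):
        super().__init__()
        if kernel < stride:
            raise ConfigurationError(
                f"ConvTranspose1d needs kernel >= stride "
                f"(got kernel={kernel}, stride={stride})")
        self.kernel, self.stride = kernel, stride
        fan_in, fan_out = c_in * kernel, c_out * kernel
        W = glorot_uniform((c_in, c_out, kernel), fan_in, fan_out, rng)
        b = np.zeros(c_out)
        self.params = [W, b]
        self.grads = [np.zeros_like(W), np.zeros_like(b)]
        crop = kernel - stride
        self._crop_l = crop // 2
        self._crop_r = crop - self._crop_l

    def forward(self, x, train=False):
        W, b = self.params
        n, c, L = x.shape
        full = (L - 1) * self.stride + self.kernel
        t = np.einsum("ncl,cfk->nflk", x, W, optimize=True)
        yfull = np.zeros((n, W.shape[1], full))
        s = self.stride
        for kk in range(self.kernel):
            yfull[:, :, kk:kk + s * L:s] += t[:, :, :, kk]
        self._x = x
        y = yfull[:, :, self._crop_l:full - self._crop_r]
        return y + b[None, :, None]

    def backward(self, g):
        W, _ = self.params
        x = self._x
        n, c, L = x.shape
        gfull = np.pad(g, ((0, 0), (0, 0), (self._crop_l, self._crop_r)))
        win = sliding_window_view(gfull, self.kernel, axis=2)[:, :, ::self.stride, :]
        self.grads[0] += np.einsum("ncl,nflk->cfk", x, win, optimize=True)
        self.grads[1] += g.sum(axis=(0, 2))
        return np.einsum("nflk,cfk->ncl", win, W, optimize=True)


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.99,
                 eps: float = 1e-3):
        super().__init__()
        gamma = np.ones(channels)
        beta = np.zeros(channels)
        self.params = [gamma, beta]
        self.grads = [np.zeros_like(gamma), np.zeros_like(beta)]
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, train=False):
        gamma, beta = self.params
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) / std[None, :, None]
        self._xhat, self._std, self._train = xhat, std, train
        return gamma[None, :, None] * xhat + beta[None, :, None]

    def backward(self, g):
        gamma, _ = self.params
        xhat, std = self._xhat, self._std
        self.grads[0] += (g * xhat).sum(axis=(0, 2))
        self.grads[1] += g.sum(axis=(0, 2))
        gx_hat = g * gamma[None, :, None]
        if not self._train:
            return gx_hat / std[None, :, None]
        n_eff = g.shape[0] * g.shape[2]
        term = (gx_hat
                - gx_hat.mean(axis=(0, 2), keepdims=True)
                - xhat * (gx_hat * xhat).mean(axis=(0, 2), keepdims=True))
        return term / std[None, :, None]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, g):
        return np.where(self._mask, g, self.alpha * g)


class Tanh(Layer):
    def forward(self, x, train=False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, g):
        return g * (1.0 - self._y ** 2)


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, g):
        return g * self._y * (1.0 - self._y)


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ConfigurationError(f"dropout rate must be in [0, 1), got {p}")
        self.p, self.rng = p, rng

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g):
        if self._mask is None:
            return g
        return g * self._mask


class Upsample1d(Layer):
    """Nearest-neighbour upsampling along the length axis."""

    def __init__(self, factor: int):
        super().__init__()
        if factor < 1:
            raise ConfigurationError(f"upsample factor must be >= 1, got {factor}")
        self.factor = factor

    def forward(self, x, train=False):
        return np.repeat(x, self.factor, axis=2)

    def backward(self, g):
        n, c, L = g.shape
        return g.reshape(n, c, L // self.factor, self.factor).sum(axis=3)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]):
        super().__init__()
        self.shape = shape

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, g):
        return g.reshape(self._shape)


class MovingAverage1d(Layer):
    """Trailing moving average with warm-up, matching
    :func:`emgaug.preprocess.moving_average_array` (parameter-free)."""

    def __init__(self, window: int):
        super().__init__()
        if window < 1:
            raise ConfigurationError(f"window must be >= 1, got {window}")
        self.window = window

    def _divisors(self, L: int) -> np.ndarray:
        return np.minimum(np.arange(L) + 1.0, float(self.window))

    def forward(self, x, train=False):
        L = x.shape[2]
        csum = np.concatenate(
            [np.zeros(x.shape[:2] + (1,)), np.cumsum(x, axis=2)], axis=2)
        idx = np.arange(L)
        start = np.maximum(idx - self.window + 1, 0)
        self._L = L
        return (csum[:, :, idx + 1] - csum[:, :, start]) / self._divisors(L)

    def backward(self, g):
        L = self._L
        h = g / self._divisors(L)
        S = np.concatenate(
            [np.zeros(h.shape[:2] + (1,)), np.cumsum(h, axis=2)], axis=2)
        idx = np.arange(L)
        end = np.minimum(idx + self.window, L)
        return S[:, :, end] - S[:, :, idx]


class SubtractMean(Layer):
    """Remove the per-sample mean along the length axis (parameter-free).
    Used before spectral style features so that the envelope's DC level —
    already standardized by conditioning — does not dominate the Gram
    matrices."""

    def forward(self, x, train=False):
        return x - x.mean(axis=2, keepdims=True)

    def backward(self, g):
        return g - g.mean(axis=2, keepdims=True)


class FFTMagnitude(Layer):
    """|rfft(x)| along the length axis (parameter-free, differentiable).

    With ``amplitude=True`` the spectrum is scaled by 2/n so bin values
    are in the same amplitude units as the input (a sinusoid of
    amplitude a yields a bin value of a); used where downstream weights
    were trained on time-domain inputs of that scale."""

    def __init__(self, amplitude: bool = False):
        super().__init__()
        self.amplitude = amplitude

    def forward(self, x, train=False):
        self._n = x.shape[2]
        self._F = np.fft.rfft(x, axis=2)
        self._mag = np.abs(self._F)
        if self.amplitude:
            return self._mag * (2.0 / self._n)
        return self._mag.copy()

    def backward(self, g):
        n = self._n
        if self.amplitude:
            g = g * (2.0 / n)
        safe = np.where(self._mag == 0.0, 1.0, self._mag)
        gF = g * self._F / safe          # complex gradient wrt each rfft bin
        adj = gF.copy()
        if n % 2 == 0:
            adj[:, :, 1:-1] *= 0.5       # interior bins appear twice in irfft
        else:
            adj[:, :, 1:] *= 0.5
        return np.fft.irfft(adj, n=n, axis=2) * n


class Envelope(Layer):
    """Rectify then moving-average (the EMG envelope), differentiable with
    the subgradient sign(0) = 0."""

    def __init__(self, window: int = 100):
        super().__init__()
        self.ma = MovingAverage1d(window)

    def forward(self, x, train=False):
        self._sign = np.sign(x)
        return self.ma.forward(np.abs(x), train=train)

    def backward(self, g):
        return self.ma.backward(g) * self._sign


class DWT(Layer):
    """Multi-level DWT as a fixed sparse linear map (see
    :func:`emgaug.features.dwt_operator`); adjoint used for backward."""

    def __init__(self, wavelet: str = "db7", level: int = 2):
        super().__init__()
        self.wavelet, self.level = wavelet, level

    def _op(self, L: int):
        from ..features import dwt_operator
        return dwt_operator(L, self.wavelet, self.level)

    def forward(self, x, train=False):
        n, c, L = x.shape
        self._L = L
        W = self._op(L)
        y = (W @ x.reshape(n * c, L).T).T
        return np.asarray(y).reshape(n, c, -1)

    def backward(self, g):
        n, c, nc = g.shape
        W = self._op(self._L)
        gx = (W.T @ g.reshape(n * c, nc).T).T
        return np.asarray(gx).reshape(n, c, self._L)


def minibatch_features(f: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Closed-form mini-batch discrimination output.

    ``f`` is an (n, A) feature matrix, ``T`` an (A, B, C) tensor.  Each
    sample's features are projected through T to an (B, C) matrix M_i;
    the output o(x_i)_b = sum_{j != i} exp(-||M_{i,b} - M_{j,b}||_1)
    measures how close sample i is to the rest of the batch (large for
    clones — the discriminator uses it to detect mode collapse).
    """
    f = np.asarray(f, dtype=np.float64)
    T = np.asarray(T, dtype=np.float64)
    if f.ndim != 2 or f.shape[0] < 2:
        raise InvalidArgumentError(
            "minibatch discrimination needs a batch of >= 2 samples")
    if T.ndim != 3 or T.shape[0] != f.shape[1]:
        raise InvalidArgumentError(
            f"tensor T shape {T.shape} incompatible with features {f.shape}")
    n = f.shape[0]
    A, B, C = T.shape
    M = (f @ T.reshape(A, B * C)).reshape(n, B, C)
    diff = M[:, None, :, :] - M[None, :, :, :]
    dist = np.abs(diff).sum(axis=3)                 # (n, n, B)
    E = np.exp(-dist)
    return E.sum(axis=1) - 1.0                      # exclude self (exp(0))


class MinibatchDiscrimination(Layer):
    """Learnable mini-batch discrimination; output concatenates the input
    features with the B cross-sample similarity components."""

    def __init__(self, in_features: int, num_kernels: int, kernel_dim: int,
                 rng: np.random.Generator):
        super().__init__()
        A, B, C = in_features, num_kernels, kernel_dim
        T = rng.normal(0.0, 0.05, size=(A, B, C))
        self.params = [T]
        self.grads = [np.zeros_like(T)]
        self.num_kernels = B

    def forward(self, f, train=False):
        T = self.params[0]
        n = f.shape[0]
        if n < 2:
            raise InvalidArgumentError(
                "minibatch discrimination needs a batch of >= 2 samples")
        A, B, C = T.shape
        M = (f @ T.reshape(A, B * C)).reshape(n, B, C)
        diff = M[:, None, :, :] - M[None, :, :, :]
        E = np.exp(-np.abs(diff).sum(axis=3))
        self._f, self._M, self._diff, self._E = f, M, diff, E
        o = E.sum(axis=1) - 1.0
        return np.concatenate([f, o], axis=1)

    def backward(self, g):
        T = self.params[0]
        A, B, C = T.shape
        f, diff, E = self._f, self._diff, self._E
        n = f.shape[0]
        gf_direct, go = g[:, :A], g[:, A:]
        coeff = -E * (go[:, None, :] + go[None, :, :])     # (n, n, B)
        coeff[np.arange(n), np.arange(n), :] = 0.0
        gM = (coeff[:, :, :, None] * np.sign(diff)).sum(axis=1)
        gM_flat = gM.reshape(n, B * C)
        self.grads[0] += (f.T @ gM_flat).reshape(A, B, C)
        return gf_direct + gM_flat @ T.reshape(A, B * C).T


def iter_batchnorms(layer: Layer):
    """Yield every BatchNorm1d reachable from a layer (for checkpointing
    running statistics alongside parameters)."""
    if isinstance(layer, BatchNorm1d):
        yield layer
    if isinstance(layer, Sequential):
        for sub in layer.layers:
            yield from iter_batchnorms(sub)
    body = getattr(layer, "body", None)
    if isinstance(body, Sequential):
        yield from iter_batchnorms(body)


class ResidualBlock1d(Layer):
    """conv-BN-ReLU-conv-BN with an identity skip (no post-add activation,
    so zeroed convolution weights give an exact identity block)."""

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.body = Sequential([
            Conv1d(channels, channels, kernel, rng),
            BatchNorm1d(channels),
            ReLU(),
            Conv1d(channels, channels, kernel, rng),
            BatchNorm1d(channels),
        ])
        self.params = self.body.parameters()
        self.grads = self.body.gradients()

    def forward(self, x, train=False):
        return x + self.body.forward(x, train=train)

    def backward(self, g):
        return g + self.body.backward(g)

    def zero_grad(self):
        self.body.zero_grad()
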