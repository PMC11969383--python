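"""Minimal feed-forward layers with explicit backprop, on numpy.

Every layer follows the same contract: ``forward(x, train=False)`` caches
whatever the backward pass needs, ``backward(dout)`` returns the gradient
with respect to the input and fills ``grads`` for each entry of ``params``.
Volumes are laid out ``(N, C, Z, Y, X)`` and images ``(N, C, Y, X)``;
convolutions are 3x3(x3), stride 1, padding 1, implemented as im2col + GEMM
so the heavy lifting stays inside BLAS.

All arithmetic is float32; parameter initialisation follows the standard
fan-in uniform scheme (bound = 1/sqrt(fan_in)) used by mainstream deep
learning frameworks, so parameter statistics are comparable.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class: a stateless op unless ``params`` is non-empty."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))


def _fan_in_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class ConvND(Layer):
    """3x3 (2D) or 3x3x3 (3D) convolution, stride 1, zero padding 1.

    Parameters
    ----------
    ndim : 2 or 3 spatial dimensions.
    bias : the 3D encoder blocks are bias-free (group norm precedes each
        convolution); the 2D variant uses biased convolutions.
    """

    def __init__(self, in_channels: int, out_channels: int, ndim: int,
                 bias: bool, rng: np.random.Generator) -> None:
        super().__init__()
        if ndim not in (2, 3):
            raise ValueError("ndim must be 2 or 3")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.ndim = ndim
        self.ksize = 3 ** ndim
        fan_in = in_channels * self.ksize
        self.params["weight"] = _fan_in_uniform(
            rng, (out_channels, in_channels) + (3,) * ndim, fan_in)
        self.use_bias = bias
        if bias:
            self.params["bias"] = _fan_in_uniform(rng, (out_channels,), fan_in)
        self._cols: np.ndarray | None = None
        self._spatial: tuple[int, ...] = ()

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        # x: (N, C, *spatial) -> (N * prod(spatial), C * 3**ndim)
        pad = [(0, 0), (0, 0)] + [(1, 1)] * self.ndim
        xp = np.pad(x, pad)
        win = sliding_window_view(xp, (3,) * self.ndim, axis=tuple(range(2, 2 + self.ndim)))
        # win: (N, C, *spatial, *(3,)*ndim) -> (N, *spatial, C, *(3,)*ndim)
        order = (0,) + tuple(range(2, 2 + self.ndim)) + (1,) + tuple(
            range(2 + self.ndim, 2 + 2 * self.ndim))
        win = win.transpose(order)
        n = x.shape[0]
        return np.ascontiguousarray(win).reshape(n * int(np.prod(x.shape[2:])), -1)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}")
        n = x.shape[0]
        self._spatial = x.shape[2:]
        cols = self._im2col(x)
        if train:
            self._cols = cols
        w2 = self.params["weight"].reshape(self.out_channels, -1)
        out = cols @ w2.T
        if self.use_bias:
            out += self.params["bias"]
        out = out.reshape((n,) + self._spatial + (self.out_channels,))
        axes = (0, 1 + self.ndim) + tuple(range(1, 1 + self.ndim))
        return np.ascontiguousarray(out.transpose(axes))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n = dout.shape[0]
        spatial = self._spatial
        axes = (0,) + tuple(range(2, 2 + self.ndim)) + (1,)
        dflat = np.ascontiguousarray(dout.transpose(axes)).reshape(-1, self.out_channels)
        assert self._cols is not None, "backward() requires forward(train=True)"
        self.grads["weight"] = (dflat.T @ self._cols).reshape(self.params["weight"].shape)
        if self.use_bias:
            self.grads["bias"] = dflat.sum(axis=0)
        self._cols = None
        w2 = self.params["weight"].reshape(self.out_channels, -1)
        dcols = dflat @ w2  # (N*S, C*ksize)
        dcols = dcols.reshape((n,) + spatial + (self.in_channels,) + (3,) * self.ndim)
        pad_shape = (n, self.in_channels) + tuple(s + 2 for s in spatial)
        dxp = np.zeros(pad_shape, dtype=np.float32)
        # scatter-add each kernel tap back onto the padded grid; cheaper in
        # practice than a second im2col+GEMM despite the python loop
        if self.ndim == 3:
            d, h, w = spatial
            for i in range(3):
                for j in range(3):
                    for k in range(3):
                        dxp[:, :, i:i + d, j:j + h, k:k + w] += \
                            dcols[..., i, j, k].transpose(0, 4, 1, 2, 3)
        else:
            h, w = spatial
            for i in range(3):
                for j in range(3):
                    dxp[:, :, i:i + h, j:j + w] += dcols[..., i, j].transpose(0, 3, 1, 2)
        sl = (slice(None), slice(None)) + (slice(1, -1),) * self.ndim
        return np.ascontiguousarray(dxp[sl])


class GroupNorm(Layer):
    """Group normalization over channel groups, with learnable affine.

    ``groups`` is 8 in every encoder unit except the first, where the
    single-channel input forces one group. eps = 1e-5.
    """

    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5) -> None:
        super().__init__()
        if channels < 8:
            groups = 1
        if channels % groups:
            raise ValueError(f"channels {channels} not divisible by groups {groups}")
        self.channels = channels
        self.groups = groups
        self.eps = eps
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c = x.shape[:2]
        spatial = x.shape[2:]
        g = self.groups
        xg = x.reshape(n, g, -1)
        mean = xg.mean(axis=2, keepdims=True)
        var = xg.var(axis=2, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = ((xg - mean) * inv).reshape(x.shape)
        bshape = (1, c) + (1,) * len(spatial)
        out = xhat * self.params["gamma"].reshape(bshape) + self.params["beta"].reshape(bshape)
        if train:
            self._cache = (xhat, inv)
        return out.astype(x.dtype, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache  # type: ignore[misc]
        n, c = dout.shape[:2]
        spatial = dout.shape[2:]
        bshape = (1, c) + (1,) * len(spatial)
        red = (0,) + tuple(range(2, dout.ndim))
        self.grads["gamma"] = (dout * xhat).sum(axis=red)
        self.grads["beta"] = dout.sum(axis=red)
        dxhat = (dout * self.params["gamma"].reshape(bshape)).reshape(n, self.groups, -1)
        xh = xhat.reshape(n, self.groups, -1)
        m = dxhat.shape[2]
        dx = inv * (dxhat - dxhat.mean(axis=2, keepdims=True)
                    - xh * (dxhat * xh).mean(axis=2, keepdims=True))
        self._cache = None
        return dx.reshape(dout.shape).astype(dout.dtype, copy=False)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        mask = x > 0
        if train:
            self._mask = mask
        return np.where(mask, x, np.float32(0.0))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, np.float32(0.0))


class MaxPool(Layer):
    """2x (2D) or 2x2x2 (3D) max pooling, stride = window, floor semantics:
    trailing odd planes are dropped, matching common framework defaults."""

    def __init__(self, ndim: int) -> None:
        super().__init__()
        self.ndim = ndim

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c = x.shape[:2]
        spatial = x.shape[2:]
        out_sp = tuple(s // 2 for s in spatial)
        if any(s == 0 for s in out_sp):
            raise ValueError(f"spatial dims {spatial} too small for 2x pooling")
        sl = (slice(None), slice(None)) + tuple(slice(0, 2 * s) for s in out_sp)
        xt = x[sl]
        shape = (n, c) + sum(((s, 2) for s in out_sp), ())
        xr = xt.reshape(shape)
        # bring the window axes together: (N, C, *out_sp, 2**ndim)
        win_axes = tuple(3 + 2 * i for i in range(self.ndim))
        keep_axes = (0, 1) + tuple(2 + 2 * i for i in range(self.ndim))
        xw = xr.transpose(keep_axes + win_axes).reshape((n, c) + out_sp + (2 ** self.ndim,))
        arg = xw.argmax(axis=-1)
        out = np.take_along_axis(xw, arg[..., None], axis=-1)[..., 0]
        if train:
            self._arg = arg
            self._in_spatial = spatial
            self._out_sp = out_sp
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c = dout.shape[:2]
        out_sp = self._out_sp
        dw = np.zeros((n, c) + out_sp + (2 ** self.ndim,), dtype=np.float32)
        np.put_along_axis(dw, self._arg[..., None], dout[..., None], axis=-1)
        # invert the transpose/reshape of forward
        dw = dw.reshape((n, c) + out_sp + (2,) * self.ndim)
        inv = [0, 1]
        for i in range(self.ndim):
            inv.extend([2 + i, 2 + self.ndim + i])
        dw = dw.transpose(inv).reshape((n, c) + tuple(2 * s for s in out_sp))
        dx = np.zeros((n, c) + self._in_spatial, dtype=np.float32)
        sl = (slice(None), slice(None)) + tuple(slice(0, 2 * s) for s in out_sp)
        dx[sl] = dw
        return dx


class GlobalMaxPool(Layer):
    """Adaptive max pool to a single spatial location, then flatten to (N, C)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c = x.shape[:2]
        flat = x.reshape(n, c, -1)
        arg = flat.argmax(axis=2)
        if train:
            self._arg = arg
            self._shape = x.shape
        return np.take_along_axis(flat, arg[:, :, None], axis=2)[:, :, 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c = dout.shape
        dx = np.zeros((n, c, int(np.prod(self._shape[2:]))), dtype=np.float32)
        np.put_along_axis(dx, self._arg[:, :, None], dout[:, :, None], axis=2)
        return dx.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity at inference. The mask generator is owned
    by the layer so training runs are reproducible for a fixed seed."""

    def __init__(self, p: float = 0.5, seed: int = 0) -> None:
        super().__init__()
        self.p = p
        self.rng = np.random.default_rng(seed)

    def reseed(self, seed: int) -> None:
        self.rng = np.random.default_rng(seed)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p).astype(np.float32) / np.float32(1 - self.p)
        self._mask = mask
        return x * mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["weight"] = _fan_in_uniform(rng, (out_features, in_features), in_features)
        self.params["bias"] = _fan_in_uniform(rng, (out_features,), in_features)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.params["weight"].T + self.params["bias"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["weight"] = dout.T @ self._x
        self.grads["bias"] = dout.sum(axis=0)
        return dout @ self.params["weight"]


class Sequential:
    """A flat stack of layers with named blocks for parameter accounting."""

    def __init__(self, blocks: list[tuple[str, list[Layer]]]) -> None:
        self.blocks = blocks
        self.layers: list[Layer] = [l for _, ls in blocks for l in ls]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    # -- parameter plumbing ------------------------------------------------
    def named_parameters(self):
        for bi, (bname, ls) in enumerate(self.blocks):
            for li, layer in enumerate(ls):
                for pname, p in layer.params.items():
                    yield f"{bname}.{li}.{type(layer).__name__}.{pname}", layer, pname, p

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.copy() for name, _, _, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, layer, pname, p in self.named_parameters():
            if name not in state:
                raise KeyError(f"missing parameter {name}")
            if state[name].shape != p.shape:
                raise ValueError(f"shape mismatch for {name}")
            layer.params[pname] = state[name].astype(np.float32).copy()

    def block_parameter_counts(self) -> dict[str, int]:
        return {bname: sum(l.n_parameters() for l in ls) for bname, ls in self.blocks}

    def n_parameters(self) -> int:
        return sum(self.block_parameter_counts().values())


class Adam:
    """Adam with L2-coupled weight decay (decay added to the gradient),
    matching the convention of the mainstream implementation the training
    recipe was written for. Defaults: betas (0.9, 0.999), eps 1e-8."""

    def __init__(self, model: Sequential, lr: float = 1e-5, weight_decay: float = 0.0,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.model = model
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for name, layer, pname, p in self.model.named_parameters():
            g = layer.grads[pname].astype(np.float64)
            if self.wd:
                g = g + self.wd * p
            m = self.m.setdefault(name, np.zeros_like(p, dtype=np.float64))
            v = self.v.setdefault(name, np.zeros_like(p, dtype=np.float64))
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            update = self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            layer.params[pname] = (p - update).astype(np.float32)


# -- losses ---------------------------------------------------------------

def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Binary cross-entropy on logits; returns (mean loss, dL/dlogits)."""
    z = logits.astype(np.float64).ravel()
    y = targets.astype(np.float64).ravel()
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    grad = (1.0 / (1.0 + np.exp(-z)) - y) / z.size
    return float(loss), grad.reshape(logits.shape).astype(np.float32)


def mse_loss(pred: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error; returns (mean loss, dL/dpred)."""
    diff = pred.astype(np.float64).ravel() - targets.astype(np.float64).ravel()
    loss = float(np.mean(diff ** 2))
    grad = (2.0 * diff / diff.size).reshape(pred.shape).astype(np.float32)
    return loss, grad


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
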