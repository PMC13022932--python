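"""Minimal NumPy neural-network core: layers with hand-written backprop.

Everything operates on float32 ``(N, C, D, H, W)`` arrays.  Each layer caches
what its backward pass needs during ``forward`` and releases it afterwards;
gradients accumulate on :class:`Parameter` objects, mirroring the usual
deep-learning-framework contract (``zero_grad`` → forward → backward → step).

Only the operations needed by the 3D DenseNet regression network are
implemented; convolutions are lowered to BLAS matrix products via
``sliding_window_view`` so that desk-scale training is fast enough on a CPU.
"""

from __future__ import annotations

from collections import OrderedDict
from typing import Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Parameter:
    """A learnable array with an accumulated gradient and a trainable flag."""

    __slots__ = ("data", "grad", "trainable")

    def __init__(self, data: np.ndarray, trainable: bool = True):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.trainable = trainable

    @property
    def size(self) -> int:
        return int(self.data.size)

    def accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad


class Module:
    """Base class with torch-like child/parameter/buffer registration."""

    def __init__(self):
        object.__setattr__(self, "_parameters", OrderedDict())
        object.__setattr__(self, "_buffers", OrderedDict())
        object.__setattr__(self, "_modules", OrderedDict())
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._parameters[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ---------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._parameters.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in self._buffers:
            yield prefix + name, self._buffers[name]
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def set_training(self, mode: bool) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def zero_grad(self) -> None:
        for _, p in self.named_parameters():
            p.grad = None

    # -- state -------------------------------------------------------------
    def state_dict(self) -> "OrderedDict[str, np.ndarray]":
        state: OrderedDict[str, np.ndarray] = OrderedDict()
        for name, p in self.named_parameters():
            state[name] = p.data.copy()
        for name, b in self.named_buffers():
            state[name] = b.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        own_params = dict(self.named_parameters())
        # buffers need owner references so assignment sticks
        buf_owners: dict[str, tuple[Module, str]] = {}

        def walk(mod: Module, prefix: str) -> None:
            for key in mod._buffers:
                buf_owners[prefix + key] = (mod, key)
            for name, child in mod._modules.items():
                walk(child, prefix + name + ".")

        walk(self, "")
        expected = set(own_params) | set(buf_owners)
        got = set(state)
        bad = sorted(expected.symmetric_difference(got))
        if bad:
            raise CheckpointError(
                "state mismatch; offending keys: " + ", ".join(bad[:10]))
        for name, p in own_params.items():
            arr = np.asarray(state[name])
            if arr.shape != p.data.shape:
                raise CheckpointError(
                    f"shape mismatch for '{name}': "
                    f"{arr.shape} vs {p.data.shape}")
            p.data = np.ascontiguousarray(arr, dtype=np.float32)
        for name, (mod, key) in buf_owners.items():
            arr = np.asarray(state[name])
            if arr.shape != mod._buffers[key].shape:
                raise CheckpointError(
                    f"shape mismatch for buffer '{name}': "
                    f"{arr.shape} vs {mod._buffers[key].shape}")
            mod._buffers[key] = np.ascontiguousarray(arr, dtype=np.float32)

    # -- interface ---------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class CheckpointError(ValueError):
    """Raised when a weight set does not match the model it is loaded into."""


def _triple(v) -> tuple[int, int, int]:
    if isinstance(v, int):
        return (v, v, v)
    t = tuple(int(x) for x in v)
    assert len(t) == 3
    return t


class Conv3d(Module):
    """3D convolution (cross-correlation), lowered to an im2col matmul."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size,
                 stride=1, padding=0, bias: bool = False,
                 needs_input_grad: bool = True):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = _triple(kernel_size)
        self.stride = _triple(stride)
        self.padding = _triple(padding)
        self.needs_input_grad = needs_input_grad
        self._pointwise = (self.kernel_size == (1, 1, 1)
                           and self.stride == (1, 1, 1)
                           and self.padding == (0, 0, 0))
        self.weight = Parameter(
            np.zeros((out_channels, in_channels) + self.kernel_size))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self._cache = None

    def init_weights(self, rng: np.random.Generator) -> None:
        fan_in = self.in_channels * int(np.prod(self.kernel_size))
        std = np.sqrt(2.0 / fan_in)  # He init for rectifier nets
        self.weight.data = rng.normal(
            0.0, std, self.weight.data.shape).astype(np.float32)
        if self.bias is not None:
            self.bias.data = np.zeros(self.out_channels, dtype=np.float32)

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        kd, kh, kw = self.kernel_size
        sd, sh, sw = self.stride
        pd, ph, pw = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
        win = sliding_window_view(xp, (kd, kh, kw), axis=(2, 3, 4))
        win = win[:, :, ::sd, ::sh, ::sw]  # (N, C, Do, Ho, Wo, kd, kh, kw)
        n, c, do, ho, wo = win.shape[:5]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7))
        cols = cols.reshape(n * do * ho * wo, c * kd * kh * kw)
        return cols, (xp.shape, (n, do, ho, wo))

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 5 or x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected (N, {self.in_channels}, D, H, W) input, "
                f"got shape {x.shape}")
        if self._pointwise:
            n, c, d, h, w = x.shape
            xr = x.reshape(n, c, d * h * w)
            wmat = self.weight.data.reshape(self.out_channels, c)
            out = np.matmul(wmat, xr)
            if self.bias is not None:
                out += self.bias.data[:, None]
            if self.training:
                self._cache = xr
            return out.reshape(n, self.out_channels, d, h, w)
        cols, (xp_shape, (n, do, ho, wo)) = self._im2col(x)
        wmat = self.weight.data.reshape(self.out_channels, -1)
        out = cols @ wmat.T
        if self.bias is not None:
            out += self.bias.data
        out = out.reshape(n, do, ho, wo, self.out_channels)
        out = np.ascontiguousarray(out.transpose(0, 4, 1, 2, 3))
        if self.training:
            self._cache = (cols, xp_shape, (n, do, ho, wo))
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._pointwise:
            xr, self._cache = self._cache, None
            n = grad.shape[0]
            gr = grad.reshape(n, self.out_channels, -1)
            wmat = self.weight.data.reshape(self.out_channels,
                                            self.in_channels)
            dw = np.matmul(gr, xr.transpose(0, 2, 1)).sum(axis=0)
            self.weight.accumulate(dw.reshape(self.weight.data.shape))
            if self.bias is not None:
                self.bias.accumulate(gr.sum(axis=(0, 2)))
            if not self.needs_input_grad:
                return None
            dx = np.matmul(wmat.T, gr)
            return dx.reshape(grad.shape[0], self.in_channels,
                              *grad.shape[2:]).astype(np.float32)
        cols, xp_shape, (n, do, ho, wo) = self._cache
        self._cache = None
        kd, kh, kw = self.kernel_size
        sd, sh, sw = self.stride
        pd, ph, pw = self.padding
        g = np.ascontiguousarray(grad.transpose(0, 2, 3, 4, 1))
        g = g.reshape(n * do * ho * wo, self.out_channels)
        wmat = self.weight.data.reshape(self.out_channels, -1)
        self.weight.accumulate((g.T @ cols).reshape(self.weight.data.shape))
        if self.bias is not None:
            self.bias.accumulate(g.sum(axis=0))
        if not self.needs_input_grad:
            return None
        dcols = g @ wmat  # (N*P, C*k3)
        dcols = dcols.reshape(n, do, ho, wo, self.in_channels, kd, kh, kw)
        dcols = dcols.transpose(0, 4, 5, 6, 7, 1, 2, 3)  # N,C,kd,kh,kw,Do,Ho,Wo
        dxp = np.zeros(xp_shape, dtype=np.float32)
        for i in range(kd):
            for j in range(kh):
                for k in range(kw):
                    dxp[:, :, i:i + sd * do:sd, j:j + sh * ho:sh,
                        k:k + sw * wo:sw] += dcols[:, :, i, j, k]
        d, h, w = xp_shape[2] - 2 * pd, xp_shape[3] - 2 * ph, xp_shape[4] - 2 * pw
        return dxp[:, :, pd:pd + d, ph:ph + h, pw:pw + w]


class BatchNorm3d(Module):
    """Per-channel batch normalisation with running statistics.

    When the layer's affine parameters are frozen (transfer-learning shallow
    mode) the running statistics are used even during training and are never
    updated, so a frozen feature extractor is bit-stable across rounds.

    With ``frozen_stats=True`` the stored statistics are used at all times
    and never modified (frozen-batch-norm semantics): normalisation becomes
    a fixed transform plus the learnable affine, which keeps local training
    a pure function of the parameters — a zero-learning-rate round returns
    the incoming weights bit-exactly, and federated averaging never has to
    reconcile divergent batch statistics across non-IID clients.
    """

    def __init__(self, num_features: int, eps: float = 1e-5,
                 momentum: float = 0.1, frozen_stats: bool = False):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.frozen_stats = frozen_stats
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self._buffers["running_mean"] = np.zeros(num_features, dtype=np.float32)
        self._buffers["running_var"] = np.ones(num_features, dtype=np.float32)
        self._cache = None

    @property
    def running_mean(self) -> np.ndarray:
        return self._buffers["running_mean"]

    @property
    def running_var(self) -> np.ndarray:
        return self._buffers["running_var"]

    def forward(self, x: np.ndarray) -> np.ndarray:
        shape = (1, self.num_features, 1, 1, 1)
        use_batch_stats = (self.training and self.weight.trainable
                           and not self.frozen_stats)
        if use_batch_stats:
            axes = (0, 2, 3, 4)
            m = x.mean(axis=axes)
            v = x.var(axis=axes)
            n_elem = x.size // self.num_features
            unbiased = v * (n_elem / max(n_elem - 1, 1))
            mom = self.momentum
            self._buffers["running_mean"] = (
                (1 - mom) * self._buffers["running_mean"] + mom * m
            ).astype(np.float32)
            self._buffers["running_var"] = (
                (1 - mom) * self._buffers["running_var"] + mom * unbiased
            ).astype(np.float32)
        else:
            m = self._buffers["running_mean"]
            v = self._buffers["running_var"]
        inv_std = 1.0 / np.sqrt(v + self.eps)
        xhat = (x - m.reshape(shape)) * inv_std.reshape(shape)
        out = xhat * self.weight.data.reshape(shape) + self.bias.data.reshape(shape)
        if self.training:
            self._cache = (xhat, inv_std, use_batch_stats)
        return out.astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, used_batch = self._cache
        self._cache = None
        shape = (1, self.num_features, 1, 1, 1)
        axes = (0, 2, 3, 4)
        dgamma = (grad * xhat).sum(axis=axes)
        dbeta = grad.sum(axis=axes)
        self.weight.accumulate(dgamma)
        self.bias.accumulate(dbeta)
        gw = self.weight.data.reshape(shape) * inv_std.reshape(shape)
        if not used_batch:
            return (grad * gw).astype(np.float32)
        n_elem = grad.size // self.num_features
        dx = gw * (grad
                   - dbeta.reshape(shape) / n_elem
                   - xhat * dgamma.reshape(shape) / n_elem)
        return dx.astype(np.float32)


class ReLU(Module):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if self.training:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        mask, self._mask = self._mask, None
        return grad * mask


class MaxPool3d(Module):
    def __init__(self, kernel_size=3, stride=2, padding=1):
        super().__init__()
        self.kernel_size = _triple(kernel_size)
        self.stride = _triple(stride)
        self.padding = _triple(padding)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        kd, kh, kw = self.kernel_size
        sd, sh, sw = self.stride
        pd, ph, pw = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)),
                    constant_values=-np.inf)
        win = sliding_window_view(xp, (kd, kh, kw), axis=(2, 3, 4))
        win = win[:, :, ::sd, ::sh, ::sw]
        n, c, do, ho, wo = win.shape[:5]
        flat = win.reshape(n, c, do, ho, wo, kd * kh * kw)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if self.training:
            self._cache = (idx, xp.shape, x.shape)
        return np.ascontiguousarray(out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        idx, xp_shape, x_shape = self._cache
        self._cache = None
        kd, kh, kw = self.kernel_size
        sd, sh, sw = self.stride
        pd, ph, pw = self.padding
        n, c, do, ho, wo = grad.shape
        ii, jj, kk = np.unravel_index(idx, (kd, kh, kw))
        ng, cg, dg, hg, wg = np.meshgrid(
            np.arange(n), np.arange(c), np.arange(do), np.arange(ho),
            np.arange(wo), indexing="ij")
        dxp = np.zeros(xp_shape, dtype=np.float32)
        np.add.at(dxp, (ng, cg, dg * sd + ii, hg * sh + jj, wg * sw + kk), grad)
        return dxp[:, :, pd:pd + x_shape[2], ph:ph + x_shape[3],
                   pw:pw + x_shape[4]]


class AvgPool3d(Module):
    """Non-overlapping average pooling (kernel == stride), floor mode."""

    def __init__(self, kernel_size=2):
        super().__init__()
        self.kernel_size = _triple(kernel_size)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        kd, kh, kw = self.kernel_size
        n, c, d, h, w = x.shape
        do, ho, wo = d // kd, h // kh, w // kw
        xc = x[:, :, :do * kd, :ho * kh, :wo * kw]
        out = xc.reshape(n, c, do, kd, ho, kh, wo, kw).mean(axis=(3, 5, 7))
        if self.training:
            self._cache = x.shape
        return np.ascontiguousarray(out, dtype=np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_shape = self._cache
        self._cache = None
        kd, kh, kw = self.kernel_size
        n, c, do, ho, wo = grad.shape
        g = grad / (kd * kh * kw)
        g = np.broadcast_to(
            g[:, :, :, None, :, None, :, None],
            (n, c, do, kd, ho, kh, wo, kw))
        dx = np.zeros(x_shape, dtype=np.float32)
        dx[:, :, :do * kd, :ho * kh, :wo * kw] = g.reshape(
            n, c, do * kd, ho * kh, wo * kw)
        return dx


class GlobalAvgPool3d(Module):
    """Adaptive average pooling to a single spatial location, flattened."""

    def __init__(self):
        super().__init__()
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = x.mean(axis=(2, 3, 4))
        if self.training:
            self._cache = x.shape
        return out.astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_shape = self._cache
        self._cache = None
        n, c, d, h, w = x_shape
        dx = grad[:, :, None, None, None] / (d * h * w)
        return np.broadcast_to(dx, x_shape).astype(np.float32)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(np.zeros((out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None
        self._cache = None

    def init_weights(self, rng: np.random.Generator) -> None:
        bound = 1.0 / np.sqrt(self.in_features)
        self.weight.data = rng.uniform(
            -bound, bound, self.weight.data.shape).astype(np.float32)
        if self.bias is not None:
            self.bias.data = rng.uniform(
                -bound, bound, self.out_features).astype(np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = x @ self.weight.data.T
        if self.bias is not None:
            out += self.bias.data
        if self.training:
            self._cache = x
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, self._cache = self._cache, None
        self.weight.accumulate(grad.T @ x)
        if self.bias is not None:
            self.bias.accumulate(grad.sum(axis=0))
        return grad @ self.weight.data


class Sequential(Module):
    def __init__(self, **layers: Module):
        super().__init__()
        self._order: list[str] = []
        for name, layer in layers.items():
            setattr(self, name, layer)
            self._order.append(name)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for name in self._order:
            x = self._modules[name](x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for name in reversed(self._order):
            grad = self._modules[name].backward(grad)
        return grad
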