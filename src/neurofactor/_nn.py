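"""Minimal 3D convolutional network engine (numpy, hand-written backprop).

Implements exactly the pieces the residual regression network needs: 3D
convolution (same padding, arbitrary stride), batch normalization with
running statistics, ReLU, parameter-free strided/zero-padded residual
shortcuts, global average pooling, a linear head, and an Adam optimizer.

Activations are channels-last ``(B, D, H, W, C)`` so that the im2col gather
writes and the GEMM reshapes are contiguous: each convolution builds a
column buffer ``(B, P, k^3 * C_in)`` from the k^3 shifted views and runs a
single matrix multiply against the flattened kernel.  All arrays are
float32 and everything is deterministic given the initializing
``numpy.random.Generator``.
"""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True, fastmath=True)
def _im2col(xp, cols, s, k):  # pragma: no cover - exercised via Conv3d
    """Gather k^3 shifted views of xp (B,Dp,Hp,Wp,C) into cols
    (B,Do,Ho,Wo,k^3,C); writes are contiguous per output voxel."""
    B, Dp, Hp, Wp, C = xp.shape
    Do, Ho, Wo = cols.shape[1], cols.shape[2], cols.shape[3]
    for b in range(B):
        for d in range(Do):
            for h in range(Ho):
                for w in range(Wo):
                    off = 0
                    for i in range(k):
                        for j in range(k):
                            for l in range(k):
                                for c in range(C):
                                    cols[b, d, h, w, off, c] = xp[
                                        b, d * s + i, h * s + j, w * s + l, c]
                                off += 1


@numba.njit(cache=True, fastmath=True)
def _bn_stats(x2d):  # pragma: no cover - exercised via BatchNorm3d
    """Per-channel sum and sum of squares of a (N, C) view, in float64."""
    N, C = x2d.shape
    s = np.zeros(C, dtype=np.float64)
    ss = np.zeros(C, dtype=np.float64)
    for n in range(N):
        for c in range(C):
            v = np.float64(x2d[n, c])
            s[c] += v
            ss[c] += v * v
    return s, ss


@numba.njit(cache=True, fastmath=True)
def _bn_normalize(x2d, xhat, y, mean, ivar, gamma, beta):  # pragma: no cover
    N, C = x2d.shape
    for n in range(N):
        for c in range(C):
            h = (x2d[n, c] - mean[c]) * ivar[c]
            xhat[n, c] = h
            y[n, c] = gamma[c] * h + beta[c]


@numba.njit(cache=True, fastmath=True)
def _bn_backward(dy2d, xhat, ivar, gamma, dgamma, dbeta, dx):  # pragma: no cover
    N, C = dy2d.shape
    s1 = np.zeros(C, dtype=np.float64)
    s2 = np.zeros(C, dtype=np.float64)
    for n in range(N):
        for c in range(C):
            d = np.float64(dy2d[n, c])
            h = np.float64(xhat[n, c])
            s1[c] += d
            s2[c] += d * h
            dgamma[c] += d * h
            dbeta[c] += d
    for n in range(N):
        for c in range(C):
            dx[n, c] = (ivar[c] / N) * (
                N * gamma[c] * dy2d[n, c]
                - gamma[c] * s1[c]
                - xhat[n, c] * gamma[c] * s2[c]
            )


@numba.njit(cache=True, fastmath=True)
def _col2im(dcols, dxp, s, k):  # pragma: no cover - exercised via Conv3d
    """Scatter-add column gradients back onto the padded input gradient."""
    B, Dp, Hp, Wp, C = dxp.shape
    Do, Ho, Wo = dcols.shape[1], dcols.shape[2], dcols.shape[3]
    for b in range(B):
        for d in range(Do):
            for h in range(Ho):
                for w in range(Wo):
                    off = 0
                    for i in range(k):
                        for j in range(k):
                            for l in range(k):
                                for c in range(C):
                                    dxp[b, d * s + i, h * s + j, w * s + l, c] += \
                                        dcols[b, d, h, w, off, c]
                                off += 1

__all__ = [
    "Param",
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "GlobalAvgPool",
    "Linear",
    "BasicBlock3d",
    "Adam",
]

_DT = np.float32


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=_DT)
        self.grad = np.zeros_like(self.value)


class Conv3d:
    """3D convolution, cubic kernel, 'same' padding, arbitrary stride.

    Weight layout ``(k, k, k, C_in, C_out)``; He-normal initialization.
    """

    def __init__(self, c_in: int, c_out: int, kernel_size: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        k = kernel_size
        fan_in = c_in * k**3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k, k, k, c_in, c_out))
        self.weight = Param(w)
        self.bias = Param(np.zeros(c_out))
        self.kernel_size = k
        self.stride = stride
        self.c_in = c_in
        self.c_out = c_out
        self.needs_input_grad = True  # first layer may switch this off
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def _out_shape(self, spatial) -> tuple[int, int, int]:
        k, s, p = self.kernel_size, self.stride, self.kernel_size // 2
        return tuple((d + 2 * p - k) // s + 1 for d in spatial)  # type: ignore[return-value]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        B, D, H, W, C = x.shape
        k, s, p = self.kernel_size, self.stride, self.kernel_size // 2
        Do, Ho, Wo = self._out_shape((D, H, W))
        P = Do * Ho * Wo
        ck = C * k**3
        if k == 1 and s == 1:
            cols = x.reshape(B * P, C)
        else:
            xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0))) if p else x
            cols = np.empty((B, Do, Ho, Wo, k**3, C), dtype=_DT)
            _im2col(np.ascontiguousarray(xp), cols, s, k)
            cols = cols.reshape(B * P, ck)
        # weight (k,k,k,Cin,Cout) flattens to (k^3*Cin, Cout) matching cols
        y = cols @ self.weight.value.reshape(ck, self.c_out) + self.bias.value
        if training:
            self._cache = (cols, (B, D, H, W, C), (Do, Ho, Wo))
        return y.reshape(B, Do, Ho, Wo, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, (B, D, H, W, C), (Do, Ho, Wo) = self._cache  # type: ignore[misc]
        self._cache = None
        k, s, p = self.kernel_size, self.stride, self.kernel_size // 2
        P = Do * Ho * Wo
        ck = C * k**3
        dyf = dy.reshape(B * P, self.c_out)
        self.bias.grad += dyf.sum(axis=0)
        self.weight.grad += (cols.T @ dyf).reshape(self.weight.value.shape)
        if not self.needs_input_grad:
            return None
        dcols = dyf @ self.weight.value.reshape(ck, self.c_out).T
        if k == 1 and s == 1:
            return dcols.reshape(B, D, H, W, C)
        dcols = np.ascontiguousarray(dcols).reshape(B, Do, Ho, Wo, k**3, C)
        dxp = np.zeros((B, D + 2 * p, H + 2 * p, W + 2 * p, C), dtype=_DT)
        _col2im(dcols, dxp, s, k)
        if p:
            return dxp[:, p:p + D, p:p + H, p:p + W, :]
        return dxp


class BatchNorm3d:
    """Per-channel batch normalization with running statistics.

    Batch statistics during training; frozen running statistics at inference.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=_DT)
        self.running_var = np.ones(channels, dtype=_DT)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None
        self._calib: list | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def begin_calibration(self) -> None:
        """Start accumulating exact dataset statistics (frozen weights)."""
        self._calib = [np.zeros(self.gamma.value.shape[0], dtype=np.float64),
                       np.zeros(self.gamma.value.shape[0], dtype=np.float64), 0]

    def end_calibration(self) -> None:
        """Replace running statistics with the accumulated exact ones."""
        s, ss, n = self._calib  # type: ignore[misc]
        self._calib = None
        if n == 0:
            return
        mean = s / n
        self.running_mean = mean.astype(_DT)
        self.running_var = (ss / n - mean**2).astype(_DT)

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        C = x.shape[-1]
        x2d = np.ascontiguousarray(x).reshape(-1, C)
        N = x2d.shape[0]
        if training:
            s, ss = _bn_stats(x2d)
            mean = s / N
            var = ss / N - mean**2
            if self._calib is not None:
                self._calib[0] += s
                self._calib[1] += ss
                self._calib[2] += N
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(_DT)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(_DT)
        else:
            mean, var = self.running_mean, self.running_var
        ivar = (1.0 / np.sqrt(var + self.eps)).astype(x2d.dtype, copy=False)
        mean = np.asarray(mean, dtype=x2d.dtype)
        xhat = np.empty_like(x2d)
        y = np.empty_like(x2d)
        _bn_normalize(x2d, xhat, y, mean, ivar,
                      self.gamma.value.astype(x2d.dtype, copy=False),
                      self.beta.value.astype(x2d.dtype, copy=False))
        if training:
            self._cache = (xhat, ivar, x.shape)
        return y.reshape(x.shape)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, ivar, shape = self._cache  # type: ignore[misc]
        self._cache = None
        C = shape[-1]
        dy2d = np.ascontiguousarray(dy).reshape(-1, C)
        dx = np.empty_like(dy2d)
        _bn_backward(dy2d, xhat, ivar,
                     self.gamma.value.astype(dy2d.dtype, copy=False),
                     self.gamma.grad, self.beta.grad, dx)
        return dx.reshape(shape)


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        y = np.maximum(x, 0)
        if training:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class GlobalAvgPool:
    """Mean over the spatial axes: (B, D, H, W, C) -> (B, C)."""

    def __init__(self) -> None:
        self._shape: tuple | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            self._shape = x.shape
        return x.mean(axis=(1, 2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, D, H, W, C = self._shape  # type: ignore[misc]
        self._shape = None
        scale = np.float32(1.0 / (D * H * W))
        return np.broadcast_to(dy[:, None, None, None, :] * scale,
                               (B, D, H, W, C)).astype(_DT)


class Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        bound = 1.0 / np.sqrt(d_in)
        self.weight = Param(rng.uniform(-bound, bound, size=(d_out, d_in)))
        self.bias = Param(np.zeros(d_out))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        dx = dy @ self.weight.value
        self._x = None
        return dx


class _ShortcutA:
    """Parameter-free residual shortcut: stride subsampling + channel zero-pad.

    Keeps the convolution count of the network at its nominal value (no 1x1
    projection convolutions on the skip path).
    """

    def __init__(self, c_in: int, c_out: int, stride: int):
        self.c_in, self.c_out, self.stride = c_in, c_out, stride
        self._in_shape: tuple | None = None

    def forward(self, x: np.ndarray, out_spatial, training: bool = True) -> np.ndarray:
        s = self.stride
        if training:
            self._in_shape = x.shape
        y = x[:, :s * out_spatial[0]:s, :s * out_spatial[1]:s, :s * out_spatial[2]:s, :]
        if self.c_out > self.c_in:
            y = np.pad(y, ((0, 0), (0, 0), (0, 0), (0, 0),
                           (0, self.c_out - self.c_in)))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, D, H, W, C = self._in_shape  # type: ignore[misc]
        self._in_shape = None
        s = self.stride
        dy = dy[..., :self.c_in]
        dx = np.zeros((B, D, H, W, C), dtype=_DT)
        Do, Ho, Wo = dy.shape[1:4]
        dx[:, :s * Do:s, :s * Ho:s, :s * Wo:s, :] = dy
        return dx


class BasicBlock3d:
    """Residual basic block: conv-BN-ReLU-conv-BN, add shortcut, ReLU.

    Two 3x3x3 convolutions; the first carries the block's stride.
    """

    def __init__(self, c_in: int, c_out: int, stride: int, kernel_size: int,
                 rng: np.random.Generator):
        self.conv1 = Conv3d(c_in, c_out, kernel_size, stride, rng)
        self.bn1 = BatchNorm3d(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv3d(c_out, c_out, kernel_size, 1, rng)
        self.bn2 = BatchNorm3d(c_out)
        self.relu2 = ReLU()
        self.shortcut = _ShortcutA(c_in, c_out, stride)

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in (self.conv1, self.bn1, self.conv2, self.bn2):
            out.extend(layer.params())
        return out

    def convolutions(self) -> list[Conv3d]:
        return [self.conv1, self.conv2]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        out = self.conv1.forward(x, training)
        out = self.bn1.forward(out, training)
        out = self.relu1.forward(out, training)
        out = self.conv2.forward(out, training)
        out = self.bn2.forward(out, training)
        out = out + self.shortcut.forward(x, out.shape[1:4], training)
        return self.relu2.forward(out, training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.relu2.backward(dy)
        dshort = self.shortcut.backward(d)
        d = self.bn2.backward(d)
        d = self.conv2.backward(d)
        d = self.relu1.backward(d)
        d = self.bn1.backward(d)
        d = self.conv1.backward(d)
        return d + dshort


class Adam:
    """Adam optimizer with optional decoupled weight decay.

    Decay applies only to the params listed in ``decay_params`` (convolution
    and linear weights; never biases or normalization scales).
    """

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0,
                 decay_params: list[Param] | None = None):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._decay_ids = {id(p) for p in (decay_params or [])}
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad.fill(0.0)

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if self.weight_decay and id(p) in self._decay_ids:
                p.value -= self.lr * self.weight_decay * p.value
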