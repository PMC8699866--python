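"""Layer implementations. Tensors are NCHW float32."""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np

F32 = np.float32


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """Unfold (N, C, H, W) into (N, C*k*k, OH*OW) patch columns."""
    n, c, h, w = x.shape
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    cols = np.empty((n, c, k, k, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
    return cols.reshape(n, c * k * k, oh * ow)


def col2im(cols: np.ndarray, x_shape: Tuple[int, int, int, int],
           k: int, stride: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add patch columns back to (N, C, H, W)."""
    n, c, h, w = x_shape
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    cols6 = cols.reshape(n, c, k, k, oh, ow)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += cols6[:, :, i, j]
    return xp[:, :, pad:pad + h, pad:pad + w] if pad else xp


class Layer:
    """Base layer: ``params``/``grads`` are parallel dicts of float32 arrays."""

    def __init__(self) -> None:
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int = 1, pad: int = 0,
                 rng: Optional[np.random.Generator] = None,
                 weight_scale: Optional[float] = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = weight_scale if weight_scale is not None else np.sqrt(2.0 / (in_ch * k * k))
        self.k, self.stride, self.pad = k, stride, pad
        self.in_ch, self.out_ch = in_ch, out_ch
        self.params["W"] = (scale * rng.standard_normal((out_ch, in_ch * k * k))).astype(F32)
        self.params["b"] = np.zeros(out_ch, dtype=F32)

    def forward(self, x, train=False, rng=None):
        n = x.shape[0]
        self._x_shape = x.shape
        cols = im2col(x, self.k, self.stride, self.pad)  # (N, Ckk, P)
        self._cols = cols
        oh = (x.shape[2] + 2 * self.pad - self.k) // self.stride + 1
        ow = (x.shape[3] + 2 * self.pad - self.k) // self.stride + 1
        out = np.matmul(self.params["W"][None], cols)  # (N, O, P)
        out += self.params["b"][None, :, None]
        return out.reshape(n, self.out_ch, oh, ow)

    def backward(self, dout):
        n = dout.shape[0]
        dmat = dout.reshape(n, self.out_ch, -1)  # (N, O, P)
        self.grads["W"] = np.einsum("nop,ncp->oc", dmat, self._cols, optimize=True).astype(F32)
        self.grads["b"] = dmat.sum(axis=(0, 2)).astype(F32)
        dcols = np.matmul(self.params["W"].T[None], dmat)  # (N, Ckk, P)
        return col2im(dcols, self._x_shape, self.k, self.stride, self.pad)


class ConvTranspose2d(Layer):
    """Stride-2 style transposed convolution; output spatial size = stride * input.

    Geometry is chosen so a 5x5/stride-2/pad-2 layer exactly doubles the
    spatial size (implicit output padding of 1), the standard GAN upsampler.
    """

    def __init__(self, in_ch: int, out_ch: int, k: int = 5, stride: int = 2, pad: int = 2,
                 rng: Optional[np.random.Generator] = None,
                 weight_scale: float = 0.02) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.pad = k, stride, pad
        self.in_ch, self.out_ch = in_ch, out_ch
        self.params["W"] = (weight_scale * rng.standard_normal((in_ch, out_ch * k * k))).astype(F32)
        self.params["b"] = np.zeros(out_ch, dtype=F32)

    def _out_shape(self, x_shape):
        n, _, h, w = x_shape
        return (n, self.out_ch, self.stride * h, self.stride * w)

    def forward(self, x, train=False, rng=None):
        self._x = x
        y_shape = self._out_shape(x.shape)
        # check adjoint geometry: im2col of y must tile back to x's grid
        oh = (y_shape[2] + 2 * self.pad - self.k) // self.stride + 1
        if oh != x.shape[2]:
            raise ValueError("incompatible transposed-convolution geometry")
        n = x.shape[0]
        xmat = x.reshape(n, self.in_ch, -1)  # (N, I, P)
        cols = np.matmul(self.params["W"].T[None], xmat)  # (N, Okk, P)
        y = col2im(cols, y_shape, self.k, self.stride, self.pad)
        y += self.params["b"][None, :, None, None]
        return y

    def backward(self, dout):
        n = dout.shape[0]
        cols_dy = im2col(dout, self.k, self.stride, self.pad)  # (N, Okk, P)
        xmat = self._x.reshape(n, self.in_ch, -1)
        self.grads["W"] = np.einsum("nip,nqp->iq", xmat, cols_dy, optimize=True).astype(F32)
        self.grads["b"] = dout.sum(axis=(0, 2, 3)).astype(F32)
        dx = np.matmul(self.params["W"][None], cols_dy)  # (N, I, P)
        return dx.reshape(self._x.shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int,
                 rng: Optional[np.random.Generator] = None,
                 weight_scale: Optional[float] = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = weight_scale if weight_scale is not None else np.sqrt(2.0 / in_dim)
        self.params["W"] = (scale * rng.standard_normal((in_dim, out_dim))).astype(F32)
        self.params["b"] = np.zeros(out_dim, dtype=F32)

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = (self._x.T @ dout).astype(F32)
        self.grads["b"] = dout.sum(axis=0).astype(F32)
        return dout @ self.params["W"].T


class BatchNorm2d(Layer):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.9) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(channels, dtype=F32)
        self.params["beta"] = np.zeros(channels, dtype=F32)
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)

    def forward(self, x, train=False, rng=None):
        axes = (0, 2, 3) if x.ndim == 4 else (0,)
        shape = (1, -1, 1, 1) if x.ndim == 4 else (1, -1)
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps).astype(F32)
        self._xhat = ((x - mu.reshape(shape)) / self._std.reshape(shape)).astype(F32)
        self._axes, self._shape = axes, shape
        self._m = x.size // x.shape[1]
        return self.params["gamma"].reshape(shape) * self._xhat + self.params["beta"].reshape(shape)

    def backward(self, dout):
        axes, shape, m = self._axes, self._shape, self._m
        dgamma = (dout * self._xhat).sum(axis=axes)
        dbeta = dout.sum(axis=axes)
        self.grads["gamma"] = dgamma.astype(F32)
        self.grads["beta"] = dbeta.astype(F32)
        g = self.params["gamma"].reshape(shape)
        dx = (g / (m * self._std.reshape(shape))) * (
            m * dout - self._xhat * dgamma.reshape(shape) - dbeta.reshape(shape))
        return dx.astype(F32)


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2) -> None:
        super().__init__()
        self.slope = slope

    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.slope * dout)


class Tanh(Layer):
    def forward(self, x, train=False, rng=None):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout):
        return dout * (1 - self._y**2)


class Sigmoid(Layer):
    def forward(self, x, train=False, rng=None):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, dout):
        return dout * self._y * (1 - self._y)


class Dropout(Layer):
    """Inverted dropout; active only when ``train`` and an rng is supplied."""

    def __init__(self, p: float = 0.5) -> None:
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout in training mode requires an rng")
        self._mask = (rng.random(x.shape) >= self.p).astype(x.dtype) / (1 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class MaxPool2d(Layer):
    """2x2 stride-2 max pooling."""

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        self._x_shape = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4)
        self._argmax = r.argmax(axis=-1)
        return np.take_along_axis(r, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, h, w = self._x_shape
        dr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dr, self._argmax[..., None], dout[..., None], axis=-1)
        return dr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h, w)


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: Tuple[int, ...]) -> None:
        super().__init__()
        self.shape = shape

    def forward(self, x, train=False, rng=None):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dout):
        return dout.reshape(self._in_shape)


class Sequential:
    def __init__(self, layers: List[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    __call__ = forward

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def param_items(self):
        """Yield (layer_index, name, params_dict, grads_dict) for trainable layers."""
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                yield i, name, layer.params, layer.grads

    def n_parameters(self) -> int:
        return sum(p[2][p[1]].size for p in self.param_items())

    def state_dict(self) -> Dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params.items():
                out[f"{i}.{name}"] = arr.copy()
            if isinstance(layer, BatchNorm2d):
                out[f"{i}.running_mean"] = layer.running_mean.copy()
                out[f"{i}.running_var"] = layer.running_var.copy()
        return out

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name][...] = state[f"{i}.{name}"]
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = state[f"{i}.running_mean"]
                layer.running_var[...] = state[f"{i}.running_var"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean cross-entropy and gradient w.r.t. logits for integer labels."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.mean(np.log(p[np.arange(n), labels] + 1e-12)))
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(F32)
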