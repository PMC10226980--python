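"""Minimal neural-network layers on numpy arrays.

All layers operate on float32 NHWC batches (channels last; dense layers on
(N, F) matrices), cache what their backward pass needs, and accumulate
parameter gradients in ``.grads``. Only the operations required by the
instance classifier and the benchmark architectures are implemented:
stride-1 'same' convolutions, SeLU, 2x2 average/max pooling, global average
pooling, flatten and dense layers. Backward passes are exact (verified
against finite differences in the tests), which is what makes Grad-CAM and
FGSM possible.

Convolution is computed as a sum of k*k shifted GEMMs rather than a
monolithic im2col, trading the large patch-matrix gather for contiguous
row copies — substantially faster for small kernels on a single CPU core.
"""

from __future__ import annotations

import numpy as np

# SeLU constants (Klambauer et al., self-normalizing networks)
_SELU_ALPHA = 1.6732632423543772
_SELU_LAMBDA = 1.0507009873554805


class Layer:
    """Base class: forward/backward with optional activation capture."""

    name: str = ""
    trainable: bool = True

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.capture = False
        self.captured_activation: np.ndarray | None = None
        self.captured_gradient: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Conv2d(Layer):
    """Stride-1 'same' convolution, weights stored as (k, k, in, out)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        rng: np.random.Generator | None = None,
        name: str = "",
    ) -> None:
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd for 'same' padding")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.pad = kernel_size // 2
        self.name = name
        fan_in = in_channels * kernel_size * kernel_size
        rng = rng or np.random.default_rng()
        # LeCun normal: the standard companion of SeLU
        weight = rng.normal(
            0.0,
            np.sqrt(1.0 / fan_in),
            size=(kernel_size, kernel_size, in_channels, out_channels),
        )
        self.params = {
            "weight": weight.astype(np.float32),
            "bias": np.zeros(out_channels, dtype=np.float32),
        }
        self._xp: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def _padded(self, x: np.ndarray) -> np.ndarray:
        if self.pad == 0:
            return x
        return np.pad(x, ((0, 0), (self.pad, self.pad), (self.pad, self.pad), (0, 0)))

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        xp = self._padded(x)
        self._xp, self._xshape = xp, x.shape
        k, weight = self.kernel_size, self.params["weight"]
        y = np.empty((n * h * w, self.out_channels), dtype=x.dtype)
        y[:] = self.params["bias"]
        for di in range(k):
            for dj in range(k):
                v = np.ascontiguousarray(xp[:, di : di + h, dj : dj + w, :])
                y += v.reshape(n * h * w, c) @ weight[di, dj]
        y = y.reshape(n, h, w, self.out_channels)
        if self.capture:
            self.captured_activation = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.capture:
            self.captured_gradient = dy
        n, h, w, c = self._xshape
        o = self.out_channels
        k, weight = self.kernel_size, self.params["weight"]
        dy_m = np.ascontiguousarray(dy).reshape(n * h * w, o)
        dxp = np.zeros_like(self._xp)
        if self.trainable:
            dweight = np.empty_like(weight)
        for di in range(k):
            for dj in range(k):
                if self.trainable:
                    v = np.ascontiguousarray(self._xp[:, di : di + h, dj : dj + w, :])
                    dweight[di, dj] = v.reshape(n * h * w, c).T @ dy_m
                dxp[:, di : di + h, dj : dj + w, :] += (dy_m @ weight[di, dj].T).reshape(
                    n, h, w, c
                )
        if self.trainable:
            self.grads["weight"] = dweight
            self.grads["bias"] = dy_m.sum(axis=0)
        p = self.pad
        if p == 0:
            return dxp
        return np.ascontiguousarray(dxp[:, p : p + h, p : p + w, :])


class SeLU(Layer):
    trainable = False

    def __init__(self, name: str = "") -> None:
        super().__init__()
        self.name = name
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return selu(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * selu_grad(self._x)


def selu(x: np.ndarray) -> np.ndarray:
    return (
        _SELU_LAMBDA * np.where(x > 0, x, _SELU_ALPHA * np.expm1(np.minimum(x, 0.0)))
    ).astype(x.dtype)


def selu_grad(x: np.ndarray) -> np.ndarray:
    return (
        _SELU_LAMBDA * np.where(x > 0, 1.0, _SELU_ALPHA * np.exp(np.minimum(x, 0.0)))
    ).astype(x.dtype)


class AvgPool2d(Layer):
    """2x2 average pooling; spatial dims must be even."""

    trainable = False

    def __init__(self, name: str = "") -> None:
        super().__init__()
        self.name = name

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"odd spatial size {(h, w)} cannot be 2x2-pooled")
        return x.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2) * np.float32(0.25)


class MaxPool2d(Layer):
    """2x2 max pooling (used only by the VGG16 benchmark)."""

    trainable = False

    def __init__(self, name: str = "") -> None:
        super().__init__()
        self.name = name
        self._mask: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"odd spatial size {(h, w)} cannot be 2x2-pooled")
        blocks = x.reshape(n, h // 2, 2, w // 2, 2, c)
        y = blocks.max(axis=(2, 4))
        self._mask = blocks == y[:, :, None, :, None, :]
        self._shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        # split gradient evenly among tied maxima
        counts = self._mask.sum(axis=(2, 4), keepdims=True)
        g = self._mask * (dy[:, :, None, :, None, :] / counts)
        return g.reshape(self._shape)


class GlobalAvgPool(Layer):
    trainable = False

    def __init__(self, name: str = "") -> None:
        super().__init__()
        self.name = name
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        return np.broadcast_to(
            dy[:, None, None, :] / np.float32(h * w), self._shape
        ).astype(dy.dtype)


class Flatten(Layer):
    trainable = False

    def __init__(self, name: str = "") -> None:
        super().__init__()
        self.name = name
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator | None = None,
        name: str = "",
    ) -> None:
        super().__init__()
        self.name = name
        self.in_features = in_features
        self.out_features = out_features
        rng = rng or np.random.default_rng()
        weight = rng.normal(
            0.0, np.sqrt(1.0 / in_features), size=(in_features, out_features)
        )
        self.params = {
            "weight": weight.astype(np.float32),
            "bias": np.zeros(out_features, dtype=np.float32),
        }
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = x @ self.params["weight"] + self.params["bias"]
        if self.capture:
            self.captured_activation = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.capture:
            self.captured_gradient = dy
        if self.trainable:
            self.grads["weight"] = self._x.T @ dy
            self.grads["bias"] = dy.sum(axis=0)
        return dy @ self.params["weight"].T


class ResidualBlock(Layer):
    """Three 3x3 convolutions with SeLU, a skip connection and 2x2 avg pool.

    Layout: h = c3(selu(c2(selu(c1(x))))); out = avgpool(selu(h + skip(x)))
    where skip is identity when channel counts match and a 1x1 projection
    otherwise. ``use_residual=False`` drops the skip entirely (plain block).
    Grad-CAM capture refers to the output of the final convolution ``c3``.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        use_residual: bool = True,
        rng: np.random.Generator | None = None,
        name: str = "",
    ) -> None:
        super().__init__()
        self.name = name
        self.use_residual = use_residual
        rng = rng or np.random.default_rng()
        self.conv1 = Conv2d(in_channels, out_channels, kernel_size, rng, f"{name}.conv1")
        self.conv2 = Conv2d(out_channels, out_channels, kernel_size, rng, f"{name}.conv2")
        self.conv3 = Conv2d(out_channels, out_channels, kernel_size, rng, f"{name}.conv3")
        self.act1, self.act2, self.act3 = SeLU(), SeLU(), SeLU()
        self.pool = AvgPool2d()
        self.project: Conv2d | None = None
        if use_residual and in_channels != out_channels:
            self.project = Conv2d(in_channels, out_channels, 1, rng, f"{name}.project")
        self._x: np.ndarray | None = None

    @property
    def sublayers(self) -> list[Layer]:
        subs = [self.conv1, self.conv2, self.conv3]
        if self.project is not None:
            subs.append(self.project)
        return subs

    def n_parameters(self) -> int:
        return sum(s.n_parameters() for s in self.sublayers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        h = self.act2.forward(self.conv2.forward(self.act1.forward(self.conv1.forward(x))))
        h = self.conv3.forward(h)
        if self.capture:
            self.captured_activation = h
        if self.use_residual:
            skip = self.project.forward(x) if self.project is not None else x
            h = h + skip
        return self.pool.forward(self.act3.forward(h))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.act3.backward(self.pool.backward(dy))
        if self.capture:
            # d(h + skip) w.r.t. h is the identity: d is the gradient at conv3's output
            self.captured_gradient = d
        dx_skip = 0.0
        if self.use_residual:
            dx_skip = self.project.backward(d) if self.project is not None else d
        d = self.conv1.backward(
            self.act1.backward(
                self.conv2.backward(self.act2.backward(self.conv3.backward(d)))
            )
        )
        return d + dx_skip
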