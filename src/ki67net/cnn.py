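"""Four-layer convolutional patch classifier: architecture arithmetic and
the NumPy compute core.

The network is the tumour/non-tumour patch classifier used throughout the
package (and, with infiltrate labels, the infiltrate classifier): two valid
5x5 convolutions (32 then 64 filters, stride 1), a single 2x2 max-pool,
two fully connected layers (1024, 512) with ReLU, dropout after the second
FC layer, and a K-way softmax head. On 64x64x3 input the spatial trace is
64 -> 60 -> 56 -> 28.

The compute core is written against BLAS: convolutions are im2col + GEMM in
float32, and the SGD-with-momentum weight update is fused into the
weight-gradient GEMM (``v <- momentum*v - lr*(A^T B)`` as a single
``sgemm(alpha=-lr, beta=momentum)`` call) so no gradient matrix is ever
materialised for the large layers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.linalg import blas as _blas

__all__ = [
    "ConvLayerSpec",
    "NetworkSpec",
    "feature_map_size",
    "softmax",
    "PatchCNN",
]


@dataclass(frozen=True)
class ConvLayerSpec:
    """One convolution (or pooling) stage: N kernels of size MxM."""

    num_kernels: int
    kernel_size: int
    stride: int = 1
    pad: int = 0

    def __post_init__(self):
        if self.num_kernels <= 0 or self.kernel_size <= 0 or self.stride <= 0:
            raise ValueError("num_kernels, kernel_size and stride must be positive")
        if self.pad < 0:
            raise ValueError("pad must be >= 0")


def feature_map_size(input_w: int, layer: ConvLayerSpec) -> int:
    """Spatial output size of a convolution/pool stage.

    Standard valid-convolution convention ``(W + 2*pad - M) / stride + 1``;
    the result must be a positive integer or the layer geometry is invalid.
    """
    num = input_w + 2 * layer.pad - layer.kernel_size
    if num < 0 or num % layer.stride != 0:
        raise ValueError(
            f"invalid layer geometry: ({input_w} + 2*{layer.pad} - "
            f"{layer.kernel_size}) not a non-negative multiple of stride {layer.stride}"
        )
    out = num // layer.stride + 1
    if out <= 0:
        raise ValueError("layer geometry yields non-positive feature map")
    return out


def softmax(logits) -> np.ndarray:
    """Softmax probabilities sigma(z)_j = exp(z_j) / sum_k exp(z_k).

    Numerically stabilised by max-subtraction (invariant under additive
    shifts). Accepts a vector or a (batch, K) array; NaN inputs are
    rejected.
    """
    z = np.asarray(logits, dtype=np.float64)
    if np.isnan(z).any():
        raise ValueError("softmax received NaN logits")
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyper-parameters of the patch classifier."""

    input_size: int = 64
    in_channels: int = 3
    conv1: ConvLayerSpec = field(default_factory=lambda: ConvLayerSpec(32, 5, 1, 0))
    conv2: ConvLayerSpec = field(default_factory=lambda: ConvLayerSpec(64, 5, 1, 0))
    pool_size: int = 2
    pool_stride: int = 2
    fc_sizes: tuple[int, int] = (1024, 512)
    n_classes: int = 2
    dropout_rate: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if len(self.fc_sizes) != 2 or any(s <= 0 for s in self.fc_sizes):
            raise ValueError("fc_sizes must be two positive integers")
        if self.conv1.stride != 1 or self.conv2.stride != 1:
            raise ValueError("convolution stride other than 1 is not supported")
        if self.conv1.pad != 0 or self.conv2.pad != 0:
            raise ValueError("only valid (pad=0) convolutions are supported")
        if (self.pool_size, self.pool_stride) != (2, 2):
            raise ValueError("only 2x2 stride-2 max pooling is supported")
        self.spatial_trace()  # raises if any stage is geometrically invalid

    def spatial_trace(self) -> tuple[int, int, int, int]:
        """Spatial sizes (input, after conv1, after conv2, after pool)."""
        s1 = feature_map_size(self.input_size, self.conv1)
        s2 = feature_map_size(s1, self.conv2)
        if s2 % 2 != 0:
            raise ValueError("conv2 output must be even for 2x2/2 pooling")
        sp = feature_map_size(s2, ConvLayerSpec(1, self.pool_size, self.pool_stride))
        return self.input_size, s1, s2, sp

    def n_parameters(self) -> int:
        """Total number of trainable weights and biases."""
        _, _, _, sp = self.spatial_trace()
        k1, k2 = self.conv1.kernel_size, self.conv2.kernel_size
        f1, f2 = self.conv1.num_kernels, self.conv2.num_kernels
        fc1, fc2 = self.fc_sizes
        n = k1 * k1 * self.in_channels * f1 + f1
        n += k2 * k2 * f1 * f2 + f2
        n += sp * sp * f2 * fc1 + fc1
        n += fc1 * fc2 + fc2
        n += fc2 * self.n_classes + self.n_classes
        return n

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "NetworkSpec":
        d = json.loads(s)
        d["conv1"] = ConvLayerSpec(**d["conv1"])
        d["conv2"] = ConvLayerSpec(**d["conv2"])
        d["fc_sizes"] = tuple(d["fc_sizes"])
        return cls(**d)


class _Buffers:
    """Preallocated per-batch-size scratch arrays (training allocates these
    once; repeated 250 MB malloc/free of the conv2 im2col matrix otherwise
    dominates wall time through page faults)."""

    def __init__(self, spec: NetworkSpec, batch: int, training: bool):
        _, s1, s2, _ = spec.spatial_trace()
        c = spec.in_channels
        k1, k2 = spec.conv1.kernel_size, spec.conv2.kernel_size
        f1, f2 = spec.conv1.num_kernels, spec.conv2.num_kernels
        f = np.float32
        self.batch = batch
        self.c1 = np.empty((batch * s1 * s1, k1 * k1 * c), f)
        self.a1 = np.empty((batch * s1 * s1, f1), f)
        self.c2 = np.empty((batch * s2 * s2, k2 * k2 * f1), f)
        self.a2 = np.empty((batch * s2 * s2, f2), f)
        if training:
            self.dc2 = np.empty((batch * s2 * s2, k2 * k2 * f1), f)
            self.da1 = np.empty((batch, s1, s1, f1), f)
            self.dz1 = np.empty((batch * s1 * s1, f1), f)


def _im2col(dst: np.ndarray, x: np.ndarray, k: int, out_sz: int) -> None:
    """Gather kxk patches of x (B,H,W,C) into dst rows, (i,j,c) column order."""
    b, _, _, c = x.shape
    v = dst.reshape(b, out_sz, out_sz, k, k, c)
    for i in range(k):
        for j in range(k):
            v[:, :, :, i, j, :] = x[:, i : i + out_sz, j : j + out_sz, :]


class PatchCNN:
    """The trainable network: seeded He initialisation, forward pass, and a
    fused backward-and-update step for SGD with momentum.

    Weights are float32, stored Fortran-order so the fused
    ``sgemm(..., beta=momentum, c=velocity)`` update writes velocities in
    place. All randomness (init, dropout) flows from the seed given at
    construction plus the rng passed to :meth:`train_step`.
    """

    WEIGHT_NAMES = ("W1", "W2", "W3", "W4", "W5")
    BIAS_NAMES = ("b1", "b2", "b3", "b4", "b5")

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        self.seed = int(seed)
        _, s1, s2, sp = spec.spatial_trace()
        self._sizes = (spec.input_size, s1, s2, sp)
        c = spec.in_channels
        k1, k2 = spec.conv1.kernel_size, spec.conv2.kernel_size
        f1, f2 = spec.conv1.num_kernels, spec.conv2.num_kernels
        fc1, fc2 = spec.fc_sizes
        rng = np.random.default_rng(self.seed)

        def he(n_in, n_out):
            w = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
            return np.asfortranarray(w.astype(np.float32))

        self.W1 = he(k1 * k1 * c, f1)
        self.W2 = he(k2 * k2 * f1, f2)
        self.W3 = he(sp * sp * f2, fc1)
        self.W4 = he(fc1, fc2)
        self.W5 = he(fc2, spec.n_classes)
        for name, w in zip(self.BIAS_NAMES, self.WEIGHT_NAMES):
            setattr(self, name, np.zeros(getattr(self, w).shape[1], np.float32))
        self._vel = None
        self._buf: dict[tuple[int, bool], _Buffers] = {}

    # ------------------------------------------------------------------ #

    def _buffers(self, batch: int, training: bool) -> _Buffers:
        key = (batch, training)
        if key not in self._buf:
            if len(self._buf) > 3:  # bound scratch memory
                self._buf.clear()
            self._buf[key] = _Buffers(self.spec, batch, training)
        return self._buf[key]

    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        """Probabilities for a batch x of shape (B, S, S, C), float32,
        already mean-normalised. Dropout is applied only when training."""
        spec = self.spec
        s0, s1, s2, sp = self._sizes
        if x.ndim != 4 or x.shape[1:] != (s0, s0, spec.in_channels):
            raise ValueError(
                f"expected input of shape (B, {s0}, {s0}, {spec.in_channels}), "
                f"got {x.shape}"
            )
        b = x.shape[0]
        f1, f2 = spec.conv1.num_kernels, spec.conv2.num_kernels
        k1, k2 = spec.conv1.kernel_size, spec.conv2.kernel_size
        bf = self._buffers(b, training)

        _im2col(bf.c1, np.ascontiguousarray(x, np.float32), k1, s1)
        np.matmul(bf.c1, self.W1, out=bf.a1)
        bf.a1 += self.b1
        np.maximum(bf.a1, 0, out=bf.a1)

        _im2col(bf.c2, bf.a1.reshape(b, s1, s1, f1), k2, s2)
        np.matmul(bf.c2, self.W2, out=bf.a2)
        bf.a2 += self.b2
        np.maximum(bf.a2, 0, out=bf.a2)

        v = bf.a2.reshape(b, sp, 2, sp, 2, f2)
        pooled = v.max(axis=(2, 4))
        self._pool_in = v
        self._pooled = pooled
        flat = pooled.reshape(b, sp * sp * f2)
        self._flat = flat

        z3 = flat @ self.W3
        z3 += self.b3
        np.maximum(z3, 0, out=z3)
        self._a3 = z3
        z4 = z3 @ self.W4
        z4 += self.b4
        np.maximum(z4, 0, out=z4)
        self._a4 = z4
        if training and spec.dropout_rate > 0.0:
            if rng is None:
                raise ValueError("training forward pass needs an rng for dropout")
            keep = 1.0 - spec.dropout_rate
            self._dmask = (rng.random(z4.shape) < keep).astype(np.float32) / keep
            a4d = z4 * self._dmask
        else:
            self._dmask = None
            a4d = z4
        self._a4d = a4d
        z5 = a4d @ self.W5
        z5 += self.b5
        z5 = z5.astype(np.float64)
        z5 -= z5.max(axis=1, keepdims=True)
        e = np.exp(z5)
        probs = e / e.sum(axis=1, keepdims=True)
        self._probs = probs
        return probs

    def train_step(self, x, y, lr: float, momentum: float, rng) -> float:
        """One SGD step on a mini-batch; returns the mean cross-entropy."""
        b = x.shape[0]
        probs = self.forward(x, training=True, rng=rng)
        loss = float(-np.log(np.maximum(probs[np.arange(b), y], 1e-12)).mean())
        self._backward_update(y, lr, momentum)
        return loss

    def _ensure_velocity(self):
        if self._vel is None:
            self._vel = {
                n: np.zeros_like(getattr(self, n), order="F")
                for n in self.WEIGHT_NAMES
            }
            self._vel.update(
                {n: np.zeros_like(getattr(self, n)) for n in self.BIAS_NAMES}
            )

    def _fused_dw(self, name, a, dz, lr, momentum):
        """velocity <- momentum*velocity - lr * a^T dz, in place via sgemm.

        ``a`` is C-contiguous (batch-rows, features), so ``a.T`` is an
        F-contiguous view and BLAS sees it without a copy; only the small
        ``dz`` gets transposed internally.
        """
        v = self._vel[name]
        out = _blas.sgemm(-lr, a.T, dz, beta=momentum, c=v, overwrite_c=1)
        assert out is v

    def _backward_update(self, y, lr, momentum):
        self._ensure_velocity()
        spec = self.spec
        b = len(y)
        _, s1, s2, sp = self._sizes
        f1, f2 = spec.conv1.num_kernels, spec.conv2.num_kernels
        k2 = spec.conv2.kernel_size
        bf = self._buffers(b, True)
        vel = self._vel

        dz5 = self._probs.astype(np.float32)
        dz5[np.arange(b), y] -= 1.0
        dz5 /= b
        self._fused_dw("W5", self._a4d, dz5, lr, momentum)
        vel["b5"] *= momentum
        vel["b5"] -= lr * dz5.sum(0)

        da4 = dz5 @ self.W5.T
        if self._dmask is not None:
            da4 *= self._dmask
        da4 *= self._a4 > 0
        self._fused_dw("W4", self._a3, da4, lr, momentum)
        vel["b4"] *= momentum
        vel["b4"] -= lr * da4.sum(0)

        dz3 = da4 @ self.W4.T
        dz3 *= self._a3 > 0
        self._fused_dw("W3", self._flat, dz3, lr, momentum)
        vel["b3"] *= momentum
        vel["b3"] -= lr * dz3.sum(0)

        dflat = (dz3 @ self.W3.T).reshape(b, sp, 1, sp, 1, f2)
        mask = self._pool_in == self._pooled[:, :, None, :, None, :]
        da2 = (mask * dflat).reshape(b * s2 * s2, f2)
        da2 *= bf.a2 > 0
        self._fused_dw("W2", bf.c2, da2, lr, momentum)
        vel["b2"] *= momentum
        vel["b2"] -= lr * da2.sum(0)

        np.matmul(da2, self.W2.T, out=bf.dc2)
        bf.da1[:] = 0.0
        dc2v = bf.dc2.reshape(b, s2, s2, k2, k2, f1)
        for i in range(k2):
            for j in range(k2):
                bf.da1[:, i : i + s2, j : j + s2, :] += dc2v[:, :, :, i, j, :]
        np.multiply(
            bf.da1.reshape(b * s1 * s1, f1), bf.a1 > 0, out=bf.dz1
        )
        self._fused_dw("W1", bf.c1, bf.dz1, lr, momentum)
        vel["b1"] *= momentum
        vel["b1"] -= lr * bf.dz1.sum(0)

        for n in self.WEIGHT_NAMES + self.BIAS_NAMES:
            getattr(self, n).__iadd__(vel[n])

    def release_training_state(self) -> None:
        """Drop optimiser velocities, scratch buffers and cached
        activations (several hundred MB for the default architecture);
        the model remains fully usable for inference."""
        self._vel = None
        self._buf.clear()
        for attr in (
            "_pool_in", "_pooled", "_flat", "_a3", "_a4", "_a4d",
            "_dmask", "_probs",
        ):
            if hasattr(self, attr):
                delattr(self, attr)

    # ------------------------------------------------------------------ #

    def state_dict(self) -> dict:
        d = {n: getattr(self, n) for n in self.WEIGHT_NAMES + self.BIAS_NAMES}
        d["spec_json"] = self.spec.to_json()
        d["seed"] = self.seed
        return d

    @classmethod
    def from_state_dict(cls, d: dict) -> "PatchCNN":
        spec = NetworkSpec.from_json(str(d["spec_json"]))
        net = cls(spec, seed=int(d["seed"]))
        for n in cls.WEIGHT_NAMES:
            setattr(net, n, np.asfortranarray(np.asarray(d[n], np.float32)))
        for n in cls.BIAS_NAMES:
            setattr(net, n, np.asarray(d[n], np.float32))
        return net
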