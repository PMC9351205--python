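"""Patch -> node feature pipeline: encoder, global average pooling, ridge reduction.

Each 64^3 patch passes through a 3D convolutional encoder whose spatial
output is globally average-pooled into a 1024-d raw feature, then projected
to 96 dimensions by a ridge-regularized linear reduction fitted on training
rows only.

The default encoder is a small randomly-initialized (fixed-seed) strided
3D conv net, so no downloaded weights are needed; ``Encoder`` is a plain
interface and pretrained external encoders can be plugged in through it.

The "linear ridge transform" is realised as ridge-shrunk PCA: the data are
centred, projected on the top principal directions, and each score is
shrunk by s_i^2 / (s_i^2 + lambda) where s_i is the singular value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np

from lunggraph.roles import NodeRole
from lunggraph.sampling import PATCH_SIZE, Patch

RAW_DIM = 1024
NODE_DIM = 96


@runtime_checkable
class Encoder(Protocol):
    """Contract: map a 64^3 patch to a channels-first spatial feature tensor."""

    name: str
    out_channels: int

    def forward(self, values: np.ndarray) -> np.ndarray:
        """(64, 64, 64) -> (out_channels, *spatial); deterministic."""
        ...


def _strided_conv(x: np.ndarray, w: np.ndarray, b: np.ndarray, k: int) -> np.ndarray:
    """Non-overlapping k^3 strided conv on a channels-last tensor via reshape."""
    d, h, ww, c = x.shape
    x = x.reshape(d // k, k, h // k, k, ww // k, k, c)
    x = x.transpose(0, 2, 4, 1, 3, 5, 6).reshape(d // k, h // k, ww // k, k * k * k * c)
    return x @ w + b


class RandomConvEncoder:
    """Fixed-seed randomly-initialized strided 3D conv net with 1024 channels.

    64^3 -> average-pool(4) -> conv2s2(1->128) -> conv2s2(128->512)
    -> conv2s2(512->1024), ReLU between layers.  Implemented with
    reshape+matmul (kernel = stride), so it is fast and exactly
    deterministic on CPU.
    """

    def __init__(self, seed: int = 0, out_channels: int = RAW_DIM):
        self.name = f"random-conv3d-{seed}"
        self.out_channels = out_channels
        rng = np.random.default_rng(seed)
        dims = [(8 * 1, 128), (8 * 128, 512), (8 * 512, out_channels)]
        self.weights = []
        for fan_in, fan_out in dims:
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            b = rng.normal(0.0, 0.1, size=fan_out)
            self.weights.append((w.astype(np.float32), b.astype(np.float32)))

    def forward(self, values: np.ndarray) -> np.ndarray:
        x = np.asarray(values, dtype=np.float32)
        if x.shape != (PATCH_SIZE,) * 3:
            raise ValueError(f"encoder expects {(PATCH_SIZE,)*3}, got {x.shape}")
        # average pool 4x: 64^3 -> 16^3
        x = x.reshape(16, 4, 16, 4, 16, 4).mean(axis=(1, 3, 5))
        x = x[..., None]  # channels-last
        for i, (w, b) in enumerate(self.weights):
            x = _strided_conv(x, w, b, 2)
            if i < len(self.weights) - 1:
                x = np.maximum(x, 0.0)
        return np.ascontiguousarray(np.moveaxis(x, -1, 0))  # channels-first


@dataclass
class RawFeature:
    """Pooled 1024-d encoder output for one patch."""

    vector: np.ndarray
    role: NodeRole

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("raw feature contains non-finite values")


@dataclass
class NodeFeature:
    """Final 96-d node feature."""

    vector: np.ndarray
    role: NodeRole

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("node feature contains non-finite values")


def encode_patch(patch: Patch, enc: Encoder) -> RawFeature:
    """Encode one patch and global-average-pool the spatial map to a vector."""
    if patch.values.shape != (PATCH_SIZE,) * 3:
        raise ValueError(f"patch must be {(PATCH_SIZE,)*3}, got {patch.values.shape}")
    spatial = enc.forward(patch.values)
    pooled = spatial.reshape(spatial.shape[0], -1).mean(axis=1)
    return RawFeature(vector=pooled, role=patch.role)


@dataclass
class RidgeReducer:
    """Fitted ridge-shrunk PCA projection from 1024 to ``out_dim`` dimensions."""

    projection: np.ndarray  # (in_dim, out_dim)
    center: np.ndarray  # (in_dim,)
    penalty: float
    fitted_on: str = ""
    singular_values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(
            path.with_suffix(".npz"),
            projection=self.projection,
            center=self.center,
            singular_values=self.singular_values,
        )
        meta = {"penalty": self.penalty, "out_dim": int(self.projection.shape[1]),
                "fitted_on": self.fitted_on}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RidgeReducer":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            projection=arrays["projection"],
            center=arrays["center"],
            penalty=float(meta["penalty"]),
            fitted_on=meta.get("fitted_on", ""),
            singular_values=arrays["singular_values"],
        )


def fit_reducer(
    train_matrix: np.ndarray,
    penalty: float = 1.0,
    out_dim: int = NODE_DIM,
    fitted_on: str = "",
) -> RidgeReducer:
    """Fit the ridge-shrunk PCA projection on training rows only.

    With ``penalty == 0`` the projected scores equal plain rank-``out_dim``
    PCA scores.  Sign convention: each component's largest-magnitude
    loading is made positive, so the fit is deterministic.
    """
    X = np.asarray(train_matrix, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("train_matrix must be 2D (n_samples, n_features)")
    n, p = X.shape
    if out_dim > p:
        raise ValueError(f"out_dim {out_dim} exceeds feature dimension {p}")
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    center = X.mean(axis=0)
    Xc = X - center
    # economy SVD: Xc = U S Vt
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(out_dim, s.size)
    v = vt[:k].T  # (p, k)
    s_k = s[:k]
    # deterministic sign: largest-|loading| positive per component
    for j in range(k):
        i_max = int(np.argmax(np.abs(v[:, j])))
        if v[i_max, j] < 0:
            v[:, j] = -v[:, j]
    shrink = np.ones(k) if penalty == 0 else s_k**2 / (s_k**2 + penalty)
    projection = np.zeros((p, out_dim))
    projection[:, :k] = v * shrink
    sv = np.zeros(out_dim)
    sv[:k] = s_k
    return RidgeReducer(
        projection=projection,
        center=center,
        penalty=float(penalty),
        fitted_on=fitted_on,
        singular_values=sv,
    )


def apply_reducer(reducer: RidgeReducer, raw: RawFeature) -> NodeFeature:
    """Project one raw feature; never refits."""
    vec = (raw.vector - reducer.center) @ reducer.projection
    return NodeFeature(vector=vec, role=raw.role)


def reduce_matrix(reducer: RidgeReducer, raw_matrix: np.ndarray) -> np.ndarray:
    """Vectorized ``apply_reducer`` over rows."""
    return (np.asarray(raw_matrix, dtype=np.float64) - reducer.center) @ reducer.projection
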