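"""The eight-block 3D convolutional age-regression network.

Architecture (single-map network):

* blocks 1-5: 3x3x3 convolution ('same' padding), batch normalisation,
  2x2x2 max pooling (stride 2, floor division), ReLU;
* block 6: 1x1x1 convolution, batch normalisation, ReLU;
* block 7: flatten, dropout (training only), fully connected layer
  emitting the feature vector (default length 100);
* block 8: linear regression over [features, sex, scanner] -> scalar
  predicted age.

Default channel widths are [32, 64, 128, 256, 256, 64]; with a
91x109x91 input the spatial extent after block 6 is 2x3x2, so the
flattened block-6 tensor has 64*2*3*2 = 768 entries feeding the
100-dimensional block-7 feature vector.

The five-map fusion model concatenates the five 100-entry block-7
vectors with three covariates (sex, scanner, ICV) into a 503-entry
vector and fits block 8 by ordinary least squares, with the per-map
networks frozen (see :mod:`wmbrainage.train`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn_layers as L

__all__ = ["NetworkSpec", "SFCN", "build_network"]

_MIN_AXIS = 2**5  # five pooling stages halve each axis five times


@dataclass
class NetworkSpec:
    """Hyper-structure of one single-map network.

    ``allow_small_axes`` lifts the requirement that every input axis
    survive five floor-halvings (axes that reach extent 1 then pass
    through later pooling stages unchanged); it is enabled by the
    desk-scale preset so a 24x28x24 grid can be used.
    """

    input_shape: tuple[int, int, int] = (91, 109, 91)
    conv_channels: tuple[int, ...] = (32, 64, 128, 256, 256, 64)
    feature_dim: int = 100
    dropout_rate: float = 0.5
    n_single_covariates: int = 2  # sex, scanner
    n_fusion_covariates: int = 3  # sex, scanner, ICV
    allow_small_axes: bool = False
    normalise_input: bool = True
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if len(self.conv_channels) != 6:
            raise ValueError("conv_channels must list six channel counts")
        if any(c < 1 for c in self.conv_channels):
            raise ValueError("channel counts must be positive")
        if self.feature_dim < 1:
            raise ValueError("feature_dim must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if len(self.input_shape) != 3 or any(s < 1 for s in self.input_shape):
            raise ValueError("input_shape must be three positive voxel counts")

    # -- shape arithmetic ---------------------------------------------------
    @staticmethod
    def _halve(s: int) -> int:
        return s // 2 if s >= 2 else s

    def spatial_trace(self) -> list[tuple[int, int, int]]:
        """Spatial extent after each of blocks 1..6 (conv preserves size)."""
        shape = tuple(self.input_shape)
        out = []
        for _ in range(5):
            shape = tuple(self._halve(s) for s in shape)
            out.append(shape)
        out.append(shape)  # block 6 is 1x1x1 conv: spatial size unchanged
        return out

    @property
    def post_block6_shape(self) -> tuple[int, int, int]:
        return self.spatial_trace()[-1]

    @property
    def flat_dim(self) -> int:
        return self.conv_channels[5] * int(np.prod(self.post_block6_shape))

    @property
    def fusion_input_dim(self) -> int:
        return self.feature_dim * 5 + self.n_fusion_covariates

    def shape_trace(self) -> dict:
        """Layer-by-layer audit of the architecture."""
        return {
            "input_shape": tuple(self.input_shape),
            "conv_channels": tuple(self.conv_channels),
            "spatial_after_blocks": self.spatial_trace(),
            "post_block6_spatial": self.post_block6_shape,
            "block7_flat_input": self.flat_dim,
            "block7_feature_dim": self.feature_dim,
            "block8_single_input": self.feature_dim + self.n_single_covariates,
            "block8_fusion_input": self.fusion_input_dim,
            "dropout_rate": self.dropout_rate,
        }

    @classmethod
    def desk_scale(cls, **overrides) -> "NetworkSpec":
        """Narrow configuration for CPU-scale experiments on a 24x28x24 grid."""
        # feature_dim is kept small so the fused OLS head keeps a healthy
        # sample-to-parameter ratio at a few hundred training volumes; the
        # desk-scale maps carry a single latent factor (effective age), so
        # little is lost
        base = dict(
            input_shape=(24, 28, 24),
            conv_channels=(8, 16, 16, 32, 32, 16),
            feature_dim=3,
            allow_small_axes=True,
        )
        base.update(overrides)
        return cls(**base)

    def with_(self, **overrides) -> "NetworkSpec":
        return replace(self, **overrides)


class SFCN:
    """A single-map network instance: parameters + forward/backward."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        if not spec.allow_small_axes and min(spec.input_shape) < _MIN_AXIS:
            raise ValueError(
                f"input axis smaller than {_MIN_AXIS} would be annihilated by "
                "five pooling stages; reduce pooling or set allow_small_axes"
            )
        self.spec = spec
        self.dtype = np.dtype(spec.dtype)
        rng = np.random.default_rng(seed)
        ch = (1, *spec.conv_channels)
        p: dict[str, np.ndarray] = {}
        self.bn_state: dict[int, dict[str, np.ndarray]] = {}
        for i in range(1, 7):
            k = 3 if i <= 5 else 1
            fan_in = ch[i - 1] * k**3
            p[f"conv{i}_W"] = rng.normal(
                0.0, math.sqrt(2.0 / fan_in), (ch[i], ch[i - 1], k, k, k)
            ).astype(self.dtype)
            p[f"conv{i}_b"] = np.zeros(ch[i], self.dtype)
            p[f"bn{i}_gamma"] = np.ones(ch[i], self.dtype)
            p[f"bn{i}_beta"] = np.zeros(ch[i], self.dtype)
            self.bn_state[i] = {
                "mean": np.zeros(ch[i], self.dtype),
                "var": np.ones(ch[i], self.dtype),
            }
        p["fc7_W"] = rng.normal(
            0.0, math.sqrt(2.0 / spec.flat_dim), (spec.flat_dim, spec.feature_dim)
        ).astype(self.dtype)
        p["fc7_b"] = np.zeros(spec.feature_dim, self.dtype)
        n_head = spec.feature_dim + spec.n_single_covariates
        p["head_W"] = rng.normal(0.0, math.sqrt(1.0 / n_head), n_head).astype(
            self.dtype
        )
        p["head_b"] = np.zeros((), self.dtype)
        self.params = p

    # -- input handling -----------------------------------------------------
    def _prep(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != tuple(self.spec.input_shape):
            raise ValueError(
                f"volume grid {x.shape[1:]} does not match network input "
                f"{tuple(self.spec.input_shape)}"
            )
        x = x[:, None]  # channel axis
        if self.spec.normalise_input:
            mu = x.mean(axis=(2, 3, 4), keepdims=True)
            sd = x.std(axis=(2, 3, 4), keepdims=True)
            x = (x - mu) / (sd + 1e-8)
        return x

    # -- forward ------------------------------------------------------------
    def _blocks_forward(self, x, train, rng):
        caches = []
        for i in range(1, 6):
            W, b = self.params[f"conv{i}_W"], self.params[f"conv{i}_b"]
            out = L.conv3d_forward(x, W, b, pad=1)
            bn, bc = L.bn_forward(
                out,
                self.params[f"bn{i}_gamma"],
                self.params[f"bn{i}_beta"],
                self.bn_state[i],
                train,
            )
            pooled, pc = L.maxpool3d_forward(bn)
            act, rm = L.relu_forward(pooled)
            caches.append((x, bc, pc, rm))
            x = act
        W, b = self.params["conv6_W"], self.params["conv6_b"]
        out = L.conv3d_forward(x, W, b, pad=0)
        bn, bc = L.bn_forward(
            out,
            self.params["bn6_gamma"],
            self.params["bn6_beta"],
            self.bn_state[6],
            train,
        )
        act, rm = L.relu_forward(bn)
        caches.append((x, bc, None, rm))
        flat = act.reshape(act.shape[0], -1)
        drop, dm = L.dropout_forward(flat, self.spec.dropout_rate, rng, train)
        feats, lin_cache = L.linear_forward(
            drop, self.params["fc7_W"], self.params["fc7_b"]
        )
        caches.append((act.shape, dm, lin_cache))
        return feats, caches

    def forward(self, x, covariates, train=False, rng=None):
        """Predict age.  ``covariates`` is (N, n_single_covariates)."""
        x = self._prep(x)
        if train and rng is None:
            rng = np.random.default_rng(0)
        feats, caches = self._blocks_forward(x, train, rng)
        cov = np.asarray(covariates, dtype=self.dtype).reshape(x.shape[0], -1)
        if cov.shape[1] != self.spec.n_single_covariates:
            raise ValueError(
                f"expected {self.spec.n_single_covariates} covariates, got {cov.shape[1]}"
            )
        v = np.concatenate([feats, cov], axis=1)
        pred = v @ self.params["head_W"] + self.params["head_b"]
        caches.append(v)
        return pred, caches

    def features(self, x) -> np.ndarray:
        """Block-7 feature vectors in evaluation mode (no dropout).

        Covariates are *not* part of this vector; they are concatenated
        downstream (block 8 / fusion head).
        """
        x = self._prep(x)
        feats, _ = self._blocks_forward(x, train=False, rng=None)
        return feats

    def measure_trace(self, x) -> dict:
        """Run one volume through blocks 1-7 and record the realised shapes.

        Unlike :meth:`NetworkSpec.shape_trace` (pure arithmetic), this
        measures the actual evaluation-mode tensors.
        """
        x = self._prep(x)
        shapes: dict = {}
        cur = x
        for i in range(1, 6):
            cur = L.conv3d_forward(
                cur, self.params[f"conv{i}_W"], self.params[f"conv{i}_b"], pad=1
            )
            cur, _ = L.bn_forward(
                cur,
                self.params[f"bn{i}_gamma"],
                self.params[f"bn{i}_beta"],
                self.bn_state[i],
                train=False,
            )
            cur, _ = L.maxpool3d_forward(cur)
            cur, _ = L.relu_forward(cur)
            shapes[f"block{i}_spatial"] = cur.shape[2:]
            shapes[f"block{i}_channels"] = cur.shape[1]
        cur = L.conv3d_forward(cur, self.params["conv6_W"], self.params["conv6_b"], pad=0)
        cur, _ = L.bn_forward(
            cur,
            self.params["bn6_gamma"],
            self.params["bn6_beta"],
            self.bn_state[6],
            train=False,
        )
        cur, _ = L.relu_forward(cur)
        shapes["block6_spatial"] = cur.shape[2:]
        shapes["block6_channels"] = cur.shape[1]
        flat = cur.reshape(cur.shape[0], -1)
        shapes["block7_flat_input"] = flat.shape[1]
        feats, _ = L.linear_forward(flat, self.params["fc7_W"], self.params["fc7_b"])
        shapes["block7_feature_len"] = feats.shape[1]
        return shapes

    # -- backward -----------------------------------------------------------
    def backward(self, dpred, caches):
        g: dict[str, np.ndarray] = {}
        v = caches[-1]
        feature_dim = self.spec.feature_dim
        g["head_W"] = v.T @ dpred
        g["head_b"] = dpred.sum()
        dfeats = np.outer(dpred, self.params["head_W"][:feature_dim]).astype(self.dtype)

        act_shape, dm, lin_cache = caches[-2]
        ddrop, g["fc7_W"], g["fc7_b"] = L.linear_backward(
            dfeats, lin_cache, self.params["fc7_W"]
        )
        dflat = L.dropout_backward(ddrop, dm)
        dact = dflat.reshape(act_shape)

        x6, bc, _, rm = caches[5]
        dbn = L.relu_backward(dact, rm)
        dconv, g["bn6_gamma"], g["bn6_beta"] = L.bn_backward(dbn, bc)
        dx, g["conv6_W"], g["conv6_b"] = L.conv3d_backward(
            dconv, x6, self.params["conv6_W"], pad=0
        )
        for i in range(5, 0, -1):
            xi, bc, pc, rm = caches[i - 1]
            dpool = L.relu_backward(dx, rm)
            dbn = L.maxpool3d_backward(dpool, pc)
            dconv, g[f"bn{i}_gamma"], g[f"bn{i}_beta"] = L.bn_backward(dbn, bc)
            dx, g[f"conv{i}_W"], g[f"conv{i}_b"] = L.conv3d_backward(
                dconv, xi, self.params[f"conv{i}_W"], pad=1
            )
        return g

    # -- state --------------------------------------------------------------
    def get_state(self) -> dict[str, np.ndarray]:
        state = {k: v.copy() for k, v in self.params.items()}
        for i, st in self.bn_state.items():
            state[f"bn{i}_running_mean"] = st["mean"].copy()
            state[f"bn{i}_running_var"] = st["var"].copy()
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.array(state[k], dtype=self.dtype)
        for i in self.bn_state:
            self.bn_state[i] = {
                "mean": np.array(state[f"bn{i}_running_mean"], dtype=self.dtype),
                "var": np.array(state[f"bn{i}_running_var"], dtype=self.dtype),
            }


def build_network(spec: NetworkSpec, seed: int = 0) -> SFCN:
    """Construct an untrained single-map network from its spec."""
    return SFCN(spec, seed=seed)
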