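"""Training, feature extraction, fusion and prediction.

Per-map networks are trained end-to-end with Adam on an L1 objective
(directly optimising the mean absolute error used to evaluate brain-age
models; squared error is available as an option).  After gradient
training the block-8 head is refitted in closed form by least squares
on the training features — block 8 *is* a linear regression, so this is
its exact optimum for the squared loss and stabilises small-sample
runs; it can be disabled.

The five-map fusion stage reuses the frozen per-map block-7 features:
the fused design is [features x5, sex, scanner, ICV] (100*5 + 3 entries
at the default width) and block 8 is ordinary least squares, with a
logged ridge fallback when the design is rank deficient.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .imgio import MAP_NAMES, DwiMapSet
from .network import SFCN, NetworkSpec, build_network
from .nn_layers import Adam

__all__ = [
    "TrainConfig",
    "TrainedSingleMapModel",
    "FusionHead",
    "train_single_map",
    "extract_features",
    "fit_fusion_head",
    "predict_fusion",
    "predict_age",
    "save_single_map",
    "load_single_map",
    "save_fusion_head",
    "load_fusion_head",
]

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    epochs: int = 3
    batch_size: int = 16
    lr: float = 3e-3
    loss: str = "l1"  # "l1" or "l2"
    refit_head: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loss not in ("l1", "l2"):
            raise ValueError("loss must be 'l1' or 'l2'")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


@dataclass
class TrainedSingleMapModel:
    map_label: str
    spec: NetworkSpec
    model: SFCN = field(repr=False)
    loss_log: list[float] = field(default_factory=list)
    train_config: TrainConfig | None = None

    def predict(self, volumes, sex, scanner) -> np.ndarray:
        cov = np.column_stack([np.atleast_1d(sex), np.atleast_1d(scanner)])
        pred, _ = self.model.forward(volumes, cov, train=False)
        return pred


def _as_batch(volumes) -> np.ndarray:
    v = np.asarray(volumes)
    return v[None] if v.ndim == 3 else v


def train_single_map(
    volumes,
    ages,
    sex,
    scanner,
    spec: NetworkSpec,
    config: TrainConfig | None = None,
    map_label: str = "FA",
) -> TrainedSingleMapModel:
    """Fit one single-map network on (volume, age, sex, scanner) tuples.

    Deterministic for a fixed seed under single-threaded execution.
    Raises on a single-participant training set and aborts with a
    diagnostic if the loss becomes non-finite.
    """
    config = config or TrainConfig()
    volumes = _as_batch(volumes)
    ages = np.asarray(ages, dtype=np.float64)
    n = volumes.shape[0]
    if n < 2:
        raise ValueError("training requires at least two participants")
    if not np.all(np.isfinite(ages)):
        raise ValueError("ages must be finite")
    cov = np.column_stack([np.asarray(sex), np.asarray(scanner)]).astype(np.float64)

    model = build_network(spec, seed=config.seed)
    # start the output at the mean training age so early epochs refine
    # deviations rather than the grand level
    model.params["head_b"] = np.asarray(ages.mean(), dtype=model.dtype)
    opt = Adam(model.params, lr=config.lr)
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 11])

    loss_log: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            pred, caches = model.forward(volumes[idx], cov[idx], train=True, rng=rng)
            resid = pred.astype(np.float64) - ages[idx]
            if config.loss == "l1":
                loss = np.abs(resid).mean()
                dpred = np.sign(resid) / len(idx)
            else:
                loss = (resid**2).mean()
                dpred = 2.0 * resid / len(idx)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch start {start}; "
                    "reduce the learning rate or check input scaling"
                )
            grads = model.backward(dpred.astype(model.dtype), caches)
            opt.step(model.params, grads)
            epoch_loss += loss * len(idx)
        loss_log.append(epoch_loss / n)

    trained = TrainedSingleMapModel(
        map_label=map_label,
        spec=spec,
        model=model,
        loss_log=loss_log,
        train_config=config,
    )
    if config.refit_head:
        feats = extract_features(trained, volumes)
        X = np.column_stack([feats, cov, np.ones(n)])
        coef, *_ = np.linalg.lstsq(X, ages, rcond=None)
        model.params["head_W"] = coef[:-1].astype(model.dtype)
        model.params["head_b"] = np.asarray(coef[-1], dtype=model.dtype)
    return trained


def extract_features(
    model: TrainedSingleMapModel, volumes, sex=None, scanner=None, batch_size: int = 32
) -> np.ndarray:
    """Deterministic block-7 feature vectors (dropout disabled).

    ``sex``/``scanner`` are accepted for interface symmetry with
    prediction but are not embedded in the vector — covariates enter by
    concatenation at block 8 / the fusion head.
    """
    volumes = _as_batch(volumes)
    if volumes.shape[1:] != tuple(model.spec.input_shape):
        raise ValueError(
            f"volume grid {volumes.shape[1:]} does not match network input "
            f"{tuple(model.spec.input_shape)}"
        )
    out = [
        model.model.features(volumes[i : i + batch_size])
        for i in range(0, volumes.shape[0], batch_size)
    ]
    return np.concatenate(out, axis=0)


@dataclass
class FusionHead:
    """Block-8 linear regression over the fused five-map feature vector."""

    weights: np.ndarray  # length feature_dim*5 + n_covariates
    intercept: float
    feature_dim: int
    n_covariates: int = 3
    ridge_alpha: float = 0.0

    @property
    def input_dim(self) -> int:
        return self.feature_dim * 5 + self.n_covariates


def _stack_features(features) -> np.ndarray:
    if isinstance(features, (list, tuple)):
        return np.concatenate([np.asarray(f) for f in features], axis=1)
    return np.asarray(features)


def fit_fusion_head(
    features, covariates, ages, feature_dim: int | None = None
) -> FusionHead:
    """Ordinary least squares of age on [features x5, sex, scanner, ICV].

    ``features`` is either a list of five (n, feature_dim) arrays in
    canonical map order or the pre-concatenated (n, feature_dim*5)
    matrix.  A rank-deficient design falls back to ridge with a logged
    regularisation strength.  The per-map networks are not touched.
    """
    F = _stack_features(features)
    C = np.asarray(covariates, dtype=np.float64)
    ages = np.asarray(ages, dtype=np.float64)
    if C.ndim != 2 or C.shape[1] != 3:
        raise ValueError("covariates must be (n, 3): sex, scanner, ICV")
    if F.shape[1] % 5 != 0:
        raise ValueError(f"feature matrix width {F.shape[1]} is not five maps")
    fd = F.shape[1] // 5
    if feature_dim is not None and fd != feature_dim:
        raise ValueError(
            f"fused input length {F.shape[1] + C.shape[1]} != "
            f"{feature_dim}*5 + {C.shape[1]}"
        )
    X = np.column_stack([F, C, np.ones(len(ages))])
    p = X.shape[1]
    coef, _, rank, _ = np.linalg.lstsq(X, ages, rcond=None)
    alpha = 0.0
    if rank < p:
        alpha = 1e-6 * np.trace(X.T @ X) / p
        log.warning(
            "fusion design rank %d < %d; refitting with ridge alpha=%.3g",
            rank,
            p,
            alpha,
        )
        A = X.T @ X + alpha * np.eye(p)
        coef = np.linalg.solve(A, X.T @ ages)
    return FusionHead(
        weights=coef[:-1],
        intercept=float(coef[-1]),
        feature_dim=fd,
        n_covariates=C.shape[1],
        ridge_alpha=alpha,
    )


def predict_fusion(head: FusionHead, features, covariates) -> np.ndarray:
    F = _stack_features(features)
    C = np.asarray(covariates, dtype=np.float64)
    v = np.column_stack([F, C])
    if v.shape[1] != head.input_dim:
        raise ValueError(
            f"fused input length {v.shape[1]} != expected {head.input_dim} "
            f"({head.feature_dim}*5 + {head.n_covariates})"
        )
    return v @ head.weights + head.intercept


def predict_age(
    models: dict[str, TrainedSingleMapModel],
    head: FusionHead,
    map_set: DwiMapSet | dict[str, np.ndarray],
    covariates,
) -> np.ndarray:
    """Raw fused predicted age for one participant or a batch.

    ``map_set`` maps each of FA/MD/AxD/RD/MO to a volume (or a stack of
    volumes); ``covariates`` is (sex, scanner, icv) or an (n, 3) array.
    """
    volumes = map_set.volumes if isinstance(map_set, DwiMapSet) else map_set
    missing = [m for m in MAP_NAMES if m not in volumes or m not in models]
    if missing:
        raise ValueError(f"missing maps or models for: {', '.join(missing)}")
    feats = [extract_features(models[m], volumes[m]) for m in MAP_NAMES]
    C = np.asarray(covariates, dtype=np.float64)
    if C.ndim == 1:
        C = C[None]
    return predict_fusion(head, feats, C)


# ---------------------------------------------------------------------------
# Checkpoints: npz weights + JSON sidecar with the spec and train config

def save_single_map(trained: TrainedSingleMapModel, prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savez(prefix.with_suffix(".npz"), **trained.model.get_state())
    sidecar = {
        "map_label": trained.map_label,
        "spec": asdict(trained.spec),
        "train_config": asdict(trained.train_config) if trained.train_config else None,
        "loss_log": trained.loss_log,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_single_map(prefix: str | Path) -> TrainedSingleMapModel:
    prefix = Path(prefix)
    npz_path = prefix.with_suffix(".npz")
    json_path = prefix.with_suffix(".json")
    if not npz_path.exists() or not json_path.exists():
        raise FileNotFoundError(f"checkpoint not found: {npz_path} / {json_path}")
    sidecar = json.loads(json_path.read_text())
    sd = sidecar["spec"]
    for key in ("input_shape", "conv_channels"):
        sd[key] = tuple(sd[key])
    spec = NetworkSpec(**sd)
    model = build_network(spec)
    with np.load(npz_path) as data:
        model.set_state({k: data[k] for k in data.files})
    tc = sidecar.get("train_config")
    return TrainedSingleMapModel(
        map_label=sidecar["map_label"],
        spec=spec,
        model=model,
        loss_log=sidecar.get("loss_log", []),
        train_config=TrainConfig(**tc) if tc else None,
    )


def save_fusion_head(head: FusionHead, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(
        path,
        weights=head.weights,
        intercept=head.intercept,
        feature_dim=head.feature_dim,
        n_covariates=head.n_covariates,
        ridge_alpha=head.ridge_alpha,
    )


def load_fusion_head(path: str | Path) -> FusionHead:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"fusion head checkpoint not found: {path}")
    with np.load(path) as d:
        return FusionHead(
            weights=d["weights"],
            intercept=float(d["intercept"]),
            feature_dim=int(d["feature_dim"]),
            n_covariates=int(d["n_covariates"]),
            ridge_alpha=float(d["ridge_alpha"]),
        )
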