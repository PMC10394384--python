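"""The 12-convolution 3D residual regression network and its estimator.

Architecture (default, derived by trimming a ResNet-18 backbone to 12
convolutions): one stem convolution, five residual basic blocks of two
convolutions each, and a final 1x1x1 convolution before global average
pooling and a linear scalar head — 1 + 10 + 1 = 12 convolutions.  Every
convolution is followed by batch normalization and a ReLU; residual
shortcuts are parameter-free (strided subsampling with channel zero-padding)
so they do not change the convolution count.  Channels widen 16-16-32-64-
128-256 with stride-2 downsampling entering stages 2-5.

One network maps one cubic intensity patch to one scalar factor-score
estimate; one model is trained per symptom factor.  Training minimizes mean
squared error with Adam at the configured initial learning rate (default
0.001, batch 1000).

The estimator :class:`PatchRegressor3D` follows the scikit-learn protocol
(``fit``/``predict``/``get_params``) so it composes with sklearn model
selection; ``width_scale`` shrinks all channel widths for CPU-scale runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ._nn import Adam, BasicBlock3d, BatchNorm3d, Conv3d, GlobalAvgPool, Linear, ReLU

__all__ = [
    "NetworkConfig",
    "TrainingConfig",
    "TrainedModel",
    "ResNet3dRegressor",
    "PatchRegressor3D",
    "build_network",
    "mse_loss",
    "train_model",
    "predict_patch_scores",
    "assign_patch_labels",
    "save_model",
    "load_model",
]


class ConfigurationError(ValueError):
    """Raised when a network layout is inconsistent with its stated depth."""


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class NetworkConfig:
    """Layout of the residual regression network.

    ``conv_layers`` must equal the count implied by the layout:
    1 (stem) + 2 * sum(block_layout) + 1 (head convolution).
    ``width_scale`` multiplies every channel width (minimum 1 channel),
    giving a desk-scale profile for CPU runs without changing the depth.
    """

    conv_layers: int = 12
    stem_channels: int = 16
    channel_schedule: tuple[int, ...] = (16, 32, 64, 128, 256)
    block_layout: tuple[int, ...] = (1, 1, 1, 1, 1)
    kernel_size: int = 3
    downsample_strides: tuple[int, ...] = (1, 2, 2, 2, 2)
    stem_stride: int = 1
    width_scale: float = 1.0

    def __post_init__(self) -> None:
        if len(self.channel_schedule) != len(self.block_layout) or (
            len(self.downsample_strides) != len(self.block_layout)
        ):
            raise ConfigurationError(
                "channel_schedule, block_layout and downsample_strides must have equal length"
            )
        implied = 1 + 2 * sum(self.block_layout) + 1
        if implied != self.conv_layers:
            raise ConfigurationError(
                f"block layout implies {implied} convolutions, config says {self.conv_layers}"
            )
        if self.width_scale <= 0:
            raise ConfigurationError("width_scale must be positive")

    def scaled(self, channels: int) -> int:
        return max(1, int(round(channels * self.width_scale)))


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization hyperparameters (defaults: batch 1000, initial lr 0.001)."""

    batch_size: int = 1000
    learning_rate: float = 0.001
    weight_decay: float = 0.0
    epochs: int = 50
    optimizer_name: str = "adam"
    loss_name: str = "mse"
    seed: int | None = None
    device: str = "cpu"

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


class ResNet3dRegressor:
    """The bare network: forward/backward over a stack of layers."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        c = config
        ch = [c.scaled(w) for w in c.channel_schedule]
        stem_ch = c.scaled(c.stem_channels)
        self.config = c
        self.stem = Conv3d(1, stem_ch, c.kernel_size, c.stem_stride, rng)
        self.stem.needs_input_grad = False  # input gradient is never used
        self.stem_bn = BatchNorm3d(stem_ch)
        self.stem_relu = ReLU()
        self.blocks: list[BasicBlock3d] = []
        c_in = stem_ch
        for width, n_blocks, stride in zip(ch, c.block_layout, c.downsample_strides):
            for b in range(n_blocks):
                self.blocks.append(
                    BasicBlock3d(c_in, width, stride if b == 0 else 1, c.kernel_size, rng)
                )
                c_in = width
        self.head_conv = Conv3d(c_in, c_in, 1, 1, rng)
        self.head_bn = BatchNorm3d(c_in)
        self.head_relu = ReLU()
        self.pool = GlobalAvgPool()
        self.fc = Linear(c_in, 1, rng)

    # -- structure ---------------------------------------------------------
    def convolutions(self) -> list[Conv3d]:
        convs = [self.stem]
        for block in self.blocks:
            convs.extend(block.convolutions())
        convs.append(self.head_conv)
        return convs

    def count_convolutions(self) -> int:
        return len(self.convolutions())

    def params(self):
        out = []
        for layer in (self.stem, self.stem_bn, *self.blocks,
                      self.head_conv, self.head_bn, self.fc):
            out.extend(layer.params())
        return out

    # -- compute -----------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Map (B, d, h, w) patches to (B,) scalar estimates."""
        h = np.ascontiguousarray(x, dtype=np.float32)[..., None]
        h = self.stem.forward(h, training)
        h = self.stem_bn.forward(h, training)
        h = self.stem_relu.forward(h, training)
        for block in self.blocks:
            h = block.forward(h, training)
        h = self.head_conv.forward(h, training)
        h = self.head_bn.forward(h, training)
        h = self.head_relu.forward(h, training)
        h = self.pool.forward(h, training)
        return self.fc.forward(h, training)[:, 0]

    def backward(self, dy: np.ndarray) -> None:
        d = self.fc.backward(dy[:, None])
        d = self.pool.backward(d)
        d = self.head_relu.backward(d)
        d = self.head_bn.backward(d)
        d = self.head_conv.backward(d)
        for block in reversed(self.blocks):
            d = block.backward(d)
        d = self.stem_relu.backward(d)
        d = self.stem_bn.backward(d)
        self.stem.backward(d)

    def bn_layers(self):
        bns = [self.stem_bn, self.head_bn]
        for block in self.blocks:
            bns.extend([block.bn1, block.bn2])
        return bns

    def recalibrate_bn(self, X: np.ndarray, batch_size: int) -> None:
        """Replace batch-norm running statistics with exact dataset statistics.

        One frozen-weight pass over the data; stabilizes inference-mode
        predictions after training with a high learning rate, where momentum
        averages lag the final weights.
        """
        for bn in self.bn_layers():
            bn.begin_calibration()
        for start in range(0, X.shape[0], batch_size):
            self.forward(X[start:start + batch_size], training=True)
        for bn in self.bn_layers():
            bn.end_calibration()

    # -- state -------------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {f"param_{i}": p.value for i, p in enumerate(self.params())}
        for i, bn in enumerate(self.bn_layers()):
            state[f"bn_{i}_mean"] = bn.running_mean
            state[f"bn_{i}_var"] = bn.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value[...] = state[f"param_{i}"]
        for i, bn in enumerate(self.bn_layers()):
            bn.running_mean = np.asarray(state[f"bn_{i}_mean"], dtype=np.float32)
            bn.running_var = np.asarray(state[f"bn_{i}_var"], dtype=np.float32)


def build_network(config: NetworkConfig | None = None,
                  rng: np.random.Generator | int | None = None) -> ResNet3dRegressor:
    """Instantiate an untrained network; validates the layout's depth."""
    config = config or NetworkConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    net = ResNet3dRegressor(config, rng)
    if net.count_convolutions() != config.conv_layers:
        raise ConfigurationError(
            f"built network has {net.count_convolutions()} convolutions, "
            f"expected {config.conv_layers}"
        )
    return net


def mse_loss(true_scores, estimated_scores) -> float:
    """Mean of squared residuals; zero iff the vectors are equal.

    The squared 2-norm of the residual vector divided by its length, so the
    loss scale is batch-size invariant and comparable to per-subject
    median-MSE summaries.
    """
    t = np.asarray(true_scores, dtype=np.float64)
    e = np.asarray(estimated_scores, dtype=np.float64)
    if t.shape != e.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {e.shape}")
    if t.size == 0:
        raise ValueError("mse_loss of empty vectors is undefined")
    return float(np.mean((t - e) ** 2))


def _patch_array(patches) -> np.ndarray:
    """Stack Patch objects or raw arrays into (n, d, h, w) float32."""
    if isinstance(patches, np.ndarray) and patches.ndim == 4:
        return np.ascontiguousarray(patches, dtype=np.float32)
    arrs = [p.values if hasattr(p, "values") else np.asarray(p) for p in patches]
    return np.stack(arrs).astype(np.float32, copy=False)


class PatchRegressor3D(BaseEstimator, RegressorMixin):
    """Scikit-learn estimator wrapping the residual patch regression network.

    Parameters
    ----------
    network_config : NetworkConfig, optional
        Layout; default is the 12-convolution full-width network.
    epochs, batch_size, learning_rate :
        Optimization settings (defaults 50 / 1000 / 0.001, Adam).
    random_state : int, optional
        Seeds weight initialization and minibatch shuffling.

    Attributes
    ----------
    net_ : ResNet3dRegressor
        The trained network.
    loss_history_ : list of float
        Mean training MSE per epoch.
    n_features_in_ : int
        Flattened patch size seen during fit.
    """

    def __init__(self, network_config: NetworkConfig | None = None,
                 epochs: int = 50, batch_size: int = 1000,
                 learning_rate: float = 0.001, weight_decay: float = 0.0,
                 random_state: int | None = None):
        self.network_config = network_config
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.random_state = random_state

    def fit(self, X, y):
        X = _patch_array(X)
        y = np.asarray(y, dtype=np.float32).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError(f"X has {X.shape[0]} patches but y has {y.shape[0]} labels")
        if X.shape[0] == 0:
            raise ValueError("cannot fit on an empty patch set")
        if not np.all(np.isfinite(y)):
            raise ValueError("labels must be finite")
        cfg = self.network_config or NetworkConfig()
        tcfg = TrainingConfig(batch_size=self.batch_size,
                              learning_rate=self.learning_rate,
                              weight_decay=self.weight_decay,
                              epochs=self.epochs, seed=self.random_state)
        rng = np.random.default_rng(self.random_state)
        net = build_network(cfg, rng)
        decay = [c.weight for c in net.convolutions()] + [net.fc.weight]
        opt = Adam(net.params(), lr=tcfg.learning_rate,
                   weight_decay=tcfg.weight_decay, decay_params=decay)
        n = X.shape[0]
        history: list[float] = []
        for epoch in range(tcfg.epochs):
            order = rng.permutation(n)
            losses, weights = [], []
            for start in range(0, n, tcfg.batch_size):
                idx = order[start:start + tcfg.batch_size]
                xb, yb = X[idx], y[idx]
                pred = net.forward(xb, training=True)
                resid = pred - yb
                loss = float(np.mean(resid**2))
                if not np.isfinite(loss):
                    raise DivergenceError(
                        f"non-finite training loss at epoch {epoch} "
                        f"(learning_rate={tcfg.learning_rate})"
                    )
                opt.zero_grad()
                net.backward((2.0 / len(idx)) * resid.astype(np.float32))
                opt.step()
                losses.append(loss)
                weights.append(len(idx))
            history.append(float(np.average(losses, weights=weights)))
        net.recalibrate_bn(X, tcfg.batch_size)
        self.net_ = net
        self.loss_history_ = history
        self.training_config_ = tcfg
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        self.patch_shape_ = X.shape[1:]
        return self

    def predict(self, X):
        check_is_fitted(self, "net_")
        X = _patch_array(X)
        if X.shape[0] == 0:
            return np.zeros(0, dtype=np.float64)
        if X.shape[1:] != self.patch_shape_:
            raise ValueError(
                f"patch shape {X.shape[1:]} does not match fitted shape {self.patch_shape_}"
            )
        out = np.empty(X.shape[0], dtype=np.float64)
        step = max(1, self.batch_size)
        for start in range(0, X.shape[0], step):
            out[start:start + step] = self.net_.forward(
                X[start:start + step], training=False
            )
        return out


@dataclass
class TrainedModel:
    """A fitted per-factor network with its provenance."""

    estimator: PatchRegressor3D
    network_config: NetworkConfig
    training_config: TrainingConfig
    factor_name: str = ""
    fold_id: int | None = None

    @property
    def training_loss_history(self) -> list[float]:
        return list(self.estimator.loss_history_)


def train_model(patches, labels, net_config: NetworkConfig | None = None,
                train_config: TrainingConfig | None = None,
                factor_name: str = "", fold_id: int | None = None) -> TrainedModel:
    """Train one per-factor network on labeled patches (functional wrapper)."""
    net_config = net_config or NetworkConfig()
    train_config = train_config or TrainingConfig()
    est = PatchRegressor3D(
        network_config=net_config,
        epochs=train_config.epochs,
        batch_size=train_config.batch_size,
        learning_rate=train_config.learning_rate,
        weight_decay=train_config.weight_decay,
        random_state=train_config.seed,
    )
    est.fit(patches, labels)
    return TrainedModel(estimator=est, network_config=net_config,
                        training_config=train_config,
                        factor_name=factor_name, fold_id=fold_id)


def predict_patch_scores(model: TrainedModel | PatchRegressor3D, patches) -> np.ndarray:
    """One finite scalar per patch, order-aligned with the input."""
    est = model.estimator if isinstance(model, TrainedModel) else model
    return est.predict(patches)


def assign_patch_labels(patches, scores, factor_name: str):
    """Broadcast each subject's factor score onto all of that subject's patches.

    ``scores`` is a DataFrame indexed by subject_id with one column per
    factor.  Returns ``(X, y, subject_ids)`` where every patch of a subject
    carries that subject's score for ``factor_name``.
    """
    if factor_name not in scores.columns:
        raise KeyError(f"factor {factor_name!r} not in score table columns "
                       f"{list(scores.columns)}")
    subject_ids = [p.center.subject_id for p in patches]
    missing = sorted(set(subject_ids) - set(scores.index.astype(str)))
    if missing:
        raise KeyError(f"subjects with patches but no scores: {missing}")
    lookup = scores[factor_name]
    lookup.index = lookup.index.astype(str)
    y = np.array([lookup.loc[s] for s in subject_ids], dtype=np.float32)
    return _patch_array(patches), y, subject_ids


def save_model(model: TrainedModel, path) -> None:
    """Checkpoint: npz of weights + JSON sidecar with configs and loss history."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), **model.estimator.net_.state_arrays())
    side = {
        "network_config": asdict(model.network_config),
        "training_config": asdict(model.training_config),
        "factor_name": model.factor_name,
        "fold_id": model.fold_id,
        "loss_history": model.training_loss_history,
        "patch_shape": list(model.estimator.patch_shape_),
    }
    path.with_suffix(".json").write_text(json.dumps(side, indent=2))


def load_model(path) -> TrainedModel:
    path = Path(path)
    side = json.loads(path.with_suffix(".json").read_text())
    ncfg = NetworkConfig(**{k: tuple(v) if isinstance(v, list) else v
                            for k, v in side["network_config"].items()})
    tcfg = TrainingConfig(**side["training_config"])
    est = PatchRegressor3D(network_config=ncfg, epochs=tcfg.epochs,
                           batch_size=tcfg.batch_size,
                           learning_rate=tcfg.learning_rate,
                           weight_decay=tcfg.weight_decay,
                           random_state=tcfg.seed)
    net = build_network(ncfg, np.random.default_rng(0))
    with np.load(path.with_suffix(".npz")) as data:
        net.load_state_arrays(dict(data))
    est.net_ = net
    est.loss_history_ = list(side["loss_history"])
    est.training_config_ = tcfg
    est.patch_shape_ = tuple(side["patch_shape"])
    est.n_features_in_ = int(np.prod(est.patch_shape_))
    return TrainedModel(estimator=est, network_config=ncfg, training_config=tcfg,
                        factor_name=side["factor_name"], fold_id=side["fold_id"])
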