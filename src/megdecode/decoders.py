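"""Phrase decoders: shallow ANN baseline, small CNN, score aggregation.

The baseline is a single-hidden-layer network (256 sigmoid units, softmax
head) trained with plain SGD on the per-(channel, band) RMS feature vector,
early-stopped on validation loss with a patience of 6 epochs.

The image decoder is a small convolutional network — first kernel 11 x 11
(large initial receptive fields suit scalogram energy blobs), two further
conv blocks, a dense head — trained with Adam at learning rate 1e-4, the
freshly initialized head running at 20x that rate, minibatch 64, gradient
clipping by global norm, and validation-patience early stopping.  It stands
in for large ImageNet-pretrained backbones at desk scale; the training
protocol (optimizer, rates, batch, patience) is the same.

Per-sensor decisions are combined into a trial decision by averaging the
negative log class probabilities across sensors (equivalently: argmax of the
geometric-mean probability).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nnet


@dataclass
class AnnConfig:
    input_dim: int = 1176
    hidden_nodes: int = 256
    output_classes: int = 5
    learning_rate: float = 0.01  # tuned over {0.1, 0.01, 0.001, 0.0001}
    max_epochs: int = 100
    early_stop_patience: int = 6
    batch_size: int = 16
    standardize: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.hidden_nodes < 1:
            raise ValueError("hidden_nodes must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class CnnConfig:
    input_size: tuple[int, int, int] = (48, 48, 3)  # H, W, C
    architecture: str = "small_cnn"
    output_classes: int = 5
    learning_rate: float = 1e-4
    head_lr_multiplier: float = 20.0
    minibatch: int = 64
    max_epochs: int = 60
    validation_patience: int = 6
    validate_every: int | None = 6  # optimizer steps between validations
    clip_norm: float = 1.0
    first_kernel: int = 11
    first_stride: int = 2
    conv_channels: tuple[int, ...] = (16, 32)
    dense_units: int = 64
    seed: int = 0

    def validate(self) -> None:
        if self.minibatch < 1:
            raise ValueError("minibatch must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.architecture != "small_cnn":
            raise ValueError(
                f"architecture {self.architecture!r} not available; "
                "only 'small_cnn' is built in")


@dataclass
class TrainedModel:
    """A fitted decoder with its config snapshot and training history."""

    net: nnet.Network
    config: AnnConfig | CnnConfig
    history: dict
    classes: np.ndarray
    scaler: tuple[np.ndarray, np.ndarray] | None = None  # (mean, sd)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.scaler is not None:
            mean, sd = self.scaler
            X = (X - mean) / sd
        return self.net.predict_proba(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes[self.predict_proba(X).argmax(axis=1)]


def _check_labels(y: np.ndarray, n_classes: int) -> None:
    present = np.unique(y)
    missing = set(range(n_classes)) - set(int(c) for c in present)
    if missing:
        raise ValueError(f"classes absent from training labels: {sorted(missing)}")


def train_ann(
    X: np.ndarray, y: np.ndarray,
    X_val: np.ndarray, y_val: np.ndarray,
    cfg: AnnConfig | None = None,
) -> TrainedModel:
    """Fit the shallow ANN baseline on feature vectors.

    Features are z-scored with training-set statistics (RMS features span
    orders of magnitude across bands; plain SGD needs comparable scales).
    Returns the best-validation snapshot.
    """
    cfg = cfg or AnnConfig(input_dim=X.shape[1])
    cfg.validate()
    X = np.asarray(X, dtype=float)
    if X.shape[1] != cfg.input_dim:
        raise ValueError(f"feature dim {X.shape[1]} != cfg.input_dim {cfg.input_dim}")
    y = np.asarray(y, dtype=int)
    _check_labels(y, cfg.output_classes)

    scaler = None
    Xv = np.asarray(X_val, dtype=float)
    if cfg.standardize:
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        scaler = (mean, sd)
        X = (X - mean) / sd
        Xv = (Xv - mean) / sd

    rng = np.random.default_rng(cfg.seed)
    net = nnet.Network([
        nnet.Dense(cfg.input_dim, cfg.hidden_nodes, rng),
        nnet.Sigmoid(),
        nnet.Dense(cfg.hidden_nodes, cfg.output_classes, rng),
    ])
    history = nnet.fit(
        net, X, y, Xv, np.asarray(y_val, dtype=int),
        optimizer=nnet.SGD(lr=cfg.learning_rate), rng=rng,
        batch_size=cfg.batch_size, max_epochs=cfg.max_epochs,
        patience=cfg.early_stop_patience)
    return TrainedModel(net=net, config=cfg, history=history,
                        classes=np.arange(cfg.output_classes), scaler=scaler)


def build_small_cnn(cfg: CnnConfig, rng: np.random.Generator) -> nnet.Network:
    """Conv(11x11) -> pool -> Conv(3x3) -> pool -> dense -> 5-way head."""
    h, w, c = cfg.input_size
    layers: list[nnet.Layer] = []
    ch_in = c
    kernel, stride = cfg.first_kernel, cfg.first_stride
    for i, ch_out in enumerate(cfg.conv_channels):
        layers += [nnet.Conv2D(ch_in, ch_out, kernel, stride, rng), nnet.ReLU(),
                   nnet.MaxPool2D(2)]
        h = ((h - kernel) // stride + 1) // 2
        w = ((w - kernel) // stride + 1) // 2
        ch_in = ch_out
        kernel, stride = 3, 1
        if h < 4 or w < 4:
            break
    layers.append(nnet.Flatten())
    layers.append(nnet.Dense(h * w * ch_in, cfg.dense_units, rng))
    layers.append(nnet.ReLU())
    layers.append(nnet.Dense(cfg.dense_units, cfg.output_classes, rng,
                             lr_mult=cfg.head_lr_multiplier))
    return nnet.Network(layers)


def train_cnn(
    images: np.ndarray, y: np.ndarray,
    val_images: np.ndarray, y_val: np.ndarray,
    cfg: CnnConfig | None = None,
    provenance: list[dict] | None = None,
    split_of: dict[str, str] | None = None,
) -> TrainedModel:
    """Fit the small CNN on NHWC images.

    When ``provenance`` (one dict per training+validation image, in order)
    and ``split_of`` (trial id -> split name) are supplied, any augmented
    image whose parent sits in a different split raises a hard error before
    training starts.
    """
    cfg = cfg or CnnConfig(input_size=tuple(images.shape[1:]))
    cfg.validate()
    images = np.asarray(images, dtype=float)
    if tuple(images.shape[1:]) != tuple(cfg.input_size):
        raise ValueError(
            f"images are {tuple(images.shape[1:])}, config expects {cfg.input_size}")
    y = np.asarray(y, dtype=int)
    _check_labels(y, cfg.output_classes)
    if provenance is not None and split_of is not None:
        check_augmentation_hygiene(provenance, split_of)

    rng = np.random.default_rng(cfg.seed)
    net = build_small_cnn(cfg, rng)
    history = nnet.fit(
        net, images, y, np.asarray(val_images, dtype=float),
        np.asarray(y_val, dtype=int),
        optimizer=nnet.Adam(lr=cfg.learning_rate, clip_norm=cfg.clip_norm),
        rng=rng, batch_size=cfg.minibatch, max_epochs=cfg.max_epochs,
        patience=cfg.validation_patience, validate_every=cfg.validate_every)
    return TrainedModel(net=net, config=cfg, history=history,
                        classes=np.arange(cfg.output_classes))


def check_augmentation_hygiene(
    provenance: list[dict], split_of: dict[str, str]
) -> None:
    """Raise if any augmented item straddles splits with its parent."""
    for prov in provenance:
        if prov.get("kind") != "augmented":
            continue
        child_split = split_of.get(prov.get("id", ""), None)
        parent_split = split_of.get(prov["parent"], None)
        if parent_split is not None and child_split is not None \
                and child_split != parent_split:
            raise ValueError(
                f"split leakage: augmented trial of parent {prov['parent']} "
                f"({child_split}) differs from parent split ({parent_split})")


def aggregate_trial(
    sensor_probs: np.ndarray, eps: float = 1e-12
) -> tuple[int, np.ndarray, bool]:
    """Combine per-sensor class probabilities into one trial decision.

    The trial score of class k is the mean over sensors of -log p_sensor(k);
    the prediction is the argmin (lowest class index on ties, which is
    flagged).  Returns (predicted class, per-class score vector, tie flag).
    """
    p = np.asarray(sensor_probs, dtype=float)
    if p.ndim != 2:
        raise ValueError("sensor_probs must be (n_sensors x n_classes)")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("each sensor's probabilities must sum to 1")
    scores = -np.mean(np.log(np.maximum(p, eps)), axis=0)
    best = float(scores.min())
    winners = np.nonzero(np.isclose(scores, best, rtol=0, atol=1e-12))[0]
    return int(winners[0]), scores, bool(winners.size > 1)


def aggregate_trial_mean_prob(sensor_probs: np.ndarray) -> tuple[int, np.ndarray, bool]:
    """Config alternative: arithmetic-mean probability across sensors."""
    p = np.asarray(sensor_probs, dtype=float)
    mean = p.mean(axis=0)
    best = float(mean.max())
    winners = np.nonzero(np.isclose(mean, best, rtol=0, atol=1e-12))[0]
    return int(winners[0]), mean, bool(winners.size > 1)
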