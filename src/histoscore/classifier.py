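"""Tile classifiers: model construction, training with the plateau learning-
rate schedule, probability prediction, and model persistence.

Two backends satisfy one contract (``predict_proba`` emitting a probability
vector over the score classes plus ignore):

* ``transfer_backbone`` — the production recipe: an ImageNet-pretrained
  convolutional feature extractor (Inception-V3 class of architectures) whose
  1000-class head is replaced by a fresh softmax of width 6 (Ashcroft) or 5
  (inflammation), fine-tuned on all layers. Building it requires a deep
  learning framework with downloadable pretrained weights; when none is
  available an explicit :class:`~histoscore.errors.BackboneUnavailableError`
  points at the ``small_cnn`` backend.
* ``small_cnn`` — a compact numpy conv net trainable on a CPU in seconds,
  used for desk-scale experiments on the synthetic tiles.

Training uses SGD with momentum 0.9 at an initial learning rate of 0.5e-4,
reduced by a factor of 1/5 — down to a floor of 1e-7 — whenever the
validation loss has not reached a new minimum for three consecutive epochs.
Class imbalance is compensated by oversampling; augmentation is applied to
training tiles only. The best-validation-loss weights are retained.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .dataset import (
    AugmentationPolicy,
    LabelledDataset,
    LabelledItem,
    augment,
    oversample_balance,
    resize_image,
)
from .errors import (
    BackboneUnavailableError,
    HistoscoreError,
    InvalidArgumentError,
    ModelFormatError,
)
from .smallcnn import SGDMomentum, SmallCNN

logger = logging.getLogger(__name__)

MODEL_FORMAT = "histoscore-model"
MODEL_VERSION = 1


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters. Defaults follow the fine-tuning recipe
    (initial lr 0.5e-4, momentum 0.9, plateau factor 1/5 with patience 3 down
    to 1e-7); :meth:`desk_scale` returns settings suited to training the
    small CNN from scratch."""

    initial_lr: float = 0.5e-4
    momentum: float = 0.9
    plateau_factor: float = 0.2
    plateau_patience_epochs: int = 3
    min_lr: float = 1e-7
    max_epochs: int = 50
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.plateau_factor < 1.0:
            raise InvalidArgumentError("plateau_factor must lie in (0, 1)")
        if self.min_lr >= self.initial_lr:
            raise InvalidArgumentError("min_lr must be below initial_lr")

    @classmethod
    def desk_scale(cls, *, max_epochs: int = 30, seed: int = 0) -> "TrainConfig":
        """Settings for training the small CNN from scratch on synthetic
        tiles: a from-scratch network needs a far larger initial step size
        than a fine-tuned pretrained one."""
        return cls(initial_lr=0.02, max_epochs=max_epochs, seed=seed)


def plateau_lr_trajectory(
    val_losses,
    initial_lr: float,
    factor: float = 0.2,
    patience: int = 3,
    min_lr: float = 1e-7,
) -> list[float]:
    """Learning rate in effect *after* each epoch's validation evaluation.

    Pure function of the validation-loss sequence: "did not reduce" means no
    new strict minimum; after ``patience`` consecutive non-improving epochs
    the rate is multiplied by ``factor`` (floored at ``min_lr``) and the
    counter resets. The counter also resets on improvement.
    """
    lr = initial_lr
    best = np.inf
    streak = 0
    out = []
    for loss in val_losses:
        if loss < best:
            best = loss
            streak = 0
        else:
            streak += 1
            if streak >= patience:
                lr = max(lr * factor, min_lr)
                streak = 0
        out.append(lr)
    return out


class PlateauScheduler:
    """Stateful wrapper over :func:`plateau_lr_trajectory` semantics."""

    def __init__(self, initial_lr, factor=0.2, patience=3, min_lr=1e-7):
        self.lr = initial_lr
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.streak = 0

    def step(self, val_loss: float) -> float:
        """Record one epoch's validation loss; return the lr for the next epoch."""
        if val_loss < self.best:
            self.best = val_loss
            self.streak = 0
        else:
            self.streak += 1
            if self.streak >= self.patience:
                self.lr = max(self.lr * self.factor, self.min_lr)
                self.streak = 0
        return self.lr


@dataclass
class LearningCurve:
    """Per-epoch training history."""

    epochs: list[int] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)

    def append(self, epoch, train_acc, val_acc, train_loss, val_loss, lr):
        self.epochs.append(epoch)
        self.train_accuracy.append(train_acc)
        self.val_accuracy.append(val_acc)
        self.train_loss.append(train_loss)
        self.val_loss.append(val_loss)
        self.lr.append(lr)

    def __len__(self) -> int:
        return len(self.epochs)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": self.epochs,
                "train_accuracy": self.train_accuracy,
                "val_accuracy": self.val_accuracy,
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "lr": self.lr,
            }
        )


@dataclass
class ClassifierModel:
    """A trained (or freshly initialized) tile classifier."""

    backend: str
    class_names: tuple[str, ...]
    input_px: int
    net: SmallCNN | None = None
    scheme_name: str | None = None

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def predict_proba(self, tiles) -> np.ndarray:
        return predict_proba(self, tiles)


def build_model(
    backend: str,
    class_names,
    seed: int = 0,
    *,
    input_px: int | None = None,
    scheme_name: str | None = None,
) -> ClassifierModel:
    """Construct a classifier with a softmax head of width ``len(class_names)``.

    ``backend`` is ``"small_cnn"`` (compact numpy conv net, default input
    32 px) or ``"transfer_backbone"`` (pretrained feature extractor + fresh
    head, default input 299 px). Weight initialization is reproducible per
    ``seed``.
    """
    class_names = tuple(str(c) for c in class_names)
    if len(class_names) < 2:
        raise InvalidArgumentError("need at least two class names")
    if backend in ("small_cnn", "small"):
        px = input_px or 32
        net = SmallCNN(len(class_names), input_px=px, seed=seed)
        return ClassifierModel("small_cnn", class_names, px, net, scheme_name)
    if backend in ("transfer_backbone", "transfer"):
        try:  # requires a DL framework and downloadable pretrained weights
            from keras.applications import InceptionV3  # type: ignore

            InceptionV3(weights="imagenet", include_top=False)
        except Exception as exc:
            raise BackboneUnavailableError(
                "the pretrained transfer backbone is unavailable (no deep "
                "learning framework with ImageNet weights in this "
                "environment); use backend='small_cnn' instead"
            ) from exc
        raise NotImplementedError("transfer backbone head attachment")
    raise InvalidArgumentError(f"unknown backend {backend!r}")


def _normalize(batch: np.ndarray) -> np.ndarray:
    """uint8 (N, H, W, 3) -> float32 (N, 3, H, W) in [-1, 1]."""
    x = batch.astype(np.float32) / 127.5 - 1.0
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def _load_image(path: Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def load_items(
    items: list[LabelledItem], class_names: tuple[str, ...]
) -> tuple[list[np.ndarray], np.ndarray]:
    """Load item images at native resolution with integer label indices."""
    images = [_load_image(it.path) for it in items]
    labels = np.array([class_names.index(it.label) for it in items], dtype=np.int64)
    return images, labels


def train(
    model: ClassifierModel,
    dataset: LabelledDataset,
    config: TrainConfig,
    *,
    augmentation: AugmentationPolicy | None = None,
    oversample: bool = True,
) -> tuple[ClassifierModel, LearningCurve]:
    """Train a ``small_cnn`` model on a split dataset.

    SGD with momentum on all layers; the learning rate follows the plateau
    schedule driven by the validation loss; the training partition is
    oversampled to class balance and augmented per epoch; the returned model
    carries the best-validation-loss weights. ``max_epochs=0`` is a no-op.
    """
    if model.net is None:
        raise InvalidArgumentError("train() requires a small_cnn model")
    curve = LearningCurve()
    if config.max_epochs == 0:
        return model, curve
    train_items = dataset.train_items
    val_items = dataset.val_items
    if not train_items:
        raise InvalidArgumentError("empty training partition")
    if not val_items:
        raise InvalidArgumentError("validation partition required for the plateau schedule")
    if oversample:
        train_items = oversample_balance(train_items, seed=config.seed)
    policy = augmentation or AugmentationPolicy(target_px=model.input_px)
    if policy.target_px != model.input_px:
        policy = replace(policy, target_px=model.input_px)

    # cache every distinct image once at native resolution
    cache: dict[Path, np.ndarray] = {}
    for it in set(train_items) | set(val_items):
        cache[it.path] = _load_image(it.path)
    y_train = np.array(
        [model.class_names.index(it.label) for it in train_items], dtype=np.int64
    )
    x_val = _normalize(
        np.stack([resize_image(cache[it.path], model.input_px) for it in val_items])
    )
    y_val = np.array(
        [model.class_names.index(it.label) for it in val_items], dtype=np.int64
    )

    net = model.net
    opt = SGDMomentum(net, momentum=config.momentum)
    sched = PlateauScheduler(
        config.initial_lr,
        config.plateau_factor,
        config.plateau_patience_epochs,
        config.min_lr,
    )
    rng = np.random.default_rng(config.seed)
    best_val = np.inf
    best_weights = net.get_weights()
    epochs_since_best = 0
    lr = config.initial_lr
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train_items))
        losses, accs = [], []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = np.stack(
                [augment(cache[train_items[i].path], policy, rng) for i in idx]
            )
            loss, acc = net.loss_and_grad(_normalize(batch), y_train[idx])
            if not np.isfinite(loss):
                raise HistoscoreError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(lr={lr:g}); reduce the learning rate"
                )
            opt.step(lr)
            losses.append(loss)
            accs.append(acc)
        val_probs = net.predict_proba(x_val)
        val_loss = float(-np.log(val_probs[np.arange(len(y_val)), y_val] + 1e-12).mean())
        val_acc = float((val_probs.argmax(axis=1) == y_val).mean())
        curve.append(epoch, float(np.mean(accs)), val_acc, float(np.mean(losses)), val_loss, lr)
        logger.info(
            "epoch %d: train acc %.3f loss %.3f | val acc %.3f loss %.3f | lr %g",
            epoch, np.mean(accs), np.mean(losses), val_acc, val_loss, lr,
        )
        if val_loss < best_val:
            best_val = val_loss
            best_weights = net.get_weights()
            epochs_since_best = 0
        else:
            epochs_since_best += 1
        lr = sched.step(val_loss)
        if lr <= config.min_lr and epochs_since_best >= 2 * config.plateau_patience_epochs:
            logger.info("early stop at epoch %d (lr floored, no improvement)", epoch)
            break
    net.set_weights(best_weights)
    return model, curve


def predict_proba(model: ClassifierModel, tiles) -> np.ndarray:
    """Per-tile class probabilities, one row per tile, rows summing to 1.

    ``tiles`` is a list of RGB uint8 arrays (any square size; resized to the
    model input) or a stacked ``(N, H, W, 3)`` array.
    """
    if model.net is None:
        raise InvalidArgumentError("model has no trained network")
    if isinstance(tiles, np.ndarray) and tiles.ndim == 3:
        tiles = [tiles]
    imgs = []
    for t in tiles:
        t = np.asarray(t)
        if t.ndim != 3 or t.shape[2] != 3:
            raise InvalidArgumentError(f"tile must be RGB (H, W, 3), got {t.shape}")
        imgs.append(resize_image(t, model.input_px))
    probs = model.net.predict_proba(_normalize(np.stack(imgs)))
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    return probs


class CallableClassifier:
    """Adapter giving any tile -> probability function the classifier contract.

    Useful for driving the scoring pipeline end-to-end with configured
    vectors (e.g. one-hot outputs derived from ground truth) without training.
    """

    def __init__(self, class_names, fn):
        self.class_names = tuple(class_names)
        self.backend = "callable"
        self._fn = fn

    def predict_proba(self, tiles) -> np.ndarray:
        return np.stack([np.asarray(self._fn(t), dtype=float) for t in tiles])


def save_model(model: ClassifierModel, path: str | Path) -> None:
    """Persist a model as a single-file archive (weights + JSON metadata)."""
    if model.net is None:
        raise InvalidArgumentError("only small_cnn models can be saved")
    path = Path(path)
    meta = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "backend": model.backend,
        "class_names": list(model.class_names),
        "input_px": model.input_px,
        "scheme_name": model.scheme_name,
        "channels": list(model.net.channels),
    }
    weights = {f"w{i}": w for i, w in enumerate(model.net.get_weights())}
    with open(path, "wb") as fh:
        np.savez(fh, meta=json.dumps(meta), **weights)


def load_model(path: str | Path) -> ClassifierModel:
    """Load a model archive; predictions round-trip bit-compatibly."""
    path = Path(path)
    try:
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            if meta.get("format") != MODEL_FORMAT:
                raise ModelFormatError(f"{path} is not a histoscore model archive")
            if meta.get("version") != MODEL_VERSION:
                raise ModelFormatError(
                    f"model version {meta.get('version')} unsupported "
                    f"(expected {MODEL_VERSION})"
                )
            weights = [data[f"w{i}"] for i in range(len(data.files) - 1)]
    except ModelFormatError:
        raise
    except Exception as exc:
        raise ModelFormatError(f"cannot read model archive {path}: {exc}") from exc
    net = SmallCNN(
        len(meta["class_names"]),
        input_px=meta["input_px"],
        channels=tuple(meta["channels"]),
    )
    net.set_weights(weights)
    return ClassifierModel(
        meta["backend"],
        tuple(meta["class_names"]),
        meta["input_px"],
        net,
        meta["scheme_name"],
    )
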