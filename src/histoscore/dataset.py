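"""Folder-labelled tile datasets: loading, train/validation split, class
balancing by oversampling, and training-time augmentation.

Training tiles are labelled by moving them into folders named after their
class (e.g. ``0 1 3 5 7 ignore`` for the Ashcroft scheme). 90% of the data is
randomly selected for training and 10% for validation. Class imbalance in the
training partition is compensated by oversampling to the largest class;
augmentation (uniform rotation in [-45, 45] degrees, vertical flip with
probability 0.5, then resize to the model input size) is applied to training
items only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import rotate as nd_rotate
from skimage.transform import resize as sk_resize

from .errors import ConfigurationError, InvalidArgumentError

logger = logging.getLogger(__name__)

IMAGE_EXTENSIONS = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}


@dataclass(frozen=True)
class LabelledItem:
    path: Path
    label: str


@dataclass
class LabelledDataset:
    """(image path, class label) pairs with an optional train/val partition."""

    items: list[LabelledItem]
    class_names: tuple[str, ...]
    train_idx: list[int] = field(default_factory=list)
    val_idx: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        for it in self.items:
            if it.label not in self.class_names:
                raise InvalidArgumentError(f"label {it.label!r} not in class_names")
        if set(self.train_idx) & set(self.val_idx):
            raise InvalidArgumentError("train and validation partitions overlap")

    def __len__(self) -> int:
        return len(self.items)

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in self.class_names}
        for it in self.items:
            out[it.label] += 1
        return out

    @property
    def train_items(self) -> list[LabelledItem]:
        return [self.items[i] for i in self.train_idx]

    @property
    def val_items(self) -> list[LabelledItem]:
        return [self.items[i] for i in self.val_idx]


def load_labelled_folders(root: str | Path, class_names) -> LabelledDataset:
    """Index every readable image under ``root/<class>/`` with its folder label.

    Raises :class:`ConfigurationError` if a class folder is missing; files
    that cannot be opened as images are logged and skipped. Empty class
    folders load with a zero-count warning.
    """
    root = Path(root)
    class_names = tuple(class_names)
    items: list[LabelledItem] = []
    for name in class_names:
        folder = root / name
        if not folder.is_dir():
            raise ConfigurationError(f"missing class folder {folder}")
        n_before = len(items)
        for p in sorted(folder.iterdir()):
            if not p.is_file() or p.suffix.lower() not in IMAGE_EXTENSIONS:
                continue
            try:
                with Image.open(p) as im:
                    im.verify()
            except Exception as exc:
                logger.warning("skipping unreadable image %s (%s)", p, exc)
                continue
            items.append(LabelledItem(p, name))
        n = len(items) - n_before
        if n == 0:
            logger.warning("class folder %s contains no readable images", folder)
        logger.info("class %r: %d items", name, n)
    return LabelledDataset(items, class_names)


def split_train_val(
    ds: LabelledDataset,
    val_fraction: float = 0.1,
    seed: int = 0,
    *,
    stratified: bool = False,
) -> LabelledDataset:
    """Randomly partition a dataset into train and validation indices.

    The split is global (a single random draw over all items) unless
    ``stratified=True``, in which case it is performed per class. After the
    global draw, any class with at least two items that ended up absent from
    one partition has one item swapped in, so both partitions cover every
    adequately represented class. Classes with a single item go to training
    with a warning. Reproducible per seed.
    """
    if not 0.0 < val_fraction < 1.0:
        raise InvalidArgumentError("val_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    n = len(ds.items)
    if n == 0:
        raise InvalidArgumentError("cannot split an empty dataset")
    by_class: dict[str, list[int]] = {c: [] for c in ds.class_names}
    for i, it in enumerate(ds.items):
        by_class[it.label].append(i)

    if stratified:
        train, val = [], []
        for c, idxs in by_class.items():
            idxs = list(rng.permutation(idxs))
            if len(idxs) < 2:
                if idxs:
                    logger.warning("class %r has <2 items; assigned to train", c)
                train += idxs
                continue
            n_val = max(1, int(round(len(idxs) * val_fraction)))
            val += idxs[:n_val]
            train += idxs[n_val:]
    else:
        order = list(rng.permutation(n))
        n_val = int(round(n * val_fraction))
        val = order[:n_val]
        train = order[n_val:]
        train_set, val_set = set(train), set(val)
        for c, idxs in by_class.items():
            if len(idxs) < 2:
                for i in idxs:
                    if i in val_set:
                        val_set.discard(i)
                        train_set.add(i)
                        logger.warning("class %r has <2 items; moved to train", c)
                continue
            if not any(i in val_set for i in idxs):
                mover = idxs[int(rng.integers(len(idxs)))]
                train_set.discard(mover)
                val_set.add(mover)
                _swap_back(rng, by_class, val_set, train_set, exclude=c)
            if not any(i in train_set for i in idxs):
                mover = next(i for i in idxs if i in val_set)
                val_set.discard(mover)
                train_set.add(mover)
                _swap_back(rng, by_class, train_set, val_set, exclude=c)
        train = sorted(train_set)
        val = sorted(val_set)

    return LabelledDataset(ds.items, ds.class_names, list(train), list(val))


def _swap_back(
    rng: np.random.Generator,
    by_class: dict[str, list[int]],
    grown: set[int],
    shrunk: set[int],
    exclude: str,
) -> None:
    """Restore partition sizes after a coverage swap by moving one item of a
    class with at least two members in ``grown`` back to ``shrunk``."""
    candidates = [
        i
        for c, idxs in by_class.items()
        if c != exclude and sum(j in grown for j in idxs) >= 2
        for i in idxs
        if i in grown
    ]
    if candidates:
        back = candidates[int(rng.integers(len(candidates)))]
        grown.discard(back)
        shrunk.add(back)


def oversample_balance(
    train_items: list[LabelledItem], seed: int = 0
) -> list[LabelledItem]:
    """Balance classes by sampling with replacement up to the largest class.

    Every emitted item references an original file with its original label;
    the returned list is shuffled. Classes absent from the input stay absent.
    """
    if not train_items:
        raise InvalidArgumentError("empty training set")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[LabelledItem]] = {}
    for it in train_items:
        by_class.setdefault(it.label, []).append(it)
    target = max(len(v) for v in by_class.values())
    out: list[LabelledItem] = []
    for items in by_class.values():
        out.extend(items)
        deficit = target - len(items)
        if deficit > 0:
            extra = rng.integers(0, len(items), size=deficit)
            out.extend(items[i] for i in extra)
    rng.shuffle(out)  # type: ignore[arg-type]
    return out


@dataclass(frozen=True)
class AugmentationPolicy:
    """Training-time augmentation: rotation range (degrees), vertical flip,
    and the model input size the tile is finally resized to."""

    rotation_range_deg: tuple[float, float] = (-45.0, 45.0)
    vertical_flip: bool = True
    flip_probability: float = 0.5
    target_px: int = 299

    def __post_init__(self) -> None:
        lo, hi = self.rotation_range_deg
        if lo > hi:
            raise InvalidArgumentError("rotation range must satisfy lo <= hi")
        if not 0.0 <= self.flip_probability <= 1.0:
            raise InvalidArgumentError("flip_probability must lie in [0, 1]")


def sample_augmentation(
    policy: AugmentationPolicy, rng: np.random.Generator
) -> tuple[float, bool]:
    """Draw one (rotation angle, flip?) pair from the policy's distributions."""
    lo, hi = policy.rotation_range_deg
    angle = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    flip = bool(policy.vertical_flip and rng.random() < policy.flip_probability)
    return angle, flip


def resize_image(image: np.ndarray, target_px: int) -> np.ndarray:
    """Resize an RGB image to ``target_px`` square (uint8, anti-aliased)."""
    img = np.asarray(image)
    if img.shape[0] == target_px and img.shape[1] == target_px:
        return img.astype(np.uint8, copy=False)
    out = sk_resize(
        img, (target_px, target_px), order=1, anti_aliasing=True, preserve_range=True
    )
    return out.round().astype(np.uint8)


def augment(
    image: np.ndarray,
    policy: AugmentationPolicy,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Apply one random augmentation draw to a square RGB tile.

    Rotation angle ~ Uniform over the policy range, with reflection filling
    the exposed corners (constant fill would create artificial borders the
    classifier could exploit); vertical flip with the policy's probability;
    finally resized to ``policy.target_px``.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3 or img.shape[0] != img.shape[1]:
        raise InvalidArgumentError(
            f"augment expects a square RGB image, got shape {img.shape}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    angle, flip = sample_augmentation(policy, rng)
    if angle != 0.0:
        img = nd_rotate(
            img, angle, axes=(0, 1), reshape=False, order=1, mode="reflect"
        ).astype(np.uint8)
    if flip:
        img = img[::-1]
    return resize_image(img, policy.target_px)
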