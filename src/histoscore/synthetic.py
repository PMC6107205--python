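"""Deterministic synthetic Masson-trichrome-like tiles with known ground truth.

The generator produces caricatures of the two tile families the scoring
pipeline classifies, so that every downstream stage (dataset loading,
training, scoring, map rendering, evaluation) can be exercised with exact
ground truth and no external image data:

* **Fibrosis tiles** — pink/red parenchyma-like texture with airspace lumina,
  plus a blue collagen-like texture occupying a controlled fraction of the
  tissue area. The collagen fraction increases with the Ashcroft class, so a
  trivial colour feature (blue-dominant pixel fraction) linearly orders the
  classes and the classification task is learnable at desk scale.
* **Inflammation tiles** — parenchyma background with an exact number of
  dark-purple nucleus-like blobs; the class label follows the cell-count
  thresholding rule (0-5 -> 0, 6-10 -> 1, 11-20 -> 2, >=21 -> 3).
* **Ignore tiles** — two visually distinct non-scorable morphologies mixed
  50/50: near-blank glass, and large pale fat-like lobules.

Identical spec + seed yields a bit-identical image. The morphology constants
live in :class:`GeneratorParams` so tests can reference one config table.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from imageio.v3 import imwrite
from scipy.ndimage import gaussian_filter
from skimage.draw import disk
from skimage.measure import label as cc_label

from .errors import ConfigurationError, InvalidArgumentError
from .schemes import (
    INFLAMMATION_COUNT_RANGES,
    cell_count_to_class,
    get_scheme,
)

__all__ = [
    "GeneratorParams",
    "DEFAULT_PARAMS",
    "SyntheticTileSpec",
    "TileRender",
    "cell_count_to_class",
    "render_tile",
    "render_tile_meta",
    "generate_labelled_folders",
    "generate_virtual_slide",
    "blue_dominant_fraction",
    "count_dark_blobs",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Morphology constants of the synthetic generator (one config table).

    Colours are RGB in [0, 1] approximating a Masson-trichrome palette:
    collagen stains blue, cytoplasm red/pink, nuclei dark purple.
    """

    #: Collagen area fraction of tissue per Ashcroft class (strictly monotone).
    collagen_table: dict[str, float] = field(
        default_factory=lambda: {"0": 0.02, "1": 0.08, "3": 0.25, "5": 0.50, "7": 0.85}
    )
    #: Gaussian jitter (sd) applied to the table value per generated tile,
    #: clipped to +/- 0.02 so the class ordering stays separable.
    collagen_jitter_sd: float = 0.01
    #: Nucleus blob radius range in pixels at a 512-px tile; scaled down
    #: proportionally for smaller tiles, never below 2 px.
    blob_radius_512: tuple[int, int] = (4, 8)
    #: Fraction of the tile that is airspace (alveolar lumina).
    airspace_fraction: float = 0.35
    parenchyma_rgb: tuple[float, float, float] = (0.88, 0.62, 0.70)
    collagen_rgb: tuple[float, float, float] = (0.33, 0.42, 0.80)
    nucleus_rgb: tuple[float, float, float] = (0.28, 0.17, 0.40)
    lumen_rgb: tuple[float, float, float] = (0.970, 0.955, 0.945)
    glass_rgb: tuple[float, float, float] = (0.972, 0.960, 0.950)

    def blob_radius_range(self, tile_px: int) -> tuple[int, int]:
        scale = tile_px / 512.0
        lo, hi = self.blob_radius_512
        lo = max(2, round(lo * scale))
        hi = max(lo + 1, round(hi * scale))
        return lo, hi


DEFAULT_PARAMS = GeneratorParams()

MIN_TILE_PX = 64


@dataclass(frozen=True)
class SyntheticTileSpec:
    """Complete recipe for one synthetic tile.

    For inflammation specs the class label is implied by ``cell_count`` under
    the cell-count thresholds and must agree with ``class_label``; fibrosis
    specs carry a ``collagen_fraction`` in [0, 1] (defaulted from the class
    table when omitted). Rendering is a pure function of the spec.
    """

    scheme: str  # "fibrosis" or "inflammation"
    class_label: str
    seed: int
    tile_px: int = 512
    cell_count: int | None = None
    collagen_fraction: float | None = None
    clustered: bool = False

    def __post_init__(self) -> None:
        if self.scheme not in ("fibrosis", "inflammation"):
            raise InvalidArgumentError(f"unknown synthetic scheme {self.scheme!r}")
        if self.tile_px < MIN_TILE_PX:
            raise InvalidArgumentError(
                f"tile_px={self.tile_px} too small to carry morphology "
                f"(minimum {MIN_TILE_PX})"
            )
        scheme = get_scheme(self.scheme)
        if self.class_label not in scheme.all_labels:
            raise InvalidArgumentError(
                f"label {self.class_label!r} not in scheme {self.scheme!r}"
            )
        if self.class_label == scheme.ignore_label:
            return
        if self.scheme == "inflammation":
            if self.cell_count is None:
                raise InvalidArgumentError("inflammation spec requires cell_count")
            implied = str(cell_count_to_class(self.cell_count))
            if implied != self.class_label:
                raise InvalidArgumentError(
                    f"cell_count={self.cell_count} implies class {implied}, "
                    f"spec says {self.class_label}"
                )
        else:
            frac = self.collagen_fraction
            if frac is None:
                object.__setattr__(
                    self, "collagen_fraction", DEFAULT_PARAMS.collagen_table[self.class_label]
                )
            elif not 0.0 <= frac <= 1.0:
                raise InvalidArgumentError("collagen_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class TileRender:
    """A rendered tile plus the generator's own ground-truth bookkeeping."""

    image: np.ndarray  # uint8, (tile_px, tile_px, 3)
    spec: SyntheticTileSpec
    nucleus_centers: tuple[tuple[int, int], ...] = ()
    collagen_fraction_actual: float | None = None
    ignore_style: str | None = None  # "glass" or "fat"


def _smooth_field(rng: np.random.Generator, px: int, sigma: float) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal((px, px)), sigma, mode="wrap")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def _parenchyma(rng: np.random.Generator, px: int, params: GeneratorParams):
    """Pink tissue with airspace lumina; returns (image float, tissue mask)."""
    coarse = _smooth_field(rng, px, sigma=px / 16)
    thr = np.quantile(coarse, 1.0 - params.airspace_fraction)
    lumen = coarse > thr
    img = np.empty((px, px, 3), dtype=np.float64)
    img[:] = params.parenchyma_rgb
    # fine multiplicative speckle keeps the texture from being flat colour
    speckle = 1.0 + 0.05 * _smooth_field(rng, px, sigma=1.2)
    img *= speckle[..., None]
    img[lumen] = params.lumen_rgb
    img[lumen] += rng.normal(0.0, 0.004, size=(int(lumen.sum()), 3))
    return img, ~lumen


def _place_blobs(
    rng: np.random.Generator,
    count: int,
    px: int,
    radii: tuple[int, int],
    clustered: bool,
) -> list[tuple[int, int, int]]:
    """Sample ``count`` non-overlapping (row, col, radius) triples."""
    lo, hi = radii
    margin = hi + 2
    placed: list[tuple[int, int, int]] = []
    attempts = 0
    max_attempts = 400 * max(count, 1)
    if clustered:
        c0 = rng.uniform(margin + px / 6, px - margin - px / 6, size=2)
    while len(placed) < count:
        if attempts > max_attempts:
            raise InvalidArgumentError(
                f"cannot place {count} non-overlapping blobs in a {px}-px tile"
            )
        attempts += 1
        r = int(rng.integers(lo, hi + 1))
        if clustered:
            pos = rng.normal(c0, px / 8, size=2)
            if not (margin <= pos[0] < px - margin and margin <= pos[1] < px - margin):
                continue
            row, col = int(pos[0]), int(pos[1])
        else:
            row = int(rng.integers(margin, px - margin))
            col = int(rng.integers(margin, px - margin))
        if all(
            (row - r0) ** 2 + (col - c0_) ** 2 > (r + rr + 2) ** 2
            for r0, c0_, rr in placed
        ):
            placed.append((row, col, r))
    return placed


def _render_fibrosis(rng, spec: SyntheticTileSpec, params: GeneratorParams) -> TileRender:
    px = spec.tile_px
    img, tissue = _parenchyma(rng, px, params)
    frac = float(spec.collagen_fraction)
    collagen_field = _smooth_field(rng, px, sigma=px / 24)
    vals = collagen_field[tissue]
    if frac <= 0.0:
        mask = np.zeros_like(tissue)
    elif frac >= 1.0:
        mask = tissue.copy()
    else:
        thr = np.quantile(vals, 1.0 - frac)
        mask = tissue & (collagen_field > thr)
    shade = 1.0 + 0.05 * _smooth_field(rng, px, sigma=3.0)
    blue = np.array(params.collagen_rgb) * shade[..., None]
    img[mask] = blue[mask]
    actual = float(mask.sum() / max(tissue.sum(), 1))
    return TileRender(_to_uint8(img), spec, collagen_fraction_actual=actual)


def _render_inflammation(rng, spec: SyntheticTileSpec, params: GeneratorParams) -> TileRender:
    px = spec.tile_px
    img, _ = _parenchyma(rng, px, params)
    radii = params.blob_radius_range(px)
    blobs = _place_blobs(rng, int(spec.cell_count), px, radii, spec.clustered)
    for row, col, r in blobs:
        rr, cc = disk((row, col), r, shape=(px, px))
        shade = rng.uniform(0.85, 1.1)
        img[rr, cc] = np.clip(np.array(params.nucleus_rgb) * shade, 0, 1)
    centers = tuple((row, col) for row, col, _ in blobs)
    return TileRender(_to_uint8(img), spec, nucleus_centers=centers)


def _render_ignore(rng, spec: SyntheticTileSpec, params: GeneratorParams) -> TileRender:
    px = spec.tile_px
    style = "glass" if rng.random() < 0.5 else "fat"
    img = np.empty((px, px, 3), dtype=np.float64)
    img[:] = params.glass_rgb
    img += rng.normal(0.0, 0.004, size=img.shape)
    if style == "fat":
        # large empty adipocyte-like lobules with thin pink rims
        n_lobules = int(rng.integers(6, 13))
        for _ in range(n_lobules):
            r = int(rng.integers(px // 12, px // 5))
            row = int(rng.integers(r, px - r))
            col = int(rng.integers(r, px - r))
            rr, cc = disk((row, col), r, shape=(px, px))
            img[rr, cc] = (0.93, 0.90, 0.93)
            rim_rr, rim_cc = disk((row, col), max(r - max(2, px // 170), 1), shape=(px, px))
            rim = np.zeros((px, px), bool)
            rim[rr, cc] = True
            rim[rim_rr, rim_cc] = False
            img[rim] = (0.87, 0.70, 0.76)
    return TileRender(_to_uint8(img), spec, ignore_style=style)


def _to_uint8(img: np.ndarray) -> np.ndarray:
    return (np.clip(img, 0.0, 1.0) * 255).round().astype(np.uint8)


def render_tile_meta(
    spec: SyntheticTileSpec, params: GeneratorParams = DEFAULT_PARAMS
) -> TileRender:
    """Render a tile and return it with the generator's ground-truth metadata."""
    rng = np.random.default_rng(spec.seed)
    if spec.class_label == "ignore":
        return _render_ignore(rng, spec, params)
    if spec.scheme == "fibrosis":
        return _render_fibrosis(rng, spec, params)
    return _render_inflammation(rng, spec, params)


def render_tile(
    spec: SyntheticTileSpec, params: GeneratorParams = DEFAULT_PARAMS
) -> np.ndarray:
    """Render a tile as a ``(tile_px, tile_px, 3)`` uint8 RGB array."""
    return render_tile_meta(spec, params).image


def blue_dominant_fraction(image: np.ndarray) -> float:
    """Fraction of pixels whose blue channel strictly dominates red and green.

    A deliberately trivial hand-written feature: on synthetic fibrosis tiles
    it orders the Ashcroft classes, which guarantees the classification task
    is learnable.
    """
    img = np.asarray(image, dtype=np.float64)
    b_dom = (img[..., 2] > img[..., 0]) & (img[..., 2] > img[..., 1])
    return float(b_dom.mean())


def count_dark_blobs(image: np.ndarray, params: GeneratorParams = DEFAULT_PARAMS) -> int:
    """Count connected dark nucleus-like regions (inverse check of the generator)."""
    img = np.asarray(image, dtype=np.float64) / 255.0
    dist = np.linalg.norm(img - np.array(params.nucleus_rgb), axis=-1)
    labels = cc_label(dist < 0.25)
    sizes = np.bincount(labels.ravel())[1:]
    return int((sizes >= 3).sum())


def _tile_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0])


def _spec_for(
    scheme_name: str,
    label: str,
    seed: int,
    tile_px: int,
    aux_rng: np.random.Generator,
    params: GeneratorParams,
    clustered: bool = False,
) -> SyntheticTileSpec:
    """Build a concrete spec for a class label, drawing per-tile variation."""
    if label == "ignore":
        return SyntheticTileSpec(scheme_name, "ignore", seed, tile_px)
    if scheme_name == "inflammation":
        lo, hi = INFLAMMATION_COUNT_RANGES[int(label)]
        hi = int(min(hi, lo + 9))  # open-ended top class sampled from 21-30
        count = int(aux_rng.integers(lo, hi + 1))
        return SyntheticTileSpec(
            scheme_name, label, seed, tile_px, cell_count=count, clustered=clustered
        )
    base = params.collagen_table[label]
    jitter = float(np.clip(aux_rng.normal(0.0, params.collagen_jitter_sd), -0.02, 0.02))
    frac = float(np.clip(base + jitter, 0.0, 0.98))
    return SyntheticTileSpec(scheme_name, label, seed, tile_px, collagen_fraction=frac)


def generate_labelled_folders(
    root: str | Path,
    scheme: str,
    counts_per_class: int,
    seed: int,
    *,
    tile_px: int = 512,
    overwrite: bool = False,
    clustered: bool = False,
    params: GeneratorParams = DEFAULT_PARAMS,
) -> pd.DataFrame:
    """Write a folder-per-class tree of labelled PNG tiles plus a manifest.

    The layout mirrors how training tiles are labelled in practice: one
    subfolder per class named exactly by its label (fibrosis: ``0 1 3 5 7
    ignore``; inflammation: ``0 1 2 3 ignore``), each holding
    ``counts_per_class`` tiles. ``manifest.csv`` in ``root`` records every
    tile's spec and seed. Regeneration with the same arguments reproduces
    identical files.

    Returns the manifest as a DataFrame with columns
    ``path, scheme, class, cell_count, collagen_fraction, seed``.
    """
    root = Path(root)
    if root.exists() and any(root.iterdir()):
        if not overwrite:
            raise ConfigurationError(
                f"{root} exists and is not empty; pass overwrite=True to replace it"
            )
        shutil.rmtree(root)
    root.mkdir(parents=True, exist_ok=True)
    sch = get_scheme(scheme)
    scheme_name = "inflammation" if sch.name == "inflammation" else "fibrosis"
    rows = []
    for class_idx, label in enumerate(sch.all_labels):
        folder = root / label
        folder.mkdir()
        for i in range(counts_per_class):
            tile_seed = _tile_seed(seed, class_idx, i)
            aux = np.random.default_rng([seed, 7919, class_idx, i])
            spec = _spec_for(scheme_name, label, tile_seed, tile_px, aux, params, clustered)
            rel = Path(label) / f"{scheme_name}_{label}_{i:04d}.png"
            imwrite(root / rel, render_tile(spec, params))
            rows.append(
                {
                    "path": str(rel),
                    "scheme": scheme_name,
                    "class": label,
                    "cell_count": spec.cell_count,
                    "collagen_fraction": spec.collagen_fraction,
                    "seed": tile_seed,
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(root / "manifest.csv", index=False)
    return manifest


def generate_virtual_slide(
    width_tiles: int,
    height_tiles: int,
    score_field,
    seed: int,
    *,
    scheme: str = "fibrosis",
    tile_px: int = 512,
    params: GeneratorParams = DEFAULT_PARAMS,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble a virtual whole-slide image from per-tile ground-truth classes.

    ``score_field`` is a ``(height_tiles, width_tiles)`` array of class labels
    (ints or strings; ``"ignore"`` allowed). Returns ``(slide, labels)`` where
    ``slide`` is a uint8 RGB image of ``height_tiles*tile_px`` by
    ``width_tiles*tile_px`` pixels and ``labels`` the aligned string grid.
    Re-slicing the slide into ``tile_px`` tiles recovers the rendered tiles
    bit-exactly.
    """
    field_arr = np.asarray(score_field, dtype=object)
    if field_arr.shape != (height_tiles, width_tiles):
        raise InvalidArgumentError(
            f"score_field shape {field_arr.shape} does not match "
            f"({height_tiles}, {width_tiles})"
        )
    sch = get_scheme(scheme)
    scheme_name = "inflammation" if sch.name == "inflammation" else "fibrosis"
    labels = np.empty((height_tiles, width_tiles), dtype=object)
    rows_of_tiles = []
    for r in range(height_tiles):
        row_imgs = []
        for c in range(width_tiles):
            label = str(field_arr[r, c])
            if label not in sch.all_labels:
                raise InvalidArgumentError(f"label {label!r} not in scheme {scheme!r}")
            labels[r, c] = label
            aux = np.random.default_rng([seed, 104729, r, c])
            spec = _spec_for(scheme_name, label, _tile_seed(seed, r, c), tile_px, aux, params)
            row_imgs.append(render_tile(spec, params))
        rows_of_tiles.append(np.concatenate(row_imgs, axis=1))
    slide = np.concatenate(rows_of_tiles, axis=0)
    return slide, labels
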