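"""Whole-slide handling: reading, downscaling, and slicing into the tile grid.

Slides are scanned with a 20x objective, downscaled by 50% to a working
resolution of 0.44 um/pixel, and cut into non-overlapping 512x512-pixel
tiles. Grid coordinates (0-based row, col; row-major) are preserved so that
per-tile scores can be reassembled into spatial score maps. Right/bottom
remainders smaller than a tile are dropped rather than padded: partial tiles
would distort the cell-count and area-fraction semantics the classes encode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import EmptyGridError, InvalidArgumentError

DEFAULT_TILE_PX = 512
#: Mean-luminance threshold above which a tile is considered blank glass.
WHITENESS_THRESHOLD = 0.95


@dataclass
class SlideImage:
    """An RGB whole-slide raster with its physical pixel size."""

    pixels: np.ndarray  # uint8, (H, W, 3)
    microns_per_pixel: float = 0.44
    source_path: Path | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise InvalidArgumentError(
                f"slide must be an RGB (H, W, 3) raster, got shape {px.shape}"
            )
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class Tile:
    row: int
    col: int
    image: np.ndarray


@dataclass
class TileGrid:
    """Non-overlapping tiles cut from a slide, with grid coordinates."""

    tiles: list[Tile]
    tile_px: int
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        coords = [(t.row, t.col) for t in self.tiles]
        if len(set(coords)) != len(coords):
            raise InvalidArgumentError("duplicate (row, col) in tile grid")

    def __len__(self) -> int:
        return len(self.tiles)

    def images(self) -> list[np.ndarray]:
        return [t.image for t in self.tiles]

    def assemble(self) -> np.ndarray:
        """Reassemble the tiles into the cropped slide region (exact inverse
        of slicing when no tiles were filtered)."""
        out = np.zeros(
            (self.n_rows * self.tile_px, self.n_cols * self.tile_px, 3), dtype=np.uint8
        )
        for t in self.tiles:
            r0, c0 = t.row * self.tile_px, t.col * self.tile_px
            out[r0 : r0 + self.tile_px, c0 : c0 + self.tile_px] = t.image
        return out


def read_slide(path: str | Path, microns_per_pixel: float = 0.44) -> SlideImage:
    """Read a TIFF/PNG slide image from disk."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"))
    except Exception as exc:  # Pillow raises several format errors
        raise InvalidArgumentError(f"cannot read image {path}: {exc}") from exc
    return SlideImage(arr, microns_per_pixel, source_path=path)


def downscale_slide(slide: SlideImage, factor: float = 0.5) -> SlideImage:
    """Downscale a slide by ``factor`` using area averaging.

    Output dimensions are ``floor(input * factor)`` and the micron-per-pixel
    value is divided by ``factor`` (e.g. a 0.22 um/px scan at factor 0.5
    becomes 0.44 um/px, approximating 10x optical sampling of a 20x scan).
    """
    if not 0.0 < factor <= 1.0:
        raise InvalidArgumentError(f"downscale factor must be in (0, 1], got {factor}")
    if factor == 1.0:
        return SlideImage(slide.pixels.copy(), slide.microns_per_pixel, slide.source_path)
    new_w = int(slide.width * factor)
    new_h = int(slide.height * factor)
    if new_w < 1 or new_h < 1:
        raise InvalidArgumentError("downscale factor collapses the slide to nothing")
    im = Image.fromarray(slide.pixels)
    # BOX resampling = area averaging
    small = np.asarray(im.resize((new_w, new_h), Image.Resampling.BOX))
    return SlideImage(small, slide.microns_per_pixel / factor, slide.source_path)


def _mean_luminance(tile: np.ndarray) -> float:
    img = tile.astype(np.float64) / 255.0
    return float((0.2126 * img[..., 0] + 0.7152 * img[..., 1] + 0.0722 * img[..., 2]).mean())


def slice_tiles(
    slide: SlideImage,
    tile_px: int = DEFAULT_TILE_PX,
    *,
    white_filter: bool = False,
    white_threshold: float = WHITENESS_THRESHOLD,
) -> TileGrid:
    """Cut a slide into a non-overlapping grid of ``tile_px`` square tiles.

    The grid is anchored at (0, 0); ``n_rows = floor(H / tile_px)`` and
    ``n_cols = floor(W / tile_px)``, remainders dropped. With
    ``white_filter=True``, tiles whose mean luminance exceeds
    ``white_threshold`` (blank glass) are removed from the grid — an optional
    optimization, off by default: non-scorable content is normally left to
    the classifier's ignore class.
    """
    if tile_px < 1:
        raise InvalidArgumentError("tile_px must be positive")
    n_rows = slide.height // tile_px
    n_cols = slide.width // tile_px
    if n_rows == 0 or n_cols == 0:
        raise EmptyGridError(
            f"slide {slide.width}x{slide.height} smaller than one {tile_px}-px tile"
        )
    tiles = []
    for r in range(n_rows):
        for c in range(n_cols):
            img = slide.pixels[
                r * tile_px : (r + 1) * tile_px, c * tile_px : (c + 1) * tile_px
            ]
            if white_filter and _mean_luminance(img) > white_threshold:
                continue
            tiles.append(Tile(r, c, img))
    return TileGrid(tiles, tile_px, n_rows, n_cols)


def write_tiles(grid: TileGrid, out_dir: str | Path) -> pd.DataFrame:
    """Write tiles as ``r{row}_c{col}.png`` plus a CSV grid index."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in grid.tiles:
        name = f"r{t.row}_c{t.col}.png"
        Image.fromarray(t.image).save(out_dir / name)
        rows.append({"row": t.row, "col": t.col, "path": name})
    index = pd.DataFrame(rows)
    index.to_csv(out_dir / "tiles.csv", index=False)
    return index
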