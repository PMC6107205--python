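"""Continuous score aggregation from per-tile class probabilities, slide-level
means, and spatial score maps.

The classifier emits, per tile, a probability vector over the score classes
plus an ignore class, e.g. ``p = (p0, p1, p3, p5, p7, p_ignore)`` for the
Ashcroft scheme. A tile enters scoring only if ``p_ignore`` is not the
strictly largest component. The remaining probabilities are renormalized to
sum to 1 without the ignore mass,

    p~_i = p_i / (p_0 + p_1 + p_3 + p_5 + p_7),

and the continuous score is the weight-weighted sum ``A = sum_i w_i * p~_i``.
A classifier undecided 50/50 between classes 1 and 3 thus scores
``0.5*1 + 0.5*3 = 2``, interpolating between the discrete classes. The slide
score is the arithmetic mean of A over all non-ignored tiles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateVectorError, InvalidArgumentError
from .schemes import ScoreScheme, get_scheme
from .tiling import TileGrid

__all__ = [
    "validate_proba",
    "is_ignored",
    "renormalize",
    "tile_score",
    "TileScore",
    "ScoreMap",
    "SlideScore",
    "score_tile_grid",
    "slide_score",
    "render_score_map",
    "write_tile_scores",
    "read_tile_scores",
]

_SUM_TOL = 1e-6


def validate_proba(p, scheme: ScoreScheme) -> np.ndarray:
    """Check a probability vector (score classes then ignore) and return it."""
    arr = np.asarray(p, dtype=float)
    if arr.shape != (scheme.n_classes,):
        raise InvalidArgumentError(
            f"expected {scheme.n_classes} components for scheme "
            f"{scheme.name!r}, got shape {arr.shape}"
        )
    if (arr < -_SUM_TOL).any():
        raise InvalidArgumentError("probabilities must be non-negative")
    if abs(arr.sum() - 1.0) > _SUM_TOL:
        raise InvalidArgumentError(f"probabilities sum to {arr.sum():.8f}, not 1")
    return arr


def is_ignored(p, scheme: ScoreScheme) -> bool:
    """True iff the ignore probability is strictly the largest component.

    A tie between the ignore mass and the best score class resolves to *not*
    ignored: the tile is scored.
    """
    arr = validate_proba(p, scheme)
    return bool(arr[-1] > arr[:-1].max())


def renormalize(p, scheme: ScoreScheme) -> np.ndarray:
    """Renormalize the score-class components to sum to 1 without the ignore mass."""
    arr = validate_proba(p, scheme)
    total = arr[:-1].sum()
    if total <= 0.0:
        raise DegenerateVectorError(
            "all score-class probabilities are zero; nothing to renormalize"
        )
    return arr[:-1] / total


@dataclass(frozen=True)
class TileScore:
    """Continuous score of one tile, or its exclusion via the ignore rule."""

    row: int
    col: int
    ignored: bool
    score: float | None

    def __post_init__(self) -> None:
        if self.ignored != (self.score is None):
            raise InvalidArgumentError("score must be None exactly when ignored")


def tile_score(p, scheme: ScoreScheme, row: int = 0, col: int = 0) -> TileScore:
    """Score one tile: ignore-gate, renormalize, weight-weighted sum."""
    if is_ignored(p, scheme):
        return TileScore(row, col, True, None)
    p_tilde = renormalize(p, scheme)
    a = float(np.dot(np.asarray(scheme.weights), p_tilde))
    return TileScore(row, col, False, a)


@dataclass
class ScoreMap:
    """Per-tile scores on the slide grid; NaN marks ignored tiles."""

    scores: np.ndarray  # float (n_rows, n_cols), NaN where ignored
    scheme: ScoreScheme
    tile_px: int | None = None

    @property
    def n_rows(self) -> int:
        return self.scores.shape[0]

    @property
    def n_cols(self) -> int:
        return self.scores.shape[1]

    def tile_scores(self) -> list[TileScore]:
        out = []
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                v = self.scores[r, c]
                ignored = bool(np.isnan(v))
                out.append(TileScore(r, c, ignored, None if ignored else float(v)))
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "row": t.row,
                "col": t.col,
                "ignored": t.ignored,
                "score": np.nan if t.score is None else round(t.score, 3),
            }
            for t in self.tile_scores()
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SlideScore:
    """Mean score over the non-ignored tiles of a slide.

    ``mean`` is ``None`` when every tile was ignored — an explicit typed
    outcome, never a silent zero.
    """

    mean: float | None
    n_scored: int
    n_ignored: int

    @property
    def all_ignored(self) -> bool:
        return self.n_scored == 0

    def to_json(self) -> str:
        return json.dumps(
            {"mean": self.mean, "n_scored": self.n_scored, "n_ignored": self.n_ignored}
        )


def score_tile_grid(classifier, grid: TileGrid, scheme: ScoreScheme | str) -> ScoreMap:
    """Run a classifier over a tile grid and assemble the score map.

    ``classifier`` is anything with ``class_names`` ending in the ignore
    label and a ``predict_proba(tiles) -> (n, k)`` method.
    """
    scheme = get_scheme(scheme) if isinstance(scheme, str) else scheme
    if tuple(classifier.class_names) != scheme.all_labels:
        raise InvalidArgumentError(
            f"classifier classes {classifier.class_names} do not match "
            f"scheme order {scheme.all_labels}"
        )
    probs = np.asarray(classifier.predict_proba(grid.images()))
    scores = np.full((grid.n_rows, grid.n_cols), np.nan)
    for tile, p in zip(grid.tiles, probs):
        ts = tile_score(p, scheme, tile.row, tile.col)
        if not ts.ignored:
            scores[tile.row, tile.col] = ts.score
    return ScoreMap(scores, scheme, grid.tile_px)


def slide_score(tile_scores) -> SlideScore:
    """Arithmetic mean score over non-ignored tiles.

    Accepts a :class:`ScoreMap` or an iterable of :class:`TileScore`.
    """
    if isinstance(tile_scores, ScoreMap):
        tile_scores = tile_scores.tile_scores()
    tile_scores = list(tile_scores)
    if not tile_scores:
        raise InvalidArgumentError("slide_score requires at least one tile")
    values = [t.score for t in tile_scores if not t.ignored]
    n_ignored = len(tile_scores) - len(values)
    if not values:
        return SlideScore(None, 0, n_ignored)
    return SlideScore(float(np.mean(values)), len(values), n_ignored)


def render_score_map(
    score_map: ScoreMap,
    out_path: str | Path | None = None,
    *,
    cmap: str = "viridis",
    ax=None,
):
    """Render a score map as one coloured cell per tile with a colourbar.

    The colour scale spans the scheme's full weight range so maps from
    different slides are comparable; ignored tiles render in neutral grey.
    Returns the matplotlib Axes; writes a PNG when ``out_path`` is given.
    """
    import matplotlib

    if out_path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if score_map.scores.size == 0:
        raise InvalidArgumentError("cannot render an empty score map")
    created = ax is None
    if created:
        _, ax = plt.subplots(figsize=(6, 5))
    cm = matplotlib.colormaps[cmap].copy()
    cm.set_bad(color="0.85")
    masked = np.ma.masked_invalid(score_map.scores)
    im = ax.imshow(
        masked,
        cmap=cm,
        vmin=score_map.scheme.min_weight,
        vmax=score_map.scheme.max_weight,
        interpolation="nearest",
    )
    ax.set_xlabel("tile column")
    ax.set_ylabel("tile row")
    label = f"{score_map.scheme.name} score"
    ax.figure.colorbar(im, ax=ax, label=label)
    if out_path is not None:
        ax.figure.savefig(out_path, dpi=150, bbox_inches="tight")
        if created:
            plt.close(ax.figure)
    return ax


def write_tile_scores(score_map: ScoreMap, path: str | Path) -> None:
    """Write the per-tile score table (3-decimal CSV)."""
    score_map.to_dataframe().to_csv(path, index=False)


def read_tile_scores(path: str | Path, scheme: ScoreScheme | str) -> ScoreMap:
    """Rebuild a :class:`ScoreMap` from a per-tile score CSV."""
    scheme = get_scheme(scheme) if isinstance(scheme, str) else scheme
    df = pd.read_csv(path)
    n_rows = int(df["row"].max()) + 1
    n_cols = int(df["col"].max()) + 1
    scores = np.full((n_rows, n_cols), np.nan)
    for _, rec in df.iterrows():
        if not bool(rec["ignored"]):
            scores[int(rec["row"]), int(rec["col"])] = float(rec["score"])
    return ScoreMap(scores, scheme)
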