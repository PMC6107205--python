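"""Score schemes: the ordered class labels, their numeric weights, and the
inflammation cell-count labelling rule.

Two schemes are supported. The Ashcroft fibrosis scheme uses the discrete
score classes 0, 1, 3, 5, 7 (the subset of the 0-8 Ashcroft scale observed in
practice in the mouse bleomycin model); the inflammation scheme uses classes
0-3 defined by the number of inflammatory cells per field of view. Both carry
an additional "ignore" class for non-alveolar content (fat, lymph nodes,
large vessels/bronchi, artifacts) that must not enter score aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InvalidArgumentError

IGNORE_LABEL = "ignore"

#: Inclusive cell-count ranges defining the inflammation classes.
INFLAMMATION_COUNT_RANGES: dict[int, tuple[int, float]] = {
    0: (0, 5),
    1: (6, 10),
    2: (11, 20),
    3: (21, float("inf")),
}


@dataclass(frozen=True)
class ScoreScheme:
    """Ordered score classes with numeric weights plus an ignore class.

    Parameters
    ----------
    name
        Scheme identifier, ``"ashcroft"`` or ``"inflammation"``.
    class_labels
        Score-class labels in increasing weight order (ignore excluded).
    weights
        Numeric weight of each score class, strictly increasing.
    ignore_label
        Label of the non-scorable class; carries no weight.
    """

    name: str
    class_labels: tuple[str, ...]
    weights: tuple[float, ...]
    ignore_label: str = IGNORE_LABEL

    def __post_init__(self) -> None:
        if len(self.class_labels) != len(self.weights):
            raise InvalidArgumentError("labels and weights must align")
        if any(b <= a for a, b in zip(self.weights, self.weights[1:])):
            raise InvalidArgumentError("weights must be strictly increasing")
        if self.ignore_label in self.class_labels:
            raise InvalidArgumentError("ignore label collides with a score class")

    @property
    def all_labels(self) -> tuple[str, ...]:
        """Score-class labels followed by the ignore label (classifier order)."""
        return self.class_labels + (self.ignore_label,)

    @property
    def n_classes(self) -> int:
        """Width of the classifier softmax head (score classes + ignore)."""
        return len(self.class_labels) + 1

    @property
    def min_weight(self) -> float:
        return self.weights[0]

    @property
    def max_weight(self) -> float:
        return self.weights[-1]

    def weight_of(self, label: str) -> float:
        return self.weights[self.class_labels.index(label)]


ASHCROFT = ScoreScheme("ashcroft", ("0", "1", "3", "5", "7"), (0.0, 1.0, 3.0, 5.0, 7.0))
INFLAMMATION = ScoreScheme("inflammation", ("0", "1", "2", "3"), (0.0, 1.0, 2.0, 3.0))

_ALIASES = {
    "ashcroft": ASHCROFT,
    "fibrosis": ASHCROFT,
    "inflammation": INFLAMMATION,
}


def get_scheme(name: str) -> ScoreScheme:
    """Look up a scheme by name; ``"fibrosis"`` aliases the Ashcroft scheme."""
    try:
        return _ALIASES[name.lower()]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown scheme {name!r}; expected one of {sorted(_ALIASES)}"
        ) from None


def cell_count_to_class(count: int) -> int:
    """Map an inflammatory-cell count per field of view to its class.

    The rule is piecewise constant: 0-5 cells -> class 0, 6-10 -> 1,
    11-20 -> 2, 21 and above -> 3.

    Raises
    ------
    InvalidArgumentError
        If ``count`` is negative or not an integer.
    """
    if isinstance(count, bool) or int(count) != count:
        raise InvalidArgumentError(f"cell count must be an integer, got {count!r}")
    count = int(count)
    if count < 0:
        raise InvalidArgumentError(f"cell count must be non-negative, got {count}")
    for cls, (lo, hi) in INFLAMMATION_COUNT_RANGES.items():
        if lo <= count <= hi:
            return cls
    raise AssertionError("count ranges cover all non-negative integers")
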