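"""Evaluation analyses: accuracy, row-normalized confusion matrices, adjacent-
error structure, CNN-vs-expert linear comparison, and the accuracy-versus-
training-set-size curve with an asymptotic fit.

These mirror the analyses used to characterize a tile classifier: the
row-normalized confusion matrix shows per-class recall and whether
misclassifications concentrate in neighbouring score classes (they should,
reflecting the inherent ordinal ambiguity of the data); the slide-level
comparison against a human expert is an ordinary least-squares fit with
bootstrap 5%/95% confidence intervals on slope and intercept; the
data-amount curve quantifies how validation accuracy saturates with the
number of labelled training tiles.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.metrics import confusion_matrix as _sk_confusion

from .classifier import TrainConfig, build_model
from .classifier import predict_proba as clf_predict
from .classifier import train as clf_train
from .dataset import LabelledDataset
from .errors import InvalidArgumentError
from .schemes import ScoreScheme


def accuracy(reference_labels, predicted_labels) -> float:
    """Fraction of exact label matches."""
    ref = list(reference_labels)
    pred = list(predicted_labels)
    if len(ref) != len(pred):
        raise InvalidArgumentError(
            f"label sequences differ in length ({len(ref)} vs {len(pred)})"
        )
    if not ref:
        raise InvalidArgumentError("empty label sequences")
    return float(np.mean([r == p for r, p in zip(ref, pred)]))


@dataclass
class ConfusionMatrix:
    """Row-normalized class-agreement table (rows: reference, cols: predicted).

    Raw counts are retained alongside the normalized probabilities; rows with
    zero support are emitted as all-zero and flagged, so matrices from
    different runs stay conformable.
    """

    classes: tuple[str, ...]
    counts: np.ndarray  # int (k, k)
    normalized: np.ndarray  # float (k, k), rows with support sum to 1
    zero_support: tuple[str, ...] = ()

    def to_dataframe(self, normalized: bool = True) -> pd.DataFrame:
        data = self.normalized if normalized else self.counts
        return pd.DataFrame(data, index=list(self.classes), columns=list(self.classes))

    def plot(self, out_path=None, ax=None):
        """Heatmap of the row-normalized matrix."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4.5))
        im = ax.imshow(self.normalized, cmap="Blues", vmin=0, vmax=1)
        k = len(self.classes)
        ax.set_xticks(range(k), self.classes)
        ax.set_yticks(range(k), self.classes)
        ax.set_xlabel("predicted")
        ax.set_ylabel("reference")
        for i in range(k):
            for j in range(k):
                ax.text(
                    j, i, f"{self.normalized[i, j]:.2f}",
                    ha="center", va="center",
                    color="white" if self.normalized[i, j] > 0.5 else "black",
                    fontsize=8,
                )
        ax.figure.colorbar(im, ax=ax)
        if out_path is not None:
            ax.figure.savefig(out_path, dpi=150, bbox_inches="tight")
        return ax


def confusion_matrix(reference_labels, predicted_labels, classes) -> ConfusionMatrix:
    """Count-based confusion matrix with row normalization.

    Entry (r, c) of the normalized matrix is
    ``count(ref=r, pred=c) / count(ref=r)``.
    """
    classes = tuple(str(c) for c in classes)
    ref = [str(x) for x in reference_labels]
    pred = [str(x) for x in predicted_labels]
    if len(ref) != len(pred):
        raise InvalidArgumentError("label sequences differ in length")
    for lab in set(ref) | set(pred):
        if lab not in classes:
            raise InvalidArgumentError(f"unknown label {lab!r}")
    counts = _sk_confusion(ref, pred, labels=list(classes))
    support = counts.sum(axis=1)
    normalized = np.zeros_like(counts, dtype=float)
    nz = support > 0
    normalized[nz] = counts[nz] / support[nz, None]
    zero = tuple(c for c, s in zip(classes, support) if s == 0)
    return ConfusionMatrix(classes, counts, normalized, zero)


#: Sentinel returned when a confusion matrix has no off-diagonal mass at all.
NO_OFF_DIAGONAL = None


def adjacent_confusion_mass(cm: ConfusionMatrix, scheme: ScoreScheme) -> float | None:
    """Fraction of misclassified mass lying in an adjacent score class.

    Restricted to the score classes (ignore excluded), ordered by weight:
    of all off-diagonal counts, the fraction with ``|rank(ref) - rank(pred)|
    == 1``. Returns the ``NO_OFF_DIAGONAL`` sentinel when the restricted
    matrix has no off-diagonal mass (nothing was misclassified).
    """
    labels = scheme.class_labels
    if len(labels) < 3:
        raise InvalidArgumentError("adjacent-error structure needs >=3 score classes")
    idx = [cm.classes.index(lab) for lab in labels]
    sub = cm.counts[np.ix_(idx, idx)].astype(float)
    off_total = sub.sum() - np.trace(sub)
    if off_total == 0:
        return NO_OFF_DIAGONAL
    adjacent = sum(sub[i, i + 1] + sub[i + 1, i] for i in range(len(labels) - 1))
    return float(adjacent / off_total)


@dataclass(frozen=True)
class ComparisonFit:
    """OLS fit of CNN slide scores against expert scores."""

    slope: float
    intercept: float
    r_squared: float
    ci_slope: tuple[float, float]
    ci_intercept: tuple[float, float]
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise InvalidArgumentError("r_squared out of [0, 1]")


def compare_to_expert(
    slide_scores_cnn,
    slide_scores_expert,
    *,
    n_bootstrap: int = 2000,
    seed: int = 0,
    ci_method: str = "bootstrap",
) -> ComparisonFit:
    """Least-squares comparison of automated vs expert slide scores.

    Fits ``cnn = m * expert + b`` by OLS and reports r² plus 5%/95%
    confidence intervals on slope and intercept — percentile bootstrap over
    paired resamples by default (``n_bootstrap`` draws, seeded), or analytic
    OLS intervals with ``ci_method="analytic"``.
    """
    y = np.asarray(slide_scores_cnn, dtype=float)
    x = np.asarray(slide_scores_expert, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("paired 1-d score arrays required")
    n = len(x)
    if n < 3:
        raise InvalidArgumentError("need at least 3 paired scores")
    if np.ptp(x) == 0:
        raise InvalidArgumentError("expert scores have zero variance")
    fit = stats.linregress(x, y)
    if ci_method == "analytic":
        # 5%/95% two-sided interval from the t distribution
        tcrit = stats.t.ppf(0.95, n - 2)
        ci_m = (fit.slope - tcrit * fit.stderr, fit.slope + tcrit * fit.stderr)
        ci_b = (
            fit.intercept - tcrit * fit.intercept_stderr,
            fit.intercept + tcrit * fit.intercept_stderr,
        )
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        slopes = np.empty(n_bootstrap)
        intercepts = np.empty(n_bootstrap)
        for i in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            xb, yb = x[idx], y[idx]
            if np.ptp(xb) == 0:  # degenerate resample; redraw deterministic-ally
                slopes[i], intercepts[i] = fit.slope, fit.intercept
                continue
            m, b = np.polyfit(xb, yb, 1)
            slopes[i], intercepts[i] = m, b
        ci_m = tuple(np.quantile(slopes, [0.05, 0.95]))
        ci_b = tuple(np.quantile(intercepts, [0.05, 0.95]))
    else:
        raise InvalidArgumentError(f"unknown ci_method {ci_method!r}")
    return ComparisonFit(
        float(fit.slope),
        float(fit.intercept),
        float(fit.rvalue**2),
        (float(ci_m[0]), float(ci_m[1])),
        (float(ci_b[0]), float(ci_b[1])),
        n,
    )


# -- accuracy vs training-set size -----------------------------------------

def saturation_michaelis(n, a_inf, k):
    """Michaelis-Menten-like saturation: A(n) = A_inf * n / (n + k)."""
    return a_inf * n / (n + k)


def saturation_exponential(n, a_inf, tau):
    """Exponential saturation: A(n) = A_inf * (1 - exp(-n / tau))."""
    return a_inf * (1.0 - np.exp(-n / tau))


_FORMS = {"michaelis": saturation_michaelis, "exponential": saturation_exponential}


@dataclass
class DataAmountCurve:
    """Validation accuracy as a function of the training-set size."""

    sizes: np.ndarray
    accuracies: np.ndarray  # mean over replicate seeds, aligned with sizes
    a_max: float  # accuracy at the largest size
    fit_params: tuple[float, float]  # (A_inf, k) of the asymptotic form
    form: str = "michaelis"
    per_seed: np.ndarray | None = None  # (n_sizes, n_seeds)

    @property
    def relative(self) -> np.ndarray:
        """A(n) / A_max."""
        return self.accuracies / self.a_max

    def predict(self, n) -> np.ndarray:
        return _FORMS[self.form](np.asarray(n, dtype=float), *self.fit_params)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n": self.sizes,
                "accuracy": self.accuracies,
                "relative_accuracy": self.relative,
                "fitted": self.predict(self.sizes),
            }
        )


def fit_saturation(sizes, accuracies, form: str = "michaelis") -> tuple[float, float]:
    """Fit the chosen asymptotic form to (n, A(n)) points."""
    if form not in _FORMS:
        raise InvalidArgumentError(f"unknown asymptotic form {form!r}")
    n = np.asarray(sizes, dtype=float)
    a = np.asarray(accuracies, dtype=float)
    if len(n) < 2:
        raise InvalidArgumentError("need at least two points to fit")
    p0 = (max(a.max(), 1e-6), max(n.min(), 1.0))
    popt, _ = optimize.curve_fit(_FORMS[form], n, a, p0=p0, maxfev=20000)
    return float(popt[0]), float(popt[1])


def accuracy_vs_training_size(
    dataset: LabelledDataset,
    sizes,
    train_config: TrainConfig,
    seeds=(0, 1, 2),
    *,
    backend: str = "small_cnn",
    input_px: int = 32,
    form: str = "michaelis",
) -> DataAmountCurve:
    """Measure validation accuracy for nested random training subsets.

    For each ``n`` in ``sizes`` and each replicate seed, ``n`` items are
    sampled without replacement from the training partition, a fresh model is
    trained at matched effort (the same ``train_config``), and accuracy is
    measured on the one shared validation partition. Replicates are averaged
    per ``n`` and the asymptotic form is fitted to the averaged points.
    """
    sizes = sorted(int(s) for s in sizes)
    n_train = len(dataset.train_idx)
    if sizes[-1] > n_train:
        raise InvalidArgumentError(
            f"requested subset size {sizes[-1]} exceeds training size {n_train}"
        )
    from .classifier import predict_proba as _predict  # local alias for clarity

    val_items = dataset.val_items
    val_images = None
    per_seed = np.empty((len(sizes), len(seeds)))
    for si, n in enumerate(sizes):
        for ki, seed in enumerate(seeds):
            rng = np.random.default_rng([train_config.seed, n, seed])
            pick = rng.choice(n_train, size=n, replace=False)
            sub = LabelledDataset(
                dataset.items,
                dataset.class_names,
                [dataset.train_idx[i] for i in pick],
                list(dataset.val_idx),
            )
            model = build_model(
                backend, dataset.class_names, seed=int(seed), input_px=input_px
            )
            cfg = replace(train_config, seed=int(seed))
            model, _curve = clf_train(model, sub, cfg)
            if val_images is None:
                from .classifier import _load_image

                val_images = [_load_image(it.path) for it in val_items]
            probs = clf_predict(model, val_images)
            pred = [dataset.class_names[i] for i in probs.argmax(axis=1)]
            per_seed[si, ki] = accuracy([it.label for it in val_items], pred)
    accs = per_seed.mean(axis=1)
    params = fit_saturation(sizes, accs, form)
    return DataAmountCurve(
        np.asarray(sizes, dtype=float), accs, float(accs[-1]), params, form, per_seed
    )
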