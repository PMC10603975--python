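"""Confusion-matrix metrics, aggregation, overlays, and report tables.

All six scores derive from pixel tallies against the ground truth:

    Dice        = 2 TP / (2 TP + FP + FN)
    Accuracy    = (TP + TN) / (TP + FP + TN + FN)
    Sensitivity = TP / (TP + FN)
    Specificity = TN / (TN + FP)
    Precision   = TP / (TP + FP)
    F1          = 2 * Precision * Sensitivity / (Precision + Sensitivity)

From a single set of counts, F1 and Dice are algebraically identical; they
can differ only when computed under different aggregations (e.g. a median
of per-image Dice values vs an F1 from pooled counts), which is why
:func:`aggregate` and :func:`pooled_metrics` are both provided and reports
label which route produced each number.

Undefined ratios (an empty ground truth or an empty prediction makes a
denominator zero) are reported as NaN with the affected metric named in
``MetricSet.undefined`` — silent 0/1 conventions would corrupt medians on
small datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import BinaryMask, GrayscaleImage

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "confusion",
    "metrics",
    "pooled_metrics",
    "aggregate",
    "overlay",
    "results_table",
    "methods_table",
    "PALETTES",
]

METRIC_NAMES = ("dice", "accuracy", "sensitivity", "specificity", "precision", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN pixel tallies; they always partition the frame."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


@dataclass(frozen=True)
class MetricSet:
    """The six scores; undefined entries are NaN and listed by name."""

    dice: float
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    undefined: tuple[str, ...] = ()

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def confusion(pred: BinaryMask, gt: BinaryMask) -> ConfusionCounts:
    """Pixelwise confusion tallies of a prediction against ground truth."""
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    p = pred.labels.astype(bool)
    g = gt.labels.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & g)),
        fp=int(np.count_nonzero(p & ~g)),
        tn=int(np.count_nonzero(~p & ~g)),
        fn=int(np.count_nonzero(~p & g)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def metrics(c: ConfusionCounts) -> MetricSet:
    """Evaluate the six closed forms on one set of counts."""
    dice = _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)
    accuracy = _ratio(c.tp + c.tn, c.total)
    sensitivity = _ratio(c.tp, c.tp + c.fn)
    specificity = _ratio(c.tn, c.tn + c.fp)
    precision = _ratio(c.tp, c.tp + c.fp)
    if math.isnan(precision) or math.isnan(sensitivity) or precision + sensitivity == 0:
        f1 = math.nan
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    vals = dict(
        dice=dice, accuracy=accuracy, sensitivity=sensitivity,
        specificity=specificity, precision=precision, f1=f1,
    )
    undefined = tuple(k for k, v in vals.items() if math.isnan(v))
    return MetricSet(**vals, undefined=undefined)


def pooled_metrics(counts: list[ConfusionCounts]) -> MetricSet:
    """Metrics from counts pooled over images (micro-average).  From pooled
    counts F1 equals Dice exactly; contrast with :func:`aggregate`."""
    if not counts:
        raise ValueError("no counts to pool")
    total = counts[0]
    for c in counts[1:]:
        total = total + c
    return metrics(total)


def aggregate(per_image: list[MetricSet], method: str = "median") -> MetricSet:
    """Componentwise median (default) or mean over per-image metric sets.

    NaN (undefined) entries are excluded per component; components whose
    values were all NaN stay NaN and are listed in ``undefined`` together
    with per-metric exclusion counts encoded as ``"name:n_excluded"``.
    """
    if not per_image:
        raise ValueError("nothing to aggregate")
    if method not in ("median", "mean"):
        raise ValueError(f"method must be 'median' or 'mean', got {method!r}")
    reducer = np.nanmedian if method == "median" else np.nanmean
    vals: dict[str, float] = {}
    notes: list[str] = []
    for name in METRIC_NAMES:
        col = np.array([getattr(m, name) for m in per_image], dtype=float)
        n_bad = int(np.isnan(col).sum())
        if n_bad == len(col):
            vals[name] = math.nan
            notes.append(name)
        else:
            vals[name] = float(reducer(col))
            if n_bad:
                notes.append(f"{name}:{n_bad}")
    return MetricSet(**vals, undefined=tuple(notes))


#: FP/FN accent palettes (RGB).  "pink-green" is the default overlay
#: description; "purple-cyan" matches the qualitative figure captions.
PALETTES: dict[str, dict[str, tuple[int, int, int]]] = {
    "pink-green": {"fp": (255, 182, 193), "fn": (144, 238, 144)},
    "purple-cyan": {"fp": (160, 32, 240), "fn": (0, 255, 255)},
}


def overlay(
    gt: BinaryMask,
    pred: BinaryMask,
    img: GrayscaleImage | None = None,
    palette: str = "pink-green",
) -> np.ndarray:
    """Render an RGB error overlay: TP white, TN black (or the dimmed
    source image when ``img`` is given), FP/FN in the accent colors."""
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: gt {gt.shape} vs pred {pred.shape}")
    colors = PALETTES[palette] if isinstance(palette, str) else palette
    g = gt.labels.astype(bool)
    p = pred.labels.astype(bool)
    h, w = g.shape
    if img is not None:
        if img.shape != g.shape:
            raise ValueError("image shape does not match masks")
        base = (img.pixels * 0.5 * 255).astype(np.uint8)
        out = np.stack([base] * 3, axis=-1)
    else:
        out = np.zeros((h, w, 3), dtype=np.uint8)
    out[p & g] = (255, 255, 255)
    out[p & ~g] = colors["fp"]
    out[~p & g] = colors["fn"]
    return out


def results_table(
    fold_results,
    aggregation: str = "median",
) -> pd.DataFrame:
    """Architecture x strategy grid of aggregated Dice scores.

    One row per architecture/ablation preset, one column per augmentation
    strategy; a companion boolean ``<strategy>__best`` column marks the
    row maximum (all tied cells flagged).
    """
    rows: dict[str, dict[str, list[MetricSet]]] = {}
    for r in fold_results:
        arch = r.launch.architecture
        strat = r.launch.strategy
        rows.setdefault(arch, {}).setdefault(strat, []).append(r.scores)
    if not rows:
        raise ValueError("no fold results to tabulate")
    strategies = sorted({s for by in rows.values() for s in by})
    data = {}
    for arch, by in rows.items():
        data[arch] = {
            s: aggregate(by[s], aggregation).dice if s in by else math.nan
            for s in strategies
        }
    table = pd.DataFrame.from_dict(data, orient="index", columns=strategies)
    best = table.apply(lambda row: row == row.max(), axis=1)
    for s in strategies:
        table[f"{s}__best"] = best[s]
    return table


_METHOD_ROWS = ("Dice", "F1-score", "Sensitivity", "Specificity", "Accuracy")


def methods_table(
    per_method: dict[str, list[MetricSet]],
    aggregation: str = "median",
) -> pd.DataFrame:
    """Methods-comparison table: five metric rows (Dice, F1-score,
    Sensitivity, Specificity, Accuracy), one column per segmentation
    method, values aggregated per image."""
    if not per_method:
        raise ValueError("no results to tabulate")
    cols = {}
    for name, sets in per_method.items():
        agg = aggregate(sets, aggregation)
        cols[name] = {
            "Dice": agg.dice,
            "F1-score": agg.f1,
            "Sensitivity": agg.sensitivity,
            "Specificity": agg.specificity,
            "Accuracy": agg.accuracy,
        }
    return pd.DataFrame(cols).reindex(list(_METHOD_ROWS))
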