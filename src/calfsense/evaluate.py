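"""Evaluation mathematics for the behavior classifiers.

Per-class metrics come from one-vs-rest confusion counts:

.. math::

    \\mathrm{Acc} = \\frac{TP+TN}{TP+TN+FP+FN},\\quad
    \\mathrm{TPR} = \\frac{TP}{TP+FN},\\quad
    \\mathrm{TNR} = \\frac{TN}{TN+FP},

.. math::

    \\mathrm{PPV} = \\frac{TP}{TP+FP},\\quad
    F_1 = \\frac{2\\,\\mathrm{PPV}\\cdot\\mathrm{TPR}}
                 {\\mathrm{PPV}+\\mathrm{TPR}}.

The "overall" row is the unweighted macro average across classes; metrics
with a zero denominator are undefined and excluded from the macro (logged).
ROC/AUC uses a full threshold sweep with trapezoid integration, which for
tie-free scores equals the Mann–Whitney pairwise-concordance statistic.

Field validation converts window predictions into daily behavior time
budgets (10 s per predicted window) and compares them with the observed
annotation time via Pearson's r; inter-observer agreement of the video
annotation itself is quantified by Cohen's kappa,
K = (P0 - Pc) / (1 - Pc).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from .core import AnnotationTrack
from .errors import ShapeError, VocabularyError

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "tpr", "tnr", "ppv", "f1")
OVERALL_ROW = "overall"
SECONDS_PER_DAY = 86_400.0


@dataclass
class ConfusionMatrix:
    """Actual-by-predicted count grid with one-vs-rest derived counts."""

    classes: tuple[str, ...]
    grid: np.ndarray  # grid[i, j] = count(actual=classes[i], predicted=classes[j])

    @property
    def total(self) -> int:
        return int(self.grid.sum())

    def one_vs_rest(self, cls: str) -> tuple[int, int, int, int]:
        """(TP, TN, FP, FN) counts for one class against the rest."""
        i = self.classes.index(cls)
        tp = int(self.grid[i, i])
        fn = int(self.grid[i].sum() - tp)
        fp = int(self.grid[:, i].sum() - tp)
        tn = self.total - tp - fn - fp
        return tp, tn, fp, fn

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.grid, index=self.classes, columns=self.classes)


def confusion(actual, predicted, classes: tuple[str, ...]) -> ConfusionMatrix:
    actual = np.asarray(actual, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    if actual.shape != predicted.shape or actual.size == 0:
        raise ShapeError("actual/predicted must be equal-length and non-empty")
    index = {c: i for i, c in enumerate(classes)}
    grid = np.zeros((len(classes), len(classes)), dtype=int)
    for a, p in zip(actual, predicted):
        if a not in index or p not in index:
            raise VocabularyError(f"label outside class list: {a!r}/{p!r}")
        grid[index[a], index[p]] += 1
    return ConfusionMatrix(tuple(classes), grid)


def harmonic_f1(ppv: float, tpr: float) -> float:
    """F1 = 2*PPV*TPR/(PPV+TPR); works on fractions or percentages."""
    if ppv + tpr == 0:
        return 0.0
    return 2.0 * ppv * tpr / (ppv + tpr)


def class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class metric table (values in [0, 1]) plus the macro 'overall' row.

    Undefined cells (zero denominator) are NaN and skipped by the macro.
    """
    rows = {}
    for cls in cm.classes:
        tp, tn, fp, fn = cm.one_vs_rest(cls)
        def ratio(num, den):
            if den == 0:
                logger.info("undefined metric for class %r (zero denominator)", cls)
                return np.nan
            return num / den
        acc = ratio(tp + tn, tp + tn + fp + fn)
        tpr = ratio(tp, tp + fn)
        tnr = ratio(tn, tn + fp)
        ppv = ratio(tp, tp + fp)
        f1 = harmonic_f1(ppv, tpr) if not (np.isnan(ppv) or np.isnan(tpr)) else np.nan
        rows[cls] = {"accuracy": acc, "tpr": tpr, "tnr": tnr, "ppv": ppv, "f1": f1}
    table = pd.DataFrame.from_dict(rows, orient="index")[list(METRIC_NAMES)]
    table.loc[OVERALL_ROW] = table.mean(axis=0, skipna=True)
    return table


def metrics_percent(table: pd.DataFrame) -> pd.DataFrame:
    """Metric table rescaled to percentages, rounded to 2 decimals."""
    return (table * 100).round(2)


@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(actual, scores, positive_label) -> RocResult:
    """ROC threshold sweep and trapezoid AUC for one positive class."""
    actual = np.asarray(actual, dtype=object)
    scores = np.asarray(scores, float)
    y = actual == positive_label
    if y.all() or not y.any():
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thresholds = roc_curve(y.astype(int), scores)
    return RocResult(thresholds, fpr, tpr, float(_trapezoid_auc(fpr, tpr)))


def time_budget(
    predictions: pd.DataFrame,
    track: AnnotationTrack,
    tier: str,
    window_s: float = 10.0,
) -> pd.DataFrame:
    """Daily per-behavior seconds, predicted (10 s per window) vs observed.

    ``predictions`` needs columns calf_id, start_s, predicted and must use
    non-overlapping windows, else 10 s-per-window double-counts time.
    Rows are (calf_id, day, behavior, predicted_s, observed_s).
    """
    starts = np.sort(predictions["start_s"].to_numpy(float))
    if len(starts) > 1 and np.any(np.diff(starts) < window_s - 1e-9):
        raise ValueError("time_budget requires non-overlapping prediction windows")
    pred = predictions.copy()
    pred["day"] = (pred["start_s"] // SECONDS_PER_DAY).astype(int)
    agg = (
        pred.groupby(["calf_id", "day", "predicted"], as_index=False)
        .size()
        .rename(columns={"predicted": "behavior", "size": "windows"})
    )
    agg["predicted_s"] = agg["windows"] * window_s

    observed: dict[tuple[str, int, str], float] = {}
    for iv in track.tier_intervals(tier):
        d0 = int(iv.start_s // SECONDS_PER_DAY)
        d1 = int(np.ceil(iv.end_s / SECONDS_PER_DAY))
        for day in range(d0, max(d1, d0 + 1)):
            lo, hi = day * SECONDS_PER_DAY, (day + 1) * SECONDS_PER_DAY
            ov = max(0.0, min(iv.end_s, hi) - max(iv.start_s, lo))
            if ov > 0:
                key = (track.calf_id, day, iv.behavior)
                observed[key] = observed.get(key, 0.0) + ov

    keys = {(r.calf_id, r.day, r.behavior) for r in agg.itertuples()} | set(observed)
    rows = []
    pred_map = {
        (r.calf_id, r.day, r.behavior): r.predicted_s for r in agg.itertuples()
    }
    for calf_id, day, behavior in sorted(keys):
        rows.append(
            {
                "calf_id": calf_id,
                "day": day,
                "behavior": behavior,
                "predicted_s": pred_map.get((calf_id, day, behavior), 0.0),
                "observed_s": observed.get((calf_id, day, behavior), 0.0),
            }
        )
    return pd.DataFrame(rows)


def pearson_r(x, y) -> float:
    """Product-moment correlation; errors on constant input."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise ShapeError("pearson_r needs equal-length series of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant series")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class KappaResult:
    kappa: float
    p0: float
    pc: float
    table: np.ndarray


def cohens_kappa(obs1, obs2, categories: tuple[str, ...] | None = None) -> KappaResult:
    """Chance-corrected agreement K = (P0 - Pc) / (1 - Pc) between two
    aligned categorical label sequences."""
    obs1 = np.asarray(obs1, dtype=object)
    obs2 = np.asarray(obs2, dtype=object)
    if obs1.shape != obs2.shape or obs1.size == 0:
        raise ShapeError("observer sequences must be equal-length and non-empty")
    if categories is None:
        categories = tuple(sorted(set(obs1) | set(obs2)))
    return kappa_from_table(confusion(obs1, obs2, categories).grid)


def kappa_from_table(table: np.ndarray) -> KappaResult:
    """Kappa from an agreement contingency table (observer1 x observer2)."""
    table = np.asarray(table, float)
    n = table.sum()
    if n == 0:
        raise ShapeError("empty contingency table")
    p0 = float(np.trace(table) / n)
    pc = float((table.sum(axis=1) / n) @ (table.sum(axis=0) / n))
    if pc >= 1.0:
        raise ValueError("kappa undefined: chance agreement Pc = 1")
    return KappaResult((p0 - pc) / (1.0 - pc), p0, pc, table.astype(int))


def align_tracks(
    track1: AnnotationTrack,
    track2: AnnotationTrack,
    tier: str = "state",
    bin_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Bin two observers' interval tracks onto a common 1 s lattice.

    Only bins covered by both tracks enter the comparison; an empty
    intersection is an alignment error.
    """
    from .errors import AlignmentError

    if track1.calf_id != track2.calf_id:
        raise AlignmentError(
            f"tracks for different calves: {track1.calf_id} vs {track2.calf_id}"
        )

    def labels_on(track: AnnotationTrack, grid: np.ndarray) -> np.ndarray:
        out = np.full(len(grid), None, dtype=object)
        for iv in track.tier_intervals(tier):
            mask = (grid >= iv.start_s) & (grid + bin_s <= iv.end_s + 1e-9)
            out[mask] = iv.behavior
        return out

    end = max(
        [iv.end_s for iv in track1.tier_intervals(tier)]
        + [iv.end_s for iv in track2.tier_intervals(tier)],
        default=0.0,
    )
    grid = np.arange(0.0, end, bin_s)
    l1, l2 = labels_on(track1, grid), labels_on(track2, grid)
    both = (l1 != None) & (l2 != None)  # noqa: E711
    if not both.any():
        raise AlignmentError("tracks share no covered time on this tier")
    return l1[both], l2[both]
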