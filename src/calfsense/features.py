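"""Window features and feature selection.

Per window and channel the pipeline computes twelve statistics spanning the
time and frequency domains:

====================  =====================================================
``mean/var/sd``       location and movement-intensity (posture separation)
``min/max/iqr``       range and interquartile spread (chewing amplitude)
``zero_crossings``    sign changes of the mean-centered signal (chew rate)
``dom_freq/power``    DFT bin (DC excluded) with maximal power (periodicity
                      of nodding and chewing)
``grad_*``            forward-difference gradient statistics (sharp cough
                      transients)
====================  =====================================================

Feature names follow ``<channel>_<statistic>`` over the eight channels
(ax, ay, az, gx, gy, gz, am, gm). The full grid is computed for every model
table; correlation and tree-importance filters then shrink it.

Conventions: variance/SD are population (ddof 0); quartiles use linear
interpolation between order statistics; the DFT is taken on the
mean-removed series and only bins 1..floor(N/2) compete for dominance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .core import ALL_CHANNELS
from .errors import ShapeError
from .windowing import EventWindow, Window

STATISTICS = (
    "mean",
    "var",
    "sd",
    "min",
    "max",
    "iqr",
    "zero_crossings",
    "dom_freq",
    "dom_power",
    "grad_mean_abs",
    "grad_max_abs",
    "grad_sd",
)

META_COLUMNS = ("calf_id", "start_s", "action_label", "state_label", "event_label")


# ---------------------------------------------------------------------------
# Single-series operations


def dominant_frequency(x: np.ndarray, fs: float) -> tuple[float, float]:
    """Frequency (Hz) and power of the strongest non-DC DFT bin.

    The series mean is removed first; bins 1..floor(N/2) compete. A constant
    series has an empty spectrum and returns (0, 0) by convention.
    """
    x = np.asarray(x, float)
    if x.size < 2:
        raise ValueError("dominant_frequency needs at least 2 samples")
    freq, power = _batch_dominant_frequency(x[None, :], fs)
    return float(freq[0]), float(power[0])


def iqr(x: np.ndarray) -> float:
    """Interquartile range Q3 - Q1 (linear-interpolation quantiles)."""
    x = np.asarray(x, float)
    if x.size == 0:
        raise ValueError("iqr of empty series")
    q1, q3 = np.percentile(x, [25, 75])
    return float(q3 - q1)


def zero_crossings(x: np.ndarray) -> int:
    """Sign changes of the mean-centered series.

    Exact zeros inherit the previous nonzero sign, so a touch of the axis
    without a crossing is not counted.
    """
    x = np.asarray(x, float)
    if x.size < 2:
        raise ValueError("zero_crossings needs at least 2 samples")
    return int(_batch_zero_crossings((x - x.mean())[None, :])[0])


def gradient_series(x: np.ndarray, dt: float) -> np.ndarray:
    """Forward differences (x[n+1] - x[n]) / dt, length N-1."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    x = np.asarray(x, float)
    if x.size < 2:
        raise ValueError("gradient_series needs at least 2 samples")
    return np.diff(x) / dt


# ---------------------------------------------------------------------------
# Vectorized batch implementations (axis 1 = time)


def _batch_dominant_frequency(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    n = x.shape[1]
    centered = x - x.mean(axis=1, keepdims=True)
    spec = np.fft.rfft(centered, axis=1)
    power = np.abs(spec) ** 2
    kmax = n // 2
    band = power[:, 1 : kmax + 1]
    if band.shape[1] == 0:
        return np.zeros(x.shape[0]), np.zeros(x.shape[0])
    k = np.argmax(band, axis=1) + 1
    pk = np.take_along_axis(band, (k - 1)[:, None], axis=1)[:, 0]
    freq = k * fs / n
    # all-zero spectrum (constant series) -> (0, 0)
    silent = pk <= 0
    freq = np.where(silent, 0.0, freq)
    pk = np.where(silent, 0.0, pk)
    return freq, pk


def _batch_zero_crossings(centered: np.ndarray) -> np.ndarray:
    s = np.sign(centered)
    # forward-fill zeros with the previous nonzero sign
    idx = np.where(s != 0, np.arange(s.shape[1])[None, :], -1)
    idx = np.maximum.accumulate(idx, axis=1)
    filled = np.where(
        idx >= 0, np.take_along_axis(s, np.maximum(idx, 0), axis=1), 0.0
    )
    return np.sum(filled[:, :-1] * filled[:, 1:] < 0, axis=1)


def _feature_block(x: np.ndarray, fs: float) -> dict[str, np.ndarray]:
    """All twelve statistics for a (n_windows, window_len) block."""
    dt = 1.0 / fs
    grad = np.diff(x, axis=1) / dt
    q1, q3 = np.percentile(x, [25, 75], axis=1)
    dom_freq, dom_power = _batch_dominant_frequency(x, fs)
    return {
        "mean": x.mean(axis=1),
        "var": x.var(axis=1),
        "sd": x.std(axis=1),
        "min": x.min(axis=1),
        "max": x.max(axis=1),
        "iqr": q3 - q1,
        "zero_crossings": _batch_zero_crossings(
            x - x.mean(axis=1, keepdims=True)
        ).astype(float),
        "dom_freq": dom_freq,
        "dom_power": dom_power,
        "grad_mean_abs": np.abs(grad).mean(axis=1),
        "grad_max_abs": np.abs(grad).max(axis=1),
        "grad_sd": grad.std(axis=1),
    }


def feature_names() -> list[str]:
    return [f"{c}_{s}" for c in ALL_CHANNELS for s in STATISTICS]


def extract_features(
    windows: list[Window] | list[EventWindow],
    model_tag: str,
    fs: float,
) -> pd.DataFrame:
    """One feature row per window: identity and label columns, then the
    full statistic-by-channel grid.

    ``model_tag`` selects which label column is the classification target
    downstream (``model1`` -> action, ``model2`` -> state, ``model3`` ->
    event); features are identical across tags.
    """
    if not windows:
        raise ValueError("no windows to featurize")
    lengths = {w.signals.shape[0] for w in windows}
    if len(lengths) != 1:
        raise ShapeError(f"non-uniform window lengths: {sorted(lengths)}")
    stack = np.stack([w.signals for w in windows])  # (n, L, 8)

    meta: dict[str, list] = {"calf_id": [], "start_s": []}
    is_event = isinstance(windows[0], EventWindow)
    if is_event:
        meta["event_label"] = []
        meta["peak_value"] = []
        for w in windows:
            meta["calf_id"].append(w.calf_id)
            meta["start_s"].append(w.peak_s)
            meta["event_label"].append(w.label)
            meta["peak_value"].append(w.peak_value)
    else:
        meta["action_label"] = []
        meta["state_label"] = []
        for w in windows:
            meta["calf_id"].append(w.calf_id)
            meta["start_s"].append(w.start_s)
            meta["action_label"].append(w.action_label)
            meta["state_label"].append(w.state_label)

    cols: dict[str, np.ndarray] = {}
    for ci, channel in enumerate(ALL_CHANNELS):
        block = _feature_block(stack[:, :, ci], fs)
        for stat in STATISTICS:
            cols[f"{channel}_{stat}"] = block[stat]

    df = pd.DataFrame({**meta, **cols})
    df.attrs["model_tag"] = model_tag
    return df


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Feature (non-meta) columns of a feature table, in column order."""
    meta = set(META_COLUMNS) | {"peak_value"}
    return [c for c in table.columns if c not in meta]


LABEL_COLUMN = {"model1": "action_label", "model2": "state_label", "model3": "event_label"}


# ---------------------------------------------------------------------------
# Feature selection


@dataclass
class SelectionReport:
    """Audit trail of a selection pass; surviving + dropped = original."""

    surviving: list[str]
    dropped_correlated: list[tuple[str, str, float]] = field(default_factory=list)
    dropped_low_importance: list[tuple[str, float]] = field(default_factory=list)
    importances: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "surviving": self.surviving,
            "dropped_correlated": [
                {"kept": k, "dropped": d, "abs_r": r}
                for k, d, r in self.dropped_correlated
            ],
            "dropped_low_importance": [
                {"feature": f, "importance": v} for f, v in self.dropped_low_importance
            ],
            "importances": self.importances,
        }


def drop_correlated(
    table: pd.DataFrame, threshold: float = 0.9
) -> tuple[pd.DataFrame, SelectionReport]:
    """Greedy correlation filter in fixed column order.

    A feature is dropped when its |Pearson r| with an already-kept feature
    reaches the threshold. Constant features are dropped outright; the
    correlation of any feature with a zero-variance one is defined as 0.
    """
    feats = feature_columns(table)
    if len(table) < 2:
        raise ValueError("correlation filter needs at least 2 rows")
    X = table[feats].to_numpy(float)
    sd = X.std(axis=0)
    kept: list[int] = []
    report = SelectionReport(surviving=[])
    with np.errstate(invalid="ignore", divide="ignore"):
        Xc = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    for j, name in enumerate(feats):
        if sd[j] == 0:
            report.dropped_correlated.append((name, name, 0.0))
            continue
        clash = None
        for i in kept:
            r = abs(float(Xc[:, i] @ Xc[:, j]) / len(X)) if sd[i] > 0 else 0.0
            if r >= threshold:
                clash = (feats[i], name, r)
                break
        if clash is None:
            kept.append(j)
        else:
            report.dropped_correlated.append(clash)
    report.surviving = [feats[i] for i in kept]
    meta = [c for c in table.columns if c not in feats]
    return table[meta + report.surviving].copy(), report


def select_by_importance(
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    min_importance: float | None = None,
    top_k: int | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, SelectionReport]:
    """Rank features by decision-tree impurity importance and drop the tail.

    Default policy drops features with exactly zero importance; ``top_k``
    keeps the k best instead; ``min_importance`` sets an explicit floor.
    """
    feats = feature_columns(table)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("importance selection needs at least 2 classes")
    if top_k is not None and top_k > len(feats):
        raise ValueError(f"top_k={top_k} exceeds {len(feats)} features")
    tree = DecisionTreeClassifier(random_state=seed)
    tree.fit(table[feats].to_numpy(float), y)
    imp = tree.feature_importances_
    ranked = sorted(zip(feats, imp), key=lambda p: (-p[1], feats.index(p[0])))
    if top_k is not None:
        keep = {f for f, _ in ranked[:top_k]}
    else:
        floor = min_importance if min_importance is not None else 0.0
        keep = {f for f, v in zip(feats, imp) if v > floor}
        if not keep:  # degenerate tree: keep the best feature
            keep = {ranked[0][0]}
    report = SelectionReport(
        surviving=[f for f in feats if f in keep],
        dropped_low_importance=[
            (f, float(v)) for f, v in zip(feats, imp) if f not in keep
        ],
        importances={f: float(v) for f, v in zip(feats, imp)},
    )
    meta = [c for c in table.columns if c not in feats]
    return table[meta + report.surviving].copy(), report
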