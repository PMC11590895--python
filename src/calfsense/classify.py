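"""The three gradient-boosted behavior classifiers.

* Model 1 — four-class action model (natural suckling, rumination, feeding,
  others) on 10 s analysis windows.
* Model 2 — two-class posture model (lying, standing) on the same windows.
* Model 3 — two-class cough model on peak-anchored 31-sample event windows,
  with minority oversampling (SMOTE) because coughs are rare.

Splitting is individual-wise: whole calves go to train or test, never rows,
so reported performance reflects generalization to unseen animals. Within
the training calves an 8:2 row-level split provides the validation set used
for early stopping and tuning.

All randomness is seeded and LightGBM runs single-threaded deterministic,
so splits, oversampling, training, tuning and prediction are reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import lightgbm as lgb
import numpy as np
import pandas as pd
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .errors import ShapeError
from .features import LABEL_COLUMN, feature_columns

logger = logging.getLogger(__name__)

DEFAULT_PARAMS = {
    "learning_rate": 0.1,
    "n_estimators": 300,
    "max_depth": -1,
    "num_leaves": 31,
    "min_child_samples": 10,
}

EARLY_STOPPING_ROUNDS = 50


@dataclass(frozen=True)
class SplitPlan:
    """Individual-wise train/test assignment plus row-level validation rows."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    val_fraction: float
    seed: int
    val_rows: tuple[int, ...]  # positional indices into the source table

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test calf sets overlap")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")


def split_by_individual(
    table: pd.DataFrame, n_test: int, val_fraction: float = 0.2, seed: int = 0
) -> SplitPlan:
    """Assign whole calves to test; hold out validation rows within train."""
    ids = sorted(table["calf_id"].astype(str).unique())
    if not 1 <= n_test < len(ids):
        raise ValueError(f"n_test must be in [1, {len(ids) - 1}]")
    rng = np.random.default_rng(seed)
    test_ids = tuple(sorted(rng.choice(ids, size=n_test, replace=False)))
    train_ids = tuple(i for i in ids if i not in test_ids)
    train_pos = np.flatnonzero(table["calf_id"].astype(str).isin(train_ids).to_numpy())
    n_val = int(round(val_fraction * len(train_pos)))
    val_rows = tuple(
        int(i) for i in sorted(rng.choice(train_pos, size=n_val, replace=False))
    )
    return SplitPlan(train_ids, test_ids, val_fraction, seed, val_rows)


def apply_split(
    table: pd.DataFrame, plan: SplitPlan
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Materialize (train, validation, test) row subsets of a feature table."""
    ids = table["calf_id"].astype(str)
    test = table[ids.isin(plan.test_ids)]
    val_mask = np.zeros(len(table), dtype=bool)
    val_mask[list(plan.val_rows)] = True
    train = table[ids.isin(plan.train_ids).to_numpy() & ~val_mask]
    val = table[val_mask]
    return train, val, test


def oversample_minority(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    k_neighbors: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE: balance a binary problem by interpolated minority synthesis.

    Each synthetic row lies on the segment between a minority row and one
    of its ``k_neighbors`` nearest minority neighbors (uniform interpolation
    factor). Majority rows and the original minority rows are untouched;
    synthesis continues until the classes are equal-sized.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("oversample_minority requires binary labels")
    if counts[0] == counts[1]:
        return X.copy(), y.copy()
    minority = classes[np.argmin(counts)]
    n_needed = int(abs(counts[0] - counts[1]))
    Xm = X[y == minority]
    if len(Xm) <= k_neighbors:
        raise ValueError(
            f"minority class has {len(Xm)} rows <= k_neighbors={k_neighbors}; "
            "lower k_neighbors"
        )
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xm)
    _, idx = nn.kneighbors(Xm)  # column 0 is the point itself
    rng = np.random.default_rng(seed)
    base = rng.integers(0, len(Xm), size=n_needed)
    neigh = idx[base, rng.integers(1, k_neighbors + 1, size=n_needed)]
    lam = rng.uniform(0.0, 1.0, size=n_needed)[:, None]
    synth = Xm[base] + lam * (Xm[neigh] - Xm[base])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    return X_out, y_out


@dataclass
class TrainedModel:
    """A fitted LightGBM classifier plus everything needed to reuse it."""

    model_tag: str
    booster: lgb.LGBMClassifier
    classes: tuple[str, ...]
    feature_names: tuple[str, ...]
    hyperparameters: dict
    seed: int
    metadata: dict = field(default_factory=dict)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.booster.booster_.save_model(str(directory / "model.txt"))
        sidecar = {
            "model_tag": self.model_tag,
            "classes": list(self.classes),
            "feature_names": list(self.feature_names),
            "hyperparameters": self.hyperparameters,
            "seed": self.seed,
            "lightgbm_version": lgb.__version__,
            "metadata": self.metadata,
        }
        (directory / "model.json").write_text(json.dumps(sidecar, indent=2))


class _BoosterAdapter:
    """predict_proba shim over a raw Booster loaded from model.txt."""

    def __init__(self, booster: lgb.Booster):
        self.booster = booster

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        raw = np.asarray(self.booster.predict(X))
        if raw.ndim == 1:  # binary: probability of the second class
            return np.column_stack([1.0 - raw, raw])
        return raw


def load_model(directory) -> TrainedModel:
    """Load a model bundle persisted by :meth:`TrainedModel.save`."""
    directory = Path(directory)
    sidecar = json.loads((directory / "model.json").read_text())
    booster = lgb.Booster(model_file=str(directory / "model.txt"))
    return TrainedModel(
        model_tag=sidecar["model_tag"],
        booster=_BoosterAdapter(booster),
        classes=tuple(sidecar["classes"]),
        feature_names=tuple(sidecar["feature_names"]),
        hyperparameters=sidecar["hyperparameters"],
        seed=sidecar["seed"],
        metadata=sidecar.get("metadata", {}),
    )


def _lgbm(model_tag: str, params: dict, seed: int) -> lgb.LGBMClassifier:
    merged = {**DEFAULT_PARAMS, **params}
    return lgb.LGBMClassifier(
        objective="multiclass" if model_tag == "model1" else "binary",
        random_state=seed,
        n_jobs=1,
        deterministic=True,
        force_row_wise=True,
        verbose=-1,
        **merged,
    )


def train_model(
    train: pd.DataFrame,
    val: pd.DataFrame,
    model_tag: str,
    hyperparameters: dict | None = None,
    seed: int = 0,
    oversample: bool = False,
) -> TrainedModel:
    """Fit a leaf-wise gradient-boosted tree ensemble with early stopping.

    ``oversample`` applies SMOTE to the training rows only (the validation
    set keeps its natural class ratio) — used for the cough model.
    """
    label_col = LABEL_COLUMN[model_tag]
    feats = feature_columns(train)
    if feature_columns(val) != feats:
        raise ShapeError("train/validation feature columns differ")
    X, y = train[feats].to_numpy(float), train[label_col].to_numpy(str)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if oversample:
        X, y = oversample_minority(X, y, seed=seed)
    clf = _lgbm(model_tag, hyperparameters or {}, seed)
    clf.fit(
        pd.DataFrame(X, columns=feats),
        y,
        eval_set=[(val[feats], val[label_col].to_numpy(str))],
        callbacks=[lgb.early_stopping(EARLY_STOPPING_ROUNDS, verbose=False)],
    )
    return TrainedModel(
        model_tag=model_tag,
        booster=clf,
        classes=tuple(clf.classes_),
        feature_names=tuple(feats),
        hyperparameters={**DEFAULT_PARAMS, **(hyperparameters or {})},
        seed=seed,
        metadata={"best_iteration": int(clf.best_iteration_ or 0)},
    )


def predict(model: TrainedModel, table: pd.DataFrame) -> pd.DataFrame:
    """Predicted label and per-class probabilities, one row per input row."""
    feats = list(model.feature_names)
    missing = [f for f in feats if f not in table.columns]
    if missing:
        raise ShapeError(f"prediction table missing features: {missing}")
    id_cols = [c for c in ("calf_id", "start_s") if c in table.columns]
    out = table[id_cols].copy() if id_cols else pd.DataFrame(index=table.index)
    if len(table) == 0:
        out["predicted"] = pd.Series(dtype=str)
        for c in model.classes:
            out[f"p_{c}"] = pd.Series(dtype=float)
        return out
    proba = model.booster.predict_proba(table[feats])
    labels = [model.classes[i] for i in np.argmax(proba, axis=1)]
    out["predicted"] = labels
    for j, c in enumerate(model.classes):
        out[f"p_{c}"] = proba[:, j]
    return out


def cross_validate(
    table: pd.DataFrame,
    model_tag: str,
    k: int = 5,
    seed: int = 0,
    oversample: bool = False,
    hyperparameters: dict | None = None,
) -> list[dict]:
    """Stratified k-fold CV; oversampling only ever touches training folds.

    Returns one metric dict per fold (accuracy, macro F1, fold class
    counts — the counts let callers audit that validation folds keep the
    natural imbalance).
    """
    label_col = LABEL_COLUMN[model_tag]
    feats = feature_columns(table)
    X = table[feats].to_numpy(float)
    y = table[label_col].to_numpy(str)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError("every class needs at least k members for stratification")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    results = []
    for fold, (tr, va) in enumerate(skf.split(X, y)):
        Xtr, ytr = X[tr], y[tr]
        if oversample:
            Xtr, ytr = oversample_minority(Xtr, ytr, seed=seed + fold)
        clf = _lgbm(model_tag, hyperparameters or {}, seed)
        clf.fit(pd.DataFrame(Xtr, columns=feats), ytr)
        pred = clf.predict(pd.DataFrame(X[va], columns=feats))
        classes, val_counts = np.unique(y[va], return_counts=True)
        results.append(
            {
                "fold": fold,
                "n_val": len(va),
                "accuracy": float(np.mean(pred == y[va])),
                "macro_f1": float(f1_score(y[va], pred, average="macro")),
                "val_class_counts": dict(zip(classes.tolist(), val_counts.tolist())),
            }
        )
    return results


@dataclass(frozen=True)
class TuningSpec:
    """Random-search space over the main boosting hyperparameters."""

    n_trials: int = 20
    seed: int = 0
    learning_rate: tuple[float, float] = (0.01, 0.3)
    n_estimators: tuple[int, int] = (100, 600)
    max_depth: tuple[int, int] = (2, 12)

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


def tune_hyperparameters(
    train: pd.DataFrame,
    val: pd.DataFrame,
    model_tag: str,
    spec: TuningSpec,
) -> tuple[dict, list[dict]]:
    """Seeded random search maximizing macro F1 on the validation rows.

    Returns the best configuration and the full trial log (every sampled
    configuration with its objective).
    """
    label_col = LABEL_COLUMN[model_tag]
    rng = np.random.default_rng(spec.seed)
    trials = []
    for trial in range(spec.n_trials):
        params = {
            "learning_rate": float(
                np.exp(rng.uniform(*np.log(spec.learning_rate)))
            ),
            "n_estimators": int(rng.integers(spec.n_estimators[0], spec.n_estimators[1] + 1)),
            "max_depth": int(rng.integers(spec.max_depth[0], spec.max_depth[1] + 1)),
        }
        model = train_model(train, val, model_tag, params, seed=spec.seed)
        pred = predict(model, val)["predicted"].to_numpy(str)
        obj = float(f1_score(val[label_col].to_numpy(str), pred, average="macro"))
        trials.append({"trial": trial, "params": params, "macro_f1": obj})
        logger.info("tuning trial %d: macro F1 %.4f %s", trial, obj, params)
    best = max(trials, key=lambda t: t["macro_f1"])
    return dict(best["params"]), trials
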