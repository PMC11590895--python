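"""End-to-end orchestration: simulate -> window -> featurize -> select ->
split -> train -> predict -> evaluate, for all three models.

This is the programmatic backbone of the ``calfsense run-all`` command and
of reproducibility scripts. One global seed fans out to per-stage seeds by
fixed offsets so stages stay independently reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import classify, evaluate, features, synthetic, windowing
from .core import ACTION_BEHAVIORS, STATE_BEHAVIORS, SensorConfig
from .windowing import COUGH_LABEL, NON_COUGH_LABEL, OTHERS_LABEL, PeakConfig

logger = logging.getLogger(__name__)

MODEL1_CLASSES = ACTION_BEHAVIORS + (OTHERS_LABEL,)
MODEL2_CLASSES = STATE_BEHAVIORS
MODEL3_CLASSES = (NON_COUGH_LABEL, COUGH_LABEL)

# fixed per-stage seed offsets from the global seed
SEED_COHORT, SEED_SPLIT, SEED_SELECT, SEED_TRAIN, SEED_SMOTE = 11, 23, 37, 53, 71


@dataclass
class RunConfig:
    """Configuration of a full synthetic-cohort run."""

    n_calves: int = 48
    day_length_s: float = 3600.0
    n_test: int = 6
    val_fraction: float = 0.2
    seed: int = 0
    window_s: float = 10.0
    train_overlap: float = 0.5
    peak: PeakConfig = field(default_factory=PeakConfig)
    sensor: SensorConfig = field(default_factory=SensorConfig)
    cough_rate_per_hour: float = synthetic.DEFAULT_COUGH_RATE_PER_HOUR
    corr_threshold: float = 0.9
    hyperparameters: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a run configuration from a YAML mapping.

        Nested ``peak`` and ``sensor`` mappings build the corresponding
        config objects; unknown keys are rejected.
        """
        raw = yaml.safe_load(open(path)) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "peak" in raw:
            raw["peak"] = PeakConfig(**raw["peak"])
        if "sensor" in raw:
            raw["sensor"] = SensorConfig(**raw["sensor"])
        return cls(**raw)


def build_window_tables(
    cohort, config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(training windows, non-overlapping inference windows, event windows).

    Training windows use 50 % overlap; inference windows use none so the
    10 s-per-window daily time budget does not double-count.
    """
    fs = config.sensor.fs
    train_w, infer_w, event_w = [], [], []
    for rec, track in cohort:
        w = windowing.segment_windows(rec, config.window_s, config.train_overlap)
        train_w.extend(windowing.label_windows(w, track, fs))
        w0 = windowing.segment_windows(rec, config.window_s, 0.0)
        infer_w.extend(windowing.label_windows(w0, track, fs))
        peaks = windowing.detect_peaks(rec.channel("am"), config.peak, fs)
        event_w.extend(windowing.extract_event_windows(rec, peaks, track))
    t_train = features.extract_features(train_w, "model1", fs)
    t_infer = features.extract_features(infer_w, "model1", fs)
    t_event = features.extract_features(event_w, "model3", fs)
    return t_train, t_infer, t_event


def _select(table, train_mask, label_col, corr_threshold, seed):
    """Correlation + tree-importance selection fitted on training rows only."""
    train = table[train_mask]
    reduced, corr_report = features.drop_correlated(train, corr_threshold)
    surviving, imp_report = features.select_by_importance(
        reduced, reduced[label_col], seed=seed
    )
    keep = features.feature_columns(surviving)
    meta = [c for c in table.columns if c not in features.feature_columns(table)]
    return table[meta + keep], {"correlation": corr_report, "importance": imp_report}


def _evaluate_windows(model, test_table, classes, label_col):
    pred = classify.predict(model, test_table)
    actual = test_table[label_col].to_numpy(str)
    cm = evaluate.confusion(actual, pred["predicted"].to_numpy(str), classes)
    metrics = evaluate.class_metrics(cm)
    aucs = {}
    for cls in classes:
        y = actual == cls
        if y.any() and not y.all():
            aucs[cls] = evaluate.roc_auc(actual, pred[f"p_{cls}"], cls).auc
    return pred, cm, metrics, aucs


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a report dict per model."""
    logger.info("simulating cohort: %d calves x %.0f s", config.n_calves, config.day_length_s)
    cohort = synthetic.simulate_cohort(
        config.n_calves,
        config.day_length_s,
        seed=config.seed + SEED_COHORT,
        config=config.sensor,
        cough_rate_per_hour=config.cough_rate_per_hour,
    )
    tracks = {track.calf_id: track for _, track in cohort}
    t_train, t_infer, t_event = build_window_tables(cohort, config)
    logger.info(
        "windows: %d training, %d inference, %d event",
        len(t_train), len(t_infer), len(t_event),
    )

    plan = classify.split_by_individual(
        t_train, config.n_test, config.val_fraction, seed=config.seed + SEED_SPLIT
    )
    report: dict = {"split": {"train_ids": plan.train_ids, "test_ids": plan.test_ids}}

    # Models 1 and 2 share windows; selection is label-aware per model
    for tag, classes in (("model1", MODEL1_CLASSES), ("model2", MODEL2_CLASSES)):
        label_col = features.LABEL_COLUMN[tag]
        train_mask = t_train["calf_id"].astype(str).isin(plan.train_ids).to_numpy()
        sel_train, sel_reports = _select(
            t_train, train_mask, label_col, config.corr_threshold, config.seed + SEED_SELECT
        )
        keep = features.feature_columns(sel_train)
        meta_i = [c for c in t_infer.columns if c not in features.feature_columns(t_infer)]
        sel_infer = t_infer[meta_i + keep]
        train, val, _ = classify.apply_split(sel_train, plan)
        model = classify.train_model(
            train, val, tag,
            config.hyperparameters.get(tag), seed=config.seed + SEED_TRAIN,
        )
        test_infer = sel_infer[sel_infer["calf_id"].astype(str).isin(plan.test_ids)]
        pred, cm, metrics, aucs = _evaluate_windows(model, test_infer, classes, label_col)

        budgets = []
        for calf_id in plan.test_ids:
            p = pred[pred["calf_id"].astype(str) == calf_id]
            tier = "action" if tag == "model1" else "state"
            budgets.append(
                evaluate.time_budget(p, tracks[calf_id], tier, config.window_s)
            )
        budget = pd.concat(budgets, ignore_index=True)
        budget_r = {}
        for behavior in classes:
            sub = budget[budget["behavior"] == behavior]
            if len(sub) >= 3 and sub["predicted_s"].nunique() > 1 and sub["observed_s"].nunique() > 1:
                budget_r[behavior] = evaluate.pearson_r(
                    sub["predicted_s"], sub["observed_s"]
                )
        report[tag] = {
            "n_features": len(keep),
            "confusion": cm.to_frame().to_dict(),
            "metrics_percent": evaluate.metrics_percent(metrics).to_dict(),
            "auc": aucs,
            "time_budget_r": budget_r,
            "selection": {k: v.to_dict() for k, v in sel_reports.items()},
            "model": model,
            "time_budget": budget,
        }

    # Model 3: event windows, SMOTE on the training portion only
    label_col = features.LABEL_COLUMN["model3"]
    ev_train_mask = t_event["calf_id"].astype(str).isin(plan.train_ids).to_numpy()
    sel_event, sel_reports = _select(
        t_event, ev_train_mask, label_col, config.corr_threshold, config.seed + SEED_SELECT
    )
    ev_train_all = sel_event[ev_train_mask]
    rng = np.random.default_rng(config.seed + SEED_SPLIT)
    n_val = int(round(config.val_fraction * len(ev_train_all)))
    val_idx = rng.choice(len(ev_train_all), size=n_val, replace=False)
    val_mask = np.zeros(len(ev_train_all), dtype=bool)
    val_mask[val_idx] = True
    ev_train, ev_val = ev_train_all[~val_mask], ev_train_all[val_mask]
    model3 = classify.train_model(
        ev_train, ev_val, "model3",
        config.hyperparameters.get("model3"),
        seed=config.seed + SEED_TRAIN, oversample=True,
    )
    ev_test = sel_event[~ev_train_mask]
    pred3, cm3, metrics3, aucs3 = _evaluate_windows(
        model3, ev_test, MODEL3_CLASSES, label_col
    )

    # daily cough frequency: predicted coughing windows vs annotated events
    counts = []
    for calf_id in plan.test_ids:
        p = pred3[pred3["calf_id"].astype(str) == calf_id]
        predicted = int((p["predicted"] == COUGH_LABEL).sum())
        observed = len(tracks[calf_id].tier_intervals("event"))
        counts.append(
            {"calf_id": calf_id, "predicted_count": predicted, "observed_count": observed}
        )
    counts = pd.DataFrame(counts)
    cough_r = None
    if (
        len(counts) >= 3
        and counts["predicted_count"].nunique() > 1
        and counts["observed_count"].nunique() > 1
    ):
        cough_r = evaluate.pearson_r(counts["predicted_count"], counts["observed_count"])

    report["model3"] = {
        "n_features": len(features.feature_columns(sel_event)),
        "confusion": cm3.to_frame().to_dict(),
        "metrics_percent": evaluate.metrics_percent(metrics3).to_dict(),
        "auc": aucs3,
        "cough_count_r": cough_r,
        "cough_counts": counts,
        "selection": {k: v.to_dict() for k, v in sel_reports.items()},
        "model": model3,
    }
    return report
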