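"""Individual-wise splitting, SMOTE oversampling, gradient-boosted
training, cross-validation and the tuning hook."""

import numpy as np
import pandas as pd
import pytest

from calfsense.classify import (
    TuningSpec,
    apply_split,
    cross_validate,
    load_model,
    oversample_minority,
    predict,
    split_by_individual,
    train_model,
    tune_hyperparameters,
)


def make_table(
    n_calves=8,
    rows_per_calf=40,
    seed=0,
    model="model2",
    minority_fraction=None,
):
    """Feature table with two well-separated Gaussian classes.

    For model2 the classes are postures; for model3 they are cough labels
    with an optional minority fraction.
    """
    rng = np.random.default_rng(seed)
    rows = []
    label_col = {"model2": "state_label", "model3": "event_label"}[model]
    classes = (
        ("lying", "standing") if model == "model2" else ("non_coughing", "coughing")
    )
    for c in range(n_calves):
        for i in range(rows_per_calf):
            if minority_fraction is None:
                label = classes[i % 2]
            else:
                label = classes[1] if rng.random() < minority_fraction else classes[0]
            center = 0.0 if label == classes[0] else 3.0
            rows.append(
                {
                    "calf_id": f"calf{c:02d}",
                    "start_s": float(i * 10),
                    label_col: label,
                    "f1": rng.normal(center, 0.5),
                    "f2": rng.normal(-center, 0.5),
                    "f3": rng.normal(0, 1.0),
                }
            )
    return pd.DataFrame(rows)


class TestSplit:
    def test_forty_eight_calves_split_42_6(self):
        table = make_table(n_calves=48, rows_per_calf=4)
        plan = split_by_individual(table, n_test=6, seed=0)
        assert len(plan.train_ids) == 42 and len(plan.test_ids) == 6
        assert not set(plan.train_ids) & set(plan.test_ids)

    def test_seed_reproducibility(self):
        table = make_table()
        p1 = split_by_individual(table, 2, seed=9)
        p2 = split_by_individual(table, 2, seed=9)
        assert p1 == p2

    def test_validation_rows_come_from_training_calves(self):
        table = make_table()
        plan = split_by_individual(table, 2, val_fraction=0.2, seed=1)
        train, val, test = apply_split(table, plan)
        assert set(val["calf_id"]) <= set(plan.train_ids)
        assert set(test["calf_id"]) == set(plan.test_ids)
        assert len(val) == round(0.2 * (len(train) + len(val)))

    def test_invalid_n_test(self):
        table = make_table(n_calves=4)
        with pytest.raises(ValueError):
            split_by_individual(table, n_test=4)


class TestSMOTE:
    def _imbalanced(self, n_maj=28, n_min=10, seed=0, d=3):
        rng = np.random.default_rng(seed)
        X = np.vstack(
            [rng.normal(0, 1, (n_maj, d)), rng.normal(5, 1, (n_min, d))]
        )
        y = np.array(["neg"] * n_maj + ["pos"] * n_min)
        return X, y

    def test_balances_28_to_10(self):
        X, y = self._imbalanced()
        Xo, yo = oversample_minority(X, y, seed=0)
        assert (yo == "pos").sum() == (yo == "neg").sum() == 28
        np.testing.assert_array_equal(Xo[: len(X)], X)  # originals preserved

    def test_already_balanced_unchanged(self):
        X, y = self._imbalanced(n_maj=10, n_min=10)
        Xo, yo = oversample_minority(X, y, seed=0)
        np.testing.assert_array_equal(Xo, X)
        np.testing.assert_array_equal(yo, y)

    def test_synthetic_rows_lie_between_minority_pairs(self):
        X, y = self._imbalanced(seed=3)
        Xo, yo = oversample_minority(X, y, seed=3)
        minority = X[y == "pos"]
        for s in Xo[len(X):]:
            on_segment = False
            for i in range(len(minority)):
                for j in range(len(minority)):
                    if i == j:
                        continue
                    a, b = minority[i], minority[j]
                    inside = np.all(s >= np.minimum(a, b) - 1e-9) and np.all(
                        s <= np.maximum(a, b) + 1e-9
                    )
                    d = b - a
                    lam = (s - a) @ d / (d @ d)
                    collinear = np.allclose(a + lam * d, s, atol=1e-9)
                    if inside and collinear:
                        on_segment = True
            assert on_segment

    def test_small_minority_guidance(self):
        X, y = self._imbalanced(n_min=4)
        with pytest.raises(ValueError, match="k_neighbors"):
            oversample_minority(X, y, k_neighbors=5)


class TestTraining:
    def test_separable_postures_high_validation_accuracy(self):
        table = make_table(n_calves=10, rows_per_calf=60, seed=1)
        plan = split_by_individual(table, 2, seed=1)
        train, val, _ = apply_split(table, plan)
        model = train_model(train, val, "model2", seed=1)
        pred = predict(model, val)
        acc = np.mean(pred["predicted"].to_numpy() == val["state_label"].to_numpy())
        assert acc >= 0.95

    def test_training_determinism(self):
        table = make_table(seed=2)
        plan = split_by_individual(table, 2, seed=2)
        train, val, _ = apply_split(table, plan)
        p1 = predict(train_model(train, val, "model2", seed=5), val)
        p2 = predict(train_model(train, val, "model2", seed=5), val)
        pd.testing.assert_frame_equal(p1, p2)

    def test_single_class_rejected(self):
        table = make_table()
        table["state_label"] = "lying"
        plan = split_by_individual(table, 2, seed=0)
        train, val, _ = apply_split(table, plan)
        with pytest.raises(ValueError):
            train_model(train, val, "model2")

    def test_save_load_round_trip(self, tmp_path):
        table = make_table(seed=4)
        plan = split_by_individual(table, 2, seed=4)
        train, val, test = apply_split(table, plan)
        model = train_model(train, val, "model2", seed=4)
        model.save(tmp_path / "m2")
        loaded = load_model(tmp_path / "m2")
        pd.testing.assert_frame_equal(predict(loaded, test), predict(model, test))


class TestPredict:
    def test_probabilities_sum_to_one(self):
        table = make_table(seed=6)
        plan = split_by_individual(table, 2, seed=6)
        train, val, test = apply_split(table, plan)
        model = train_model(train, val, "model2", seed=6)
        pred = predict(model, test)
        sums = pred[[f"p_{c}" for c in model.classes]].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
        assert (pred["predicted"] == pred[[f"p_{c}" for c in model.classes]]
                .idxmax(axis=1).str.removeprefix("p_")).all()

    def test_empty_table(self):
        table = make_table(seed=7)
        plan = split_by_individual(table, 2, seed=7)
        train, val, _ = apply_split(table, plan)
        model = train_model(train, val, "model2", seed=7)
        out = predict(model, table.iloc[:0])
        assert len(out) == 0 and "predicted" in out.columns


class TestCrossValidation:
    def test_fold_sizes(self):
        table = make_table(n_calves=5, rows_per_calf=20, model="model3",
                           minority_fraction=0.5, seed=8)
        results = cross_validate(table, "model3", k=5, seed=8)
        assert [r["n_val"] for r in results] == [20] * 5

    def test_separable_data_perfect_folds(self):
        table = make_table(n_calves=5, rows_per_calf=40, seed=9)
        results = cross_validate(table, "model2", k=5, seed=9)
        assert all(r["accuracy"] == 1.0 for r in results)

    def test_oversampling_never_touches_validation_folds(self):
        table = make_table(
            n_calves=5, rows_per_calf=38, model="model3",
            minority_fraction=0.26, seed=10,
        )
        counts = table["event_label"].value_counts()
        results = cross_validate(table, "model3", k=5, seed=10, oversample=True)
        for r in results:
            vc = r["val_class_counts"]
            # validation folds keep the natural imbalance (stratified)
            ratio = vc["non_coughing"] / vc["coughing"]
            natural = counts["non_coughing"] / counts["coughing"]
            assert ratio == pytest.approx(natural, rel=0.35)

    def test_small_class_stratification_error(self):
        table = make_table(n_calves=2, rows_per_calf=10, model="model3",
                           minority_fraction=0.5, seed=11)
        table.loc[table["event_label"] == "coughing", "event_label"] = "non_coughing"
        table.loc[:2, "event_label"] = "coughing"
        with pytest.raises(ValueError):
            cross_validate(table, "model3", k=5)


class TestTuning:
    def _split(self, seed=12):
        table = make_table(n_calves=6, rows_per_calf=30, seed=seed)
        plan = split_by_individual(table, 2, seed=seed)
        return apply_split(table, plan)

    def test_single_trial_returns_it(self):
        train, val, _ = self._split()
        best, log = tune_hyperparameters(
            train, val, "model2", TuningSpec(n_trials=1, seed=0)
        )
        assert len(log) == 1 and best == log[0]["params"]

    def test_best_dominates_log(self):
        train, val, _ = self._split()
        best, log = tune_hyperparameters(
            train, val, "model2", TuningSpec(n_trials=5, seed=1)
        )
        best_obj = max(t["macro_f1"] for t in log)
        assert any(t["params"] == best and t["macro_f1"] == best_obj for t in log)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            TuningSpec(n_trials=0)
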