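"""Epoch alignment, binary relabeling, splitting, random-forest models."""

import numpy as np
import pandas as pd
import pytest

import actisleep as a
from actisleep.dataset_model import COUNT_COLUMNS, RAW_COLUMNS, FeatureConfig


class TestEpochAlign:
    def test_one_row_per_epoch(self, small_cohort):
        rec, hyp = small_cohort[0]
        table = a.epoch_align(rec, hyp)
        assert len(table) == len(hyp)
        assert list(table["epoch_index"]) == list(range(len(hyp)))

    def test_hypnogram_longer_than_record_truncates(self, small_cohort):
        rec, hyp = small_cohort[0]
        table = a.epoch_align(rec, hyp + ["W"] * 5)
        assert len(table) == rec.n_epochs

    def test_zero_overlap_is_an_error(self, small_cohort):
        rec, _ = small_cohort[0]
        with pytest.raises(ValueError, match="no complete epoch"):
            a.epoch_align(rec, [])

    def test_boundary_beat_goes_to_later_epoch(self):
        from actisleep.hrv_features import extract_epoch_features
        from actisleep.rr_preprocess import RRSeries
        # beats at 28.8, 29.4, 30.0: the t=30.0 beat belongs to epoch 1
        times = np.arange(0.6, 30.01, 0.6)
        rr = RRSeries(times, np.full(len(times), 600.0),
                      np.full(len(times), "observed", dtype=object))
        f0 = extract_epoch_features(rr, 0)
        assert f0["n_beats"] == len(times) - 1

    def test_pooled_dataset_has_unique_keys(self, epoch_table):
        assert not epoch_table.duplicated(["subject_id", "epoch_index"]).any()


class TestRelabelBinary:
    def test_wake_is_zero_sleep_is_one(self):
        df = pd.DataFrame({"stage": ["W", "R", "S1", "S2", "S3"]})
        out = a.relabel_binary(df)
        assert list(out["label"]) == [0, 1, 1, 1, 1]

    def test_counts_preserved(self, epoch_table):
        out = a.relabel_binary(epoch_table)
        n_wake = (epoch_table["stage"] == "W").sum()
        assert (out["label"] == 0).sum() == n_wake
        assert (out["label"] == 1).sum() == len(out) - n_wake

    def test_positive_rate_complements_wake_fraction(self, epoch_table):
        out = a.relabel_binary(epoch_table)
        wake_fraction = (epoch_table["stage"] == "W").mean()
        assert out["label"].mean() == pytest.approx(1.0 - wake_fraction, abs=1e-12)

    def test_unknown_label_is_an_error(self):
        with pytest.raises(ValueError, match="unknown stage"):
            a.relabel_binary(pd.DataFrame({"stage": ["W", "N4"]}))


class TestSplit:
    def test_half_split_sizes(self, epoch_table):
        train, valid = a.split(epoch_table, fraction=0.5, seed=0)
        assert abs(len(train) - len(valid)) <= 3
        assert len(train) + len(valid) == len(epoch_table)

    def test_same_seed_same_split(self, epoch_table):
        t1, v1 = a.split(epoch_table, seed=4)
        t2, v2 = a.split(epoch_table, seed=4)
        assert list(v1.index) == list(v2.index)

    def test_subject_strategy_holds_out_whole_subjects(self, epoch_table):
        train, valid = a.split(epoch_table, strategy="subject", fraction=0.25, seed=1)
        assert set(train["subject_id"]) & set(valid["subject_id"]) == set()
        assert valid["subject_id"].nunique() == 1

    def test_stratification_keeps_all_labels_in_train(self, epoch_table):
        train, valid = a.split(epoch_table, fraction=0.2, seed=2)
        assert set(valid["stage"]) <= set(train["stage"])


class TestTrainRF:
    def test_perfectly_encoding_feature_is_learned(self, rng):
        stages = rng.choice(["W", "R", "S1", "S2", "S3"], size=300)
        code = {"W": 0.0, "R": 1.0, "S1": 2.0, "S2": 3.0, "S3": 4.0}
        table = pd.DataFrame({
            "subject_id": "s", "epoch_index": np.arange(300), "stage": stages,
            "counts_x": [code[s] for s in stages],
            "counts_y": 0.0, "counts_z": 0.0, "vm": 0.0,
        })
        cfg = FeatureConfig("acceleration", include_raw=False)
        m = a.train_rf(table, cfg, n_estimators=50, seed=0)
        assert (m.predict(table) == stages).all()

    def test_same_seed_identical_predictions(self, epoch_table):
        cfg = FeatureConfig("hrv", include_raw=False)
        train, valid = a.split(epoch_table, seed=1)
        m1 = a.train_rf(train, cfg, n_estimators=50, seed=1)
        m2 = a.train_rf(train, cfg, n_estimators=50, seed=1)
        v = valid.dropna(subset=m1.feature_names)
        assert (m1.predict(v) == m2.predict(v)).all()

    def test_single_class_training_set_is_an_error(self, epoch_table):
        one = epoch_table[epoch_table["stage"] == "S2"]
        cfg = FeatureConfig("hrv", include_raw=True)
        with pytest.raises(ValueError, match="single class"):
            a.train_rf(one, cfg, n_estimators=10, seed=0)


class TestFeatureImportance:
    def test_importances_sum_to_one_and_descend(self, epoch_table):
        cfg = FeatureConfig("acceleration", include_raw=True)
        m = a.train_rf(epoch_table, cfg, n_estimators=50, seed=0)
        ranked = a.feature_importance(m)
        vals = [v for _, v in ranked]
        assert sum(vals) == pytest.approx(1.0, abs=1e-9)
        assert vals == sorted(vals, reverse=True)

    def test_noise_feature_ranks_below_signal(self, rng):
        stages = rng.choice(["W", "S2"], size=400)
        table = pd.DataFrame({
            "subject_id": "s", "epoch_index": np.arange(400), "stage": stages,
            "counts_x": np.where(stages == "W", 10.0, 0.0) + rng.normal(0, 0.1, 400),
            "counts_y": rng.normal(0, 1, 400),  # pure noise
            "counts_z": 0.0, "vm": 0.0,
        })
        cfg = FeatureConfig("acceleration", include_raw=False)
        m = a.train_rf(table, cfg, n_estimators=100, seed=0)
        ranked = dict(a.feature_importance(m))
        assert ranked["counts_x"] > ranked["counts_y"]


class TestCompareAlgorithms:
    def test_schema_has_the_seven_metrics(self, epoch_table):
        train, valid = a.split(epoch_table, seed=0)
        df = a.compare_algorithms(train, valid,
                                  algorithms=["Decision Tree Classifier"])
        assert list(df.columns) == ["Model", "Accuracy", "AUC", "Recall",
                                    "Prec.", "F1", "Kappa", "MCC"]
        assert len(df) == 1

    def test_tree_model_beats_lda_on_nonlinear_data(self, rng):
        # XOR-style labels: linearly inseparable, trivially tree-separable
        x = rng.uniform(-1, 1, 600)
        y = rng.uniform(-1, 1, 600)
        stages = np.where(x * y > 0, "W", "S2")
        table = pd.DataFrame({
            "subject_id": "s", "epoch_index": np.arange(600), "stage": stages,
            "counts_x": x, "counts_y": y, "counts_z": 0.0, "vm": 0.0,
        })
        train, valid = a.split(table, fraction=0.3, seed=3)
        cfg = FeatureConfig("acceleration", include_raw=False)
        df = a.compare_algorithms(
            train, valid, config=cfg,
            algorithms=["Decision Tree Classifier", "Linear Discriminant Analysis"],
        ).set_index("Model")
        assert (df.loc["Decision Tree Classifier", "Accuracy"]
                > df.loc["Linear Discriminant Analysis", "Accuracy"])

    def test_unknown_algorithm_rejected(self, epoch_table):
        train, valid = a.split(epoch_table, seed=0)
        with pytest.raises(ValueError, match="unknown algorithm"):
            a.compare_algorithms(train, valid, algorithms=["AutoML"])


class TestEndToEnd:
    def test_hrv_model_recovers_stages_on_small_cohort(self, epoch_table):
        result = a.run_config(epoch_table, FeatureConfig("hrv", True),
                              n_estimators=100, seed=1)
        assert result["kappa"] > 0.8

    def test_binary_mode_runs_and_scores_high(self, epoch_table):
        result = a.run_config(epoch_table, FeatureConfig("hrv", True, "binary"),
                              n_estimators=100, seed=1)
        assert result["accuracy"] > 0.9
        assert result["confusion_matrix"].shape == (2, 2)
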