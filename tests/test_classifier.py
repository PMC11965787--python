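import numpy as np
import pandas as pd
import pytest

from ppgrhythm import (
    AF_BINARY,
    AFL_3CLASS,
    ClassifierConfig,
    FEATURE_NAMES,
    TrainedModel,
    loso_cross_validate,
    predict,
    predict_batch,
    train_classifier,
)

from conftest import rhythm_feature_frame


def blob_frame(n_per_class=100, sep=6.0, seed=0, n_subjects=10):
    """Two well-separated Gaussian blobs in the first two feature dims."""
    rng = np.random.default_rng(seed)
    rows = []
    for i, label in enumerate(["SR", "AF"]):
        center = np.zeros(13)
        center[:2] = sep * (1 if label == "AF" else -1)
        for j in range(n_per_class):
            x = center + rng.normal(0, 1, 13)
            rows.append({
                "subject_id": f"B{(i * n_per_class + j) % n_subjects:02d}",
                "label": label,
                **{k: v for k, v in zip(FEATURE_NAMES, x)},
            })
    return pd.DataFrame(rows)


class TestTraining:
    def test_separable_blobs_reach_perfect_training_accuracy(self):
        df = blob_frame(100)
        model = train_classifier(df, AF_BINARY, rng=0)
        preds = predict_batch(model, df)
        assert (preds["pred_label"] == df["label"]).mean() == 1.0

    def test_same_seed_gives_identical_predictions(self, small_binary_cohort):
        probe = small_binary_cohort.iloc[::7]
        m1 = train_classifier(small_binary_cohort, AF_BINARY, rng=5)
        m2 = train_classifier(small_binary_cohort, AF_BINARY, rng=5)
        p1 = predict_batch(m1, probe)
        p2 = predict_batch(m2, probe)
        assert np.array_equal(p1["p_AF"].to_numpy(), p2["p_AF"].to_numpy())

    def test_deployment_like_training_mix_trains_without_class_failure(self):
        # ~51% SR / 45% AF / 4% AFL, as in the deployed training data
        df = rhythm_feature_frame(
            22, 20, ["SR"] * 11 + ["AF"] * 10 + ["AFL"], seed=9
        )
        mix = df["label"].value_counts(normalize=True)
        assert mix["AFL"] < 0.10
        model = train_classifier(df, AFL_3CLASS, rng=0)
        assert model.classes == ["SR", "AF", "AFL"]

    def test_rare_class_refused_with_explicit_message(self, small_binary_cohort):
        df = small_binary_cohort.copy()
        df.loc[df.index[:3], "label"] = "AFL"  # only 3 AFL recordings
        with pytest.raises(ValueError, match="fewer than 5"):
            train_classifier(df, AFL_3CLASS, rng=0)

    def test_model_json_roundtrip_is_lossless(self, small_binary_cohort, tmp_path):
        model = train_classifier(small_binary_cohort, AF_BINARY, rng=2)
        model.save(tmp_path / "m.json")
        back = TrainedModel.load(tmp_path / "m.json")
        X = small_binary_cohort[FEATURE_NAMES].to_numpy(float)
        assert np.array_equal(model.posterior(X), back.posterior(X))
        assert back.metadata["hyperparameters"]["C"] == 1.0


class TestPrediction:
    def test_posteriors_sum_to_one_and_certainty_bounds(self, small_binary_cohort):
        model = train_classifier(small_binary_cohort, AF_BINARY, rng=1)
        X = small_binary_cohort[FEATURE_NAMES].to_numpy(float)
        post = model.posterior(X)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)
        certainty = post.max(axis=1)
        assert np.all(certainty >= 0.5)  # binary floor
        assert np.all(certainty <= 1.0)

    def test_three_class_certainty_floor(self):
        df = rhythm_feature_frame(12, 12, ["SR", "AF", "AFL"] * 4, seed=13)
        model = train_classifier(df, AFL_3CLASS, rng=1)
        post = model.posterior(df[FEATURE_NAMES].to_numpy(float))
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(post.max(axis=1) >= 1 / 3 - 1e-12)

    def test_gate_flag_matches_strict_inequality(self, small_binary_cohort):
        model = train_classifier(small_binary_cohort, AF_BINARY, rng=1)
        preds = predict_batch(model, small_binary_cohort)
        assert (preds["gated_low_certainty"] == (preds["certainty"] < 0.9)).all()
        one = predict(model, small_binary_cohort[FEATURE_NAMES].iloc[0].to_dict())
        assert one.gated_low_certainty == (one.certainty < 0.9)

    def test_non_finite_features_rejected(self, small_binary_cohort):
        model = train_classifier(small_binary_cohort, AF_BINARY, rng=1)
        bad = np.full(13, np.nan)
        with pytest.raises(ValueError, match="finite"):
            predict(model, bad)


class TestLoso:
    def test_folds_partition_the_recordings(self, small_binary_cohort):
        df = small_binary_cohort[
            small_binary_cohort["subject_id"].isin(["S000", "S001", "S002", "S003"])
        ]
        preds = loso_cross_validate(df, AF_BINARY, rng=0)
        assert preds["fold_subject"].nunique() == 4
        assert len(preds) == len(df)
        # every prediction is out-of-subject by construction
        assert (preds["fold_subject"] == preds["subject_id"]).all()

    def test_too_few_subjects_rejected(self, small_binary_cohort):
        df = small_binary_cohort[small_binary_cohort["subject_id"] == "S000"]
        with pytest.raises(ValueError, match="3 subjects"):
            loso_cross_validate(df, AF_BINARY)

    def test_subject_leakage_collapses_under_loso(self):
        # Each subject sits at a random offset carrying NO label information
        # across subjects; record-wise splits can memorize subject identity,
        # LOSO cannot.
        rng = np.random.default_rng(21)
        rows = []
        for s in range(14):
            label = "AF" if s % 2 else "SR"
            offset = rng.normal(0, 6, 13)
            for r in range(20):
                x = offset + rng.normal(0, 0.3, 13)
                rows.append({
                    "subject_id": f"L{s:02d}", "label": label,
                    **{k: v for k, v in zip(FEATURE_NAMES, x)},
                })
        df = pd.DataFrame(rows)

        # record-wise split: subjects present on both sides -> leakage works
        shuffled = df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        half = len(shuffled) // 2
        model = train_classifier(shuffled.iloc[:half], AF_BINARY, rng=0)
        rw_acc = (
            predict_batch(model, shuffled.iloc[half:])["pred_label"]
            == shuffled.iloc[half:]["label"]
        ).mean()

        loso_preds = loso_cross_validate(df, AF_BINARY, rng=0)
        loso_acc = (loso_preds["pred_label"] == loso_preds["label"]).mean()

        assert rw_acc > 0.9
        assert loso_acc < 0.7  # near chance: the planted signal was leakage


class TestGateMonotonicityAndGrouping:
    def test_raising_the_gate_filters_more_and_never_hurts_accuracy(self):
        gates = [0.6, 0.8, 0.9, 0.95]
        acc_by_gate = {g: [] for g in gates}
        for seed in range(10):
            train = rhythm_feature_frame(8, 10, ["SR", "AF"] * 4, seed=100 + seed)
            test = rhythm_feature_frame(8, 10, ["SR", "AF"] * 4,
                                        seed=200 + seed, prefix="Q")
            model = train_classifier(train, AF_BINARY, rng=seed)
            preds = predict_batch(model, test)
            prev_n = None
            for g in gates:
                kept = preds[preds["certainty"] >= g]
                if prev_n is not None:
                    assert len(kept) <= prev_n
                prev_n = len(kept)
                acc_by_gate[g].append(
                    (kept["pred_label"] == kept["label"]).mean()
                    if len(kept) else np.nan
                )
        means = [np.nanmean(acc_by_gate[g]) for g in gates]
        assert all(b >= a - 1e-9 for a, b in zip(means, means[1:]))

    def test_collapsed_three_class_matches_binary_on_af_only_data(self):
        train = rhythm_feature_frame(24, 10, ["SR", "AF"] * 10 + ["AFL"] * 4,
                                     seed=55)
        test = rhythm_feature_frame(12, 10, ["SR", "AF"] * 6, seed=56, prefix="Q")
        m2 = train_classifier(train, AF_BINARY, rng=3)
        m3 = train_classifier(train, AFL_3CLASS, rng=3)
        acc2 = (predict_batch(m2, test)["pred_label"] == test["label"]).mean()
        pred3 = predict_batch(m3, test)["pred_label"].replace({"AFL": "AF"})
        acc3 = (pred3 == test["label"]).mean()
        assert abs(acc2 - acc3) <= 0.01
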