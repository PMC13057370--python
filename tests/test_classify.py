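"""Migration classifier, feature relevance and between-group ordination."""

import numpy as np
import pandas as pd
import pytest

from temflow.classify import (MLPSpec, MLPMigrationClassifier,
                              BetweenGroupOrdination, split_train_test,
                              train, predict, evaluate, feature_relevance,
                              bga_ordination, merge_to_binary)
from temflow.morphometry import FEATURE_NAMES
from temflow.synth import generate_feature_table


def three_class_table(n_per_class=200, seed=0):
    """Attached and in_process share one distribution; transmigrated is
    shifted — mirroring the morphological overlap of the apical stages."""
    rng = np.random.default_rng(seed)
    table = generate_feature_table(n_per_class * 2, seed=seed)
    att = table[table["class"] == "attached_process"].copy()
    half = len(att) // 2
    att.iloc[:half, att.columns.get_loc("class")] = "attached"
    att.iloc[half:, att.columns.get_loc("class")] = "in_process"
    tra = table[table["class"] == "transmigrated"].iloc[:n_per_class]
    out = pd.concat([att, tra], ignore_index=True)
    return out.sample(frac=1.0, random_state=seed).reset_index(drop=True)


class TestMergeToBinary:
    def test_merge_is_deterministic_union(self):
        merged = merge_to_binary(["attached", "in_process", "transmigrated"])
        assert merged.tolist() == ["attached_process", "attached_process",
                                   "transmigrated"]

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            merge_to_binary(["attached", "rolling"])


class TestSplit:
    def test_stratified_half_split(self):
        table = generate_feature_table(100, seed=0)
        split = split_train_test(table, 0.5, seed=0)
        for part in (split.train, split.test):
            counts = part["class"].value_counts()
            assert counts["attached_process"] == 50
            assert counts["transmigrated"] == 50

    def test_same_seed_identical_splits(self):
        table = generate_feature_table(60, seed=1)
        s1 = split_train_test(table, 0.3, seed=5)
        s2 = split_train_test(table, 0.3, seed=5)
        assert s1.train.equals(s2.train) and s1.test.equals(s2.test)

    def test_reference_train_test_sizes(self):
        """A 4979-cell table split at the reference fraction yields the
        2438-cell train set and 2541-cell held-out test set."""
        table = generate_feature_table(2490, seed=2).iloc[:4979]
        split = split_train_test(table, test_fraction=2541 / 4979, seed=0)
        assert len(split.train) == 2438
        assert len(split.test) == 2541

    def test_small_class_rejected(self):
        table = generate_feature_table(5, seed=3)
        table = pd.concat([table[table["class"] == "attached_process"],
                           table[table["class"] == "transmigrated"].iloc[:1]])
        with pytest.raises(ValueError, match="fewer than 2"):
            split_train_test(table, 0.5)


class TestSpec:
    def test_three_hidden_layers_enforced(self):
        with pytest.raises(ValueError, match="three hidden"):
            MLPSpec(hidden_layers=(64, 32))
        assert MLPSpec().hidden_layers == (64, 32, 16)


class TestTrainPredict:
    def test_separable_fixture_learned_close_to_oracle(self):
        """With a 6-sd AR-only gap a near-perfect threshold exists; the
        network must get close to that single-feature oracle.  Early stopping
        halts once the internal validation fold saturates, so a few points
        below the oracle is the designed behaviour, not a defect."""
        table = generate_feature_table(500, class_shift={"AR": 6.0}, seed=4)
        split = split_train_test(table, 0.5, seed=4)
        model = train(split.train, MLPSpec(seed=4))
        y = split.train["class"].to_numpy()
        acc = (model.predict(split.train) == y).mean()
        # oracle: best AR threshold on the same rows
        ar = split.train["AR"].to_numpy()
        truth = y == "transmigrated"
        oracle = max((((ar >= t) == truth).mean()) for t in np.unique(ar))
        assert oracle >= 0.99
        assert acc >= oracle - 0.05
        assert acc >= 0.95

    def test_shuffled_labels_give_chance_accuracy(self):
        table = generate_feature_table(1000, seed=5)
        rng = np.random.default_rng(5)
        table["class"] = rng.permutation(table["class"].to_numpy())
        split = split_train_test(table, 0.5, seed=5)
        model = train(split.train, MLPSpec(seed=5))
        rep = evaluate(model, split.test)
        assert 0.45 <= rep.overall_accuracy <= 0.55

    def test_training_is_deterministic_under_seed(self):
        table = generate_feature_table(150, seed=6)
        split = split_train_test(table, 0.5, seed=6)
        m1 = train(split.train, MLPSpec(seed=6))
        m2 = train(split.train, MLPSpec(seed=6))
        np.testing.assert_array_equal(m1.predict(split.test),
                                      m2.predict(split.test))
        p1 = m1.predict_proba(split.test)
        np.testing.assert_allclose(p1, m2.predict_proba(split.test))

    def test_probabilities_normalized_and_stable_under_duplication(self):
        table = generate_feature_table(100, seed=7)
        model = train(table, MLPSpec(seed=7))
        proba = model.predict_proba(table)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)
        doubled = pd.concat([table, table], ignore_index=True)
        pd2 = model.predict_proba(doubled)
        np.testing.assert_array_equal(pd2[:len(table)], pd2[len(table):])

    def test_class_centroid_classified_confidently(self):
        table = generate_feature_table(500, seed=8)
        model = train(table, MLPSpec(seed=8))
        centroid = (table[table["class"] == "transmigrated"]
                    [list(model.feature_names_in_)].mean().to_frame().T)
        proba = model.predict_proba(centroid)
        assert proba[0, list(model.classes_).index("transmigrated")] > 0.5

    def test_missing_feature_column_rejected(self):
        table = generate_feature_table(50, seed=9)
        model = train(table, MLPSpec(seed=9))
        with pytest.raises(ValueError, match="missing"):
            model.predict(table.drop(columns=["AR"]))

    def test_non_finite_features_rejected(self):
        table = generate_feature_table(50, seed=10)
        table.loc[3, "Area"] = np.nan
        with pytest.raises(ValueError, match="finite"):
            train(table)

    def test_single_class_table_rejected(self):
        table = generate_feature_table(50, seed=11)
        with pytest.raises(ValueError, match="single class"):
            train(table[table["class"] == "transmigrated"])

    def test_scaling_fitted_on_train_only(self):
        """An extreme row in the held-out data must not alter the model or
        the predictions of other rows (no leakage)."""
        table = generate_feature_table(200, seed=12)
        split = split_train_test(table, 0.5, seed=12)
        model = train(split.train, MLPSpec(seed=12))
        np.testing.assert_allclose(
            model.scaler_mean_,
            split.train[list(model.feature_names_in_)].mean().to_numpy())
        test = split.test.copy()
        base = model.predict_proba(test.iloc[[0]])
        extreme = test.iloc[[1]].copy()
        extreme.loc[:, "Area"] = 1e6
        both = pd.concat([test.iloc[[0]], extreme], ignore_index=True)
        np.testing.assert_array_equal(model.predict_proba(both)[0], base[0])


class TestPersistence:
    def test_json_round_trip_replays_predictions_exactly(self, tmp_path):
        table = generate_feature_table(150, seed=13)
        model = train(table, MLPSpec(seed=13))
        path = tmp_path / "model.json"
        model.to_json(path)
        back = MLPMigrationClassifier.from_json(path)
        np.testing.assert_array_equal(model.predict_proba(table),
                                      back.predict_proba(table))
        np.testing.assert_array_equal(model.predict(table),
                                      back.predict(table))


class TestEvaluate:
    def test_perfect_predictions_identity_confusion(self):
        table = generate_feature_table(5, class_shift={"AR": 50.0}, seed=14)
        model = train(table, MLPSpec(seed=14, epochs=300))
        rep = evaluate(model, table)
        assert rep.n_test == 10
        assert int(np.trace(rep.confusion.to_numpy())) == rep.confusion.to_numpy().sum()
        assert rep.overall_accuracy == 1.0

    def test_counting_logic_on_constant_predictor(self):
        """5 A + 5 B all predicted A: recall 1.0 / 0.0, overall 0.5."""
        model = MLPMigrationClassifier()
        model.feature_names_in_ = np.asarray(["AR"], dtype=object)
        model.classes_ = np.asarray(["A", "B"], dtype=object)
        model.scaler_mean_ = np.zeros(1)
        model.scaler_scale_ = np.ones(1)
        model.coefs_ = [np.array([[0.0]])]
        model.intercepts_ = [np.array([-5.0])]  # sigmoid ~ 0 -> always class A
        table = pd.DataFrame({"AR": np.ones(10),
                              "class": ["A"] * 5 + ["B"] * 5})
        rep = evaluate(model, table)
        assert rep.per_class_accuracy["A"] == 1.0
        assert rep.per_class_accuracy["B"] == 0.0
        assert rep.overall_accuracy == 0.5
        assert rep.confusion.to_numpy().sum() == rep.n_test == 10

    def test_empty_test_table_rejected(self):
        table = generate_feature_table(20, seed=15)
        model = train(table, MLPSpec(seed=15))
        with pytest.raises(ValueError, match="empty"):
            evaluate(model, table.iloc[:0])


class TestFeatureRelevance:
    def test_ar_only_fixture_gives_positive_top_relevance(self):
        table = generate_feature_table(400, class_shift={"AR": 2.5}, seed=16)
        model = train(table, MLPSpec(seed=16))
        rel = feature_relevance(model, table)
        row = rel.table.set_index("feature")
        assert rel.sign_defined
        assert rel.ranking()[0] == "AR"
        assert row.loc["AR", "relevance"] > 0
        assert row.loc["AR", "permutation_importance"] == \
            row["permutation_importance"].max()

    def test_circ_only_fixture_gives_negative_relevance(self):
        table = generate_feature_table(400, class_shift={"Circ": -2.5},
                                       seed=17)
        model = train(table, MLPSpec(seed=17))
        rel = feature_relevance(model, table)
        row = rel.table.set_index("feature")
        assert rel.ranking()[0] == "Circ"
        assert row.loc["Circ", "relevance"] < 0

    def test_null_models_carry_little_relevance(self):
        """Models trained on label-shuffled data: the 20-seed mean of the
        maximum |relevance| stays under a quarter of the separable fixture's
        maximum."""
        sep_table = generate_feature_table(300, class_shift={"AR": 2.0},
                                           seed=18)
        sep = np.abs(feature_relevance(
            train(sep_table, MLPSpec(seed=18))).table["relevance"]).max()
        null_max = []
        for seed in range(20):
            table = generate_feature_table(300, class_shift={}, seed=seed)
            rng = np.random.default_rng(seed)
            table["class"] = rng.permutation(table["class"].to_numpy())
            model = train(table, MLPSpec(seed=seed))
            null_max.append(
                np.abs(feature_relevance(model).table["relevance"]).max())
        assert np.mean(null_max) < 0.25 * sep

    def test_multiclass_relevance_is_magnitude_only(self):
        table = three_class_table(150, seed=19)
        model = train(table, MLPSpec(seed=19))
        rel = feature_relevance(model)
        assert not rel.sign_defined
        assert (rel.table["relevance"] >= 0).all()


class TestBinaryVsMulticlass:
    def test_merging_predictions_never_lowers_merged_recall(self):
        table = three_class_table(200, seed=20)
        split = split_train_test(table, 0.5, seed=20)
        model = train(split.train, MLPSpec(seed=20))
        rep3 = evaluate(model, split.test)
        y_true = merge_to_binary(split.test["class"].to_numpy())
        y_pred = merge_to_binary(model.predict(split.test))
        merged_recall = ((y_pred == "attached_process")
                         & (y_true == "attached_process")).sum() \
            / (y_true == "attached_process").sum()
        # merging cannot lose correct calls: a prediction counted correct for
        # either sibling class stays correct after the merge, so the merged
        # recall is at least the size-weighted mean of the sibling recalls
        n = {cls: (split.test["class"] == cls).sum()
             for cls in ("attached", "in_process")}
        weighted = sum(n[c] * rep3.per_class_accuracy[c] for c in n) \
            / sum(n.values())
        assert merged_recall >= weighted - 1e-12


class TestBGA:
    def test_identical_distributions_show_no_group_structure(self):
        """With no class shift the between-group fraction sits at chance
        level, which for p standardized features and n samples is of order
        p / n (the top eigenvalue of the null centroid scatter)."""
        table = generate_feature_table(2000, class_shift={}, seed=21)
        res = bga_ordination(table)
        p, n = len(res.feature_names), len(table)
        assert res.between_variance_fraction < 5 * p / n  # ~0.019
        assert res.between_variance_fraction < 0.05

    def test_strong_single_feature_shift_dominates_first_axis(self):
        table = generate_feature_table(500, class_shift={"AR": 5.0}, seed=22)
        res = bga_ordination(table)
        loading = res.loadings[:, 0]
        ar_idx = res.feature_names.index("AR")
        assert abs(loading[ar_idx]) / np.linalg.norm(loading) > 0.9
        assert res.between_variance_fraction > 0.8

    def test_label_permutation_preserves_total_dispersion(self):
        table = generate_feature_table(300, seed=23)
        X = table[[c for c in FEATURE_NAMES]].to_numpy()
        y = table["class"].to_numpy(dtype=object)
        rng = np.random.default_rng(23)
        est1 = BetweenGroupOrdination().fit(X, y)
        est2 = BetweenGroupOrdination().fit(X, rng.permutation(y))
        # total dispersion of the standardized cloud is label-free
        z1 = (X - est1.mean_) / est1.scale_
        z2 = (X - est2.mean_) / est2.scale_
        assert np.allclose((z1 ** 2).mean(0).sum(), (z2 ** 2).mean(0).sum())
        assert est2.between_variance_fraction_ < est1.between_variance_fraction_

    def test_single_group_rejected(self):
        table = generate_feature_table(50, seed=24)
        with pytest.raises(ValueError, match="two groups"):
            bga_ordination(table[table["class"] == "transmigrated"])

    def test_transform_projects_new_samples(self):
        # three groups so two between-group axes exist (rank g - 1 = 2)
        table = three_class_table(100, seed=25)
        X = table[[c for c in FEATURE_NAMES]].to_numpy()
        y = table["class"].to_numpy(dtype=object)
        est = BetweenGroupOrdination(n_axes=2).fit(X, y)
        scores = est.transform(X[:5])
        assert scores.shape == (5, 2)
        np.testing.assert_allclose(scores, est.scores_[:5])

    def test_binary_table_keeps_single_axis(self):
        table = generate_feature_table(200, seed=25)
        res = bga_ordination(table)
        assert res.scores.shape[1] == 1
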