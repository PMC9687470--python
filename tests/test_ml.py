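import numpy as np
import pytest
from sklearn.metrics import roc_auc_score as _sk_auc

from acmgml.io_annotation import CRITERIA_ORDER, LabeledDataset, VariantKey
from acmgml.engine import CriterionVector
from acmgml.ml import (MLConfig, ModelSpec, N_FEATURES, confusion_and_metrics,
                       cross_validate, default_specs, evaluate_flat_three_class,
                       evaluate_tier, feature_importance, fit_tier,
                       predict_serial, relabel_for_tier, roc_auc, round2,
                       spearman_collinearity, split_train_test)
from acmgml.synthetic import (predictions_from_confusion,
                              reference_confusion_fixtures)


def make_labels(n_p, n_vus, n_b):
    return np.array(["P/LP"] * n_p + ["VUS"] * n_vus + ["B/LB"] * n_b,
                    dtype=object)


def pattern_dataset(labels, rng):
    """Features that deterministically encode the label (separable)."""
    X = np.zeros((len(labels), N_FEATURES), dtype=int)
    X[labels == "P/LP", 0] = 1       # PVS1 column
    X[labels == "B/LB", 11] = 1      # BS1 column
    X[:, 4] = rng.integers(0, 2, len(labels))   # irrelevant noise column
    return X


class TestRelabel:
    def test_tier1_pools_plp_and_blb_as_other(self):
        out = relabel_for_tier(["P/LP", "VUS", "B/LB"], 1)
        assert list(out) == ["other", "VUS", "other"]

    def test_tier1_other_count_on_full_mixture(self):
        labels = make_labels(173, 130, 194)
        out = relabel_for_tier(labels, 1)
        assert (out == "other").sum() == 367 and (out == "VUS").sum() == 130

    def test_tier2_rejects_vus_and_empty_passes_through(self):
        with pytest.raises(ValueError):
            relabel_for_tier(["VUS"], 2)
        assert list(relabel_for_tier([], 1)) == []
        assert list(relabel_for_tier(["P/LP", "B/LB"], 2)) == ["P/LP", "B/LB"]


class TestSplit:
    @pytest.mark.parametrize("n_p,n_vus,n_b,test_size", [
        (173, 130, 194, 100),    # full cohort -> printed support 100
        (173, 0, 194, 74),       # non-VUS subset -> printed support 74
    ])
    def test_test_partition_sizes_match_printed_supports(self, n_p, n_vus,
                                                         n_b, test_size):
        labels = make_labels(n_p, n_vus, n_b)
        X = np.zeros((len(labels), N_FEATURES))
        cfg = MLConfig(seed=0)
        X_tr, X_te, y_tr, y_te = split_train_test(X, labels, cfg)
        assert len(y_te) == test_size
        assert len(y_tr) + len(y_te) == len(labels)

    def test_split_is_stratified_and_deterministic(self):
        labels = make_labels(40, 30, 30)
        X = np.arange(100 * N_FEATURES).reshape(100, -1)
        cfg = MLConfig(seed=5)
        _, X_te1, _, y_te1 = split_train_test(X, labels, cfg)
        _, X_te2, _, y_te2 = split_train_test(X, labels, cfg)
        assert np.array_equal(X_te1, X_te2) and np.array_equal(y_te1, y_te2)
        # stratified: class shares preserved within one row
        assert abs((y_te1 == "P/LP").sum() - 8) <= 1

    def test_singleton_class_cannot_stratify(self):
        labels = np.array(["P/LP"] * 10 + ["VUS"], dtype=object)
        with pytest.raises(ValueError):
            split_train_test(np.zeros((11, N_FEATURES)), labels, MLConfig())


class TestCrossValidate:
    def test_separable_features_reach_full_accuracy(self):
        rng = np.random.default_rng(0)
        labels = make_labels(30, 0, 30)
        y = relabel_for_tier(labels, 2)
        X = pattern_dataset(labels, rng)
        cfg = MLConfig(seed=0, cv_repeats=2)
        out = cross_validate(default_specs()["CART"], X, y, cfg)
        assert out["mean_accuracy"] == 1.0

    def test_fold_bookkeeping(self):
        X = np.zeros((4, N_FEATURES))
        X[:2, 0] = 1
        y = np.array(["a", "a", "b", "b"], dtype=object)
        cfg = MLConfig(seed=0, cv_folds=2, cv_repeats=1)
        out = cross_validate(default_specs()["CART"], X, y, cfg)
        assert out["n_folds"] == 2

    def test_uninformative_features_score_near_chance(self):
        rng = np.random.default_rng(1)
        y = np.array((["a", "b"] * 30), dtype=object)
        X = rng.integers(0, 2, (60, N_FEATURES))
        cfg = MLConfig(seed=0, cv_repeats=20)
        out = cross_validate(default_specs()["LR"], X, y, cfg)
        assert 0.3 < out["mean_accuracy"] < 0.7


class TestTierModels:
    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("GBM")

    def test_degenerate_single_class_training_set(self):
        X = np.zeros((5, N_FEATURES))
        with pytest.raises(ValueError, match="single-class"):
            fit_tier(default_specs()["LR"], X, ["a"] * 5, 1)

    def test_rf_memorizes_separable_training_data(self):
        rng = np.random.default_rng(2)
        labels = make_labels(40, 0, 40)
        y = relabel_for_tier(labels, 2)
        X = pattern_dataset(labels, rng)
        m = fit_tier(default_specs()["RF"], X, y, 2, seed=0)
        assert (m.predict(X) == y).mean() == 1.0

    def test_feature_width_enforced(self):
        with pytest.raises(ValueError, match="17"):
            fit_tier(default_specs()["LR"], np.zeros((4, 5)),
                     ["a", "b", "a", "b"], 1)


class TestSerialPrediction:
    def _models(self, rng):
        labels = make_labels(40, 40, 40)
        X = pattern_dataset(labels, rng)
        m1 = fit_tier(default_specs()["CART"], X, relabel_for_tier(labels, 1), 1)
        keep = labels != "VUS"
        m2 = fit_tier(default_specs()["CART"], X[keep],
                      relabel_for_tier(labels[keep], 2), 2)
        return m1, m2, X, labels

    def test_perfect_models_recover_true_labels(self):
        m1, m2, X, labels = self._models(np.random.default_rng(3))
        assert (predict_serial(m1, m2, X) == labels).all()

    def test_tier1_vus_rows_never_reach_tier2(self):
        m1, m2, X, labels = self._models(np.random.default_rng(4))
        vus_rows = X[labels == "VUS"]
        assert (predict_serial(m1, m2, vus_rows) == "VUS").all()

    def test_empty_input_and_tier_order_checks(self):
        m1, m2, X, _ = self._models(np.random.default_rng(5))
        assert len(predict_serial(m1, m2, X[:0])) == 0
        with pytest.raises(ValueError):
            predict_serial(m2, m1, X)
        with pytest.raises(ValueError):
            predict_serial(m1, m2, X[:, :5])


class TestMetrics:
    @pytest.mark.parametrize("fixture", reference_confusion_fixtures(),
                             ids=lambda f: f["name"])
    def test_worked_example_confusion_matrices(self, fixture):
        """Every published per-class and weighted metric must be recovered
        from its confusion matrix at display rounding."""
        truth, pred = predictions_from_confusion(
            fixture["confusion"], fixture["class_order"])
        rep = confusion_and_metrics(pred, truth, fixture["class_order"])
        assert np.array_equal(rep.confusion, fixture["confusion"])
        assert round2(rep.accuracy) == fixture["accuracy"]
        for cls, expected in fixture["per_class"].items():
            row = rep.per_class.loc[cls]
            assert row["support"] == expected["support"]
            for metric in ("precision", "recall", "specificity", "f1"):
                assert round2(row[metric]) == expected[metric], (cls, metric)
        for metric, value in fixture["weighted"].items():
            assert round2(rep.weighted[metric]) == value

    def test_perfect_predictions_score_one(self):
        y = np.array(["a", "b", "a"], dtype=object)
        rep = confusion_and_metrics(y, y, ["a", "b"])
        assert rep.accuracy == 1.0
        assert (rep.per_class[["precision", "recall", "f1"]] == 1.0).all().all()

    def test_weighted_metrics_are_support_weighted_means(self):
        rng = np.random.default_rng(6)
        classes = ["x", "y", "z"]
        for _ in range(50):
            truth = rng.choice(classes, 60)
            pred = rng.choice(classes, 60)
            rep = confusion_and_metrics(pred.astype(object),
                                        truth.astype(object), classes)
            support = rep.per_class["support"].to_numpy(float)
            for m in ("precision", "recall", "specificity", "f1"):
                manual = float(np.average(rep.per_class[m], weights=support))
                assert rep.weighted[m] == pytest.approx(manual)
            # accuracy is the support-weighted recall, by identity
            assert rep.accuracy == pytest.approx(rep.weighted["recall"])

    def test_length_mismatch_and_unknown_labels(self):
        with pytest.raises(ValueError):
            confusion_and_metrics(["a"], ["a", "b"], ["a", "b"])
        with pytest.raises(ValueError):
            confusion_and_metrics(["q"], ["a"], ["a", "b"])


class TestROC:
    def test_textbook_cases(self):
        auc, _ = roc_auc([0.1, 0.9], [0, 1])
        assert auc == 1.0
        auc, _ = roc_auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])
        assert auc == 0.5
        auc, _ = roc_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])
        assert auc == 0.75   # 3 of 4 pos-neg pairs concordant, one discordant

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        scores = rng.uniform(size=40)
        truth = rng.integers(0, 2, 40)
        truth[0], truth[1] = 0, 1
        base, _ = roc_auc(scores, truth)
        for f in (lambda s: 2 * s + 1, np.exp, lambda s: s ** 3):
            assert roc_auc(f(scores), truth)[0] == pytest.approx(base)

    def test_matches_sklearn_and_rejects_single_class(self):
        rng = np.random.default_rng(8)
        scores = rng.uniform(size=50)
        truth = rng.integers(0, 2, 50)
        truth[:2] = [0, 1]
        ours, _ = roc_auc(scores, truth)
        assert ours == pytest.approx(_sk_auc(truth, scores))
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestSpearman:
    def test_self_and_complement_correlations(self):
        rng = np.random.default_rng(9)
        col = rng.integers(0, 2, 50)
        F = np.zeros((50, N_FEATURES), dtype=int)
        F[:, 0] = col
        F[:, 1] = col
        F[:, 2] = 1 - col
        matrix, flagged = spearman_collinearity(F, MLConfig())
        names = list(CRITERIA_ORDER)
        assert matrix.loc[names[0], names[0]] == pytest.approx(1.0)
        assert matrix.loc[names[0], names[1]] == pytest.approx(1.0)
        assert matrix.loc[names[0], names[2]] == pytest.approx(-1.0)
        flagged_pairs = {(a, b) for a, b, _ in flagged}
        assert (names[0], names[1]) in flagged_pairs

    def test_direct_rank_formula_oracle_on_small_joint_table(self):
        # joint distribution: (0,0)x4, (0,1)x1, (1,0)x2, (1,1)x5
        a = np.array([0] * 5 + [1] * 7, dtype=float)
        b = np.array([0] * 4 + [1] + [0] * 2 + [1] * 5, dtype=float)
        F = np.zeros((12, N_FEATURES))
        F[:, 0], F[:, 1] = a, b
        matrix, _ = spearman_collinearity(F, MLConfig())

        def rank_avg(x):
            order = np.argsort(x, kind="stable")
            ranks = np.empty(len(x))
            ranks[order] = np.arange(1, len(x) + 1)
            for val in np.unique(x):
                ranks[x == val] = ranks[x == val].mean()
            return ranks

        ra, rb = rank_avg(a), rank_avg(b)
        rho = (np.mean(ra * rb) - ra.mean() * rb.mean()) / (ra.std() * rb.std())
        assert matrix.iloc[0, 1] == pytest.approx(rho, abs=1e-12)

    def test_constant_columns_undefined_and_never_flagged(self):
        F = np.zeros((30, N_FEATURES))
        F[:, 0] = np.arange(30) % 2
        matrix, flagged = spearman_collinearity(F, MLConfig())
        assert np.isnan(matrix.iloc[1, 2])
        assert all("PM1" not in pair[:2] for pair in flagged)


class TestFeatureImportance:
    def _fitted(self, rng):
        labels = make_labels(40, 0, 40)
        y = relabel_for_tier(labels, 2)
        X = pattern_dataset(labels, rng)
        return fit_tier(default_specs()["RF"], X, y, 2, seed=0), X

    def test_constant_features_attribute_zero_and_are_droppable(self):
        model, X = self._fitted(np.random.default_rng(10))
        imp = feature_importance(model, X, MLConfig(seed=0))
        table = imp.set_index("feature")
        constant = [c for i, c in enumerate(CRITERIA_ORDER)
                    if X[:, i].min() == X[:, i].max()]
        assert (table.loc[constant, "mean_abs_shap"] == 0.0).all()
        assert table.loc[constant, "droppable"].all()

    def test_decisive_feature_dominates_ranking(self):
        model, X = self._fitted(np.random.default_rng(11))
        imp = feature_importance(model, X, MLConfig(seed=0))
        assert imp.iloc[0]["feature"] in ("PVS1", "BS1")
        assert imp.attrs["method"] == "exact"


class TestExperimentDrivers:
    def _dataset(self, labels, rng):
        X = pattern_dataset(labels, rng)
        keys = [VariantKey.make("17", 41_000_000 + i, "A", "G")
                for i in range(len(labels))]
        vectors = [CriterionVector.from_mapping(dict(zip(CRITERIA_ORDER, row)))
                   for row in X]
        return LabeledDataset(keys=keys, vectors=vectors, labels=list(labels))

    def test_separable_dataset_reaches_full_accuracy_on_both_tiers(self):
        rng = np.random.default_rng(12)
        ds = self._dataset(make_labels(40, 30, 40), rng)
        cfg = MLConfig(seed=0, cv_repeats=1)
        specs = {k: default_specs()[k] for k in ("CART", "RF")}
        rep1 = evaluate_tier(ds, 1, cfg, specs)
        rep2 = evaluate_tier(ds, 2, cfg, specs)
        assert rep1["best_test_accuracy"] == 1.0
        assert rep2["best_test_accuracy"] == 1.0

    def test_flat_three_class_support_and_separable_accuracy(self):
        rng = np.random.default_rng(13)
        ds = self._dataset(make_labels(40, 30, 40), rng)
        cfg = MLConfig(seed=0, cv_repeats=1)
        rep = evaluate_flat_three_class(default_specs()["CART"], ds, cfg)
        assert int(rep.per_class["support"].sum()) == 22   # ceil(0.2 * 110)
        assert rep.accuracy == 1.0
        assert rep.confusion.shape == (3, 3)

    def test_shuffled_labels_score_near_majority_rate(self):
        rng = np.random.default_rng(14)
        labels = make_labels(40, 30, 40)
        shuffled = labels.copy()
        rng.shuffle(shuffled)
        X = pattern_dataset(labels, rng)   # features encode the *unshuffled* labels
        keys = [VariantKey.make("17", 41_000_000 + i, "A", "G")
                for i in range(len(labels))]
        vectors = [CriterionVector.from_mapping(dict(zip(CRITERIA_ORDER, row)))
                   for row in X]
        ds = LabeledDataset(keys=keys, vectors=vectors, labels=list(shuffled))
        rep = evaluate_flat_three_class(default_specs()["CART"], ds,
                                        MLConfig(seed=0, cv_repeats=1))
        assert rep.accuracy < 0.65
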