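import numpy as np
import pandas as pd
import pytest

from cvmstage import modeling as mod
from cvmstage.datamodel import LabeledDataset

from conftest import make_dataset


class TestStratifiedSplit:
    def test_exact_70_30_per_stage(self):
        ds = make_dataset(n_per_stage=100)
        train, test = mod.stratified_split(ds, mod.SplitSpec(seed=1))
        assert train.stage_counts().tolist() == [70] * 6
        assert test.stage_counts().tolist() == [30] * 6

    def test_small_stage_rounding(self):
        ds = make_dataset(n_per_stage=10)
        train, test = mod.stratified_split(ds, mod.SplitSpec(seed=1))
        assert train.stage_counts().tolist() == [7] * 6
        assert test.stage_counts().tolist() == [3] * 6

    def test_deterministic_and_disjoint(self):
        ds = make_dataset(n_per_stage=25)
        t1, e1 = mod.stratified_split(ds, mod.SplitSpec(seed=3))
        t2, e2 = mod.stratified_split(ds, mod.SplitSpec(seed=3))
        assert list(t1.X.index) == list(t2.X.index)
        assert set(t1.X.index).isdisjoint(e1.X.index)
        assert set(t1.X.index) | set(e1.X.index) == set(ds.X.index)

    def test_singleton_stage_goes_to_train(self):
        ds = make_dataset(n_per_stage=5)
        keep = [s for s in ds.X.index if not (ds.y[s] == 6 and
                                              s != ds.y.index[ds.y == 6][0])]
        small = ds.subset(keep)
        with pytest.warns(UserWarning, match="single subject"):
            train, test = mod.stratified_split(small, mod.SplitSpec(seed=0))
        assert train.stage_counts()[6] == 1
        assert test.stage_counts()[6] == 0


class TestSelectFeatures:
    def test_perfect_predictor_beats_noise(self):
        rng = np.random.default_rng(0)
        stages = np.repeat(np.arange(1, 7), 40)
        X = pd.DataFrame({
            "copy": stages.astype(float),
            "noise": rng.normal(size=len(stages)),
        }, index=pd.Index([f"S{i}" for i in range(len(stages))],
                          name="subject_id"))
        ds = LabeledDataset("Rater1", X, pd.Series(stages, index=X.index))
        sel = mod.select_features(ds, n_trees=100, seed=0)
        assert sel.selected == ["copy"]
        assert sel.importances.sum() == pytest.approx(1.0)

    def test_duplicated_informative_features_both_kept(self):
        rng = np.random.default_rng(1)
        stages = np.repeat(np.arange(1, 7), 50)
        sig = stages + rng.normal(0, 0.4, len(stages))
        X = pd.DataFrame({
            "sig_a": sig, "sig_b": sig,
            "noise1": rng.normal(size=len(stages)),
            "noise2": rng.normal(size=len(stages)),
        }, index=pd.Index([f"S{i}" for i in range(len(stages))],
                          name="subject_id"))
        ds = LabeledDataset("Rater1", X, pd.Series(stages, index=X.index))
        sel = mod.select_features(ds, n_trees=400, seed=0)
        assert {"sig_a", "sig_b"} <= set(sel.selected)

    def test_top_k_rule(self):
        ds = make_dataset(n_per_stage=20)
        sel = mod.select_features(ds, n_trees=50, threshold_rule="top_k",
                                  top_k=1, seed=0)
        assert sel.selected == ["signal"]

    def test_constant_label_rejected(self):
        ds = make_dataset(n_per_stage=10)
        const = LabeledDataset("Rater1", ds.X,
                               pd.Series(3, index=ds.X.index))
        with pytest.raises(ValueError, match="constant"):
            mod.select_features(const)


class TestTuneAndTrain:
    def test_separable_data_high_cv_accuracy(self):
        ds = make_dataset(n_per_stage=30, seed=1)
        train, _ = mod.stratified_split(ds, mod.SplitSpec(seed=0))
        model = mod.tune_and_train(train, "LogReg", search_budget=5,
                                   cv_folds=3, seed=0)
        assert model.cv_accuracy > 0.9

    def test_shuffled_labels_give_chance_accuracy(self):
        ds = make_dataset(n_per_stage=40, seed=2)
        rng = np.random.default_rng(0)
        y_perm = pd.Series(rng.permutation(ds.y.to_numpy()),
                           index=ds.y.index)
        shuffled = LabeledDataset(ds.provenance, ds.X, y_perm)
        train, test = mod.stratified_split(shuffled, mod.SplitSpec(seed=0))
        model = mod.tune_and_train(train, "KNeighbors", search_budget=5,
                                   cv_folds=3, seed=0)
        rep = mod.evaluate(model, test)
        p, n = 1 / 6, len(test)
        assert abs(rep.test_accuracy - p) < 4 * np.sqrt(p * (1 - p) / n)

    def test_fixed_seed_fixes_hyperparameters(self):
        ds = make_dataset(n_per_stage=15)
        train, _ = mod.stratified_split(ds, mod.SplitSpec(seed=0))
        m1 = mod.tune_and_train(train, "SVM", search_budget=8, cv_folds=2,
                                seed=7)
        m2 = mod.tune_and_train(train, "SVM", search_budget=8, cv_folds=2,
                                seed=7)
        assert m1.params == m2.params

    def test_budget_floor(self):
        ds = make_dataset(n_per_stage=10)
        with pytest.raises(ValueError, match="budget"):
            mod.tune_and_train(ds, "LogReg", search_budget=0)

    def test_unknown_family(self):
        with pytest.raises(ValueError, match="unknown family"):
            mod.search_space("DeepNet")


class TestEvaluate:
    def test_accuracy_and_confusion_identity(self):
        ds = make_dataset(n_per_stage=20, seed=3)
        train, test = mod.stratified_split(ds, mod.SplitSpec(seed=0))
        model = mod.tune_and_train(train, "RForest", search_budget=3,
                                   cv_folds=2, seed=0)
        rep = mod.evaluate(model, test)
        assert np.trace(rep.confusion.to_numpy()) / rep.confusion.to_numpy(
            ).sum() == pytest.approx(rep.test_accuracy)
        assert rep.confusion.to_numpy().sum(axis=1).tolist() == \
            test.stage_counts().tolist()

    def test_empty_test_rejected(self):
        ds = make_dataset(n_per_stage=10)
        train, test = mod.stratified_split(ds, mod.SplitSpec(seed=0))
        model = mod.tune_and_train(train, "LogReg", search_budget=2,
                                   cv_folds=2, seed=0)
        with pytest.raises(ValueError, match="empty"):
            mod.evaluate(model, test.subset([]))

    def test_feature_schema_guard(self):
        ds = make_dataset(n_per_stage=10)
        train, test = mod.stratified_split(ds, mod.SplitSpec(seed=0))
        model = mod.tune_and_train(train, "LogReg", search_budget=2,
                                   cv_folds=2, seed=0)
        bad = test.X.rename(columns={"signal": "other"})
        with pytest.raises(ValueError, match="lacks features"):
            model.predict(bad)


class TestPickTopModel:
    def _report(self, family, acc, n_features=5):
        return mod.ModelReport(family=family, provenance="Rater1", params={},
                               cv_accuracy=acc, test_accuracy=acc,
                               confusion=pd.DataFrame(), n_features=n_features)

    def test_argmax(self):
        reports = [self._report(f, a) for f, a in
                   zip(mod.FAMILIES, (0.5, 0.6, 0.7, 0.8, 0.9, 0.65))]
        assert mod.pick_top_model(reports).family == "SVM"

    def test_tie_broken_by_family_order_and_flagged(self):
        reports = [self._report("SVM", 0.8), self._report("LogReg", 0.8)]
        top = mod.pick_top_model(reports)
        assert top.family == "LogReg"
        assert top.tie

    def test_no_information_leak_from_test_rows(self):
        # the fitted model is a function of the training split only
        ds = make_dataset(n_per_stage=20, seed=4)
        train, test = mod.stratified_split(ds, mod.SplitSpec(seed=0))
        m1 = mod.tune_and_train(train, "LogReg", search_budget=3,
                                cv_folds=2, seed=1)
        rng = np.random.default_rng(0)
        y_perm = pd.Series(rng.permutation(test.y.to_numpy()),
                           index=test.y.index)
        scrambled = LabeledDataset(ds.provenance, test.X, y_perm)
        np.testing.assert_array_equal(m1.predict(test.X),
                                      m1.predict(scrambled.X))
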