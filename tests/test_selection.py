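import numpy as np
import pandas as pd
import pytest

from crosstalk_mir import (baseline_classifier, mccv_split, pair_auc, run_mccv)


@pytest.fixture()
def separable():
    """12+12 samples; one perfectly separating feature, one noise feature."""
    rng = np.random.default_rng(0)
    samples = [f"t{i}" for i in range(12)] + [f"n{i}" for i in range(12)]
    labels = pd.Series(["tumor"] * 12 + ["normal"] * 12, index=samples)
    ds = pd.DataFrame({
        "A|B": np.r_[rng.normal(5, 0.3, 12), rng.normal(-5, 0.3, 12)],
        "A|C": rng.normal(0, 1, 24),
    }, index=samples)
    return ds, labels


class TestMCCVSplit:
    def _samples(self, nt=10, nn=10):
        samples = [f"t{i}" for i in range(nt)] + [f"n{i}" for i in range(nn)]
        labels = pd.Series(["tumor"] * nt + ["normal"] * nn, index=samples)
        return samples, labels

    def test_stratified_arithmetic(self):
        samples, labels = self._samples()
        train, test = mccv_split(samples, labels, 0.6, seed=1)
        assert len(train) == 12 and len(test) == 8
        assert sum(labels[s] == "tumor" for s in train) == 6
        assert sum(labels[s] == "tumor" for s in test) == 4

    def test_deterministic_under_seed(self):
        samples, labels = self._samples()
        assert mccv_split(samples, labels, seed=7) == mccv_split(
            samples, labels, seed=7)

    def test_disjoint_and_exhaustive(self):
        samples, labels = self._samples(9, 7)
        train, test = mccv_split(samples, labels, 0.6, seed=3)
        assert set(train) & set(test) == set()
        assert sorted(train + test) == sorted(samples)

    def test_full_train_fraction_rejected(self):
        samples, labels = self._samples()
        with pytest.raises(ValueError):
            mccv_split(samples, labels, train_frac=1.0)

    def test_tiny_class_rejected(self):
        samples, labels = self._samples(1, 10)
        with pytest.raises(ValueError):
            mccv_split(samples, labels)


class TestPairAUC:
    def test_separable_feature_near_one(self, separable):
        ds, labels = separable
        auc = pair_auc(ds["A|B"], labels, k=5, ntree=50, seed=0)
        assert auc > 0.95

    def test_permuted_labels_near_half(self, separable):
        ds, labels = separable
        rng = np.random.default_rng(4)
        aucs = []
        for rep in range(5):
            perm = pd.Series(rng.permutation(labels.to_numpy()),
                             index=labels.index)
            aucs.append(pair_auc(ds["A|B"], perm, k=5, ntree=50, seed=rep))
        assert abs(np.mean(aucs) - 0.5) < 0.15

    def test_negated_feature_same_auc(self, separable):
        ds, labels = separable
        a = pair_auc(ds["A|B"], labels, k=5, ntree=50, seed=0)
        b = pair_auc(-ds["A|B"], labels, k=5, ntree=50, seed=0)
        assert a == pytest.approx(b, abs=0.05)

    def test_constant_feature_returns_half(self, separable):
        ds, labels = separable
        const = pd.Series(1.0, index=ds.index)
        assert pair_auc(const, labels) == 0.5


class TestRunMCCV:
    def test_single_bootstrap_frequencies_one(self, separable):
        ds, labels = separable
        boots, agg = run_mccv(ds, labels, n_bootstraps=1, k=3, ntree=20, seed=0)
        assert (agg["frequency"] == 1).all()

    def test_zero_bootstraps_empty(self, separable):
        ds, labels = separable
        boots, agg = run_mccv(ds, labels, n_bootstraps=0)
        assert boots == [] and len(agg) == 0

    def test_train_test_disjoint_every_bootstrap(self, separable):
        ds, labels = separable
        boots, _ = run_mccv(ds, labels, n_bootstraps=3, k=3, ntree=20, seed=5)
        for b in boots:
            assert set(b.train_samples) & set(b.test_samples) == set()

    def test_frequency_sum_rule(self):
        # 12 pairs >= top-10 cut: total frequency = n_bootstraps * 10
        rng = np.random.default_rng(2)
        samples = [f"t{i}" for i in range(8)] + [f"n{i}" for i in range(8)]
        labels = pd.Series(["tumor"] * 8 + ["normal"] * 8, index=samples)
        ds = pd.DataFrame(rng.normal(size=(16, 12)),
                          index=samples,
                          columns=[f"P{i}|Q{i}" for i in range(12)])
        boots, agg = run_mccv(ds, labels, n_bootstraps=3, k=3, ntree=10, seed=1)
        assert agg["frequency"].sum() == 3 * 10

    def test_separable_pair_tops_ranking(self, separable):
        ds, labels = separable
        _, agg = run_mccv(ds, labels, n_bootstraps=3, k=3, ntree=30, seed=2)
        assert agg["pair"].iloc[0] == "A|B"
        assert agg["mean_test_auc"].iloc[0] > 0.9

    def test_deterministic_under_seed(self, separable):
        ds, labels = separable
        _, a = run_mccv(ds, labels, n_bootstraps=2, k=3, ntree=20, seed=9)
        _, b = run_mccv(ds, labels, n_bootstraps=2, k=3, ntree=20, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestBaselineClassifier:
    def test_empty_subset_rejected(self, separable):
        _, labels = separable
        with pytest.raises(ValueError):
            baseline_classifier(pd.DataFrame(), labels)

    def test_duplicated_features_identical_aucs(self, separable):
        ds, labels = separable
        expr = pd.DataFrame({"f1": ds["A|B"], "f2": ds["A|B"]}).T
        boots, _ = baseline_classifier(expr, labels, k=3, ntree=20,
                                       n_bootstraps=1, seed=0)
        aucs = boots[0].train_auc
        assert aucs["f1"] == pytest.approx(aucs["f2"])

    def test_separable_feature_wins(self, separable):
        ds, labels = separable
        expr = ds.T  # features x samples
        _, agg = baseline_classifier(expr, labels, k=3, ntree=30,
                                     n_bootstraps=2, seed=1)
        assert agg["pair"].iloc[0] == "A|B"
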