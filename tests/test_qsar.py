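"""Split plan, metric suite and the under-sampling ensemble."""

import numpy as np
import pandas as pd
import pytest

from hergscreen import qsar
from hergscreen.errors import QSARError


def _labels(n_active, n_inactive, seed=0):
    ids = [f"A{i}" for i in range(n_active)] + [f"I{i}" for i in range(n_inactive)]
    return pd.Series([True] * n_active + [False] * n_inactive, index=ids)


class TestMakeSplit:
    def test_split_arithmetic_549_actives_gives_467_training(self):
        labels = _labels(549, 6598)
        plan = qsar.make_split(labels, test_frac=0.15, seed=0)
        train = labels.loc[plan.train_ids]
        assert int(train.sum()) == 467
        assert set(plan.train_ids).isdisjoint(plan.test_ids)
        assert len(plan.train_ids) + len(plan.test_ids) == 7147

    def test_inactive_subsets_cover_training_inactives(self):
        labels = _labels(100, 900, seed=1)
        plan = qsar.make_split(labels, seed=1)
        train_inact = {i for i in plan.train_ids if not labels[i]}
        union = set().union(*map(set, plan.inactive_subsets))
        assert union == train_inact
        # each subset targets the 75/25 ratio: 3x the training actives
        n_train_act = sum(labels[i] for i in plan.train_ids)
        for s in plan.inactive_subsets:
            assert len(s) == 3 * n_train_act
            assert len(set(s)) == len(s)

    def test_seeded_determinism(self):
        labels = _labels(60, 300)
        p1 = qsar.make_split(labels, seed=7)
        p2 = qsar.make_split(labels, seed=7)
        assert p1.train_ids == p2.train_ids and p1.test_ids == p2.test_ids
        assert [list(s) for s in p1.inactive_subsets] == [list(s) for s in p2.inactive_subsets]

    def test_tiny_class_raises(self):
        with pytest.raises(QSARError):
            qsar.make_split(_labels(4, 100))


class TestMetrics:
    def test_hand_worked_confusion(self):
        # TP=3 TN=4 FP=1 FN=2
        y_true = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        y_pred = [1, 1, 1, 0, 0, 1, 0, 0, 0, 0]
        m = qsar.compute_metrics(y_true, y_pred)
        assert (m.TP, m.TN, m.FP, m.FN) == (3, 4, 1, 2)
        assert m.SE == pytest.approx(0.6)
        assert m.SP == pytest.approx(0.8)
        assert m.Q == pytest.approx(0.7)
        assert m.Qb == pytest.approx(0.7)
        assert m.MCC == pytest.approx(10 / np.sqrt(600))

    def test_perfect_and_degenerate_predictions(self):
        y = [1, 0, 1, 0]
        assert qsar.compute_metrics(y, y).MCC == pytest.approx(1.0)
        assert qsar.compute_metrics(y, y).Qb == pytest.approx(1.0)
        assert qsar.compute_metrics(y, [1, 1, 1, 1]).MCC == 0.0

    def test_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = rng.integers(2, 40)
            y_true = rng.integers(0, 2, n)
            y_pred = rng.integers(0, 2, n)
            m = qsar.compute_metrics(y_true, y_pred)
            # independent element-by-element tally
            tp = sum(1 for a, b in zip(y_true, y_pred) if a == 1 and b == 1)
            tn = sum(1 for a, b in zip(y_true, y_pred) if a == 0 and b == 0)
            fp = sum(1 for a, b in zip(y_true, y_pred) if a == 0 and b == 1)
            fn = sum(1 for a, b in zip(y_true, y_pred) if a == 1 and b == 0)
            assert (m.TP, m.TN, m.FP, m.FN) == (tp, tn, fp, fn)
            se = tp / (tp + fn) if tp + fn else 0.0
            sp = tn / (tn + fp) if tn + fp else 0.0
            assert m.SE == pytest.approx(se) and m.SP == pytest.approx(sp)
            assert m.Q == pytest.approx((tp + tn) / n)
            assert m.Qb == pytest.approx((se + sp) / 2, abs=1e-12)
            denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
            assert m.MCC == pytest.approx(mcc, abs=1e-12)

    def test_empty_input_raises(self):
        with pytest.raises(QSARError):
            qsar.compute_metrics([], [])


SMALL_GRIDS = {
    "CART": {"ccp_alpha": [0.01]},
    "NN": {"hidden_layer_sizes": [(16,)]},
    "DNN": {"alpha": [1e-4]},
    "SVM_linear": {"C": [1]},
    "SVM_radial": {"C": [1, 10]},
    "SVM_sigmoid": {"C": [0.1, 1, 10]},
    "RF": {"n_estimators": [200]},
    "LDA": {},
}


class TestTrainBundle:
    @pytest.fixture(scope="class")
    def trained(self, labelled_descriptors):
        X, labels = labelled_descriptors
        plan = qsar.make_split(labels, seed=5)
        bundle = qsar.train_bundle(X, labels, "RF", plan, cv_folds=4,
                                   grid=SMALL_GRIDS["RF"], seed=5)
        return X, labels, plan, bundle

    def test_ensemble_probabilities_in_unit_interval(self, trained):
        X, _, _, bundle = trained
        p = bundle.predict_proba(X)
        assert ((0 <= p) & (p <= 1)).all()

    def test_metrics_reported_per_submodel_with_qb_identity(self, trained):
        _, _, plan, bundle = trained
        for split in ("cv", "fit", "test"):
            df = bundle.metrics[split]
            assert len(df) == plan.n_submodels
            np.testing.assert_allclose(df["Qb"], (df["SE"] + df["SP"]) / 2, atol=1e-12)

    def test_scaler_never_sees_test_rows(self, trained):
        X, _, plan, bundle = trained
        expected = X.loc[plan.train_ids].mean().to_numpy()
        np.testing.assert_allclose(bundle.scaler.mean_, expected, rtol=1e-10)

    def test_undersampling_disabled_trains_single_model(self, labelled_descriptors):
        X, labels = labelled_descriptors
        plan = qsar.make_split(labels, seed=2)
        bundle = qsar.train_bundle(X, labels, "RF", plan, cv_folds=3,
                                   grid=SMALL_GRIDS["RF"], undersample=False, seed=2)
        assert len(bundle.models) == 1

    def test_manifest_mismatch_raises(self, trained):
        X, _, _, bundle = trained
        with pytest.raises(QSARError):
            bundle.predict_proba(X.iloc[:, :-1])

    @pytest.mark.parametrize("algorithm", sorted(SMALL_GRIDS))
    def test_every_algorithm_beats_its_permuted_baseline(
            self, algorithm, labelled_descriptors):
        # planted-signal labels vs label-permuted baseline, margin >= 0.3
        X, labels = labelled_descriptors
        plan = qsar.make_split(labels, seed=13)
        bundle = qsar.train_bundle(X, labels, algorithm, plan, cv_folds=4,
                                   grid=SMALL_GRIDS[algorithm],
                                   undersample=False, seed=13)
        rng = np.random.default_rng(13)
        perm = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
        null = qsar.train_bundle(X, perm, algorithm, plan, cv_folds=4,
                                 grid=SMALL_GRIDS[algorithm],
                                 undersample=False, seed=13)
        signal = bundle.metrics["cv"]["MCC"].mean()
        baseline = null.metrics["cv"]["MCC"].mean()
        assert signal >= baseline + 0.3


class TestConsensus:
    class _Stub:
        def __init__(self, prob, names):
            self.feature_names = names
            self._p = prob

        def predict_proba(self, X):
            return np.full(len(X), self._p)

    def test_mean_probability_and_tie_rule(self):
        X = pd.DataFrame(np.zeros((3, 2)), columns=["a", "b"])
        out = qsar.consensus_predict({"RF": self._Stub(0.8, ["a", "b"]),
                                      "DNN": self._Stub(0.4, ["a", "b"])}, X)
        assert out["consensus_prob"].tolist() == pytest.approx([0.6] * 3)
        assert out["call"].all()  # 0.6 >= 0.5
        tie = qsar.consensus_predict({"RF": self._Stub(0.5, ["a", "b"]),
                                      "DNN": self._Stub(0.5, ["a", "b"])}, X)
        assert tie["call"].all()  # exact 0.5 calls active

    def test_identical_bundles_equal_either(self):
        X = pd.DataFrame(np.zeros((2, 1)), columns=["a"])
        out = qsar.consensus_predict({"RF": self._Stub(0.3, ["a"]),
                                      "DNN": self._Stub(0.3, ["a"])}, X)
        assert out["consensus_prob"].tolist() == pytest.approx([0.3, 0.3])

    def test_manifest_mismatch_raises(self):
        X = pd.DataFrame(np.zeros((2, 1)), columns=["a"])
        with pytest.raises(QSARError):
            qsar.consensus_predict({"RF": self._Stub(0.3, ["a"]),
                                    "DNN": self._Stub(0.3, ["b"])}, X)
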