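"""Class weighting, weighted BCE, stratified folds, and the training
loop's determinism and progress."""

import numpy as np
import pytest

import pssmrnn as pr


class TestInverseClassFrequencyWeights:
    def test_balanced_gives_unit_weights(self):
        w_pos, w_neg = pr.inverse_class_frequency_weights(np.array([1, 0, 1, 0]))
        assert w_pos == w_neg == 1.0

    def test_ratio_equals_inverse_frequency(self):
        w_pos, w_neg = pr.inverse_class_frequency_weights(np.array([1, 0, 0, 0, 0]))
        assert w_pos / w_neg == pytest.approx(4.0)

    def test_weighted_class_totals_equal(self, rng):
        for _ in range(20):
            n_pos = int(rng.integers(1, 50))
            n_neg = int(rng.integers(1, 50))
            labels = np.array([1] * n_pos + [0] * n_neg)
            w_pos, w_neg = pr.inverse_class_frequency_weights(labels)
            assert n_pos * w_pos == pytest.approx(n_neg * w_neg, abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pr.inverse_class_frequency_weights(np.array([1, 1, 1]))


class TestWeightedBCE:
    def test_single_sample_closed_form(self):
        loss = pr.weighted_bce_loss(np.array([0.5]), np.array([1]), (2.0, 1.0))
        assert loss == pytest.approx(2 * np.log(2), abs=1e-12)

    def test_unit_weights_equal_plain_bce(self, rng):
        p = rng.uniform(0.01, 0.99, 30)
        y = rng.integers(0, 2, 30)
        plain = float(np.mean(-(y * np.log(p) + (1 - y) * np.log(1 - p))))
        assert pr.weighted_bce_loss(p, y, (1.0, 1.0)) == pytest.approx(plain, abs=1e-9)

    def test_perfect_prediction_loss_near_zero(self):
        y = np.array([1, 0, 1])
        loss = pr.weighted_bce_loss(y.astype(float), y)
        assert loss <= -np.log(1 - 1e-7) + 1e-12

    def test_duplication_weight_invariance(self, rng):
        """Duplicating every negative and halving w_neg keeps the total
        per-class contribution identical (mean adjusts by count)."""
        p = rng.uniform(0.05, 0.95, 20)
        y = np.array([1] * 5 + [0] * 15)
        w = pr.inverse_class_frequency_weights(y)
        base = pr.weighted_bce_loss(p, y, w) * len(y)
        p2 = np.concatenate([p, p[y == 0]])
        y2 = np.concatenate([y, np.zeros(15, dtype=int)])
        dup = pr.weighted_bce_loss(p2, y2, (w[0], w[1] / 2)) * len(y2)
        assert dup == pytest.approx(base, abs=1e-7)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pr.weighted_bce_loss(np.array([0.5, 0.5]), np.array([1]))


class TestStratifiedKFold:
    def test_balanced_tiny_case(self):
        labels = np.array([1] * 5 + [0] * 5)
        folds = pr.stratified_kfold(labels, k=5, seed=0)
        for f in folds:
            val = labels[f.validation_indices]
            assert (val == 1).sum() == 1 and (val == 0).sum() == 1

    def test_partition_properties(self, rng):
        labels = rng.integers(0, 2, 97)
        while min((labels == 0).sum(), (labels == 1).sum()) < 5:
            labels = rng.integers(0, 2, 97)
        folds = pr.stratified_kfold(labels, k=5, seed=3)
        all_val = np.concatenate([f.validation_indices for f in folds])
        assert sorted(all_val) == list(range(97))
        for f in folds:
            assert set(f.train_indices).isdisjoint(f.validation_indices)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            pr.stratified_kfold(np.array([1, 0, 0, 0, 0, 0]), k=5)


class TestTrain:
    def test_defaults_match_protocol(self):
        tc = pr.TrainConfig()
        assert tc.learning_rate == 1e-4
        assert tc.epochs == 30
        assert tc.optimizer == "adam"
        assert tc.k_folds == 5
        assert tc.seed == 7

    def test_single_class_dataset_rejected(self, small_order_dataset):
        ds = small_order_dataset
        bad = pr.LabeledDataset(ds.profiles[:5], np.ones(5, dtype=int))
        with pytest.raises(ValueError):
            pr.train(bad, pr.desk_model_config(), pr.desk_train_config())

    def test_identical_seeds_identical_histories_and_weights(self, small_order_dataset):
        mc = pr.desk_model_config(gru_hidden=8, fc_size=8, conv_filters=(4, 8))
        tc = pr.desk_train_config(epochs=2, seed=7)
        m1, h1 = pr.train(small_order_dataset, mc, tc)
        m2, h2 = pr.train(small_order_dataset, mc, tc)
        assert h1 == h2
        for p1, p2 in zip(m1.params, m2.params):
            assert np.array_equal(p1.v, p2.v)

    def test_loss_decreases_on_learnable_data(self, trained_order_model):
        _, _, history = trained_order_model
        assert history[-1] < history[0]

    def test_history_length_equals_epochs(self, trained_order_model):
        _, _, history = trained_order_model
        assert len(history) == 5


class TestCrossValidate:
    def test_fold_reports_and_support(self, small_order_dataset):
        mc = pr.desk_model_config(gru_hidden=8, fc_size=8, conv_filters=(4, 8))
        tc = pr.desk_train_config(epochs=2, k_folds=3, seed=1)
        reports, summary = pr.cross_validate(small_order_dataset, mc, tc)
        assert len(reports) == 3
        folds = pr.stratified_kfold(small_order_dataset.labels, 3, 1)
        for rep, fold in zip(reports, folds):
            assert rep.support_positive + rep.support_negative == len(fold.validation_indices)
        assert set(summary) == {"sensitivity", "specificity", "accuracy", "mcc", "auc"}
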