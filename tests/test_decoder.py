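"""Shrinkage covariance, the two decoders, scoring and symbol selection."""

import json

import numpy as np
import pytest

from llpspeller import (
    ClassMeans,
    EpochSet,
    LLPDecoder,
    ShrinkageLDA,
    auc,
    score_epochs,
    select_symbol,
    shrinkage_covariance,
    train_llp,
    train_supervised,
)
from llpspeller.decoder import load_model, save_model
from llpspeller.paradigm import label_events
from llpspeller.simulate import sample_feature_epochs, sample_trial_epochs


def ledoit_wolf_reference(x):
    """Textbook Ledoit–Wolf (2004) analytic shrinkage toward nu*I."""
    n, d = x.shape
    xc = x - x.mean(axis=0)
    s = xc.T @ xc / n
    nu = np.trace(s) / d
    d2 = np.sum((s - nu * np.eye(d)) ** 2) / d
    b2bar = sum(np.sum((np.outer(row, row) - s) ** 2) for row in xc) / (n**2 * d)
    gamma = min(b2bar, d2) / d2
    return (1 - gamma) * s + gamma * nu * np.eye(d), gamma


class TestShrinkageCovariance:
    def test_matches_textbook_reference_on_fixed_table(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((6, 3)) * [1.0, 2.0, 0.5] + [0.3, -1.0, 0.0]
        cov_ref, gamma_ref = ledoit_wolf_reference(x)
        cov, gamma = shrinkage_covariance(x)
        assert gamma == pytest.approx(gamma_ref, abs=1e-8)
        assert np.allclose(cov, cov_ref, atol=1e-8)

    def test_large_sample_recovers_generating_covariance(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((50_000, 5))
        cov, _ = shrinkage_covariance(x)
        assert np.abs(cov - np.eye(5)).max() < 0.1

    def test_intensity_vanishes_for_anisotropic_large_samples(self):
        # gamma -> 0 requires the truth to differ from the shrinkage
        # target; for isotropic data the target is the truth and full
        # shrinkage is optimal
        rng = np.random.default_rng(2)
        x = rng.standard_normal((50_000, 5)) * np.asarray([0.5, 1.0, 2.0, 3.0, 4.0])
        _, gamma = shrinkage_covariance(x)
        assert gamma < 0.05

    def test_two_samples_fall_back_to_scaled_identity(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((2, 100))
        cov, gamma = shrinkage_covariance(x)
        assert gamma == 1.0
        assert np.allclose(cov, cov[0, 0] * np.eye(100))
        assert np.linalg.eigvalsh(cov).min() > 0

    def test_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            shrinkage_covariance(np.zeros((1, 4)))
        with pytest.raises(ValueError):
            shrinkage_covariance(np.full((5, 2), np.nan))


class TestShrinkageLDA:
    def test_recovers_bayes_direction(self):
        rng = np.random.default_rng(4)
        cov = np.asarray([[2.0, 0.5], [0.5, 1.0]])
        chol = np.linalg.cholesky(cov)
        n = 10_000
        mu_pos, mu_neg = np.asarray([3.0, 1.0]), np.asarray([0.0, 0.0])
        x = np.vstack(
            [
                mu_pos + rng.standard_normal((n // 2, 2)) @ chol.T,
                mu_neg + rng.standard_normal((n // 2, 2)) @ chol.T,
            ]
        )
        y = np.r_[np.ones(n // 2), -np.ones(n // 2)].astype(int)
        model = ShrinkageLDA().fit(x, y)
        bayes = np.linalg.solve(cov, mu_pos - mu_neg)
        cosine = model.coef_ @ bayes / np.linalg.norm(model.coef_) / np.linalg.norm(bayes)
        assert np.degrees(np.arccos(np.clip(cosine, -1, 1))) < 5.0

    def test_identical_class_means_give_zero_weights(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((200, 4))
        y = np.r_[np.ones(100), -np.ones(100)].astype(int)
        model = ShrinkageLDA().fit(x[np.argsort(rng.random(200))], y)
        x[:100] = x[100:]  # identical samples in both classes
        model = ShrinkageLDA().fit(x, y)
        assert np.allclose(model.coef_, 0.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ShrinkageLDA().fit(np.zeros((4, 2)), np.ones(4, dtype=int))

    def test_pooling_flag(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((300, 3))
        y = np.r_[np.ones(250), -np.ones(50)].astype(int)
        weighted = ShrinkageLDA(pooling="weighted").fit(x, y)
        unweighted = ShrinkageLDA(pooling="unweighted").fit(x, y)
        assert not np.allclose(weighted.covariance_, unweighted.covariance_)
        with pytest.raises(ValueError):
            ShrinkageLDA(pooling="median").fit(x, y)

    def test_eq12_self_consistency(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((500, 6)) + np.linspace(0, 1, 6)
        y = rng.choice([-1, 1], size=500)
        model = ShrinkageLDA().fit(x, y)
        residual = model.covariance_ @ model.coef_ - model.class_means_.difference
        assert np.linalg.norm(residual) < 1e-8 * max(
            np.linalg.norm(model.class_means_.difference), 1e-12
        )


class TestLLPDecoder:
    def test_weight_direction_on_known_model(self, study_mixing):
        rng = np.random.default_rng(8)
        cm = ClassMeans(np.asarray([1.0, 0.0]), np.asarray([0.0, 1.0]))
        epochs = sample_feature_epochs(
            study_mixing, [20_000, 20_000], cm, np.eye(2), rng
        )
        model = train_llp(epochs, study_mixing)
        direction = model.coef_ / np.linalg.norm(model.coef_)
        assert direction @ np.asarray([1.0, -1.0]) / np.sqrt(2) > 0.99

    def test_matches_supervised_weights_on_large_sample(self, study_mixing):
        rng = np.random.default_rng(9)
        cm = ClassMeans(np.asarray([1.0, 0.0, 0.5, 0.0]), np.asarray([0.0, 1.0, 0.0, 0.5]))
        epochs = sample_feature_epochs(
            study_mixing, [10_000, 10_000], cm, 2.0 * np.eye(4), rng
        )
        llp = train_llp(epochs, study_mixing)
        sup = train_supervised(epochs)
        cosine = llp.coef_ @ sup.coef_ / np.linalg.norm(llp.coef_) / np.linalg.norm(sup.coef_)
        assert cosine > 0.95

    def test_labels_never_read(self, study_mixing):
        rng = np.random.default_rng(10)
        cm = ClassMeans(np.ones(3), np.zeros(3))
        epochs = sample_feature_epochs(study_mixing, [500, 500], cm, np.eye(3), rng)
        shuffled = EpochSet(
            epochs.features,
            epochs.group,
            label=epochs.label[np.random.default_rng(0).permutation(epochs.n_epochs)],
        )
        a = train_llp(epochs, study_mixing)
        b = train_llp(shuffled, study_mixing)
        assert np.array_equal(a.coef_, b.coef_)

    def test_more_trials_improve_held_out_auc(self, grid, study_mixing):
        from llpspeller.paradigm import generate_trial
        from llpspeller.simulate import feature_space_model

        cm, cov = feature_space_model(snr=2.0)
        rng = np.random.default_rng(11)
        schedules = [generate_trial(grid, rng, trial_id=t) for t in range(24)]
        attended = [int(grid.selectable_indices[t % 32]) for t in range(24)]
        epochs = sample_trial_epochs(schedules, attended, grid, cm, cov, rng)
        test = epochs.select(epochs.trial >= 16)
        small = epochs.select(epochs.trial < 1)
        large = epochs.select(epochs.trial < 16)
        auc_small = auc(train_llp(small, study_mixing).decision_function(test.features), test.label)
        auc_large = auc(train_llp(large, study_mixing).decision_function(test.features), test.label)
        assert auc_large > auc_small

    def test_group_tag_mismatch_raises(self, study_mixing):
        with pytest.raises(ValueError, match="group tags"):
            LLPDecoder(mixing=study_mixing).fit(np.zeros((4, 2)), np.asarray([1, 1, 1, 1]))

    def test_sklearn_param_round_trip(self, study_mixing):
        model = LLPDecoder(mixing=study_mixing)
        assert model.get_params()["mixing"] is study_mixing
        model.set_params(mixing=None)
        assert model.mixing is None


class TestScoring:
    def test_score_is_plain_projection(self):
        model = LLPDecoder()
        model.coef_ = np.asarray([1.0, 1.0])
        model.n_features_in_ = 2
        assert model.decision_function(np.asarray([[2.0, 3.0]]))[0] == 5.0

    def test_scores_invariant_to_orthogonal_shift(self):
        rng = np.random.default_rng(12)
        model = LLPDecoder()
        model.coef_ = np.asarray([1.0, -2.0, 0.5])
        model.n_features_in_ = 3
        x = rng.standard_normal((20, 3))
        shift = np.asarray([2.0, 1.0, 0.0])  # orthogonal to coef_
        assert model.coef_ @ shift == 0.0
        assert np.allclose(
            model.decision_function(x), model.decision_function(x + shift)
        )

    def test_dimension_mismatch_raises(self):
        model = LLPDecoder()
        model.coef_ = np.ones(3)
        model.n_features_in_ = 3
        with pytest.raises(ValueError, match="features"):
            model.decision_function(np.zeros((2, 4)))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([1.0, 2.0, -1.0, -2.0], [1, 1, -1, -1]) == 1.0

    def test_chance_level(self):
        rng = np.random.default_rng(13)
        scores = rng.standard_normal(10_000)
        labels = rng.choice([-1, 1], size=10_000)
        assert auc(scores, labels) == pytest.approx(0.5, abs=0.02)

    def test_four_epoch_example_matches_pairwise_oracle(self):
        scores = np.asarray([0.1, 0.4, 0.35, 0.8])
        labels = np.asarray([-1, -1, 1, 1])
        wins = sum(
            1.0 if s > t else 0.5 if s == t else 0.0
            for s in scores[labels == 1]
            for t in scores[labels == -1]
        )
        assert wins / 4 == 0.75
        assert auc(scores, labels) == pytest.approx(0.75)

    def test_matches_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(14)
        scores = rng.integers(0, 5, size=60).astype(float)  # many ties
        labels = rng.choice([-1, 1], size=60)
        pos, neg = scores[labels == 1], scores[labels == -1]
        oracle = sum(
            1.0 if s > t else 0.5 if s == t else 0.0 for s in pos for t in neg
        ) / (len(pos) * len(neg))
        assert auc(scores, labels) == pytest.approx(oracle, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1.0, 2.0], [1, 1])


class TestSymbolSelection:
    def _trial_epochs(self, highlighted, n_features=2):
        n = len(highlighted)
        return EpochSet(
            np.zeros((n, n_features)),
            np.ones(n),
            trial=np.zeros(n, dtype=int),
            highlighted=highlighted,
        )

    def test_argmax_of_symbol_sums(self, grid):
        epochs = self._trial_epochs([{0, 1}, {0}, {1}])
        assert select_symbol([1.0, 1.0, -1.0], epochs, grid) == 0  # A beats B

    def test_tie_breaks_to_lowest_index(self, grid):
        epochs = self._trial_epochs([{2}, {5}])
        assert select_symbol([1.0, 1.0], epochs, grid) == 2

    def test_blanks_never_selected(self, grid):
        blank = int(grid.blank_indices[0])
        epochs = self._trial_epochs([{blank}, {3}])
        assert select_symbol([100.0, 0.1], epochs, grid) == 3

    def test_constant_score_shift_cancels_in_study_trial(self, grid, study_trial):
        # every selectable symbol is highlighted exactly 16 times per trial
        # (3x in each of 4 sequence-1 blocks + 2x in each of 2 sequence-2
        # blocks), so a constant bias adds the same amount to every
        # symbol's sum
        rng = np.random.default_rng(15)
        epochs = EpochSet(
            np.zeros((68, 1)),
            study_trial.groups(),
            trial=np.zeros(68, dtype=int),
            highlighted=study_trial.highlighted(),
        )
        scores = rng.standard_normal(68)
        assert select_symbol(scores, epochs, grid) == select_symbol(scores + 7.5, epochs, grid)

    def test_positive_weight_scaling_changes_nothing(self, grid, study_trial):
        epochs = EpochSet(
            np.random.default_rng(16).standard_normal((68, 1)),
            study_trial.groups(),
            trial=np.zeros(68, dtype=int),
            highlighted=study_trial.highlighted(),
        )
        labels = label_events(study_trial, 0, grid)
        scores = epochs.features[:, 0]
        assert select_symbol(scores, epochs, grid) == select_symbol(3.7 * scores, epochs, grid)
        assert auc(scores, labels) == auc(3.7 * scores, labels)

    def test_empty_trial_rejected(self, grid):
        epochs = self._trial_epochs([])
        with pytest.raises(ValueError, match="empty"):
            select_symbol(np.asarray([]), epochs, grid)


class TestSerialization:
    def test_round_trip_preserves_predictions(self, tmp_path, study_mixing):
        rng = np.random.default_rng(17)
        cm = ClassMeans(np.ones(4), np.zeros(4))
        epochs = sample_feature_epochs(study_mixing, [200, 200], cm, np.eye(4), rng)
        model = train_llp(epochs, study_mixing)
        save_model(model, tmp_path / "model")
        loaded = load_model(tmp_path / "model")
        x = rng.standard_normal((10, 4))
        assert np.array_equal(model.decision_function(x), loaded.decision_function(x))
        assert loaded.shrinkage_ == model.shrinkage_

    def test_json_fields_bit_stable(self, tmp_path, study_mixing):
        rng = np.random.default_rng(18)
        cm = ClassMeans(np.ones(3), np.zeros(3))
        epochs = sample_feature_epochs(study_mixing, [100, 100], cm, np.eye(3), rng)
        model = train_llp(epochs, study_mixing)
        save_model(model, tmp_path / "a")
        save_model(model, tmp_path / "b")
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()
        json.loads((tmp_path / "a.json").read_text())  # valid JSON

    def test_supervised_round_trip(self, tmp_path):
        rng = np.random.default_rng(19)
        x = rng.standard_normal((100, 3)) + np.asarray([1.0, 0.0, 0.0])
        y = rng.choice([-1, 1], size=100)
        model = ShrinkageLDA(pooling="unweighted").fit(x, y)
        save_model(model, tmp_path / "lda")
        loaded = load_model(tmp_path / "lda")
        assert isinstance(loaded, ShrinkageLDA)
        assert loaded.pooling == "unweighted"
        assert np.array_equal(loaded.coef_, model.coef_)


def test_score_epochs_wrapper(study_mixing):
    rng = np.random.default_rng(20)
    cm = ClassMeans(np.ones(2), np.zeros(2))
    epochs = sample_feature_epochs(study_mixing, [50, 50], cm, np.eye(2), rng)
    model = train_llp(epochs, study_mixing)
    assert np.array_equal(
        score_epochs(model, epochs), model.decision_function(epochs.features)
    )


def test_llp_supervised_angle_shrinks_with_data(study_mixing):
    """The LLP weight vector converges toward the supervised one as N grows."""
    cm = ClassMeans(np.asarray([1.0, 0.0, 0.3]), np.asarray([0.0, 0.8, 0.0]))
    sizes = [250, 1000, 4000]
    mean_angles = []
    for n in sizes:
        angles = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            epochs = sample_feature_epochs(study_mixing, [n, n], cm, np.eye(3), rng)
            llp = train_llp(epochs, study_mixing)
            sup = train_supervised(epochs)
            cosine = (
                llp.coef_ @ sup.coef_ / np.linalg.norm(llp.coef_) / np.linalg.norm(sup.coef_)
            )
            angles.append(np.degrees(np.arccos(np.clip(cosine, -1, 1))))
        mean_angles.append(np.mean(angles))
    assert mean_angles[0] > mean_angles[1] > mean_angles[2]
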