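"""LSTM training, prediction, cross-validation harness and model selection."""

import numpy as np
import pandas as pd
import pytest

from tibhip._lstm import LSTMNet
from tibhip.augment import AugmentationConfig
from tibhip.io import MinuteSeries
from tibhip.model import (
    ConfigurationError,
    CVResult,
    DegenerateLabelsError,
    IncompatibleNormalizationError,
    ModelConfig,
    cross_validate,
    load_model,
    predict,
    save_model,
    select_model,
    train,
)
from tibhip.preprocess import apply_normalizer, fit_normalizer

NOON = pd.Timestamp("2024-03-04T12:00:00")

TINY = ModelConfig(bidirectional=False, n_layers=1, cells_per_layer=4,
                   max_epochs=50, early_stop_patience=50, batch_size=8,
                   learning_rate=1e-2, seed=0)
FAST_AUG = AugmentationConfig(n_crops=8, min_crop_minutes=30)


def _separable_cohort(n_subjects=4, n_minutes=240, seed=0):
    """Toy problem: in-bed minutes sit at a lying gravity vector, out-of-bed
    minutes at an upright vector with added jitter — linearly separable."""
    rng = np.random.default_rng(seed)
    cohort = []
    for _ in range(n_subjects):
        labels = np.zeros(n_minutes, dtype=np.int8)
        start = int(rng.integers(40, 120))
        labels[start:start + 100] = 1
        values = np.where(labels[:, None] == 1,
                          np.array([0.0, 0.0, 1.0]),
                          np.array([0.0, -1.0, 0.0]))
        values = values + rng.normal(0, 0.05, size=(n_minutes, 3))
        cohort.append(MinuteSeries(NOON, values, labels=labels))
    return cohort


def _normalized(cohort):
    stats = fit_normalizer(cohort)
    return [apply_normalizer(s, stats) for s in cohort], stats


class TestLSTMCore:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        net = LSTMNet(3, 4, 2, True, seed=1)
        T, B = 7, 3
        x = rng.normal(size=(T, B, 3))
        y = (rng.random((T, B)) < 0.4).astype(float)
        lengths = np.array([7, 5, 3])
        mask = (np.arange(T)[:, None] < lengths[None, :]).astype(float)
        probs, cache = net.forward(x, mask, lengths, need_cache=True)
        _, grads = net.backward(probs, y, cache)

        def loss_fn():
            p = net.forward(x, mask, lengths)
            eps = 1e-12
            return float(-(mask * (y * np.log(p + eps)
                                   + (1 - y) * np.log(1 - p + eps))).sum()
                         / mask.sum())

        rng2 = np.random.default_rng(1)
        for name, g in grads.items():
            P = net.params[name]
            flat = rng2.choice(P.size, size=min(4, P.size), replace=False)
            for j in flat:
                idx = np.unravel_index(j, P.shape)
                h = 1e-6
                old = P[idx]
                P[idx] = old + h
                lp = loss_fn()
                P[idx] = old - h
                lm = loss_fn()
                P[idx] = old
                assert abs((lp - lm) / (2 * h) - g[idx]) < 1e-7, name

    def test_padding_does_not_change_predictions(self):
        rng = np.random.default_rng(2)
        net = LSTMNet(3, 8, 1, True, seed=3)
        x1 = rng.normal(size=(50, 1, 3))
        p_alone = net.forward(x1, np.ones((50, 1)), np.array([50]))
        # same sequence padded inside a batch with a longer one
        x2 = np.zeros((80, 2, 3))
        x2[:50, 0] = x1[:, 0]
        x2[:, 1] = rng.normal(size=(80, 3))
        mask = np.zeros((80, 2))
        mask[:50, 0] = 1
        mask[:, 1] = 1
        p_batch = net.forward(x2, mask, np.array([50, 80]))
        np.testing.assert_allclose(p_batch[:50, 0], p_alone[:, 0], atol=1e-12)


class TestTrain:
    def test_separable_problem_reaches_high_accuracy(self):
        cohort, _ = _normalized(_separable_cohort())
        model = train(cohort, TINY, FAST_AUG)
        assert model.training_log[-1]["accuracy"] >= 0.99

    def test_all_zero_labels_rejected(self):
        cohort = _separable_cohort()
        for s in cohort:
            s.labels[:] = 0
        cohort, _ = _normalized(cohort)
        with pytest.raises(DegenerateLabelsError):
            train(cohort, TINY, FAST_AUG)

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ConfigurationError, match="normalized"):
            train(_separable_cohort(), TINY, FAST_AUG)

    def test_deterministic_training(self):
        cohort, _ = _normalized(_separable_cohort())
        cfg = ModelConfig(bidirectional=False, n_layers=1, cells_per_layer=4,
                          max_epochs=3, seed=7)
        a = train(cohort, cfg, FAST_AUG)
        b = train(cohort, cfg, FAST_AUG)
        assert a.training_log[-1]["loss"] == b.training_log[-1]["loss"]
        for k in a.weights:
            np.testing.assert_array_equal(a.weights[k], b.weights[k])


@pytest.fixture(scope="module")
def trained():
    cohort, stats = _normalized(_separable_cohort())
    return train(cohort, TINY, FAST_AUG), stats


class TestPredict:
    def test_stats_hash_mismatch_rejected(self, trained):
        model, stats = trained
        rng = np.random.default_rng(5)
        rogue = MinuteSeries(NOON, rng.normal(size=(30, 3)), normalized=True,
                             norm_ref="deadbeefdeadbeef")
        with pytest.raises(IncompatibleNormalizationError):
            predict(model, rogue)

    @pytest.mark.parametrize("length", [5, 1440, 2000])
    def test_output_length_matches_input(self, trained, length):
        model, stats = trained
        rng = np.random.default_rng(6)
        series = MinuteSeries(NOON, rng.normal(size=(length, 3)),
                              normalized=True, norm_ref=stats.stats_hash)
        probs, track = predict(model, series)
        assert probs.shape == (length,) and track.shape == (length,)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_beats_all_out_of_bed_baseline_on_held_out(self, trained):
        model, stats = trained
        held_out = _separable_cohort(n_subjects=2, seed=99)
        correct = total = base = 0
        for s in held_out:
            sn = apply_normalizer(s, stats)
            _, track = predict(model, sn)
            correct += (track == s.labels).sum()
            base += (s.labels == 0).sum()
            total += s.labels.size
        assert correct / total > base / total

    def test_checkpoint_round_trip_bit_exact(self, trained, tmp_path):
        model, stats = trained
        save_model(model, tmp_path / "ckpt")
        back = load_model(tmp_path / "ckpt")
        assert back.config == model.config
        assert back.norm_stats_ref == model.norm_stats_ref
        for k in model.weights:
            np.testing.assert_array_equal(back.weights[k], model.weights[k])
        rng = np.random.default_rng(8)
        series = MinuteSeries(NOON, rng.normal(size=(60, 3)), normalized=True,
                              norm_ref=stats.stats_hash)
        np.testing.assert_array_equal(predict(model, series)[0],
                                      predict(back, series)[0])


class TestCrossValidate:
    def test_folds_partition_subjects(self):
        cohort = _separable_cohort(n_subjects=10)
        cfg = ModelConfig(bidirectional=False, n_layers=1, cells_per_layer=2,
                          max_epochs=1, seed=0)
        [res] = cross_validate(cohort, [cfg], FAST_AUG, k=5)
        all_val = [s for fold in res.fold_assignments for s in fold]
        assert sorted(all_val) == list(range(10))
        assert len(res.fold_accuracies) == 5
        # normalizer provenance: per-fold stats differ from whole-cohort stats
        whole = fit_normalizer(cohort).stats_hash
        assert all(h != whole for h in res.norm_hashes)

    def test_fewer_subjects_than_folds_rejected(self):
        with pytest.raises(ConfigurationError):
            cross_validate(_separable_cohort(n_subjects=3), [TINY], k=10)

    def test_equal_fold_sizes_with_divisible_cohort(self):
        cohort = _separable_cohort(n_subjects=8)
        cfg = ModelConfig(bidirectional=False, n_layers=1, cells_per_layer=2,
                          max_epochs=1, seed=0)
        [res] = cross_validate(cohort, [cfg], FAST_AUG, k=4)
        assert all(len(f) == 2 for f in res.fold_assignments)


def _cv_result(layers, cells, accs, bidirectional=True):
    cfg = ModelConfig(bidirectional=bidirectional, n_layers=layers,
                      cells_per_layer=cells, max_epochs=1)
    return CVResult(cfg, tuple(accs), ((0,),) * len(accs),
                    ("h",) * len(accs))


class TestSelectModel:
    def test_single_candidate(self):
        r = _cv_result(1, 4, [0.9, 0.91])
        assert select_model([r]) == r.config

    def test_sparser_of_equal_accuracy(self):
        small = _cv_result(1, 4, [0.93, 0.93])
        big = _cv_result(4, 32, [0.93, 0.93])
        assert select_model([big, small]) == small.config

    def test_clear_winner_outside_se_band_wins_despite_size(self):
        # the large cell is far better than everyone else's band
        big = _cv_result(4, 32, [0.95, 0.951, 0.949])
        small = _cv_result(1, 2, [0.70, 0.71, 0.69])
        assert select_model([small, big]) == big.config

    def test_within_one_se_prefers_fewest_parameters(self):
        best = _cv_result(2, 16, [0.94, 0.90, 0.92])  # mean .92, se ~.0115
        near = _cv_result(1, 8, [0.915, 0.91, 0.92])  # mean .915, inside band
        far = _cv_result(1, 2, [0.80, 0.81, 0.79])
        assert select_model([best, near, far]) == near.config

    def test_parameter_count_formula(self):
        # 1 unidirectional layer, H cells: 4H(3+H+1) + H+1 read-out
        cfg = ModelConfig(bidirectional=False, n_layers=1, cells_per_layer=8)
        assert cfg.n_parameters == 4 * 8 * (3 + 8 + 1) + 8 + 1
        bi = ModelConfig(bidirectional=True, n_layers=2, cells_per_layer=4)
        expected = (2 * 4 * 4 * (3 + 4 + 1)      # layer 1, both directions
                    + 2 * 4 * 4 * (8 + 4 + 1)    # layer 2 reads 2*4 features
                    + 8 + 1)
        assert bi.n_parameters == expected

    def test_grid_membership_enforced(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(n_layers=3)
        with pytest.raises(ConfigurationError):
            ModelConfig(cells_per_layer=10)
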