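"""CNN regressor contracts: forward oracle, loss, training, RC invariance."""

import dataclasses
import math

import numpy as np
import pytest

import rcbind as rb
from rcbind.cnn import (
    CnnConfig,
    CnnModel,
    evaluate_strand_consistency,
    pairs_correlation,
    penalized_loss,
    r_squared,
    select_hyperparameters,
    train_cnn,
)
from rcbind.selex import SelexDataset

IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def sigmoid(x):
    return 1.0 / (1.0 + math.exp(-x))


def naive_forward(model: CnnModel, seq: str) -> float:
    """Independent direct-summation oracle for the CNN forward pass."""
    cfg = model.config
    filters = model.filters.data
    b = model.rect_shift.data
    f, _, m = filters.shape
    K = len(seq) - m + 1
    p = cfg.pool_window

    def conv(filt):
        out = []
        for k in range(K):
            total = 0.0
            for j in range(m):
                base = seq[k + j]
                if base != "N":
                    total += filt[IDX[base]][j]
            out.append(total)
        return out

    def rect_pool(filt, shift):
        act = [max(0.0, v + shift) for v in conv(filt)]
        return [max(act[k * p : (k + 1) * p]) for k in range(K // p)]

    if cfg.variant == "canonical":
        flat = []
        for fi in range(f):
            flat.extend(rect_pool(filters[fi], b[fi]))
        z = sum(w * v for w, v in zip(model.dense_w.data[:, 0], flat))
        return sigmoid(z + model.dense_b.data[0])

    w1 = model.w1.data
    kp = K // p
    z = 0.0
    for fi in range(f):
        pooled = rect_pool(filters[fi], b[fi])
        partner = [[filters[fi][3 - i][m - 1 - j] for j in range(m)] for i in range(4)]
        pooled_rc = rect_pool(partner, b[fi])
        channel = sum(w1[fi][k] * pooled[k] for k in range(kp))
        channel += sum(w1[fi][kp - 1 - k] * pooled_rc[k] for k in range(kp))
        z += model.dense_w.data[fi, 0] * channel
    return sigmoid(z + model.dense_b.data[0])


def make_additive_model(length=2, dense=1.0):
    """sigma(#A in sequence): one A-indicator filter of width 1."""
    cfg = CnnConfig(
        n_filters=1, filter_width=1, pool_window=1, dropout_rate=0.0,
        input_length=length, seed=0,
    )
    model = CnnModel(cfg)
    model.filters.data = np.array([[[1.0], [0.0], [0.0], [0.0]]])
    model.rect_shift.data = np.zeros(1)
    model.dense_w.data = np.full((length, 1), dense)
    model.dense_b.data = np.zeros(1)
    return model


class TestForward:
    def test_all_zero_parameters_give_half(self):
        model = CnnModel(CnnConfig(n_filters=2, input_length=14, seed=0))
        for p in model.parameters():
            p.data = np.zeros_like(p.data)
        assert model.predict(["ACGTACGTACGTAC"])[0] == pytest.approx(0.5)

    def test_hand_arithmetic_single_filter(self):
        # one A-indicator filter, m=1, p=2, dense weight 1: input "AC" gives
        # conv (1, 0) -> ReLU -> pool 1 -> sigmoid(1)
        cfg = CnnConfig(n_filters=1, filter_width=1, pool_window=2,
                        dropout_rate=0.0, input_length=2, seed=0)
        model = CnnModel(cfg)
        model.filters.data = np.array([[[1.0], [0.0], [0.0], [0.0]]])
        model.rect_shift.data = np.zeros(1)
        model.dense_w.data = np.ones((1, 1))
        model.dense_b.data = np.zeros(1)
        assert model.predict(["AC"])[0] == pytest.approx(sigmoid(1.0), abs=1e-9)
        assert model.predict(["AC"])[0] == pytest.approx(0.73106, abs=1e-5)

    @pytest.mark.parametrize("variant", ["canonical", "rc_shared"])
    @pytest.mark.parametrize("n_filters,m", [(1, 1), (3, 2), (2, 2)])
    def test_matches_direct_summation_oracle(self, variant, n_filters, m):
        cfg = CnnConfig(
            n_filters=n_filters, filter_width=m, pool_window=1,
            dropout_rate=0.0, input_length=m + 3, seed=5, variant=variant,
        )
        model = CnnModel(cfg)
        rng = np.random.default_rng(8)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=cfg.input_length))
            assert model.predict([seq])[0] == pytest.approx(
                naive_forward(model, seq), abs=1e-9
            )

    def test_oracle_with_n_padding(self):
        cfg = CnnConfig(n_filters=2, filter_width=2, pool_window=1,
                        dropout_rate=0.0, input_length=6, seed=3)
        model = CnnModel(cfg)
        seq = "ACNNGT"
        assert model.predict([seq])[0] == pytest.approx(
            naive_forward(model, seq), abs=1e-9
        )

    def test_wrong_length_rejected(self):
        model = CnnModel(CnnConfig(input_length=14, seed=0))
        with pytest.raises(ValueError, match="length"):
            model.predict(["ACGT"])


class TestRcInvariance:
    def test_exact_at_initialization_and_during_training(self, small_sim):
        rng = np.random.default_rng(12)
        probes = ["".join(rng.choice(list("ACGT"), size=14)) for _ in range(50)]
        rcs = [rb.reverse_complement(s) for s in probes]

        diffs = []

        def check(epoch, model):
            diffs.append(np.abs(model.predict(probes) - model.predict(rcs)).max())

        cfg = rb.CnnConfig(variant="rc_shared", n_filters=4, epochs=3, seed=12)
        model = CnnModel(cfg)
        assert np.abs(model.predict(probes) - model.predict(rcs)).max() < 1e-5
        sub = small_sim.subset(np.arange(800))
        model, _ = train_cnn(sub, cfg, epoch_callback=check)
        assert len(diffs) == 3
        assert max(diffs) < 1e-5


class TestLossAndMetrics:
    def test_perfect_predictions_zero_loss(self):
        assert penalized_loss([0.3, 0.7], [0.3, 0.7], np.zeros((1, 4, 2)), 0, 0) == 0.0

    def test_constant_half_on_half_targets(self):
        assert penalized_loss([0.5, 0.5], [0.5, 0.5], np.zeros((1, 4, 1)), 0.1, 0.1) == 0.0

    def test_hand_arithmetic_with_penalties(self):
        # MSE 0.25 + 0.1*|2| + 0.01*4 = 0.49
        loss = penalized_loss([0.7], [0.2], np.array([2.0]), 0.1, 0.01)
        assert loss == pytest.approx(0.49)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            penalized_loss([], [], np.zeros(1), 0, 0)

    def test_r_squared_examples(self):
        assert r_squared([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert r_squared([1, 2, 3], [2, 2, 2]) == pytest.approx(0.0)
        assert r_squared([0, 1, 1], [0, 1, 0]) == pytest.approx(-0.5)

    def test_r_squared_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            r_squared([1, 1, 1], [1, 2, 3])


class TestTraining:
    def test_loss_decreases_and_is_seed_reproducible(self, small_sim):
        sub = small_sim.subset(np.arange(2000))
        cfg = rb.CnnConfig(n_filters=4, epochs=4, seed=21)
        _, h1 = train_cnn(sub, cfg)
        _, h2 = train_cnn(sub, cfg)
        assert h1.train_loss[-1] < h1.train_loss[0]
        assert h1.train_loss == h2.train_loss  # bit-identical traces

    def test_predict_deterministic(self, tiny_rc_model, small_sim):
        seqs = small_sim.sequences[:100]
        assert np.array_equal(tiny_rc_model.predict(seqs), tiny_rc_model.predict(seqs))

    def test_length_mismatch_between_config_and_data(self, small_sim):
        with pytest.raises(ValueError):
            train_cnn(small_sim, rb.CnnConfig(input_length=38, seed=0))

    def test_monotone_l1_penalty(self, small_sim):
        sub = small_sim.subset(np.arange(1500))
        norms = []
        for lam1 in (1e-6, 5e-2):
            cfg = rb.CnnConfig(n_filters=4, epochs=5, seed=2, lambda1=lam1)
            model, _ = train_cnn(sub, cfg)
            norms.append(np.abs(model.filters.data).sum())
        assert norms[1] <= norms[0]

    def test_save_load_round_trip(self, tiny_rc_model, small_sim, tmp_path):
        path = tmp_path / "model.json"
        tiny_rc_model.save(path)
        back = CnnModel.load(path)
        seqs = small_sim.sequences[:50]
        assert np.array_equal(back.predict(seqs), tiny_rc_model.predict(seqs))


class TestHyperparameterSelection:
    def test_single_candidate_returned(self, small_sim):
        sub = small_sim.subset(np.arange(300))
        base = rb.CnnConfig(n_filters=2, epochs=2, seed=0)
        only = (1e-6, 1e-6, 1e-3)
        assert select_hyperparameters(sub, [only], k=2, base_config=base) == only

    def test_zero_learning_rate_candidate_loses(self, small_sim):
        sub = small_sim.subset(np.arange(600))
        base = rb.CnnConfig(n_filters=4, epochs=3, seed=0)
        live = (1e-6, 1e-6, 1e-3)
        dead = (1e-6, 1e-6, 0.0)
        assert select_hyperparameters(sub, [dead, live], k=2, base_config=base) == live

    def test_selection_seed_reproducible(self, small_sim):
        sub = small_sim.subset(np.arange(600))
        base = rb.CnnConfig(n_filters=2, epochs=2, seed=4)
        cands = [(1e-6, 1e-6, 1e-3), (1e-4, 1e-4, 5e-4), (1e-3, 1e-3, 1e-4)]
        a = select_hyperparameters(sub, cands, k=2, base_config=base)
        b = select_hyperparameters(sub, cands, k=2, base_config=base)
        assert a == b


class TestStrandConsistency:
    def test_rc_shared_pairs_equal_with_unit_correlation(self, tiny_rc_model, small_sim):
        test = small_sim.subset(np.arange(200))
        pairs, r = evaluate_strand_consistency(tiny_rc_model, "raw", test)
        assert np.abs(pairs["forward"] - pairs["reverse"]).max() < 1e-5
        assert r == pytest.approx(1.0)

    def test_constant_predictor_reports_undefined(self, small_sim):
        model = CnnModel(rb.CnnConfig(n_filters=2, input_length=14, seed=0))
        for p in model.parameters():
            p.data = np.zeros_like(p.data)
        _, r = evaluate_strand_consistency(model, "raw", small_sim.subset(np.arange(20)))
        assert r is None

    def test_collinear_toy_pairs(self):
        assert pairs_correlation([0.1, 0.3, 0.5], [0.2, 0.4, 0.6]) == pytest.approx(1.0)

    def test_rc_augmented_mode_uses_constructed_inputs(self, small_sim):
        cfg = rb.CnnConfig(variant="canonical", n_filters=4, epochs=2, seed=9,
                           input_length=38)
        aug = rb.augment(small_sim.subset(np.arange(500)),
                         rb.AugmentationStrategy("rc_augmented"))
        model, _ = train_cnn(aug, cfg)
        pairs, r = evaluate_strand_consistency(
            model, "rc_augmented", small_sim.subset(np.arange(100))
        )
        assert len(pairs) == 100
        assert r is not None
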