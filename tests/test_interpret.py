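"""Attribution methods: ISM deltas, gradients, DeconvNet, consistency."""

import math

import numpy as np
import pytest

import rcbind as rb
from rcbind.autodiff import Tensor
from rcbind.cnn import CnnConfig, CnnModel
from rcbind.interpret import (
    ImportanceMatrix,
    consistency_score,
    consistency_study,
    deconvnet,
    gradient_times_input,
    ism,
    logo_projection,
    sliding_window_predictions,
)

IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def sigmoid(x):
    return 1.0 / (1.0 + math.exp(-x))


def count_a_model(length):
    """f(s) = sigmoid(#A in s): A-indicator filter, unit dense weights."""
    cfg = CnnConfig(n_filters=1, filter_width=1, pool_window=1,
                    dropout_rate=0.0, input_length=length, seed=0)
    model = CnnModel(cfg)
    model.filters.data = np.array([[[1.0], [0.0], [0.0], [0.0]]])
    model.rect_shift.data = np.zeros(1)
    model.dense_w.data = np.ones((length, 1))
    model.dense_b.data = np.zeros(1)
    return model


class TestIsm:
    def test_toy_count_a_delta_matches_hand_arithmetic(self):
        model = count_a_model(2)
        imp = ism(model, "AA")
        s1, s2 = sigmoid(1), sigmoid(2)
        expected = (s1 - s2) * s2  # mutant lowers #A; max(f, f_hat) = sigmoid(2)
        assert imp.scores[IDX["C"], 0] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(-0.13189, abs=1e-5)
        # every non-reference base at either position gives the same delta
        for j in range(2):
            for b in "CGT":
                assert imp.scores[IDX[b], j] == pytest.approx(expected, abs=1e-9)

    def test_reference_entries_exactly_zero(self, tiny_rc_model, small_sim):
        seq = small_sim.sequences[0]
        imp = ism(tiny_rc_model, seq)
        for j, b in enumerate(seq):
            assert imp.scores[IDX[b], j] == 0.0
        # exactly 3 free entries per column
        assert np.count_nonzero(imp.scores == 0.0) >= len(seq)

    def test_sign_matches_prediction_change(self, tiny_rc_model, small_sim):
        seq = small_sim.sequences[1]
        imp = ism(tiny_rc_model, seq)
        f0 = tiny_rc_model.predict([seq])[0]
        for j in range(len(seq)):
            for b in "ACGT":
                if b == seq[j]:
                    continue
                mut = seq[:j] + b + seq[j + 1 :]
                fm = tiny_rc_model.predict([mut])[0]
                assert np.sign(imp.scores[IDX[b], j]) == np.sign(fm - f0)

    def test_model_agnostic_across_serialization(self, tiny_rc_model, small_sim, tmp_path):
        seq = small_sim.sequences[2]
        path = tmp_path / "m.json"
        tiny_rc_model.save(path)
        back = CnnModel.load(path)
        assert np.array_equal(ism(tiny_rc_model, seq).scores, ism(back, seq).scores)

    def test_length_mismatch_rejected(self, tiny_rc_model):
        with pytest.raises(ValueError):
            ism(tiny_rc_model, "ACGT")


class TestGradientTimesInput:
    def test_constant_model_gives_zero_matrix(self):
        model = CnnModel(CnnConfig(n_filters=2, input_length=8, seed=0))
        for p in model.parameters():
            p.data = np.zeros_like(p.data)
        imp = gradient_times_input(model, "ACGTACGT")
        assert np.array_equal(imp.scores, np.zeros((4, 8)))

    def test_linear_pre_sigmoid_chain_rule(self):
        # f = sigmoid(#A): observed-base score is sigma'(z) for A, 0 otherwise
        model = count_a_model(3)
        seq = "ACA"
        imp = gradient_times_input(model, seq)
        z = 2.0
        sp = sigmoid(z) * (1 - sigmoid(z))
        assert imp.scores[IDX["A"], 0] == pytest.approx(sp, abs=1e-12)
        assert imp.scores[IDX["A"], 2] == pytest.approx(sp, abs=1e-12)
        # C occupies position 1 but its filter weight is zero
        assert imp.scores[IDX["C"], 1] == 0.0

    def test_off_reference_entries_are_zero(self, tiny_rc_model, small_sim):
        seq = small_sim.sequences[3]
        imp = gradient_times_input(tiny_rc_model, seq)
        for j, b in enumerate(seq):
            for other in "ACGT":
                if other != b:
                    assert imp.scores[IDX[other], j] == 0.0

    def test_gradient_matches_finite_differences(self, small_sim):
        cfg = CnnConfig(n_filters=3, filter_width=4, dropout_rate=0.0,
                        input_length=14, seed=13)
        model = CnnModel(cfg)
        seq = small_sim.sequences[4]
        X = Tensor(rb.one_hot(seq)[None], requires_grad=True)
        model.forward_tensor(X).backward()
        grad = X.grad[0]
        eps = 1e-5
        for i in range(4):
            for j in range(14):
                x = rb.one_hot(seq)[None]
                x[0, i, j] += eps
                up = model.forward(Tensor(x)).data[0]
                x[0, i, j] -= 2 * eps
                dn = model.forward(Tensor(x)).data[0]
                assert grad[i, j] == pytest.approx((up - dn) / (2 * eps), abs=1e-4)


class TestDeconvNet:
    def test_equals_gradient_when_all_signals_nonnegative(self):
        model = count_a_model(3)  # positive weights throughout
        g = gradient_times_input(model, "AAA").scores
        d = deconvnet(model, "AAA").scores
        assert np.allclose(g, d)

    def test_negative_backward_signal_zeroed_hand_case(self):
        # active ReLU with a negative dense weight: gradient keeps the
        # negative signal, DeconvNet rectifies it away
        cfg = CnnConfig(n_filters=1, filter_width=1, pool_window=1,
                        dropout_rate=0.0, input_length=1, seed=0)
        model = CnnModel(cfg)
        model.filters.data = np.array([[[1.0], [0.0], [0.0], [0.0]]])
        model.rect_shift.data = np.zeros(1)
        model.dense_w.data = np.array([[-2.0]])
        model.dense_b.data = np.array([1.0])
        # f("A") = sigmoid(1 * -2 + 1) = sigmoid(-1)
        sp = sigmoid(-1) * (1 - sigmoid(-1))
        g = gradient_times_input(model, "A").scores
        assert g[IDX["A"], 0] == pytest.approx(sp * -2.0, abs=1e-12)
        d = deconvnet(model, "A").scores
        assert d[IDX["A"], 0] == 0.0

    def test_sa_model_rejected(self, small_sim):
        model = rb.SaModel(rb.SaConfig(d_model=8, n_layers=1, n_heads=2, seed=0))
        model.input_length = 14
        with pytest.raises(TypeError):
            deconvnet(model, small_sim.sequences[0])


class TestLogoProjection:
    def test_ism_projection_is_zero(self, tiny_rc_model, small_sim):
        imp = ism(tiny_rc_model, small_sim.sequences[5])
        assert np.array_equal(logo_projection(imp), np.zeros(14))

    def test_gradient_projection_picks_observed_entries(self, tiny_rc_model, small_sim):
        seq = small_sim.sequences[6]
        imp = gradient_times_input(tiny_rc_model, seq)
        proj = logo_projection(imp)
        for j, b in enumerate(seq):
            assert proj[j] == imp.scores[IDX[b], j]

    def test_hand_matrix_exact_pick(self):
        scores = np.arange(8, dtype=float).reshape(4, 2)
        imp = ImportanceMatrix(scores, "CT", "ism")
        assert np.array_equal(logo_projection(imp), [scores[1, 0], scores[3, 1]])


class TestConsistencyScore:
    def test_identical_matrices_give_one(self):
        m = np.random.default_rng(0).normal(size=(4, 3))
        assert consistency_score(m, m.copy(), m.copy()) == pytest.approx(1.0)

    def test_hand_arithmetic_on_two_entry_vectors(self):
        a, b = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        assert consistency_score(a, b, a.copy()) == pytest.approx(-1 / 3)

    def test_spearman_invariant_under_monotone_transform(self):
        m = np.random.default_rng(1).normal(size=(4, 5))
        assert consistency_score(m, m**3, np.tanh(m), kind="spearman") == (
            pytest.approx(1.0)
        )

    def test_zero_variance_pair_excluded_with_warning(self):
        rng = np.random.default_rng(2)
        m = rng.normal(size=(4, 2))
        flat = np.zeros((4, 2))
        with pytest.warns(UserWarning, match="zero-variance"):
            c = consistency_score(m, m.copy(), flat)
        assert c == pytest.approx(1.0)  # only the (0,1) pair survives

    def test_bounded_and_symmetric(self):
        rng = np.random.default_rng(3)
        ms = [rng.normal(size=(4, 4)) for _ in range(3)]
        c1 = consistency_score(*ms)
        c2 = consistency_score(ms[2], ms[0], ms[1])
        assert -1.0 <= c1 <= 1.0
        assert c1 == pytest.approx(c2)


class TestConsistencyStudy:
    def test_identical_hyperparameters_give_unit_consistency(self, small_sim):
        h = (1e-6, 1e-6, 1e-3)

        def factory(hset):
            l1, l2, l3 = hset
            return CnnConfig(variant="rc_shared", n_filters=4, epochs=2, seed=5,
                             lambda1=l1, lambda2=l2, learning_rate=l3)

        seqs = small_sim.sequences[:4]
        table = consistency_study(
            small_sim.subset(np.arange(800)), factory, [h, h, h], seqs,
            methods=("ism", "gradient_times_input"), min_r2=-100.0, seed=5,
        )
        assert len(table) == 2 * 4
        assert np.allclose(table["c"], 1.0)

    def test_r2_floor_enforced(self, small_sim):
        def factory(hset):
            return CnnConfig(n_filters=2, epochs=1, seed=5)

        h = (1e-6, 1e-6, 1e-3)
        with pytest.raises(RuntimeError, match="floor"):
            consistency_study(
                small_sim.subset(np.arange(400)), factory, [h, h, h],
                small_sim.sequences[:2], min_r2=0.999999, seed=5,
            )


class TestSlidingWindow:
    def test_track_length(self, tiny_rc_model):
        rng = np.random.default_rng(9)
        long_seq = "".join(rng.choice(list("ACGT"), size=74))
        assert sliding_window_predictions(tiny_rc_model, long_seq).shape == (61,)

    def test_exact_length_equals_direct_prediction(self, tiny_rc_model, small_sim):
        seq = small_sim.sequences[7]
        track = sliding_window_predictions(tiny_rc_model, seq)
        assert track.shape == (1,)
        assert track[0] == tiny_rc_model.predict([seq])[0]

    def test_consensus_injection_maximizes_track_near_offset(self, truth, truth_handle):
        rng = np.random.default_rng(10)
        background = "".join(rng.choice(list("CT"), size=60))
        offset = 23
        seq = background[:offset] + truth.consensus + background[offset + 8 :]
        track = sliding_window_predictions(truth_handle, seq)
        peak = int(np.argmax(track))
        # windows fully containing the core start in [offset-(l-w), offset]
        assert offset - 6 <= peak <= offset

    def test_too_short_rejected(self, tiny_rc_model):
        with pytest.raises(ValueError):
            sliding_window_predictions(tiny_rc_model, "ACGTACGT")
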