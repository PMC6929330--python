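"""The CNN-GRU architecture: GRU cell against a scalar oracle, front-end
shape contract, forward-pass properties, gradient correctness."""

import math

import numpy as np
import pytest

import pssmrnn as pr
from pssmrnn.model import GRUParams, front_end_length
from pssmrnn.nn import sigmoid


def scalar_gru_oracle(x, h_prev, p: GRUParams):
    """Element-by-element evaluation of the GRU equations with plain
    Python floats — independent of the vectorized implementation."""
    H = p.hidden_size
    D = len(x)
    sig = lambda v: 1.0 / (1.0 + math.exp(-v))
    h_new = []
    for i in range(H):
        az = p.b_iz[i] + p.b_hz[i]
        ar = p.b_ir[i] + p.b_hr[i]
        an_in = p.b_in[i]
        c = p.b_hn[i]
        for j in range(D):
            az += p.W_iz[i, j] * x[j]
            ar += p.W_ir[i, j] * x[j]
            an_in += p.W_in[i, j] * x[j]
        for j in range(H):
            az += p.W_hz[i, j] * h_prev[j]
            ar += p.W_hr[i, j] * h_prev[j]
            c += p.W_hn[i, j] * h_prev[j]
        z, r = sig(az), sig(ar)
        n = math.tanh(an_in + r * c)
        h_new.append((1.0 - z) * n + z * h_prev[i])
    return np.array(h_new)


def random_gru_params(rng, hidden, inp):
    u = lambda shape: rng.normal(0, 0.5, size=shape)
    return GRUParams(
        W_iz=u((hidden, inp)), W_ir=u((hidden, inp)), W_in=u((hidden, inp)),
        W_hz=u((hidden, hidden)), W_hr=u((hidden, hidden)), W_hn=u((hidden, hidden)),
        b_iz=u(hidden), b_ir=u(hidden), b_in=u(hidden),
        b_hz=u(hidden), b_hr=u(hidden), b_hn=u(hidden),
        hidden_size=hidden,
    )


class TestGRUCell:
    def test_zero_params_halves_hidden_state(self, rng):
        """sigma(0) = 1/2 and tanh(0) = 0 force h_t = h_prev / 2."""
        p = random_gru_params(rng, 4, 3)
        for name in ("W_iz", "W_ir", "W_in", "W_hz", "W_hr", "W_hn",
                     "b_iz", "b_ir", "b_in", "b_hz", "b_hr", "b_hn"):
            getattr(p, name)[...] = 0.0
        h_prev = np.array([1.0, -2.0, 0.5, 3.0])
        assert np.array_equal(pr.gru_cell_step(np.zeros(3), h_prev, p),
                              0.5 * h_prev)
        assert np.array_equal(pr.gru_cell_step(np.zeros(3), np.zeros(4), p),
                              np.zeros(4))

    def test_matches_scalar_oracle(self, rng):
        for _ in range(100):
            hidden = int(rng.integers(1, 9))
            inp = int(rng.integers(1, 6))
            p = random_gru_params(rng, hidden, inp)
            x = rng.normal(0, 1, inp)
            h_prev = rng.normal(0, 1, hidden)
            np.testing.assert_allclose(
                pr.gru_cell_step(x, h_prev, p),
                scalar_gru_oracle(x, h_prev, p),
                atol=1e-10,
            )

    def test_dimension_mismatch_rejected(self, rng):
        p = random_gru_params(rng, 3, 2)
        with pytest.raises(ValueError):
            pr.gru_cell_step(np.zeros(2), np.zeros(5), p)
        with pytest.raises(ValueError):
            pr.gru_cell_step(np.zeros(7), np.zeros(3), p)


@pytest.fixture(scope="module")
def model():
    return pr.CNNGRUClassifier(pr.desk_model_config(), seed=0)


class TestFrontEnd:
    @pytest.mark.parametrize("n,expected", [(900, 100), (9, 1), (100, 11)])
    def test_downsampling_lengths(self, model, n, expected):
        out = model.front_end(np.zeros((n, 20)))
        assert out.shape == (expected, model.config.conv_filters[1])

    def test_length_formula_over_range(self, model, rng):
        for n in rng.integers(9, 2000, size=30):
            n = int(n)
            assert model.front_end(np.zeros((n, 20))).shape[0] == (n // 3) // 3
            assert front_end_length(n) == (n // 3) // 3

    def test_short_profile_rejected_by_default(self, model):
        with pytest.raises(ValueError, match="pad_short"):
            model.front_end(np.zeros((5, 20)))

    def test_short_profile_padded_when_opted_in(self):
        m = pr.CNNGRUClassifier(pr.desk_model_config(pad_short=True), seed=0)
        assert m.front_end(np.zeros((5, 20))).shape[0] == 1


class TestForward:
    def test_output_in_unit_interval(self, rng):
        m = pr.CNNGRUClassifier(
            pr.ModelConfig(conv_filters=(4, 6), gru_hidden=5, fc_size=7), seed=1)
        for _ in range(50):
            n = int(rng.integers(9, 120))
            p = m.predict_proba(rng.normal(0, 3, size=(n, 20)))
            assert 0.0 <= p <= 1.0

    def test_zero_output_layer_gives_half(self, rng):
        m = pr.CNNGRUClassifier(pr.desk_model_config(), seed=2)
        m.out.W.v[...] = 0.0
        m.out.b.v[...] = 0.0
        assert m.predict_proba(rng.normal(0, 2, (30, 20))) == 0.5

    def test_forward_equals_stepwise_gru_loop(self, rng):
        """Full forward agrees with the front-end -> gru_cell_step loop ->
        FC path assembled by hand."""
        m = pr.CNNGRUClassifier(
            pr.ModelConfig(conv_filters=(4, 6), gru_hidden=5, fc_size=7,
                           dropout_rate=0.0), seed=3)
        scores = rng.normal(0, 2, (45, 20))
        xs = m.front_end(scores)
        gp = m.gru_params(0)
        h = np.zeros(5)
        for t in range(xs.shape[0]):
            h = pr.gru_cell_step(xs[t], h, gp)
        f = np.maximum(m.fc.W.v @ h + m.fc.b.v, 0.0)
        logit = float((m.out.W.v @ f + m.out.b.v)[0])
        prob = float(sigmoid(np.array([logit]))[0])
        assert abs(prob - m.predict_proba(scores)) < 1e-6

    def test_inference_deterministic_despite_dropout_config(self, rng):
        m = pr.CNNGRUClassifier(pr.desk_model_config(dropout_rate=0.5), seed=4)
        scores = rng.normal(0, 2, (40, 20))
        assert m.predict_proba(scores) == m.predict_proba(scores)

    def test_predictions_not_invariant_to_row_permutation(self, trained_order_model, rng):
        """The architecture preserves row order: for a trained model,
        shuffling profile rows moves predictions (unlike summed features)."""
        model, dataset, _ = trained_order_model
        changed = 0
        profiles = dataset.profiles[:50]
        for p in profiles:
            perm = rng.permutation(p.length)
            before = model.predict_proba(p.scores)
            after = model.predict_proba(p.scores[perm])
            if abs(before - after) > 1e-6:
                changed += 1
        # sign test: under invariance essentially none would move
        assert changed >= 0.9 * len(profiles)


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, rng):
        m = pr.CNNGRUClassifier(
            pr.ModelConfig(conv_filters=(4, 6), gru_hidden=5, fc_size=7), seed=5)
        path = tmp_path / "model.npz"
        pr.save_checkpoint(m, path)
        m2 = pr.load_checkpoint(path)
        scores = rng.normal(0, 2, (33, 20))
        assert m.predict_proba(scores) == m2.predict_proba(scores)


def test_backprop_matches_finite_differences(rng):
    """Analytic gradients of the whole network against central
    differences (the oracle for the hand-written backward passes)."""
    mc = pr.ModelConfig(conv_filters=(3, 4), conv_kernel=3, gru_hidden=3,
                        gru_layers=2, fc_size=5, dropout_rate=0.0)
    m = pr.CNNGRUClassifier(mc, seed=3)
    x = rng.normal(0, 2, size=(21, 20))

    def loss():
        logit = m.forward_logit(x, train=False)
        p = float(sigmoid(np.array([logit]))[0])
        return -np.log(p)  # y = 1

    for par in m.params:
        par.zero_grad()
    p = float(sigmoid(np.array([m.forward_logit(x)]))[0])
    m.backward(p - 1.0)

    eps = 1e-5
    check_rng = np.random.default_rng(1)
    for par in m.params:
        flat, grad = par.v.ravel(), par.g.ravel()
        for i in check_rng.choice(flat.size, size=min(4, flat.size), replace=False):
            orig = flat[i]
            flat[i] = orig + eps
            up = loss()
            flat[i] = orig - eps
            down = loss()
            flat[i] = orig
            numeric = (up - down) / (2 * eps)
            assert abs(numeric - grad[i]) <= 1e-4 * max(1.0, abs(numeric)), par.name
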