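import math

import numpy as np
import pytest

import semspace as ss
from semspace.meaning_space import MeaningSpace, MeaningVector, Proposition
from semspace.srn import SRNState, SRNWeights


def zero_weights(n_in, n_hid, n_out):
    return SRNWeights(
        w_ih=np.zeros((n_hid, n_in)),
        w_ch=np.zeros((n_hid, n_hid)),
        w_ho=np.zeros((n_out, n_hid)),
        b_h=np.zeros(n_hid),
        b_o=np.zeros(n_out),
    )


def sigmoid(z):
    return 1.0 / (1.0 + math.exp(-z))


class TestForwardStep:
    def test_zero_weights_give_half_activation(self):
        w = zero_weights(3, 4, 5)
        out, state = ss.forward_step(w, SRNState.initial(4), np.array([1.0, 0, 0]))
        np.testing.assert_allclose(out.values, 0.5)
        np.testing.assert_allclose(state.context, 0.5)

    def test_matches_hand_computed_logistic_composition(self):
        w = SRNWeights(
            w_ih=np.array([[0.5, -0.2], [0.1, 0.3]]),
            w_ch=np.array([[0.2, 0.0], [-0.1, 0.4]]),
            w_ho=np.array([[1.0, -1.0], [0.5, 0.5]]),
            b_h=np.array([0.1, -0.1]),
            b_o=np.array([0.0, 0.2]),
        )
        x = np.array([1.0, 0.0])
        h1 = sigmoid(0.5 + 0.2 * 0.5 + 0.0 * 0.5 + 0.1)
        h2 = sigmoid(0.1 + (-0.1) * 0.5 + 0.4 * 0.5 - 0.1)
        y1 = sigmoid(1.0 * h1 - 1.0 * h2 + 0.0)
        y2 = sigmoid(0.5 * h1 + 0.5 * h2 + 0.2)
        out, state = ss.forward_step(w, SRNState.initial(2), x)
        np.testing.assert_allclose(out.values, [y1, y2], atol=1e-12)
        np.testing.assert_allclose(state.context, [h1, h2], atol=1e-12)

    def test_context_reset_makes_first_word_deterministic(self, toy_world):
        _, space, corpus = toy_world
        rng = np.random.default_rng(0)
        cfg = ss.SRNConfig(n_input=len(corpus.vocabulary), n_hidden=8, n_output=8)
        w = SRNWeights.initialize(cfg, rng)
        vocab = corpus.vocabulary
        a = ss.run_sentence(w, np.array([vocab.index("beth"), vocab.index("paid")]))
        b = ss.run_sentence(w, np.array([vocab.index("beth"), vocab.index("left")]))
        np.testing.assert_array_equal(a[0], b[0])
        assert (a[1] != b[1]).any()


def toy_config(**kw):
    # the miniature problem trains comfortably at a faster rate than the
    # full pipeline's conservative default
    defaults = dict(
        n_input=5, n_hidden=16, n_output=8, epochs=500, learning_rate=0.1, seed=1
    )
    defaults.update(kw)
    return ss.SRNConfig(**defaults)


class TestTrain:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_toy_world_convergence(self, toy_world, seed):
        _, space, corpus = toy_world
        weights, _ = ss.train(toy_config(seed=seed), corpus, space)
        assert ss.mean_comprehension(weights, corpus, space) >= 0.95

    def test_zero_learning_rate_leaves_weights_unchanged(self, toy_world):
        _, space, corpus = toy_world
        cfg = toy_config(epochs=3, learning_rate=0.0)
        weights, _ = ss.train(cfg, corpus, space)
        init = SRNWeights.initialize(cfg, np.random.default_rng(cfg.seed))
        np.testing.assert_array_equal(weights.w_ih, init.w_ih)
        np.testing.assert_array_equal(weights.w_ho, init.w_ho)

    def test_seed_determinism_is_bitwise(self, toy_world):
        _, space, corpus = toy_world
        cfg = toy_config(epochs=20)
        w1, log1 = ss.train(cfg, corpus, space)
        w2, log2 = ss.train(cfg, corpus, space)
        for name in ("w_ih", "w_ch", "w_ho", "b_h", "b_o"):
            np.testing.assert_array_equal(getattr(w1, name), getattr(w2, name))
        assert log1 == log2

    def test_smoothed_loss_decreases_on_toy_world(self, toy_world):
        _, space, corpus = toy_world
        _, log = ss.train(toy_config(epochs=200), corpus, space)
        loss = np.array([rec["loss"] for rec in log])
        smoothed = np.convolve(loss, np.ones(10) / 10, mode="valid")
        assert smoothed[-1] < 0.5 * smoothed[0]
        # near-monotone once shuffling noise is averaged out
        assert (np.diff(smoothed) <= 0.05).all()

    def test_gradient_clipping_bounds_the_update(self, toy_world):
        """With lr=1 and no momentum, a clipped update has norm == bound."""
        _, space, corpus = toy_world
        one = ss.Corpus(corpus.items[:1], corpus.vocabulary)
        cfg = toy_config(epochs=1, learning_rate=1.0, momentum=0.0, gradient_bound=1.0)
        before = SRNWeights.initialize(cfg, np.random.default_rng(cfg.seed))
        after, _ = ss.train(cfg, one, space)
        delta_sq = sum(
            float(((getattr(after, n) - getattr(before, n)) ** 2).sum())
            for n in ("w_ih", "w_ch", "w_ho", "b_h", "b_o")
        )
        assert math.sqrt(delta_sq) == pytest.approx(cfg.gradient_bound, abs=1e-9)

    def test_unclipped_update_stays_below_a_large_bound(self, toy_world):
        _, space, corpus = toy_world
        one = ss.Corpus(corpus.items[:1], corpus.vocabulary)
        cfg = toy_config(epochs=1, learning_rate=1.0, momentum=0.0, gradient_bound=1e6)
        before = SRNWeights.initialize(cfg, np.random.default_rng(cfg.seed))
        after, _ = ss.train(cfg, one, space)
        delta_sq = sum(
            float(((getattr(after, n) - getattr(before, n)) ** 2).sum())
            for n in ("w_ih", "w_ch", "w_ho", "b_h", "b_o")
        )
        assert math.sqrt(delta_sq) < cfg.gradient_bound


class TestComprehensionScore:
    def space(self):
        props = (Proposition("p"),)
        return MeaningSpace(props, np.array([[1], [1], [0], [0]], dtype=np.uint8))

    def test_perfect_comprehension(self):
        space = self.space()
        target = MeaningVector(np.array([1.0, 1, 0, 0]))
        assert ss.comprehension_score(target, target, space) == 1.0

    def test_perfect_rejection(self):
        space = self.space()
        target = MeaningVector(np.array([1.0, 1, 0, 0]))
        complement = MeaningVector(1 - target.values)
        assert ss.comprehension_score(target, complement, space) == -1.0

    def test_chance_level(self):
        space = self.space()
        target = MeaningVector(np.array([1.0, 1, 0, 0]))
        uniform = MeaningVector(np.ones(4))
        assert ss.comprehension_score(target, uniform, space) == pytest.approx(0.0)

    def test_degenerate_prior_rejected(self):
        space = self.space()
        with pytest.raises(ValueError, match="prior"):
            ss.comprehension_score(MeaningVector(np.ones(4)), MeaningVector(np.ones(4)), space)


def test_weights_round_trip(tmp_path):
    cfg = ss.SRNConfig(n_input=4, n_hidden=3, n_output=5)
    w = SRNWeights.initialize(cfg, np.random.default_rng(0))
    w.save(tmp_path / "weights")
    loaded = SRNWeights.load(tmp_path / "weights")
    for name in ("w_ih", "w_ch", "w_ho", "b_h", "b_o"):
        np.testing.assert_allclose(getattr(loaded, name), getattr(w, name), atol=1e-12)
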