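import math

import numpy as np
import pytest

import semspace as ss
from semspace.language import Corpus, Sentence, Vocabulary
from semspace.meaning_space import (
    Atom,
    MeaningSpace,
    MeaningVector,
    Or,
    Proposition,
    parse_formula,
    vector_of,
)
from semspace.metrics import CLAMP_COUNTER, linguistic_surprisal, online_entropy
from semspace.srn import SRNConfig

P = Proposition


def mv(*values):
    return MeaningVector(np.array(values, dtype=float))


class TestOnlineSurprisal:
    def test_no_transition_no_surprisal(self, f4_space):
        v = vector_of(f4_space, Atom(P("p")))
        assert ss.online_surprisal(f4_space, v, v) == pytest.approx(0.0)

    def test_fixture_conditional(self, f4_space):
        p = vector_of(f4_space, Atom(P("p")))
        pq = vector_of(f4_space, parse_formula("(p & q)"))
        assert ss.online_surprisal(f4_space, p, pq) == pytest.approx(-math.log(2 / 3))

    def test_degenerate_condition_is_clamped_and_counted(self, f4_space):
        CLAMP_COUNTER.reset()
        s = ss.online_surprisal(f4_space, mv(0, 0, 0, 0), mv(1, 1, 1, 1))
        assert CLAMP_COUNTER.count == 1
        assert s == pytest.approx(-math.log(1e-10))

    def test_nonnegative_on_graded_vectors(self, f4_space):
        rng = np.random.default_rng(5)
        for _ in range(100):
            a, b = MeaningVector(rng.random(4)), MeaningVector(rng.random(4))
            assert ss.online_surprisal(f4_space, a, b) >= 0.0


class TestOnlineEntropy:
    def test_one_hot_on_unique_model_is_zero(self, f4_space):
        # row 1 (pattern 10) is unique in the fixture space
        assert ss.online_entropy(f4_space, mv(0, 1, 0, 0)) == pytest.approx(0.0)

    def test_duplicate_rows_aggregate_belief(self, f4_space):
        # rows 0 and 3 share pattern 11: all-ones groups to (1/2, 1/4, 1/4)
        expected = -(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25))
        assert ss.online_entropy(f4_space, mv(1, 1, 1, 1)) == pytest.approx(expected)

    def test_uniform_over_150_distinct_models(self, reduced_space):
        v = MeaningVector(np.ones(150))
        assert ss.online_entropy(reduced_space, v) == pytest.approx(math.log(150))
        assert math.log(150) == pytest.approx(5.01, abs=0.01)

    def test_all_zero_vector_rejected(self, f4_space):
        with pytest.raises(ValueError, match="all-zero"):
            ss.online_entropy(f4_space, mv(0, 0, 0, 0))

    def test_bounds_for_random_graded_vectors(self, f4_space):
        rng = np.random.default_rng(6)
        hmax = math.log(f4_space.n_unique_models)
        for _ in range(200):
            h = ss.online_entropy(f4_space, MeaningVector(rng.random(4)))
            assert 0.0 <= h <= hmax + 1e-12

    def test_continuity_under_small_perturbation(self, f4_space):
        rng = np.random.default_rng(7)
        base = MeaningVector(rng.random(4))
        h0 = ss.online_entropy(f4_space, base)
        bumped = MeaningVector(np.clip(base.values + 1e-6, 0, 1))
        assert abs(ss.online_entropy(f4_space, bumped) - h0) < 1e-4


class TestEntropyReduction:
    def test_identity_and_full_disambiguation(self):
        assert ss.entropy_reduction(1.5, 1.5) == 0.0
        assert ss.entropy_reduction(math.log(4), 0.0) == pytest.approx(math.log(4))

    def test_may_be_negative(self):
        assert ss.entropy_reduction(0.2, 0.9) < 0


def make_toy_corpus():
    vocab = Vocabulary(("a", "b", "c"))
    dummy = Atom(P("x"))
    return Corpus(
        [
            (Sentence(("a", "b"), dummy, "simple"), 3),
            (Sentence(("a", "c"), dummy, "simple"), 1),
        ],
        vocab,
    )


class TestLinguisticSurprisal:
    def test_count_ratio(self):
        corpus = make_toy_corpus()
        assert linguistic_surprisal(corpus, ("a", "b"), 2) == pytest.approx(-math.log(3 / 4))
        assert linguistic_surprisal(corpus, ("a", "c"), 2) == pytest.approx(-math.log(1 / 4))

    def test_forced_continuation_is_zero(self):
        corpus = make_toy_corpus()
        assert linguistic_surprisal(corpus, ("a", "b"), 1) == pytest.approx(-math.log(1.0))

    def test_unseen_prefix_rejected(self):
        with pytest.raises(ValueError, match="does not occur"):
            linguistic_surprisal(make_toy_corpus(), ("b", "a"), 2)

    def test_nine_to_one_contrast_in_default_corpus(self, default_corpus):
        s_pop = linguistic_surprisal(default_corpus, "beth ordered popcorn".split(), 3)
        s_din = linguistic_surprisal(default_corpus, "beth ordered dinner".split(), 3)
        assert s_pop - s_din == pytest.approx(math.log(9))


class TestSituationVectors:
    def test_dave_drank_is_drink_disjunction(self, reduced_space, default_corpus):
        sit = ss.situation_vector(reduced_space, default_corpus, ("dave", "drank"))
        expected = vector_of(
            reduced_space,
            parse_formula("((drink(dave,champagne) | drink(dave,cola)) | drink(dave,water))"),
        )
        np.testing.assert_array_equal(sit.values, expected.values)

    def test_full_sentence_prefix_is_its_own_semantics(self, reduced_space, default_corpus):
        sit = ss.situation_vector(reduced_space, default_corpus, ("beth", "ordered", "cola"))
        expected = vector_of(reduced_space, parse_formula("order(beth,cola)"))
        np.testing.assert_array_equal(sit.values, expected.values)

    def test_person_prefix_covers_39_sentences(self, reduced_space, default_corpus):
        beth = [s for s in default_corpus.sentences if s.words[0] == "beth"]
        assert len(beth) == 39
        sit = ss.situation_vector(reduced_space, default_corpus, ("beth",))
        acc = np.zeros(150)
        for s in beth:
            acc = np.maximum(acc, vector_of(reduced_space, s.semantics).values)
        np.testing.assert_array_equal(sit.values, acc)

    def test_unknown_prefix_rejected(self, reduced_space, default_corpus):
        with pytest.raises(ValueError, match="prefix"):
            ss.situation_vector(reduced_space, default_corpus, ("cola",))

    def test_word_removing_no_completions_has_zero_situation_surprisal(
        self, reduced_space, default_corpus
    ):
        # after "beth asked", the only continuation is "for the menu"
        words = "beth asked for the menu".split()
        for t in (3, 4, 5):
            assert ss.situation_surprisal(
                reduced_space, default_corpus, words, t
            ) == pytest.approx(0.0)

    def test_offline_situation_entropy_reduction_degenerates_to_surprisal(
        self, reduced_space, default_corpus
    ):
        """With binary situation vectors over duplicate-free uniform models,
        the entropy drop between consecutive situation vectors equals the
        situation surprisal of the word (so the offline entropy-reduction
        variant carries no extra information)."""
        for s in default_corpus.sentences[::7]:
            for t in range(1, len(s.words) + 1):
                h_prev = online_entropy(
                    reduced_space,
                    ss.situation_vector(reduced_space, default_corpus, s.words[: t - 1]),
                )
                h_curr = online_entropy(
                    reduced_space,
                    ss.situation_vector(reduced_space, default_corpus, s.words[:t]),
                )
                s_sit = ss.situation_surprisal(reduced_space, default_corpus, s, t)
                assert h_prev - h_curr == pytest.approx(s_sit, abs=1e-9)


class TestPolarization:
    def test_binary_vector_counts_full_length(self):
        assert ss.polarization(mv(1, 0, 1, 0, 1)) == 5

    def test_middling_vector_counts_zero(self):
        assert ss.polarization(MeaningVector(np.full(10, 0.5))) == 0

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError, match="lo < hi"):
            ss.polarization(mv(0.5), lo=0.9, hi=0.1)


@pytest.fixture(scope="module")
def toy_trace(toy_world):
    _, space, corpus = toy_world
    cfg = SRNConfig(n_input=len(corpus.vocabulary), n_hidden=8, n_output=8, epochs=30, seed=0)
    weights, _ = ss.train(cfg, corpus, space)
    return space, corpus, weights


class TestTrace:

    def test_all_metrics_finite_with_one_row_per_word(self, toy_trace):
        space, corpus, weights = toy_trace
        for s in corpus.sentences:
            tr = ss.trace(space, weights, corpus, s)
            frame = tr.to_frame()
            assert len(frame) == len(s.words)
            assert np.isfinite(frame[["S_onl", "H", "dH_onl", "S_ling", "S_sit"]].to_numpy()).all()

    def test_entropy_reduction_matches_entropy_differences(self, toy_trace):
        space, corpus, weights = toy_trace
        tr = ss.trace(space, weights, corpus, corpus.sentences[0])
        np.testing.assert_allclose(tr.delta_h, tr.entropy[:-1] - tr.entropy[1:])

    def test_no_clamping_on_well_behaved_vectors(self, toy_trace):
        space, corpus, weights = toy_trace
        CLAMP_COUNTER.reset()
        for s in corpus.sentences:
            tr = ss.trace(space, weights, corpus, s)
            assert tr.n_clamped == 0
        assert CLAMP_COUNTER.count == 0
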