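"""Information-theoretic metrics over meaning-space navigation.

Online metrics are computed from the network's word-by-word output vectors:
surprisal is the negative log conditional belief of the current vector
given the previous one; entropy is the Shannon entropy of the normalized
belief distribution over the unique models of the space; entropy reduction
is the drop in entropy caused by a word.  Offline metrics are computed
from the training corpus alone: linguistic surprisal from frequency-
weighted prefix counts, and situation surprisal from situation vectors
(the disjunction of the semantics of all sentences consistent with a
prefix).  All logarithms are natural (values in nats).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .language import Corpus, Sentence
from .meaning_space import (
    MeaningSpace,
    MeaningVector,
    vector_of,
)
from .srn import SRNWeights, initial_output, run_sentence

__all__ = [
    "CLAMP_COUNTER",
    "Trajectory",
    "online_surprisal",
    "online_entropy",
    "entropy_reduction",
    "linguistic_surprisal",
    "situation_vector",
    "situation_surprisal",
    "polarization",
    "trace",
]

#: Belief floor for logarithms of near-zero conditionals.
DEFAULT_EPSILON = 1e-10


class _ClampCounter:
    """Counts epsilon-clamps of degenerate conditionals, for auditability."""

    def __init__(self) -> None:
        self.count = 0

    def reset(self) -> None:
        self.count = 0


CLAMP_COUNTER = _ClampCounter()


def online_surprisal(
    space: MeaningSpace,
    v_prev: MeaningVector,
    v_curr: MeaningVector,
    epsilon: float = DEFAULT_EPSILON,
) -> float:
    """-ln P(v_curr | v_prev); >= 0 since the conditional belief is <= 1.

    Degenerate conditions (zero prior belief or a vanishing conditional)
    are clamped at ``epsilon`` and counted on :data:`CLAMP_COUNTER` rather
    than silently producing NaN/inf.
    """
    prior = float(v_prev.values.sum())
    if prior <= 0.0:
        CLAMP_COUNTER.count += 1
        return -math.log(epsilon)
    cond = float((v_prev.values * v_curr.values).sum() / prior)
    if cond < epsilon:
        CLAMP_COUNTER.count += 1
        cond = epsilon
    return -math.log(cond)


def online_entropy(
    space: MeaningSpace, v: MeaningVector, epsilon: float = DEFAULT_EPSILON
) -> float:
    """Entropy of the belief distribution over unique models given ``v``.

    Beliefs of duplicate model rows are aggregated, normalized to a
    distribution, and scored with -sum p ln p (0 ln 0 = 0).  Zero for a
    one-hot vector on a unique model; maximal, ln(#unique models), for a
    uniform vector over a duplicate-free space.
    """
    if len(v) != space.n_models:
        raise ValueError("vector length does not match the space")
    groups = space.unique_model_index
    if len(groups) == space.n_models:
        beliefs = v.values
    else:
        beliefs = np.array([v.values[g].sum() for g in groups])
    total = beliefs.sum()
    if total <= epsilon:
        raise ValueError("entropy undefined for an all-zero meaning vector")
    p = beliefs / total
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum())


def entropy_reduction(h_prev: float, h_curr: float) -> float:
    """H(t-1) - H(t); may be negative when a word increases uncertainty."""
    if not (math.isfinite(h_prev) and math.isfinite(h_curr)):
        raise ValueError("entropy reduction requires finite entropies")
    return h_prev - h_curr


# --- offline metrics --------------------------------------------------------


class _CorpusStats:
    """Frequency-weighted prefix counts and situation vectors for a corpus."""

    def __init__(self, corpus: Corpus, space: MeaningSpace | None = None):
        self.corpus = corpus
        self.space = space
        self.prefix_freq: dict[tuple[str, ...], int] = {}
        for s, f in corpus.items:
            for t in range(len(s.words) + 1):
                key = s.words[:t]
                self.prefix_freq[key] = self.prefix_freq.get(key, 0) + f
        self._sit_cache: dict[tuple[str, ...], MeaningVector] = {}

    def situation(self, prefix: tuple[str, ...]) -> MeaningVector:
        if prefix not in self._sit_cache:
            if self.space is None:
                raise ValueError("situation vectors need a meaning space")
            consistent = [
                s for s, _ in self.corpus.items if s.words[: len(prefix)] == prefix
            ]
            if not consistent:
                raise ValueError(f"no corpus sentence has prefix {' '.join(prefix)!r}")
            values = np.zeros(self.space.n_models)
            for s in consistent:
                np.maximum(values, vector_of(self.space, s.semantics).values, out=values)
            self._sit_cache[prefix] = MeaningVector(values)
        return self._sit_cache[prefix]


_STATS_CACHE: dict[tuple[int, int], _CorpusStats] = {}


def _stats(corpus: Corpus, space: MeaningSpace | None = None) -> _CorpusStats:
    key = (id(corpus), id(space))
    if key not in _STATS_CACHE:
        if len(_STATS_CACHE) > 8:
            _STATS_CACHE.clear()
        _STATS_CACHE[key] = _CorpusStats(corpus, space)
    return _STATS_CACHE[key]


def linguistic_surprisal(corpus: Corpus, sentence: Sentence | Sequence[str], t: int) -> float:
    """-ln P(w_t | w_1..t-1) from frequency-weighted corpus prefix counts.

    ``t`` is 1-based.  The language is closed, so unseen prefixes are an
    error rather than smoothed.
    """
    words = sentence.words if isinstance(sentence, Sentence) else tuple(sentence)
    if not 1 <= t <= len(words):
        raise IndexError(f"word position {t} out of range 1..{len(words)}")
    stats = _stats(corpus)
    num = stats.prefix_freq.get(words[:t], 0)
    denom = stats.prefix_freq.get(words[: t - 1], 0)
    if num == 0 or denom == 0:
        raise ValueError(f"prefix {' '.join(words[:t])!r} does not occur in the corpus")
    return -math.log(num / denom)


def situation_vector(
    space: MeaningSpace, corpus: Corpus, prefix: Sequence[str]
) -> MeaningVector:
    """Disjunction of the semantics of all sentences consistent with ``prefix``."""
    return _stats(corpus, space).situation(tuple(prefix))


def situation_surprisal(
    space: MeaningSpace, corpus: Corpus, sentence: Sentence | Sequence[str], t: int
) -> float:
    """-ln P(sit(w_1..t) | sit(w_1..t-1)): world-knowledge surprisal."""
    words = sentence.words if isinstance(sentence, Sentence) else tuple(sentence)
    if not 1 <= t <= len(words):
        raise IndexError(f"word position {t} out of range 1..{len(words)}")
    stats = _stats(corpus, space)
    prev = stats.situation(words[: t - 1])
    curr = stats.situation(words[:t])
    return online_surprisal(space, prev, curr)


def polarization(v: MeaningVector, lo: float = 0.1, hi: float = 0.9) -> int:
    """Number of entries pushed near the Boolean poles (< lo or > hi)."""
    if lo >= hi:
        raise ValueError("polarization thresholds require lo < hi")
    return int(((v.values < lo) | (v.values > hi)).sum())


# --- trajectories -----------------------------------------------------------


@dataclass
class Trajectory:
    """Per-word record of network outputs and all metrics for one sentence.

    ``vectors`` holds v_0 (the empty-context output) followed by the T
    word outputs; ``entropy`` likewise has T+1 entries so that
    ``delta_h[t] = entropy[t] - entropy[t+1]``.
    """

    sentence: Sentence
    vectors: np.ndarray  # (T+1, n_models)
    s_onl: np.ndarray  # (T,)
    entropy: np.ndarray  # (T+1,)
    delta_h: np.ndarray  # (T,)
    s_ling: np.ndarray  # (T,)
    s_sit: np.ndarray  # (T,)
    polar: np.ndarray  # (T,) int
    n_clamped: int = 0

    def __post_init__(self) -> None:
        T = len(self.sentence.words)
        if self.vectors.shape[0] != T + 1 or self.entropy.shape[0] != T + 1:
            raise ValueError("trajectory length does not match the sentence")
        for arr in (self.s_onl, self.entropy, self.delta_h, self.s_ling, self.s_sit):
            if not np.isfinite(arr).all():
                raise ValueError("trajectory metrics must be finite")

    def to_frame(self) -> pd.DataFrame:
        T = len(self.sentence.words)
        return pd.DataFrame(
            {
                "position": np.arange(1, T + 1),
                "word": list(self.sentence.words),
                "S_onl": self.s_onl,
                "H_prev": self.entropy[:-1],
                "H": self.entropy[1:],
                "dH_onl": self.delta_h,
                "abs_dH_onl": np.abs(self.delta_h),
                "S_ling": self.s_ling,
                "S_sit": self.s_sit,
                "polarization": self.polar,
            }
        )


def trace(
    space: MeaningSpace,
    weights: SRNWeights,
    corpus: Corpus,
    sentence: Sentence,
    epsilon: float = DEFAULT_EPSILON,
) -> Trajectory:
    """Run a sentence through the network and fill in all five metrics."""
    vocab = corpus.vocabulary
    seq = np.array([vocab.index(w) for w in sentence.words])
    T = len(seq)
    before = CLAMP_COUNTER.count
    v0 = initial_output(weights)
    outputs = run_sentence(weights, seq)
    vectors = np.vstack([v0.values, outputs])
    mv = [MeaningVector(row) for row in vectors]
    ent = np.array([online_entropy(space, v, epsilon) for v in mv])
    s_onl = np.array(
        [online_surprisal(space, mv[t], mv[t + 1], epsilon) for t in range(T)]
    )
    delta_h = ent[:-1] - ent[1:]
    s_ling = np.array([linguistic_surprisal(corpus, sentence, t) for t in range(1, T + 1)])
    s_sit = np.array(
        [situation_surprisal(space, corpus, sentence, t) for t in range(1, T + 1)]
    )
    polar = np.array([polarization(v) for v in mv[1:]])
    return Trajectory(
        sentence=sentence,
        vectors=vectors,
        s_onl=s_onl,
        entropy=ent,
        delta_h=delta_h,
        s_ling=s_ling,
        s_sit=s_sit,
        polar=polar,
        n_clamped=CLAMP_COUNTER.count - before,
    )
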