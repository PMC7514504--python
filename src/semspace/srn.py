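"""Simple recurrent network mapping word sequences onto meaning vectors.

A three-layer Elman network (localist input, logistic hidden and output
layers; the hidden layer additionally receives its own previous activation
through a context layer).  The network is trained with bounded gradient
descent -- gradients accumulated over a sentence, clipped to a global norm
bound, and applied with momentum -- to produce the sentence's meaning
vector at the output layer at *every* word position.  Presenting the
sentence-final semantics as target throughout the sentence is what makes
intermediate outputs anticipatory points in meaning space.

Comprehension is evaluated with a normalized belief-gain score in [-1, +1]:
+1 when the target meaning is fully inferred from the output, -1 when it is
fully understood not to be the case, 0 at chance (prior) level.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit

from .language import Corpus
from .meaning_space import MeaningSpace, MeaningVector, vector_of

__all__ = [
    "SRNConfig",
    "SRNWeights",
    "SRNState",
    "forward_step",
    "run_sentence",
    "initial_output",
    "train",
    "comprehension_score",
    "mean_comprehension",
]

#: Context-layer activation at sentence onset.
CONTEXT_INIT = 0.5


@dataclass(frozen=True)
class SRNConfig:
    n_input: int = 21
    n_hidden: int = 100
    n_output: int = 150
    epochs: int = 5000
    learning_rate: float = 0.007
    momentum: float = 0.9
    gradient_bound: float = 1.0
    init_scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")
        if self.gradient_bound <= 0 or self.init_scale <= 0:
            raise ValueError("gradient_bound and init_scale must be positive")


@dataclass
class SRNWeights:
    w_ih: np.ndarray  # (hidden, input)
    w_ch: np.ndarray  # (hidden, hidden) context -> hidden
    w_ho: np.ndarray  # (output, hidden)
    b_h: np.ndarray  # (hidden,)
    b_o: np.ndarray  # (output,)

    def __post_init__(self) -> None:
        h, i = self.w_ih.shape
        if self.w_ch.shape != (h, h) or self.w_ho.shape[1] != h:
            raise ValueError("inconsistent weight shapes")
        if self.b_h.shape != (h,) or self.b_o.shape != (self.w_ho.shape[0],):
            raise ValueError("inconsistent bias shapes")
        for arr in (self.w_ih, self.w_ch, self.w_ho, self.b_h, self.b_o):
            if not np.isfinite(arr).all():
                raise ValueError("weights contain non-finite entries")

    @property
    def n_hidden(self) -> int:
        return self.w_ih.shape[0]

    @property
    def n_output(self) -> int:
        return self.w_ho.shape[0]

    @classmethod
    def initialize(cls, config: SRNConfig, rng: np.random.Generator) -> "SRNWeights":
        s = config.init_scale
        u = lambda *shape: rng.uniform(-s, s, shape)
        return cls(
            w_ih=u(config.n_hidden, config.n_input),
            w_ch=u(config.n_hidden, config.n_hidden),
            w_ho=u(config.n_output, config.n_hidden),
            b_h=u(config.n_hidden),
            b_o=u(config.n_output),
        )

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        names = ("w_ih", "w_ch", "w_ho", "b_h", "b_o")
        with open(directory / "manifest.tsv", "w") as fh:
            for name in names:
                arr = getattr(self, name)
                fh.write(f"{name}\t{'x'.join(map(str, arr.shape))}\n")
                np.savetxt(directory / f"{name}.tsv", np.atleast_2d(arr), delimiter="\t")

    @classmethod
    def load(cls, directory: str | Path) -> "SRNWeights":
        directory = Path(directory)
        arrays = {}
        for line in (directory / "manifest.tsv").read_text().splitlines():
            name, shape = line.split("\t")
            arr = np.loadtxt(directory / f"{name}.tsv", delimiter="\t", ndmin=2)
            arrays[name] = arr.reshape(tuple(int(d) for d in shape.split("x")))
        return cls(**arrays)


@dataclass
class SRNState:
    context: np.ndarray

    @classmethod
    def initial(cls, n_hidden: int) -> "SRNState":
        return cls(np.full(n_hidden, CONTEXT_INIT))


def _step(weights: SRNWeights, context: np.ndarray, x_col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    hidden = expit(x_col + weights.w_ch @ context + weights.b_h)
    output = expit(weights.w_ho @ hidden + weights.b_o)
    return hidden, output


def forward_step(
    weights: SRNWeights, state: SRNState, word_vector: np.ndarray
) -> tuple[MeaningVector, SRNState]:
    """One time step: logistic(hidden) from input + context, then output."""
    x = np.asarray(word_vector, dtype=float)
    hidden, output = _step(weights, state.context, weights.w_ih @ x)
    if not np.isfinite(output).all():
        raise FloatingPointError("non-finite activations (training diverged?)")
    return MeaningVector(output), SRNState(hidden)


def run_sentence(weights: SRNWeights, word_indices: np.ndarray) -> np.ndarray:
    """Forward a sentence from a reset context; returns (T, n_output) outputs."""
    context = np.full(weights.n_hidden, CONTEXT_INIT)
    outputs = np.empty((len(word_indices), weights.n_output))
    for t, wi in enumerate(word_indices):
        context, outputs[t] = _step(weights, context, weights.w_ih[:, wi])
    return outputs


def initial_output(weights: SRNWeights) -> MeaningVector:
    """Network output before the first word: zero input from a reset context."""
    _, output = _step(weights, np.full(weights.n_hidden, CONTEXT_INIT), 0.0)
    return MeaningVector(output)


# --- training ---------------------------------------------------------------


def _encode_corpus(corpus: Corpus, space: MeaningSpace):
    vocab = corpus.vocabulary
    seqs = [np.array([vocab.index(w) for w in s.words]) for s in corpus.sentences]
    targets = [vector_of(space, s.semantics).values for s in corpus.sentences]
    tokens = np.repeat(
        np.arange(len(seqs)), [f for _, f in corpus.items]
    )
    return seqs, targets, tokens


def train(
    config: SRNConfig, corpus: Corpus, space: MeaningSpace
) -> tuple[SRNWeights, list[dict]]:
    """Bounded gradient descent on summed per-unit binary cross-entropy.

    The sentence-final semantics vector is the target at every word
    position.  Gradients are accumulated over a sentence (context treated
    as fixed input at each step, i.e. no backpropagation through time),
    clipped to a global norm of ``gradient_bound``, and applied once per
    sentence with momentum.  Token order is reshuffled every epoch
    (seeded).  Returns the weights and a per-epoch log of mean loss and
    mean sentence-final comprehension over training tokens.
    """
    if len(corpus.vocabulary) != config.n_input:
        raise ValueError("n_input does not match vocabulary size")
    if space.n_models != config.n_output:
        raise ValueError("n_output does not match the meaning space")
    rng = np.random.default_rng(config.seed)
    weights = SRNWeights.initialize(config, rng)
    seqs, targets, tokens = _encode_corpus(corpus, space)
    priors = np.array([t.mean() for t in targets])
    if ((priors <= 0) | (priors >= 1)).any():
        bad = corpus.sentences[int(np.argmax((priors <= 0) | (priors >= 1)))]
        raise ValueError(
            f"degenerate semantics (prior 0 or 1) for sentence {bad.text!r}"
        )

    w = weights
    g_ih = np.zeros_like(w.w_ih)
    g_ch = np.zeros_like(w.w_ch)
    g_ho = np.zeros_like(w.w_ho)
    g_bh = np.zeros_like(w.b_h)
    g_bo = np.zeros_like(w.b_o)
    grads = (g_ih, g_ch, g_ho, g_bh, g_bo)
    vels = tuple(np.zeros_like(g) for g in grads)
    params = (w.w_ih, w.w_ch, w.w_ho, w.b_h, w.b_o)
    lr, mom, bound = config.learning_rate, config.momentum, config.gradient_bound
    eps = 1e-12
    log: list[dict] = []

    for epoch in range(config.epochs):
        order = rng.permutation(tokens)
        total_loss = 0.0
        total_words = 0
        comp_sum = 0.0
        for si in order:
            seq, target = seqs[si], targets[si]
            tau = priors[si]
            for g in grads:
                g[:] = 0.0
            context = np.full(w.n_hidden, CONTEXT_INIT)
            for wi in seq:
                hidden, y = _step(w, context, w.w_ih[:, wi])
                yc = np.clip(y, eps, 1.0 - eps)
                total_loss += -(target @ np.log(yc) + (1.0 - target) @ np.log(1.0 - yc))
                d_out = y - target
                g_ho += np.outer(d_out, hidden)
                g_bo += d_out
                d_h = (w.w_ho.T @ d_out) * hidden * (1.0 - hidden)
                g_ih[:, wi] += d_h
                g_ch += np.outer(d_h, context)
                g_bh += d_h
                context = hidden
            total_words += len(seq)
            # final-word comprehension of this token
            beta = float((y * target).sum() / y.sum())
            comp_sum += (beta - tau) / ((1.0 - tau) if beta >= tau else tau)
            # bounded update: clip the accumulated gradient's global norm
            norm = np.sqrt(sum(float((g * g).sum()) for g in grads))
            if norm > bound:
                scale = bound / norm
                for g in grads:
                    g *= scale
            for p, v, g in zip(params, vels, grads):
                v *= mom
                v -= lr * g
                p += v
        if not np.isfinite(total_loss):
            raise FloatingPointError(
                "training diverged (non-finite loss); try a lower learning rate"
            )
        log.append(
            {
                "epoch": epoch,
                "loss": total_loss / total_words,
                "comprehension": comp_sum / len(order),
            }
        )
    return w, log


# --- evaluation -------------------------------------------------------------


def comprehension_score(
    target: MeaningVector, output: MeaningVector, space: MeaningSpace
) -> float:
    """Normalized belief gain of ``target`` given ``output``, in [-1, +1].

    With prior tau = P(target) and conditional belief
    beta = P(target | output): (beta - tau) / (1 - tau) when belief rises
    above the prior, (beta - tau) / tau when it falls below.
    """
    from .meaning_space import conditional_probability, probability

    tau = probability(space, target)
    if tau <= 0.0 or tau >= 1.0:
        raise ValueError(f"comprehension score undefined for prior {tau}")
    beta = conditional_probability(space, given=output, target=target)
    return (beta - tau) / (1.0 - tau) if beta >= tau else (beta - tau) / tau


def mean_comprehension(
    weights: SRNWeights, corpus: Corpus, space: MeaningSpace
) -> float:
    """Mean sentence-final comprehension score over the corpus sentence types."""
    scores = []
    vocab = corpus.vocabulary
    for s in corpus.sentences:
        seq = np.array([vocab.index(wd) for wd in s.words])
        final = MeaningVector(run_sentence(weights, seq)[-1])
        target = vector_of(space, s.semantics)
        scores.append(comprehension_score(target, final, space))
    return float(np.mean(scores))


def save_training_log(log: list[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("epoch\tloss\tcomprehension\n")
        for rec in log:
            fh.write(f"{rec['epoch']}\t{rec['loss']:.6f}\t{rec['comprehension']:.6f}\n")
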