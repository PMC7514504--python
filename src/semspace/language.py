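"""The microlanguage: grammar, sentence semantics, corpus and encodings.

Sentences are simple (``NP VP``, one per atomic proposition) or coordinated
(``NP entered the PLACE and VP``); verb phrases map directly onto
propositions, so a simple sentence's semantics is an atom and a coordinated
sentence's a conjunction sharing the person argument.  For the default
world this yields 117 sentence types over a 21-word vocabulary.

Linguistic experience is manipulated through token frequencies: by default
the simple sentences "NP ordered dinner" and "NP ordered champagne" occur
nine times as often as their popcorn/water counterparts, while coordinated
sentences are uniform (so that place-conditioned contrasts keep linguistic
experience constant) and person-name frequencies stay balanced.

Words are encoded localistically: one input unit per vocabulary word.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .meaning_space import And, Atom, Formula, Proposition, parse_formula
from .world import WorldSpec, default_world_spec, enumerate_propositions

__all__ = [
    "Vocabulary",
    "Sentence",
    "Corpus",
    "DEFAULT_FREQUENCY_RULES",
    "build_vocabulary",
    "generate_sentences",
    "sentence_semantics",
    "parse_sentence",
    "build_corpus",
    "encode",
    "decode",
]


@dataclass(frozen=True)
class Vocabulary:
    words: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.words)) != len(self.words):
            raise ValueError("vocabulary contains duplicate words")

    def __len__(self) -> int:
        return len(self.words)

    def index(self, word: str) -> int:
        try:
            return self.words.index(word)
        except ValueError:
            raise KeyError(f"out-of-vocabulary word: {word!r}") from None

    def save(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.words) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        return cls(tuple(Path(path).read_text().split()))


def build_vocabulary(spec: WorldSpec | None = None) -> Vocabulary:
    """Canonical vocabulary (21 words for the default world)."""
    spec = spec or default_world_spec()
    words: list[str] = list(spec.persons)
    preds = dict(spec.predicates)
    if "enter" in preds:
        words += ["entered", "the", *spec.places]
    if "ask_menu" in preds:
        words += ["asked", "for", "menu"]
        if "the" not in words:
            words.append("the")
    if "order" in preds:
        words.append("ordered")
    if "eat" in preds:
        words.append("ate")
    if "drink" in preds:
        words.append("drank")
    if any(p in preds for p in ("order", "eat")):
        words += list(spec.foods)
    if any(p in preds for p in ("order", "drink")):
        words += list(spec.drinks)
    if "pay" in preds:
        words.append("paid")
    if "leave" in preds:
        words.append("left")
    words.append("and")
    return Vocabulary(tuple(words))


def _vp_words(prop: Proposition) -> tuple[str, ...]:
    pred, args = prop.predicate, prop.arguments
    if pred == "enter":
        return ("entered", "the", args[1])
    if pred == "ask_menu":
        return ("asked", "for", "the", "menu")
    if pred == "order":
        return ("ordered", args[1])
    if pred == "eat":
        return ("ate", args[1])
    if pred == "drink":
        return ("drank", args[1])
    if pred == "pay":
        return ("paid",)
    if pred == "leave":
        return ("left",)
    raise ValueError(f"no verb phrase realization for predicate {pred!r}")


@dataclass(frozen=True)
class Sentence:
    words: tuple[str, ...]
    semantics: Formula
    structure: str  # "simple" | "coordinated"

    @property
    def text(self) -> str:
        return " ".join(self.words)

    def __len__(self) -> int:
        return len(self.words)


def generate_sentences(spec: WorldSpec | None = None) -> list[Sentence]:
    """All sentence types, deterministically ordered: simple then coordinated.

    Simple sentences follow the canonical proposition order; coordinated
    sentences ("NP entered the PLACE and VP") iterate person, place, then
    the second verb phrase (ask_menu, order, eat, drink, pay).
    """
    spec = spec or default_world_spec()
    preds = dict(spec.predicates)
    out: list[Sentence] = []
    for prop in enumerate_propositions(spec):
        person = prop.arguments[0]
        out.append(
            Sentence((person, *_vp_words(prop)), Atom(prop), "simple")
        )
    if "enter" not in preds:
        return out
    second_vps: list[Proposition] = []
    for person in spec.persons:
        second_vps = []
        if "ask_menu" in preds:
            second_vps.append(Proposition("ask_menu", (person,)))
        if "order" in preds:
            second_vps += [
                Proposition("order", (person, x)) for x in spec.domain("orderable")
            ]
        if "eat" in preds:
            second_vps += [Proposition("eat", (person, x)) for x in spec.foods]
        if "drink" in preds:
            second_vps += [Proposition("drink", (person, x)) for x in spec.drinks]
        if "pay" in preds:
            second_vps.append(Proposition("pay", (person,)))
        for place in spec.places:
            enter = Proposition("enter", (person, place))
            for vp2 in second_vps:
                words = (person, "entered", "the", place, "and", *_vp_words(vp2))
                out.append(
                    Sentence(words, And(Atom(enter), Atom(vp2)), "coordinated")
                )
    return out


def parse_sentence(words: Sequence[str], spec: WorldSpec | None = None) -> Sentence:
    """Parse a word sequence into a Sentence, recovering its semantics."""
    spec = spec or default_world_spec()
    words = tuple(words)
    if not words or words[0] not in spec.persons:
        offending = words[0] if words else "<empty>"
        raise ValueError(f"cannot parse sentence: expected a person name, got {offending!r}")
    person = words[0]

    def parse_vp(rest: tuple[str, ...]) -> tuple[Proposition, tuple[str, ...]]:
        candidates = [
            Proposition(name, (person,) if dom is None else (person, obj))
            for name, dom in spec.predicates
            for obj in (spec.domain(dom) if dom is not None else (None,))
        ]
        for prop in candidates:
            vp = _vp_words(prop)
            if rest[: len(vp)] == vp:
                return prop, rest[len(vp):]
        raise ValueError(f"cannot parse verb phrase starting at {rest[0]!r}")

    prop1, rest = parse_vp(words[1:])
    if not rest:
        return Sentence(words, Atom(prop1), "simple")
    if rest[0] != "and":
        raise ValueError(f"cannot parse sentence: unexpected word {rest[0]!r}")
    prop2, rest = parse_vp(rest[1:])
    if rest:
        raise ValueError(f"cannot parse sentence: trailing word {rest[0]!r}")
    return Sentence(words, And(Atom(prop1), Atom(prop2)), "coordinated")


def sentence_semantics(s: Sentence | Sequence[str], spec: WorldSpec | None = None) -> Formula:
    """Semantics of a sentence: an atom (simple) or a conjunction (coordinated)."""
    if isinstance(s, Sentence):
        return s.semantics
    return parse_sentence(s, spec).semantics


# --- corpus -----------------------------------------------------------------

#: Default frequency manipulation: the simple "ordered dinner/champagne"
#: sentences occur nine times as often as their popcorn/water counterparts.
DEFAULT_FREQUENCY_RULES: dict[str, int] = {
    "NP ordered dinner": 9,
    "NP ordered champagne": 9,
}


@dataclass
class Corpus:
    items: list[tuple[Sentence, int]]
    vocabulary: Vocabulary

    def __post_init__(self) -> None:
        for sentence, freq in self.items:
            if freq <= 0:
                raise ValueError(f"non-positive frequency for {sentence.text!r}")
            for w in sentence.words:
                if w not in self.vocabulary.words:
                    raise KeyError(f"word {w!r} not in vocabulary")

    @property
    def sentences(self) -> list[Sentence]:
        return [s for s, _ in self.items]

    @property
    def total_tokens(self) -> int:
        return sum(f for _, f in self.items)

    def word_token_count(self, word: str) -> int:
        return sum(f * s.words.count(word) for s, f in self.items)

    def frequency_of(self, words: Sequence[str]) -> int:
        words = tuple(words)
        return sum(f for s, f in self.items if s.words == words)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s, f in self.items:
                fh.write(f"{s.text}\t{s.semantics}\t{f}\n")

    @classmethod
    def load(cls, path: str | Path, vocabulary: Vocabulary) -> "Corpus":
        items = []
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            text, formula, freq = line.split("\t")
            words = tuple(text.split())
            sem = parse_formula(formula)
            structure = "coordinated" if isinstance(sem, And) else "simple"
            items.append((Sentence(words, sem, structure), int(freq)))
        return cls(items, vocabulary)


def _pattern_matches(pattern: str, sentence: Sentence, spec: WorldSpec) -> bool:
    pat = pattern.split()
    if len(pat) != len(sentence.words):
        return False
    for p, w in zip(pat, sentence.words):
        if p == "NP":
            if w not in spec.persons:
                return False
        elif p == "PLACE":
            if w not in spec.places:
                return False
        elif p != w:
            return False
    return True


def build_corpus(
    sentences: Iterable[Sentence],
    freq_spec: dict[str, int] | None = None,
    spec: WorldSpec | None = None,
    vocabulary: Vocabulary | None = None,
) -> Corpus:
    """Assign token frequencies to sentence types.

    ``freq_spec`` maps sentence patterns (with ``NP``/``PLACE`` wildcards)
    to positive multipliers; unmatched sentences keep frequency 1.  Because
    patterns never mention specific persons, person-name token frequencies
    remain balanced.
    """
    spec = spec or default_world_spec()
    if freq_spec is None:
        freq_spec = DEFAULT_FREQUENCY_RULES
    for pattern, mult in freq_spec.items():
        if mult <= 0:
            raise ValueError(f"frequency multiplier for {pattern!r} must be positive")
    vocabulary = vocabulary or build_vocabulary(spec)
    items = []
    for s in sentences:
        freq = 1
        for pattern, mult in freq_spec.items():
            if _pattern_matches(pattern, s, spec):
                freq *= mult
        items.append((s, freq))
    return Corpus(items, vocabulary)


# --- localist encoding ------------------------------------------------------


def encode(s: Sentence | Sequence[str], v: Vocabulary) -> np.ndarray:
    """One-hot encode a sentence: (T, |V|) matrix with a single 1 per row."""
    words = s.words if isinstance(s, Sentence) else tuple(s)
    out = np.zeros((len(words), len(v)), dtype=float)
    for t, w in enumerate(words):
        out[t, v.index(w)] = 1.0
    return out


def decode(matrix: np.ndarray, v: Vocabulary) -> tuple[str, ...]:
    """Inverse of :func:`encode` for well-formed one-hot rows."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[1] != len(v):
        raise ValueError("expected a (T, |V|) one-hot matrix")
    return tuple(v.words[int(i)] for i in matrix.argmax(axis=1))
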