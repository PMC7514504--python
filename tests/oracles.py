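"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's vectorized code paths: formulas are
evaluated row by row against explicit truth assignments, and corpus
probabilities are recomputed by exhaustive enumeration over sentences.
"""

from __future__ import annotations

import math

from semspace.meaning_space import And, Atom, Formula, Not, Or


def eval_formula(f: Formula, assignment: dict[str, bool]) -> bool:
    """Truth-table evaluation of a formula against one model's assignment."""
    if isinstance(f, Atom):
        return assignment[str(f.proposition)]
    if isinstance(f, Not):
        return not eval_formula(f.operand, assignment)
    if isinstance(f, And):
        return eval_formula(f.left, assignment) and eval_formula(f.right, assignment)
    if isinstance(f, Or):
        return eval_formula(f.left, assignment) or eval_formula(f.right, assignment)
    raise TypeError(f)


def brute_vector(space, f: Formula) -> list[int]:
    """Meaning vector by per-row truth-table evaluation."""
    out = []
    for row in space.matrix:
        assignment = {str(p): bool(v) for p, v in zip(space.propositions, row)}
        out.append(int(eval_formula(f, assignment)))
    return out


def brute_linguistic_surprisal(corpus, words: tuple[str, ...], t: int) -> float:
    """Eq-by-enumeration: -ln of the frequency-weighted continuation ratio."""
    num = sum(f for s, f in corpus.items if s.words[:t] == words[:t])
    den = sum(f for s, f in corpus.items if s.words[: t - 1] == words[: t - 1])
    return -math.log(num / den)


def brute_situation_models(space, corpus, prefix: tuple[str, ...]) -> set[int]:
    """Model indices satisfying the disjunctive semantics of a prefix."""
    consistent = [s for s, _ in corpus.items if s.words[: len(prefix)] == prefix]
    sat: set[int] = set()
    for s in consistent:
        for i, v in enumerate(brute_vector(space, s.semantics)):
            if v:
                sat.add(i)
    return sat


def brute_situation_surprisal(space, corpus, words: tuple[str, ...], t: int) -> float:
    prev = brute_situation_models(space, corpus, words[: t - 1])
    curr = brute_situation_models(space, corpus, words[:t])
    return -math.log(len(curr & prev) / len(prev))
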