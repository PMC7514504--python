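"""Model-theoretic vector semantics.

A meaning space is a binary satisfaction matrix over formal models (rows)
and atomic propositions (columns).  The meaning of a propositional formula
is the vector that marks the models satisfying it; because the model set
reflects the probabilistic structure of the world, these vectors inherently
carry probabilities: the probability of a formula is the fraction of models
that satisfy it, and conditional probabilities follow as belief ratios.

Network-produced meaning vectors are graded (entries in [0, 1]); the
operations below extend the Boolean algebra to graded vectors so that the
same probability expressions apply to both.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np

__all__ = [
    "Proposition",
    "Formula",
    "Atom",
    "Not",
    "And",
    "Or",
    "MeaningSpace",
    "MeaningVector",
    "UnknownPropositionError",
    "UndefinedConditionError",
    "parse_formula",
    "vector_of",
    "conjoin_graded",
    "disjoin_graded",
    "probability",
    "conditional_probability",
]


class UnknownPropositionError(KeyError):
    """A formula atom references a proposition absent from the space."""


class UndefinedConditionError(ZeroDivisionError):
    """Conditioning on a vector of zero belief; the ratio is undefined."""


@dataclass(frozen=True)
class Proposition:
    """An atomic proposition: a predicate applied to entity symbols."""

    predicate: str
    arguments: tuple[str, ...] = ()

    def __str__(self) -> str:
        if not self.arguments:
            return self.predicate
        return f"{self.predicate}({','.join(self.arguments)})"

    @classmethod
    def parse(cls, text: str) -> "Proposition":
        text = text.strip()
        m = re.fullmatch(r"([A-Za-z_][\w]*)(?:\(([^()]*)\))?", text)
        if m is None:
            raise ValueError(f"cannot parse proposition: {text!r}")
        pred, args = m.group(1), m.group(2)
        if args is None or args.strip() == "":
            return cls(pred, ())
        return cls(pred, tuple(a.strip() for a in args.split(",")))


# --- formulas ---------------------------------------------------------------


@dataclass(frozen=True)
class Atom:
    proposition: Proposition

    def __str__(self) -> str:
        return str(self.proposition)


@dataclass(frozen=True)
class Not:
    operand: "Formula"

    def __str__(self) -> str:
        return f"!{self.operand}"


@dataclass(frozen=True)
class And:
    left: "Formula"
    right: "Formula"

    def __str__(self) -> str:
        return f"({self.left} & {self.right})"


@dataclass(frozen=True)
class Or:
    left: "Formula"
    right: "Formula"

    def __str__(self) -> str:
        return f"({self.left} | {self.right})"


Formula = Union[Atom, Not, And, Or]


def atoms_of(f: Formula) -> Iterable[Proposition]:
    """Yield every proposition occurring in *f* (with repetition)."""
    stack = [f]
    while stack:
        node = stack.pop()
        if isinstance(node, Atom):
            yield node.proposition
        elif isinstance(node, Not):
            stack.append(node.operand)
        else:
            stack.extend((node.left, node.right))


def conj(formulas: Iterable[Formula]) -> Formula:
    """Left-nested conjunction of one or more formulas."""
    it = iter(formulas)
    out = next(it)
    for f in it:
        out = And(out, f)
    return out


def disj(formulas: Iterable[Formula]) -> Formula:
    it = iter(formulas)
    out = next(it)
    for f in it:
        out = Or(out, f)
    return out


def parse_formula(text: str) -> Formula:
    """Parse the textual formula syntax.

    Grammar: ``p`` (atom, e.g. ``order(beth,cola)``), ``!f``, ``(f & g)``,
    ``(f | g)``.  Binary connectives require explicit parentheses.
    """
    tokens = re.findall(r"[A-Za-z_][\w]*\([^()]*\)|[A-Za-z_][\w]*|[!&|()]", text)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        if pos >= len(tokens):
            raise ValueError(f"unexpected end of formula: {text!r}")
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_node() -> Formula:
        tok = take()
        if tok == "!":
            return Not(parse_node())
        if tok == "(":
            left = parse_node()
            op = take()
            if op not in ("&", "|"):
                raise ValueError(f"expected connective, got {op!r} in {text!r}")
            right = parse_node()
            closing = take()
            if closing != ")":
                raise ValueError(f"expected ')' in {text!r}")
            return And(left, right) if op == "&" else Or(left, right)
        if tok in (")", "&", "|"):
            raise ValueError(f"unexpected {tok!r} in {text!r}")
        return Atom(Proposition.parse(tok))

    node = parse_node()
    if pos != len(tokens):
        raise ValueError(f"trailing input after formula: {text!r}")
    return node


# --- meaning space ----------------------------------------------------------


@dataclass
class MeaningSpace:
    """Satisfaction matrix of shape (models, propositions), entries in {0, 1}."""

    propositions: tuple[Proposition, ...]
    matrix: np.ndarray
    _index: dict = field(init=False, repr=False)
    _groups: list | None = field(default=None, init=False, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2:
            raise ValueError("satisfaction matrix must be 2-dimensional")
        m, n = self.matrix.shape
        if m < 1 or n < 1:
            raise ValueError("meaning space needs at least one model and one proposition")
        if n != len(self.propositions):
            raise ValueError("column count does not match proposition count")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("satisfaction entries must be 0 or 1")
        self._index = {p: j for j, p in enumerate(self.propositions)}

    @property
    def n_models(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_propositions(self) -> int:
        return self.matrix.shape[1]

    def column(self, p: Proposition) -> int:
        try:
            return self._index[p]
        except KeyError:
            raise UnknownPropositionError(f"unknown proposition: {p}") from None

    @property
    def unique_model_index(self) -> list[np.ndarray]:
        """Groups of row indices sharing an identical satisfaction pattern.

        Ordered by first occurrence; group sizes sum to the model count.
        """
        if self._groups is None:
            _, first, inverse = np.unique(
                self.matrix, axis=0, return_index=True, return_inverse=True
            )
            order = np.argsort(first)  # stable: group order = first occurrence
            rank = np.empty_like(order)
            rank[order] = np.arange(len(order))
            labels = rank[inverse]
            self._groups = [np.flatnonzero(labels == g) for g in range(len(order))]
        return self._groups

    @property
    def n_unique_models(self) -> int:
        return len(self.unique_model_index)

    # -- persistence: header of proposition names, then tab-separated 0/1 rows

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(str(p) for p in self.propositions) + "\n")
            np.savetxt(fh, self.matrix, fmt="%d", delimiter="\t")

    @classmethod
    def load(cls, path: str | Path) -> "MeaningSpace":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            props = tuple(Proposition.parse(tok) for tok in header)
            rows = []
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                cells = line.rstrip("\n").split("\t")
                if len(cells) != len(props):
                    raise ValueError(
                        f"line {lineno}: expected {len(props)} columns, got {len(cells)}"
                    )
                rows.append([int(c) for c in cells])
        return cls(props, np.array(rows, dtype=np.uint8))


@dataclass
class MeaningVector:
    """A point in meaning space: one belief value per model, in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("meaning vector must be 1-dimensional")
        if (self.values < 0).any() or (self.values > 1).any():
            raise ValueError("meaning vector entries must lie in [0, 1]")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def binary(self) -> bool:
        return bool(np.isin(self.values, (0.0, 1.0)).all())


def _check_length(space: MeaningSpace, v: MeaningVector) -> None:
    if len(v) != space.n_models:
        raise ValueError(
            f"vector length {len(v)} does not match model count {space.n_models}"
        )


def vector_of(space: MeaningSpace, f: Formula) -> MeaningVector:
    """Evaluate a formula to its binary meaning vector.

    Atom -> satisfaction column; negation -> complement; conjunction ->
    componentwise minimum; disjunction -> componentwise maximum.
    """
    if isinstance(f, Atom):
        col = space.column(f.proposition)
        return MeaningVector(space.matrix[:, col].astype(float))
    if isinstance(f, Not):
        return MeaningVector(1.0 - vector_of(space, f.operand).values)
    left = vector_of(space, f.left).values
    right = vector_of(space, f.right).values
    if isinstance(f, And):
        return MeaningVector(np.minimum(left, right))
    if isinstance(f, Or):
        return MeaningVector(np.maximum(left, right))
    raise TypeError(f"not a formula node: {f!r}")


def conjoin_graded(a: MeaningVector, b: MeaningVector) -> MeaningVector:
    """Graded conjunction: componentwise product.

    Reduces to logical AND on binary vectors and makes the conditional
    belief P(b | a) a normalized ratio for graded network outputs.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return MeaningVector(a.values * b.values)


def disjoin_graded(a: MeaningVector, b: MeaningVector) -> MeaningVector:
    """Graded disjunction 1-(1-a)(1-b); De Morgan dual of the product."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return MeaningVector(1.0 - (1.0 - a.values) * (1.0 - b.values))


def probability(space: MeaningSpace, v: MeaningVector) -> float:
    """Belief of a meaning vector: mean entry.

    For binary vectors this is the satisfying-model count divided by the
    total number of models; for graded vectors it is the belief average.
    """
    _check_length(space, v)
    return float(v.values.sum() / space.n_models)


def conditional_probability(
    space: MeaningSpace, given: MeaningVector, target: MeaningVector
) -> float:
    """Conditional belief P(target | given) = P(given AND target) / P(given)."""
    _check_length(space, given)
    _check_length(space, target)
    denom = given.values.sum()
    if denom <= 0.0:
        raise UndefinedConditionError(
            "conditioning vector has zero belief; conditional probability undefined"
        )
    return float((given.values * target.values).sum() / denom)
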