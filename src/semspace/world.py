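"""The restaurant/cinema microworld and meaning-space sampling.

A world specification declares entities (persons, places, foods, drinks),
a predicate inventory, and co-occurrence constraints.  Hard constraints
(forbidden/required patterns) must hold in every sampled model; probabilistic
constraints carry multiplicative sampling weights that skew how often
propositions co-occur (e.g. ordering water is more common than ordering
champagne, popcorn is more likely in the cinema than in the restaurant).

Sampling is per-model and per-person: each person's propositions are drawn
along a fixed schedule (enter -> ask_menu -> order -> eat/drink -> pay ->
leave), each truth value sampled from its weight-adjusted conditional
probability given the values already fixed.  Rows violating a hard
constraint are rejected and resampled.

`select_dimensions` reduces a large sampled space to a small set of
pairwise-distinct models that greedily preserves the full space's prior and
pairwise conditional proposition probabilities, so that the reduced space
remains a faithful probabilistic image of the world.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .meaning_space import (
    And,
    Atom,
    Formula,
    MeaningSpace,
    Not,
    Or,
    Proposition,
    parse_formula,
)

__all__ = [
    "Constraint",
    "WorldSpec",
    "SamplerConfig",
    "default_world_spec",
    "enumerate_propositions",
    "sample_models",
    "count_hard_violations",
    "select_dimensions",
]


@dataclass(frozen=True)
class Constraint:
    """A hard or probabilistic co-occurrence constraint.

    ``condition`` is a formula template over role variables (``Person``,
    ``Place``, ``Food``, ``Drink``; numbered variants such as ``Place1`` /
    ``Place2`` bind to distinct values).  Hard constraints mark the pattern
    ``forbidden`` or ``required`` in every model; probabilistic constraints
    multiply the sampling weight of the ``condition`` proposition whenever
    the ``given`` template holds for the values already sampled.
    """

    kind: str  # "hard" | "probabilistic"
    condition: str
    effect: str | None = None  # hard: "forbidden" | "required"
    weight: float | None = None  # probabilistic: multiplicative weight > 0
    given: str | None = None  # probabilistic: context template
    scope: str = "person-local"

    def __post_init__(self) -> None:
        if self.kind == "hard":
            if self.effect not in ("forbidden", "required"):
                raise ValueError("hard constraint needs effect forbidden/required")
            if self.weight is not None:
                raise ValueError("hard constraint cannot carry a weight")
        elif self.kind == "probabilistic":
            if self.weight is None or self.weight <= 0:
                raise ValueError("probabilistic constraint needs weight > 0")
        else:
            raise ValueError(f"unknown constraint kind: {self.kind!r}")


@dataclass(frozen=True)
class WorldSpec:
    """Entities, predicate inventory and constraints of a microworld.

    ``predicates`` maps each predicate name to the domain of its object
    argument (None for person-only predicates); the person argument is
    implicit and always first.
    """

    persons: tuple[str, ...] = ("beth", "dave", "thom")
    places: tuple[str, ...] = ("cinema", "restaurant")
    foods: tuple[str, ...] = ("dinner", "popcorn")
    drinks: tuple[str, ...] = ("champagne", "cola", "water")
    predicates: tuple[tuple[str, str | None], ...] = (
        ("enter", "place"),
        ("ask_menu", None),
        ("order", "orderable"),
        ("eat", "food"),
        ("drink", "drink"),
        ("pay", None),
        ("leave", None),
    )
    hard_constraints: tuple[Constraint, ...] = ()
    prob_constraints: tuple[Constraint, ...] = ()

    def save(self, path) -> None:
        """Write the spec as structured JSON (entities, predicates, constraints)."""
        import json
        from pathlib import Path

        payload = {
            "persons": list(self.persons),
            "places": list(self.places),
            "foods": list(self.foods),
            "drinks": list(self.drinks),
            "predicates": [[name, dom] for name, dom in self.predicates],
            "hard_constraints": [
                {"condition": c.condition, "effect": c.effect, "scope": c.scope}
                for c in self.hard_constraints
            ],
            "prob_constraints": [
                {
                    "condition": c.condition,
                    "weight": c.weight,
                    "given": c.given,
                    "scope": c.scope,
                }
                for c in self.prob_constraints
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def load(cls, path) -> "WorldSpec":
        import json
        from pathlib import Path

        payload = json.loads(Path(path).read_text())
        return cls(
            persons=tuple(payload["persons"]),
            places=tuple(payload["places"]),
            foods=tuple(payload["foods"]),
            drinks=tuple(payload["drinks"]),
            predicates=tuple((n, d) for n, d in payload["predicates"]),
            hard_constraints=tuple(
                Constraint("hard", c["condition"], effect=c["effect"], scope=c.get("scope", "person-local"))
                for c in payload["hard_constraints"]
            ),
            prob_constraints=tuple(
                Constraint(
                    "probabilistic",
                    c["condition"],
                    weight=c["weight"],
                    given=c.get("given"),
                    scope=c.get("scope", "person-local"),
                )
                for c in payload["prob_constraints"]
            ),
        )

    def domain(self, name: str) -> tuple[str, ...]:
        return {
            "place": self.places,
            "food": self.foods,
            "drink": self.drinks,
            "orderable": self.foods + self.drinks,
        }[name]

    @property
    def predicate_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.predicates)


@dataclass(frozen=True)
class SamplerConfig:
    n_models: int = 10_000
    seed: int = 0
    max_rejections: int = 1000

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")


def default_world_spec() -> WorldSpec:
    """The default microworld: 3 persons, 2 places, 2 foods, 3 drinks.

    Hard structure: every person enters exactly one place; at most one food
    and one drink are ordered; eating/drinking presupposes ordering.
    Probabilistic structure: drinks are ordered at odds water:cola:champagne
    = 3:2:1; popcorn is favoured 4:1 over dinner in the cinema and dinner
    4:1 over popcorn in the restaurant; menus are mostly asked for in the
    restaurant; eating, drinking, paying and leaving happen with odds 4:1.
    """
    hard = (
        Constraint("hard", "(enter(Person,Place1) & enter(Person,Place2))", effect="forbidden"),
        Constraint("hard", "(enter(Person,cinema) | enter(Person,restaurant))", effect="required"),
        Constraint("hard", "(order(Person,Food1) & order(Person,Food2))", effect="forbidden"),
        Constraint("hard", "(order(Person,Drink1) & order(Person,Drink2))", effect="forbidden"),
        Constraint("hard", "(eat(Person,Food) & !order(Person,Food))", effect="forbidden"),
        Constraint("hard", "(drink(Person,Drink) & !order(Person,Drink))", effect="forbidden"),
    )
    prob = (
        # base rates for ordering food (either food is a common choice)
        Constraint("probabilistic", "order(Person,dinner)", weight=2.0),
        Constraint("probabilistic", "order(Person,popcorn)", weight=2.0),
        # place modulates the food 4:1
        Constraint("probabilistic", "order(Person,popcorn)", weight=4.0, given="enter(Person,cinema)"),
        Constraint("probabilistic", "order(Person,dinner)", weight=4.0, given="enter(Person,restaurant)"),
        # drink preference water:cola:champagne = 3:2:1
        Constraint("probabilistic", "order(Person,water)", weight=3.0),
        Constraint("probabilistic", "order(Person,cola)", weight=2.0),
        Constraint("probabilistic", "order(Person,champagne)", weight=1.0),
        # menus belong to restaurants
        Constraint("probabilistic", "ask_menu(Person)", weight=2 / 3, given="enter(Person,restaurant)"),
        Constraint("probabilistic", "ask_menu(Person)", weight=1 / 9, given="enter(Person,cinema)"),
        # ordered things are usually consumed; people usually pay and leave
        Constraint("probabilistic", "eat(Person,Food)", weight=4.0, given="order(Person,Food)"),
        Constraint("probabilistic", "drink(Person,Drink)", weight=4.0, given="order(Person,Drink)"),
        Constraint("probabilistic", "pay(Person)", weight=4.0),
        Constraint("probabilistic", "leave(Person)", weight=4.0),
    )
    return WorldSpec(hard_constraints=hard, prob_constraints=prob)


def enumerate_propositions(spec: WorldSpec) -> list[Proposition]:
    """All propositions in canonical order: predicate, then person, then object."""
    out: list[Proposition] = []
    for name, dom in spec.predicates:
        for person in spec.persons:
            if dom is None:
                out.append(Proposition(name, (person,)))
            else:
                for obj in spec.domain(dom):
                    out.append(Proposition(name, (person, obj)))
    return out


# --- constraint templates ---------------------------------------------------

_VAR_RE = re.compile(r"^(Person|Place|Food|Drink)(\d*)$")


def _template_variables(f: Formula) -> set[str]:
    from .meaning_space import atoms_of

    vars_: set[str] = set()
    for prop in atoms_of(f):
        for arg in prop.arguments:
            if _VAR_RE.match(arg):
                vars_.add(arg)
    return vars_


def _substitute(f: Formula, binding: dict[str, str]) -> Formula:
    if isinstance(f, Atom):
        p = f.proposition
        return Atom(Proposition(p.predicate, tuple(binding.get(a, a) for a in p.arguments)))
    if isinstance(f, Not):
        return Not(_substitute(f.operand, binding))
    cls = And if isinstance(f, And) else Or
    return cls(_substitute(f.left, binding), _substitute(f.right, binding))


def _var_domain(spec: WorldSpec, var: str) -> tuple[str, ...]:
    base = _VAR_RE.match(var).group(1)
    if base == "Person":
        return spec.persons
    return spec.domain(base.lower())


def instantiate_template(spec: WorldSpec, template: str) -> list[Formula]:
    """Ground a constraint template over all role-variable bindings.

    Numbered variables sharing a base name (``Place1``/``Place2``) bind to
    distinct values.
    """
    f = parse_formula(template)
    vars_ = sorted(_template_variables(f))
    if not vars_:
        return [f]
    domains = [_var_domain(spec, v) for v in vars_]
    out = []
    for values in itertools.product(*domains):
        binding = dict(zip(vars_, values))
        ok = True
        for (v1, x1), (v2, x2) in itertools.combinations(binding.items(), 2):
            b1, b2 = _VAR_RE.match(v1).group(1), _VAR_RE.match(v2).group(1)
            if b1 == b2 and v1 != v2 and x1 == x2:
                ok = False
                break
        if ok:
            out.append(_substitute(f, binding))
    return out


def _eval_on_columns(f: Formula, columns: dict[str, np.ndarray], n: int) -> np.ndarray:
    """Evaluate a ground formula over a partial column assignment.

    Unassigned propositions count as false (the sampling schedule only
    conditions on already-fixed propositions).
    """
    if isinstance(f, Atom):
        return columns.get(str(f.proposition), np.zeros(n, dtype=bool))
    if isinstance(f, Not):
        return ~_eval_on_columns(f.operand, columns, n)
    left = _eval_on_columns(f.left, columns, n)
    right = _eval_on_columns(f.right, columns, n)
    return (left & right) if isinstance(f, And) else (left | right)


# --- sampling ---------------------------------------------------------------


def _joint_weight_table(spec: WorldSpec) -> dict[str, list[tuple[Formula | None, float]]]:
    """Weight table where condition and given templates share bindings.

    A constraint like ``eat(Person,Food) given order(Person,Food)`` must bind
    ``Food`` identically in both; instantiate condition and given jointly.
    """
    table: dict[str, list[tuple[Formula | None, float]]] = {}
    for c in spec.prob_constraints:
        cond = parse_formula(c.condition)
        given = parse_formula(c.given) if c.given is not None else None
        vars_ = _template_variables(cond)
        if given is not None:
            vars_ |= _template_variables(given)
        vars_ = sorted(vars_)
        domains = [_var_domain(spec, v) for v in vars_]
        for values in itertools.product(*domains) if vars_ else [()]:
            binding = dict(zip(vars_, values))
            ground_cond = _substitute(cond, binding)
            if not isinstance(ground_cond, Atom):
                raise ValueError("probabilistic condition must be a proposition template")
            ground_given = _substitute(given, binding) if given is not None else None
            table.setdefault(str(ground_cond.proposition), []).append(
                (ground_given, c.weight)
            )
    return table


def _weight_for(
    table: dict[str, list[tuple[Formula | None, float]]],
    prop: Proposition,
    columns: dict[str, np.ndarray],
    n: int,
) -> np.ndarray:
    w = np.ones(n)
    for given, weight in table.get(str(prop), []):
        if given is None:
            w *= weight
        else:
            mask = _eval_on_columns(given, columns, n)
            w = np.where(mask, w * weight, w)
    return w


def _bernoulli(w: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return rng.random(w.shape[0]) < w / (1.0 + w)


def _categorical(weights: list[np.ndarray], rng: np.random.Generator) -> np.ndarray:
    """Per-row categorical draw; weights is a list of (n,) arrays."""
    stacked = np.stack(weights, axis=1)
    cum = np.cumsum(stacked, axis=1)
    u = rng.random(stacked.shape[0]) * cum[:, -1]
    return (u[:, None] >= cum).sum(axis=1)


def _sample_rows(
    spec: WorldSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    props = enumerate_propositions(spec)
    col_of = {str(p): j for j, p in enumerate(props)}
    preds = dict(spec.predicates)
    table = _joint_weight_table(spec)
    matrix = np.zeros((n, len(props)), dtype=np.uint8)
    columns: dict[str, np.ndarray] = {}

    def set_col(prop: Proposition, values: np.ndarray) -> None:
        matrix[:, col_of[str(prop)]] = values
        columns[str(prop)] = values.astype(bool)

    for person in spec.persons:
        ordered_food: dict[str, np.ndarray] = {}
        ordered_drink: dict[str, np.ndarray] = {}
        if "enter" in preds:
            # each person enters exactly one place
            alts = [Proposition("enter", (person, x)) for x in spec.places]
            weights = [_weight_for(table, p, columns, n) for p in alts]
            choice = _categorical(weights, rng)
            for i, p in enumerate(alts):
                set_col(p, (choice == i).astype(np.uint8))
        if "ask_menu" in preds:
            p = Proposition("ask_menu", (person,))
            set_col(p, _bernoulli(_weight_for(table, p, columns, n), rng).astype(np.uint8))
        if "order" in preds:
            # at most one food and at most one drink per person
            for group, store in ((spec.foods, ordered_food), (spec.drinks, ordered_drink)):
                alts = [Proposition("order", (person, x)) for x in group]
                weights = [np.ones(n)] + [_weight_for(table, p, columns, n) for p in alts]
                choice = _categorical(weights, rng)  # 0 = order nothing
                for i, (x, p) in enumerate(zip(group, alts), start=1):
                    sel = (choice == i).astype(np.uint8)
                    set_col(p, sel)
                    store[x] = sel.astype(bool)
        if "eat" in preds:
            for x in spec.foods:
                p = Proposition("eat", (person, x))
                did = _bernoulli(_weight_for(table, p, columns, n), rng)
                set_col(p, (did & ordered_food.get(x, np.zeros(n, bool))).astype(np.uint8))
        if "drink" in preds:
            for x in spec.drinks:
                p = Proposition("drink", (person, x))
                did = _bernoulli(_weight_for(table, p, columns, n), rng)
                set_col(p, (did & ordered_drink.get(x, np.zeros(n, bool))).astype(np.uint8))
        for name in ("pay", "leave"):
            if name in preds:
                p = Proposition(name, (person,))
                set_col(p, _bernoulli(_weight_for(table, p, columns, n), rng).astype(np.uint8))
    return matrix


def _violation_mask(spec: WorldSpec, matrix: np.ndarray, props: Sequence[Proposition]) -> np.ndarray:
    """Boolean mask of rows violating at least one hard constraint."""
    n = matrix.shape[0]
    columns = {str(p): matrix[:, j].astype(bool) for j, p in enumerate(props)}
    bad = np.zeros(n, dtype=bool)
    for c in spec.hard_constraints:
        for ground in instantiate_template(spec, c.condition):
            sat = _eval_on_columns(ground, columns, n)
            bad |= sat if c.effect == "forbidden" else ~sat
    return bad


def count_hard_violations(spec: WorldSpec, space: MeaningSpace) -> int:
    """Number of models violating any hard constraint (0 for valid spaces)."""
    return int(_violation_mask(spec, space.matrix, space.propositions).sum())


def sample_models(spec: WorldSpec, cfg: SamplerConfig) -> MeaningSpace:
    """Sample a meaning space of ``cfg.n_models`` constraint-respecting models."""
    rng = np.random.default_rng(cfg.seed)
    props = enumerate_propositions(spec)
    matrix = _sample_rows(spec, cfg.n_models, rng)
    for _ in range(cfg.max_rejections):
        bad = _violation_mask(spec, matrix, props)
        if not bad.any():
            break
        matrix[bad] = _sample_rows(spec, int(bad.sum()), rng)
    else:
        raise RuntimeError(
            "hard constraints could not be satisfied within max_rejections; "
            "the constraint set may be unsatisfiable"
        )
    return MeaningSpace(tuple(props), matrix)


# --- dimension selection ----------------------------------------------------


def select_dimensions(
    space: MeaningSpace, k: int = 150, seed: int | None = None
) -> MeaningSpace:
    """Greedily select ``k`` pairwise-distinct models approximating the space.

    Forward selection among the distinct satisfaction patterns, at each step
    adding the row that minimizes the maximum absolute deviation between the
    subset's and the full space's (a) prior proposition probabilities and
    (b) pairwise conditional probabilities.  Ties break toward the lower row
    index; the procedure is deterministic (``seed`` is accepted for
    interface symmetry and unused).  The achieved deviations are reported on
    the returned space as ``selection_report``.
    """
    full = space.matrix.astype(np.float64)
    m, n = full.shape
    uniq, first = np.unique(full, axis=0, return_index=True)
    order = np.argsort(first)
    R = uniq[order]  # distinct rows, in order of first occurrence
    d = R.shape[0]
    if d < k:
        raise ValueError(f"need at least k={k} distinct satisfaction patterns, found {d}")

    prior = full.mean(axis=0)
    joint = full.T @ full  # co-occurrence counts
    denom_full = np.diag(joint).copy()
    defined = denom_full > 0
    cond_full = np.zeros((n, n))
    cond_full[defined] = joint[defined] / denom_full[defined, None]

    Rf = R.astype(np.float64)
    c = np.zeros(n)
    C = np.zeros((n, n))
    available = np.ones(d, dtype=bool)
    chosen: list[int] = []
    idx_defined = np.flatnonzero(defined)

    for step in range(k):
        s = step + 1
        dev = np.abs((c[None, :] + Rf) / s - prior[None, :]).max(axis=1)
        for i in idx_defined:
            denom = C[i, i] + Rf[:, i]  # (d,)
            num = C[i, :] + Rf[:, i:i + 1] * Rf  # (d, n)
            dev_i = np.full(d, 1.0)
            pos = denom > 0
            if pos.any():
                dev_i[pos] = np.abs(num[pos] / denom[pos, None] - cond_full[i]).max(axis=1)
            np.maximum(dev, dev_i, out=dev)
        dev[~available] = np.inf
        best = int(np.argmin(dev))
        chosen.append(best)
        available[best] = False
        c += Rf[best]
        C += np.outer(Rf[best], Rf[best])

    sub = R[chosen].astype(np.uint8)
    reduced = MeaningSpace(space.propositions, sub)
    sub_prior = sub.mean(axis=0)
    sub_joint = sub.astype(float).T @ sub.astype(float)
    sub_denom = np.diag(sub_joint)
    cond_dev = 0.0
    for i in idx_defined:
        if sub_denom[i] > 0:
            cond_dev = max(
                cond_dev, float(np.abs(sub_joint[i] / sub_denom[i] - cond_full[i]).max())
            )
        else:
            cond_dev = max(cond_dev, 1.0)
    reduced.selection_report = {
        "max_prior_deviation": float(np.abs(sub_prior - prior).max()),
        "max_conditional_deviation": cond_dev,
        "n_candidates": int(d),
    }
    return reduced
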