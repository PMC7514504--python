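"""Analyses over traced sentences and the end-to-end pipeline.

The analyses contrast what drives the online metrics: correlations between
online surprisal and online entropy reduction, the three linguistic-
experience / world-knowledge contrast constellations, word-by-word metric
profiles for the asked- versus ordered-coordinations, entropy by word
position, and the surprisal-polarization interaction.

Correlation analyses operate over sentence *types* (the grammar's
sentences), not frequency-weighted tokens.  Offline metrics (linguistic
and situation surprisal) never touch the network and are therefore
identical across training seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .language import Corpus, build_corpus, build_vocabulary, generate_sentences
from .meaning_space import MeaningSpace
from .metrics import Trajectory, trace
from .srn import SRNConfig, SRNWeights, mean_comprehension, train
from .world import (
    SamplerConfig,
    WorldSpec,
    default_world_spec,
    sample_models,
    select_dimensions,
)

__all__ = [
    "AnalysisReport",
    "ContrastSpec",
    "DEFAULT_CONTRASTS",
    "trace_corpus",
    "traces_frame",
    "correlate_metrics",
    "run_contrast",
    "profile_sentences",
    "entropy_by_position",
    "polarization_interaction",
    "PipelineResult",
    "run_pipeline",
]

_METRICS = ("S_ling", "S_sit", "S_onl", "dH_onl")


@dataclass
class AnalysisReport:
    """A per-word metric table plus summary statistics recomputable from it."""

    name: str
    table: pd.DataFrame
    summary: dict

    def save(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ContrastSpec:
    """Two sentence templates (with an NP slot) contrasted at one position."""

    name: str
    target_pattern: str
    control_pattern: str
    critical_position: int  # 1-based word index
    metrics: tuple[str, ...] = _METRICS


#: The three constellations: linguistic experience only, world knowledge
#: only, and the two in conflict.  Target [T] minus control [C].
DEFAULT_CONTRASTS = (
    ContrastSpec("linguistic_experience", "NP ordered popcorn", "NP ordered dinner", 3),
    ContrastSpec(
        "world_knowledge",
        "NP entered the cinema and ordered popcorn",
        "NP entered the cinema and ordered dinner",
        7,
    ),
    ContrastSpec("conflict", "NP ordered champagne", "NP ordered water", 3),
)


def trace_corpus(
    space: MeaningSpace, weights: SRNWeights, corpus: Corpus
) -> list[Trajectory]:
    """Trace every sentence type of the corpus."""
    return [trace(space, weights, corpus, s) for s in corpus.sentences]


def traces_frame(traces: Iterable[Trajectory]) -> pd.DataFrame:
    """Long per-word table over a set of trajectories."""
    frames = []
    for i, tr in enumerate(traces):
        df = tr.to_frame()
        df.insert(0, "sentence_id", i)
        df.insert(1, "sentence", tr.sentence.text)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if len(x) < 3:
        raise ValueError("correlation needs at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant metric")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def correlate_metrics(
    traces: Iterable[Trajectory], word_filter: str = "all"
) -> AnalysisReport:
    """Pearson correlation between online surprisal and entropy reduction.

    ``word_filter``: ``all`` (every word), ``exclude_first`` (drop
    sentence-initial words), or ``final_only`` (sentence-final words).
    """
    if word_filter not in ("all", "exclude_first", "final_only"):
        raise ValueError(f"unknown word filter: {word_filter!r}")
    df = traces_frame(traces)
    if word_filter == "exclude_first":
        df = df[df["position"] > 1]
    elif word_filter == "final_only":
        last = df.groupby("sentence_id")["position"].transform("max")
        df = df[df["position"] == last]
    r, p = _pearson(df["S_onl"].to_numpy(), df["dH_onl"].to_numpy())
    return AnalysisReport(
        name=f"surprisal_vs_entropy_reduction[{word_filter}]",
        table=df[["sentence", "position", "word", "S_onl", "dH_onl"]].reset_index(drop=True),
        summary={"r": r, "r2": r * r, "p": p, "n": int(len(df))},
    )


def _instantiate(pattern: str, person: str) -> tuple[str, ...]:
    return tuple(person if tok == "NP" else tok for tok in pattern.split())


def run_contrast(
    spec: ContrastSpec,
    traces: Sequence[Trajectory],
    corpus: Corpus,
    space: MeaningSpace,
    world: WorldSpec | None = None,
) -> AnalysisReport:
    """Per-metric target-minus-control differences at the critical word.

    Both templates are instantiated for every person; the report gives the
    mean difference across persons with its standard error.
    """
    world = world or default_world_spec()
    by_words = {tr.sentence.words: tr for tr in traces}
    rows = []
    for person in world.persons:
        pair = {}
        for role, pattern in (("target", spec.target_pattern), ("control", spec.control_pattern)):
            words = _instantiate(pattern, person)
            if words not in by_words:
                raise ValueError(f"pattern instance {' '.join(words)!r} is not in the grammar")
            tr = by_words[words]
            if not 1 <= spec.critical_position <= len(words):
                raise ValueError("critical position outside the sentence")
            row = tr.to_frame().iloc[spec.critical_position - 1]
            pair[role] = row
        for metric in spec.metrics:
            rows.append(
                {
                    "person": person,
                    "metric": metric,
                    "target": float(pair["target"][metric]),
                    "control": float(pair["control"][metric]),
                    "difference": float(pair["target"][metric] - pair["control"][metric]),
                }
            )
    table = pd.DataFrame(rows)
    summary = {}
    for metric in spec.metrics:
        diffs = table.loc[table["metric"] == metric, "difference"].to_numpy()
        summary[metric] = {
            "mean_difference": float(diffs.mean()),
            "se": float(diffs.std(ddof=1) / np.sqrt(len(diffs))) if len(diffs) > 1 else 0.0,
            "n": int(len(diffs)),
        }
    return AnalysisReport(name=f"contrast[{spec.name}]", table=table, summary=summary)


def _matches_profile(pattern: str, words: tuple[str, ...], world: WorldSpec) -> bool:
    toks = pattern.split()
    open_ended = toks and toks[-1] == "*"
    if open_ended:
        toks = toks[:-1]
        if len(words) < len(toks):
            return False
    elif len(words) != len(toks):
        return False
    for p, w in zip(toks, words):
        if p == "NP" and w in world.persons:
            continue
        if p == "PLACE" and w in world.places:
            continue
        if p == w:
            continue
        return False
    return True


def profile_sentences(
    patterns: Sequence[str],
    traces: Sequence[Trajectory],
    world: WorldSpec | None = None,
) -> AnalysisReport:
    """Per-position means and standard errors of all four metrics.

    ``patterns`` are sentence templates with ``NP``/``PLACE`` wildcards and
    an optional trailing ``*`` matching any continuation.
    """
    world = world or default_world_spec()
    selected = [
        tr
        for tr in traces
        if any(_matches_profile(p, tr.sentence.words, world) for p in patterns)
    ]
    if not selected:
        raise ValueError(f"no traced sentence matches {patterns!r}")
    df = traces_frame(selected)
    agg = df.groupby("position")[list(_METRICS)].agg(["mean", "sem", "count"])
    agg.columns = ["_".join(c) for c in agg.columns]
    table = agg.reset_index()
    summary = {"n_sentences": len(selected)}
    return AnalysisReport(name="profile", table=table, summary=summary)


def entropy_by_position(traces: Sequence[Trajectory]) -> AnalysisReport:
    """Online entropy against word position, with sentence-final entropies."""
    df = traces_frame(traces)
    if df["position"].nunique() < 2:
        raise ValueError("entropy-by-position undefined for a single word position")
    r, p = _pearson(df["position"].to_numpy(float), df["H"].to_numpy())
    finals = df[df["position"] == df.groupby("sentence_id")["position"].transform("max")]
    return AnalysisReport(
        name="entropy_by_position",
        table=df[["sentence", "position", "word", "H"]].reset_index(drop=True),
        summary={
            "r": r,
            "p": p,
            "n": int(len(df)),
            "final_entropy_mean": float(finals["H"].mean()),
            "final_entropy_min": float(finals["H"].min()),
        },
    )


def polarization_interaction(traces: Sequence[Trajectory]) -> AnalysisReport:
    """Correlation of online surprisal with the entropy product H(t-1)*H(t)."""
    df = traces_frame(traces)
    interaction = (df["H_prev"] * df["H"]).to_numpy()
    r, p = _pearson(df["S_onl"].to_numpy(), interaction)
    table = df[["sentence", "position", "word", "S_onl", "H_prev", "H"]].copy()
    table["H_interaction"] = interaction
    return AnalysisReport(
        name="polarization_interaction",
        table=table.reset_index(drop=True),
        summary={"r": r, "p": p, "n": int(len(df))},
    )


# --- end-to-end pipeline ----------------------------------------------------


@dataclass
class PipelineResult:
    world: WorldSpec
    space: MeaningSpace  # reduced space used by the network
    corpus: Corpus
    weights: SRNWeights
    training_log: list[dict]
    traces: list[Trajectory]
    mean_comprehension: float


def run_pipeline(
    seed: int = 1,
    n_models: int = 10_000,
    k: int = 150,
    epochs: int = 5000,
    world: WorldSpec | None = None,
    freq_spec: dict[str, int] | None = None,
    config: SRNConfig | None = None,
    sample_seed: int | None = None,
    space: MeaningSpace | None = None,
) -> PipelineResult:
    """World -> meaning space -> corpus -> training -> traces, end to end.

    ``seed`` drives training; the world sample uses ``sample_seed`` (default
    ``seed``).  A pre-built reduced ``space`` may be passed to share the
    world across training seeds.
    """
    world = world or default_world_spec()
    if space is None:
        full = sample_models(world, SamplerConfig(n_models=n_models, seed=sample_seed if sample_seed is not None else seed))
        space = select_dimensions(full, k=k)
    vocab = build_vocabulary(world)
    corpus = build_corpus(generate_sentences(world), freq_spec, spec=world, vocabulary=vocab)
    if config is None:
        config = SRNConfig(
            n_input=len(vocab), n_output=space.n_models, epochs=epochs, seed=seed
        )
    weights, log = train(config, corpus, space)
    traces = trace_corpus(space, weights, corpus)
    return PipelineResult(
        world=world,
        space=space,
        corpus=corpus,
        weights=weights,
        training_log=log,
        traces=traces,
        mean_comprehension=mean_comprehension(weights, corpus, space),
    )
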