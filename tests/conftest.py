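import numpy as np
import pytest

import semspace as ss
from semspace.meaning_space import MeaningSpace, Proposition

P = Proposition


@pytest.fixture(scope="session")
def f4_space() -> MeaningSpace:
    """Four models over {p, q} with satisfaction rows 11, 10, 01, 11."""
    return MeaningSpace(
        (P("p"), P("q")),
        np.array([[1, 1], [1, 0], [0, 1], [1, 1]], dtype=np.uint8),
    )


@pytest.fixture(scope="session")
def toy_world():
    """A miniature pipeline: 2 persons, pay/leave only, handcrafted models.

    Four propositions, four 2-word sentences, eight models chosen so every
    sentence's semantics has prior strictly between 0 and 1.
    """
    spec = ss.WorldSpec(
        persons=("beth", "dave"),
        predicates=(("pay", None), ("leave", None)),
    )
    props = tuple(ss.enumerate_propositions(spec))
    matrix = np.array(
        [
            [1, 0, 1, 0],
            [1, 1, 0, 0],
            [0, 1, 1, 1],
            [1, 0, 0, 1],
            [0, 0, 1, 1],
            [1, 1, 1, 0],
            [0, 1, 0, 1],
            [1, 0, 1, 1],
        ],
        dtype=np.uint8,
    )
    space = MeaningSpace(props, matrix)
    corpus = ss.build_corpus(ss.generate_sentences(spec), spec=spec)
    return spec, space, corpus


@pytest.fixture(scope="session")
def default_world():
    return ss.default_world_spec()


@pytest.fixture(scope="session")
def sampled_space(default_world) -> MeaningSpace:
    """The full 10k-model sample of the default world."""
    return ss.sample_models(default_world, ss.SamplerConfig(n_models=10_000, seed=0))


@pytest.fixture(scope="session")
def reduced_space(sampled_space) -> MeaningSpace:
    """The 150-model reduced space used by the network."""
    return ss.select_dimensions(sampled_space, k=150)


@pytest.fixture(scope="session")
def default_corpus(default_world):
    return ss.build_corpus(ss.generate_sentences(default_world), spec=default_world)
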