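import numpy as np
import pytest

from macrolink import (
    GeneratorConfig,
    Grammar,
    MacroActivityGNN,
    generate_dataset,
    random_prototypes,
)


@pytest.fixture
def abc_grammar() -> Grammar:
    """Single macro-activity [a, b, c]."""
    return Grammar.from_sequences(["a", "b", "c"], [[0, 1, 2]])


@pytest.fixture
def branching_grammar() -> Grammar:
    """Two macro-activities sharing the prefix [a]: [a,b] and [a,c]."""
    return Grammar.from_sequences(["a", "b", "c"], [[0, 1], [0, 2]])


@pytest.fixture
def six_seq_grammar() -> Grammar:
    """Six sequences of lengths 3-6 over 8 classes (the oracle-equivalence setting)."""
    return Grammar.from_sequences(
        [f"c{i}" for i in range(8)],
        [
            [0, 1, 2],
            [0, 1, 3, 4],
            [2, 3, 4, 5],
            [5, 6, 7, 0, 1],
            [1, 2, 3, 4, 5],
            [6, 7, 0, 1, 2, 3],
        ],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def trained_separable():
    """An estimator fitted on well-separated sigma=0.01 data (shared across tests).

    Returns (estimator, dataset, grammar); training takes ~2 s.
    """
    grammar = Grammar.from_sequences(
        [f"c{i}" for i in range(8)],
        [
            [0, 1, 2],
            [0, 1, 3, 4],
            [2, 3, 4, 5],
            [5, 6, 7, 0, 1],
            [1, 2, 3, 4, 5],
            [6, 7, 0, 1, 2, 3],
        ],
    )
    protos = random_prototypes(8, 15, 0.01, seed=1, min_distance=0.1)
    dataset = generate_dataset(grammar, protos, GeneratorConfig(repetitions=10, seed=1))
    est = MacroActivityGNN(max_epochs=100, random_state=1).fit(dataset)
    return est, dataset, grammar
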