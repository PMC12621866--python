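import numpy as np
import pytest

from foldcensus.sampling import SamplingParams, Vocabulary
from foldcensus.synthetic import (
    PlantedBatchSpec,
    make_synthetic_hit_tables,
    make_toy_markov_model,
)


@pytest.fixture(scope="session")
def uniform_model():
    """3-token uniform chain (2 residues + STOP), every conditional 1/3."""
    return make_toy_markov_model(3, "uniform")


@pytest.fixture(scope="session")
def two_mode_model():
    return make_toy_markov_model(6, "two_mode", seed=11)


@pytest.fixture
def neutral_params():
    """Transform-neutral knobs: T=1, full pool, no nucleus cut, no penalty."""
    return SamplingParams(
        temperature=1.0, top_k=None, top_p=1.0, repetition_penalty=1.0,
        max_tokens=4, max_residues=100,
    )


class ConstantTokenModel:
    """Always emits one designated token with probability 1."""

    def __init__(self, tokens, stop_index, emit_index):
        self.vocabulary = Vocabulary(tokens, stop_index)
        self.emit_index = emit_index

    def next_token_probs(self, context):
        probs = np.zeros(len(self.vocabulary))
        probs[self.emit_index] = 1.0
        return probs


@pytest.fixture
def constant_model_factory():
    return ConstantTokenModel


@pytest.fixture(scope="session")
def small_planted_batch():
    spec = PlantedBatchSpec(
        n_sequences=400,
        invalid_fraction=0.05,
        assigned_fraction=0.40,
        n_distinct_folds=9,
        escape_fraction_among_assigned=0.25,
        seed=42,
    )
    return make_synthetic_hit_tables(spec)
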