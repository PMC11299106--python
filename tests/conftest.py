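"""Shared fixtures: a small synthetic benchmark, an embedding trained on its
training genomes, and a small forest ensemble.  Session-scoped because
several test modules reuse them."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import mobclass as m

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_bench():
    return m.generate_benchmark(
        n_genomes=6,
        n_train_per_class_per_bin=60,
        n_test_per_class_per_group=25,
        seed=11,
        test_groups={"A": (801, 1200)},
    )


@pytest.fixture(scope="session")
def tiny_embedding(tiny_bench):
    corpus = [seq for _, seq, _ in tiny_bench["train_genomes"]]
    return m.train_embedding(corpus, m.EmbeddingConfig(seed=11))


@pytest.fixture(scope="session")
def train_fragments(tiny_bench):
    return [fr for frs in tiny_bench["train_fragments"].values() for fr in frs]


@pytest.fixture(scope="session")
def tiny_ensemble(train_fragments, tiny_embedding):
    return m.train_ensemble(train_fragments, tiny_embedding, n_trees=50, seed=11)


@pytest.fixture()
def toy_embedding():
    """k=1 embedding with hand-set 2-d vectors for exact arithmetic checks."""
    cfg = m.EmbeddingConfig(k=1, dimension=2)
    vectors = {
        "A": np.array([1.0, 0.0]),
        "C": np.array([0.0, 1.0]),
        "G": np.array([1.0, 1.0]),
        "T": np.array([-1.0, 2.0]),
    }
    return m.EmbeddingModel(config=cfg, vocabulary=set(vectors), vectors=vectors)
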