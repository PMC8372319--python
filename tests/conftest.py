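"""Shared fixtures: small deterministic datasets and tiny model settings."""

from __future__ import annotations

import numpy as np
import pytest

from pseudoham.molecular_io import AtomicStructure
from pseudoham.synthetic_data import make_benchmark_suite


@pytest.fixture(scope="session")
def tiny_suite():
    """A miniature benchmark suite for fast pipeline tests."""
    return make_benchmark_suite(11, n_ensemble=30, n_path=10, n_compounds=40)


@pytest.fixture(scope="session")
def full_suite():
    """The default-size suite (generation only — no training on it here)."""
    return make_benchmark_suite(5)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture()
def water():
    return AtomicStructure(
        elements=np.array([8, 1, 1]),
        positions=np.array(
            [[0.0, 0.0, 0.0], [0.9572, 0.0, 0.0], [-0.24, 0.9266, 0.0]]
        ),
        id="water",
    )


def random_structure(rng, n_atoms=5, elements=(1, 6, 7, 8), spread=2.5):
    """A random valid structure (resampled until the distance floor holds)."""
    while True:
        z = rng.choice(elements, size=n_atoms)
        pos = rng.uniform(-spread, spread, size=(n_atoms, 3))
        try:
            return AtomicStructure(z, pos)
        except ValueError:
            continue


TINY_MODEL = dict(
    n_features=16,
    n_interactions=1,
    n_rbf=8,
    cutoff=5.0,
    batch_size=8,
    max_epochs=5,
    patience=5,
)
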