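"""Shared fixtures: planted models, sampled corpora and fitted estimators.

The expensive objects (the default planted corpus and its PLM fit) are
session-scoped so the whole suite reuses one fit.
"""

from __future__ import annotations

import numpy as np
import pytest

from tcsdca import DirectCouplingAnalysis
from tcsdca.synthetic import (
    default_planted_model,
    make_noncognates,
    sample_pairs,
)

#: root seed for every fixture in the suite
SEED = 7


@pytest.fixture(scope="session")
def planted_model():
    return default_planted_model(seed=0)


@pytest.fixture(scope="session")
def corpus(planted_model):
    c = sample_pairs(planted_model, n=2000, seed=1, burn_in=1000)
    make_noncognates(c, seed=2)
    return c


@pytest.fixture(scope="session")
def fitted(corpus):
    """PLM fit of the default synthetic corpus (shared across tests)."""
    return DirectCouplingAnalysis(method="plm").fit(corpus.msa)


@pytest.fixture(scope="session")
def small_corpus(planted_model):
    """A small corpus for cheap scoring tests (no fit attached)."""
    c = sample_pairs(planted_model, n=120, seed=3, burn_in=400, pairs_per_genome=6)
    make_noncognates(c, seed=4)
    return c


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
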