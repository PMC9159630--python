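"""Shared fixtures: random-table generators and bundled example data."""

from __future__ import annotations

import numpy as np
import pytest

from fragility import TwoByTwoTable, load_example


def random_table(rng: np.random.Generator, n_max: int = 30) -> TwoByTwoTable:
    """A random 2x2 trial with arm sizes up to ``n_max`` (zero cells allowed)."""
    n0 = int(rng.integers(2, n_max + 1))
    n1 = int(rng.integers(2, n_max + 1))
    e0 = int(rng.integers(0, n0 + 1))
    e1 = int(rng.integers(0, n1 + 1))
    return TwoByTwoTable(e0, n0, e1, n1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240615)


@pytest.fixture(scope="session")
def copd():
    """The complete 3-study, 4-treatment COPD network fixture."""
    return load_example("copd")


@pytest.fixture(scope="session")
def ad_head():
    return load_example("ad_head")


@pytest.fixture(scope="session")
def ns_head():
    return load_example("ns_head")
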