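"""Shared fixtures: random CRF instances and small synthetic corpora."""

from __future__ import annotations

import numpy as np
import pytest

from sslabel.crf import CrfParameters


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_crf_instance(rng, L: int, K: int, scale: float = 2.0):
    """A random (emissions, params) pair with O(1)-scale scores."""
    emissions = scale * rng.standard_normal((L, K))
    params = CrfParameters(
        transitions=scale * rng.standard_normal((K, K)),
        start=scale * rng.standard_normal(K),
        stop=scale * rng.standard_normal(K),
    )
    return emissions, params


@pytest.fixture
def crf_instance_factory():
    return random_crf_instance
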