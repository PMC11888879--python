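"""Shared fixtures: small hand-built matrices and synthetic recipes."""

from __future__ import annotations

import numpy as np
import pytest

from rceife.io import NEG, POS, LabeledMatrix
from rceife.synthetic import Block, SyntheticSpec


def make_matrix(n_pos: int, n_neg: int, n_features: int, seed: int = 0,
                separating: int = 0, shift: float = 3.0) -> LabeledMatrix:
    """Random Gaussian matrix; the first ``separating`` features get a
    between-class mean shift of ``shift`` within-class SDs."""
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    values = rng.standard_normal((n, n_features))
    values[:n_pos, :separating] += shift
    return LabeledMatrix(
        sample_ids=tuple(f"s{i}" for i in range(n)),
        feature_ids=tuple(f"g{i:04d}" for i in range(n_features)),
        values=values,
        labels=(POS,) * n_pos + (NEG,) * n_neg,
    )


@pytest.fixture
def tiny_matrix() -> LabeledMatrix:
    """4 samples x 3 features, 2 pos / 2 neg, fixed values."""
    return LabeledMatrix(
        sample_ids=("s1", "s2", "s3", "s4"),
        feature_ids=("g1", "g2", "g3"),
        values=np.arange(12, dtype=float).reshape(4, 3),
        labels=(POS, POS, NEG, NEG),
    )


@pytest.fixture
def balanced_matrix() -> LabeledMatrix:
    """40 samples x 25 features with one strongly separating feature."""
    return make_matrix(20, 20, 25, seed=7, separating=1)


@pytest.fixture
def two_block_spec() -> SyntheticSpec:
    """Two tight correlated blocks for clustering-recovery tests."""
    return SyntheticSpec(
        n_pos=30, n_neg=30, n_features=20,
        blocks=(Block(10, effect=0.0, rho=0.95),
                Block(10, effect=0.0, rho=0.95)),
        seed=11,
    )
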