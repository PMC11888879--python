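"""Synthetic labeled matrices with planted correlated informative blocks.

The generator emulates a two-class expression/abundance table at desk
scale: most features are independent Gaussian noise; a few *blocks* of
features are mutually equicorrelated (correlation ``rho``) and carry a
between-class mean shift expressed in within-class standard-deviation
units (``effect``). The planted block features are returned as ground
truth, so clustering recovery and signal-recovery properties of the
elimination engine can be tested without any external download.

An equicorrelated block is built by the one-factor construction
``x = sqrt(rho) * z_shared + sqrt(1 - rho) * z_own`` which has unit
variance and pairwise correlation exactly ``rho``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError
from .io import NEG, POS, LabeledMatrix

__all__ = ["Block", "SyntheticSpec", "generate"]


@dataclass(frozen=True)
class Block:
    """A planted block: ``size`` features, mean shift ``effect`` (in SD
    units), within-block equicorrelation ``rho``."""

    size: int
    effect: float = 1.5
    rho: float = 0.6

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ParameterError("block size must be >= 1")
        if self.effect < 0:
            raise ParameterError("effect must be >= 0")
        if not (0.0 <= self.rho < 1.0):
            raise ParameterError("rho must be in [0, 1)")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic two-class matrix."""

    n_pos: int = 60
    n_neg: int = 60
    n_features: int = 2000
    blocks: tuple[Block, ...] = field(
        default_factory=lambda: (Block(10), Block(10), Block(10)))
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(self.blocks))
        if self.n_pos < 1 or self.n_neg < 1:
            raise ParameterError("both classes need at least one sample")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be positive")
        if sum(b.size for b in self.blocks) > self.n_features:
            raise ParameterError("block sizes exceed the total feature count")

    @property
    def n_informative(self) -> int:
        return sum(b.size for b in self.blocks)


def generate(spec: SyntheticSpec) -> tuple[LabeledMatrix, frozenset[str]]:
    """Draw one matrix from the spec; returns (matrix, informative ids).

    Rows are ``n_pos`` positive samples followed by ``n_neg`` negative
    ones; block features occupy the leading columns, the rest is noise.
    Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pos + spec.n_neg
    q = spec.n_features
    width = len(str(q - 1))
    feature_ids = tuple(f"f{i:0{width}d}" for i in range(q))
    labels = (POS,) * spec.n_pos + (NEG,) * spec.n_neg
    is_pos = np.arange(n) < spec.n_pos

    values = np.empty((n, q), dtype=np.float64)
    col = 0
    truth: list[str] = []
    for block in spec.blocks:
        shared = rng.standard_normal((n, 1))
        own = rng.standard_normal((n, block.size))
        x = np.sqrt(block.rho) * shared + np.sqrt(1.0 - block.rho) * own
        x *= spec.noise_sd
        x[is_pos] += block.effect * spec.noise_sd
        values[:, col:col + block.size] = x
        truth.extend(feature_ids[col:col + block.size])
        col += block.size
    if col < q:
        values[:, col:] = spec.noise_sd * rng.standard_normal((n, q - col))

    sample_ids = tuple(
        f"pos{i:03d}" for i in range(spec.n_pos)
    ) + tuple(f"neg{i:03d}" for i in range(spec.n_neg))
    matrix = LabeledMatrix(sample_ids=sample_ids, feature_ids=feature_ids,
                           values=values, labels=labels)
    return matrix, frozenset(truth)
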