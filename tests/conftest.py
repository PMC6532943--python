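"""Shared fixtures: reference models, small model spaces, synthetic pairs."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from epinet import ModelSpec, SimConfig
from epinet import model_space as ms

#: Minimal inversion motif: R1 -| R2 (weak), R1 -> G1 (weak), R2 -> G1 (strong).
INVERSION_MOTIF = np.array(
    [
        [0, -1, 1, 0],
        [0, 0, 5, 0],
        [0, 0, 0, 0],
        [0, 0, 0, 0],
    ],
    dtype=np.int8,
)


@pytest.fixture
def inversion_spec() -> ModelSpec:
    return ModelSpec(INVERSION_MOTIF, (0, 0, 1, 0))


@pytest.fixture
def config() -> SimConfig:
    return SimConfig(seed=0)


@pytest.fixture(scope="session")
def low_complexity_canonical() -> np.ndarray:
    """All canonical matrices with at most three edges, as (n, 16) int8."""
    values = (1, 5, -1, -5)
    positions = [(i, j) for i in range(4) for j in range(4) if i != j]
    seen = set()
    for k in (2, 3):
        for pos in itertools.combinations(positions, k):
            for vals in itertools.product(values, repeat=k):
                m = np.zeros((4, 4), dtype=np.int8)
                for (i, j), v in zip(pos, vals):
                    m[i, j] = v
                if ms.passes_conditions(m):
                    seen.add(ms.canonicalize(m).tobytes())
    return np.array([np.frombuffer(b, dtype=np.int8) for b in sorted(seen)])


def random_valid_matrices(n: int, seed: int) -> list[np.ndarray]:
    """Random matrices passing the structural conditions."""
    rng = np.random.default_rng(seed)
    values = np.array([1, 5, -1, -5], dtype=np.int8)
    out: list[np.ndarray] = []
    while len(out) < n:
        m = np.zeros((4, 4), dtype=np.int8)
        for j in range(4):
            rows = [i for i in range(4) if i != j]
            for i in rng.choice(rows, size=rng.integers(0, 3), replace=False):
                m[i, j] = values[rng.integers(0, 4)]
        if ms.passes_conditions(m):
            out.append(m)
    return out


@pytest.fixture(scope="session")
def random_specs() -> list[ModelSpec]:
    """~600 random logic-expanded model specs (fixed seed)."""
    specs: list[ModelSpec] = []
    for m in random_valid_matrices(250, seed=42):
        specs.extend(ms.expand_logic(m))
    return specs
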