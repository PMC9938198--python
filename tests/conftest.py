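"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from rnapart.struct_io import SecondaryStructure


def random_pair_structure(
    rng: np.random.Generator,
    n: int | None = None,
    max_n: int = 300,
    pair_density: float = 0.15,
    allow_triples: bool = True,
) -> SecondaryStructure:
    """A structure with uniformly random pairs.

    Deliberately unconstrained: pairs may cross (pseudoknots) and, when
    ``allow_triples``, share endpoints (multi-pairings) — the hardest
    inputs for the labeling and partitioning algebra.
    """
    if n is None:
        n = int(rng.integers(2, max_n + 1))
    seq = "".join(rng.choice(list("ACGU"), size=n))
    n_pairs = int(rng.binomial(n, pair_density))
    pairs: set[tuple[int, int]] = set()
    used: set[int] = set()
    for _ in range(n_pairs):
        i, j = sorted(int(v) for v in rng.choice(n, size=2, replace=False))
        if i == j:
            continue
        if not allow_triples and (i in used or j in used):
            continue
        pairs.add((i, j))
        used.update((i, j))
    return SecondaryStructure(seq, pairs)


def brute_force_exterior(structure: SecondaryStructure) -> np.ndarray:
    """O(n * pairs) enclosure check, independent of the implementation.

    A base is exterior iff it is an endpoint of no pair and lies
    strictly inside no pair's interval.
    """
    n = len(structure.sequence)
    labels = np.ones(n, dtype=np.int8)
    for k in range(n):
        for i, j in structure.pairs:
            if k == i or k == j or i < k < j:
                labels[k] = 0
                break
    return labels


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
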