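"""Shared fixtures and independent brute-force oracles.

The oracles here enumerate {1,2} completions in pure Python, independent
of the package's DP and vectorized enumeration, so equality tests are a
genuine dual route.
"""

from __future__ import annotations

import itertools
from typing import Dict, Hashable, Mapping

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from breaktrace.trees import PhyloTree

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def oracle_min_events(tree: PhyloTree, leaf_labels: Mapping[Hashable, int]) -> int:
    """Exhaustive minimum over every {1,2} completion (pure Python)."""
    labs = {v: leaf_labels[tree.leaf_names[v]] for v in tree.leaves}
    fixed = {v: l for v, l in labs.items() if l != 3}
    free = [v for v in tree.vertices if v not in fixed]
    edges = tree.edges
    best = None
    for combo in itertools.product((1, 2), repeat=len(free)):
        full = dict(fixed)
        full.update(zip(free, combo))
        ev = sum(1 for u, v in edges if full[u] != full[v])
        if best is None or ev < best:
            best = ev
    return best


def oracle_assignment(tree: PhyloTree, leaf_labels: Mapping[Hashable, int]):
    """Exhaustive optimal labelings: (min events, candidate edge set,
    optimum count, per-edge fractions)."""
    labs = {v: leaf_labels[tree.leaf_names[v]] for v in tree.leaves}
    fixed = {v: l for v, l in labs.items() if l != 3}
    free = [v for v in tree.vertices if v not in fixed]
    edges = tree.edges
    solutions = []
    for combo in itertools.product((1, 2), repeat=len(free)):
        full = dict(fixed)
        full.update(zip(free, combo))
        evset = frozenset((u, v) for u, v in edges if full[u] != full[v])
        solutions.append(evset)
    best = min(len(s) for s in solutions)
    optima = [s for s in solutions if len(s) == best]
    candidates = frozenset().union(*optima) if optima else frozenset()
    fractions = {
        e: sum(1 for s in optima if e in s) / len(optima) for e in candidates
    }
    return best, set(candidates), len(optima), fractions


def caterpillar7() -> PhyloTree:
    """Caterpillar tree on leaves 1..7 with spine 8..12."""
    edges = [
        (1, 8), (2, 8), (8, 9), (3, 9), (9, 10), (4, 10),
        (10, 11), (5, 11), (11, 12), (6, 12), (7, 12),
    ]
    return PhyloTree(edges, {i: i for i in range(1, 8)})
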