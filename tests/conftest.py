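"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own graph machinery:
component sizes come from a hand-written breadth-first search over a plain
adjacency dict, and small discrete distributions from explicit enumeration,
so that they can arbitrate the implementation rather than mirror it.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np
import pytest

from cystkit.topology import CystGraph, canonical_cyst


@pytest.fixture
def canonical8() -> CystGraph:
    return canonical_cyst(3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)


# -- independent oracles ---------------------------------------------------


def bfs_component_sizes(
    edges: list[tuple[int, int]], removed: tuple[int, int]
) -> tuple[int, int]:
    """Sizes (small, large) of the two components of a tree minus one edge.

    Plain BFS over an adjacency dict; no networkx.
    """
    removed = tuple(sorted(removed))
    adj: dict[int, list[int]] = {}
    for a, b in edges:
        if tuple(sorted((a, b))) == removed:
            continue
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    nodes = {n for e in edges for n in e}
    start = removed[0]
    seen = {start}
    queue = deque([start])
    while queue:
        cur = queue.popleft()
        for nxt in adj.get(cur, ()):
            if nxt not in seen:
                seen.add(nxt)
                queue.append(nxt)
    a = len(seen)
    b = len(nodes) - a
    return (min(a, b), max(a, b))


def brute_force_break_sizes(g: CystGraph) -> list[tuple[int, int]]:
    """All single-bridge fragment-size pairs of a cyst, via the BFS oracle."""
    edges = [b.endpoints for b in g.bridges]
    return [bfs_component_sizes(edges, e) for e in edges]


def enumerate_poisson_binomial(probs: list[float]) -> np.ndarray:
    """pmf of a Bernoulli-sum by explicit enumeration of all 2^n outcomes."""
    n = len(probs)
    pmf = np.zeros(n + 1)
    for bits in itertools.product((0, 1), repeat=n):
        pr = 1.0
        for b, p in zip(bits, probs):
            pr *= p if b else (1.0 - p)
        pmf[sum(bits)] += pr
    return pmf
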