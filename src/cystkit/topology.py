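"""Germline-cyst lineage trees built by synchronous incomplete divisions.

A cyst is modeled as a tree whose nodes are cells and whose edges are the
intercellular bridges (ring canals) left behind by incomplete cytokinesis.
At each division every dividing cell D spawns a new daughter D'; the single
new bridge connects D and D', and *all* pre-existing bridges of D remain
attached to D (the "retaining" daughter).  This maximally branched pattern —
the canonical insect-cyst topology — is the one consistent with the observed
breakage arithmetic of 8-cell cysts, where exactly 2 of the 7 bridges
separate a 6-cell group.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import networkx as nx
import numpy as np

CellId = int

PartialRoundPolicy = Literal["leaf_first", "random_subset"]
FragmentationSchedule = Literal["none", "eight_cell", "quartet"]


@dataclass(frozen=True, order=True)
class Bridge:
    """An intercellular bridge between two sister-lineage cells.

    The pair (cell_a, cell_b) is stored with cell_a < cell_b so that bridges
    compare and hash as unordered pairs.
    """

    cell_a: CellId
    cell_b: CellId
    round_created: int

    def __post_init__(self) -> None:
        if self.cell_a == self.cell_b:
            raise ValueError("bridge endpoints must differ")
        if self.cell_a > self.cell_b:
            a, b = self.cell_a, self.cell_b
            object.__setattr__(self, "cell_a", b)
            object.__setattr__(self, "cell_b", a)

    @property
    def endpoints(self) -> tuple[CellId, CellId]:
        return (self.cell_a, self.cell_b)


@dataclass(frozen=True)
class BreakOutcome:
    """A bridge together with the two fragment sizes its removal produces."""

    bridge: Bridge
    size_small: int
    size_large: int

    @property
    def sizes(self) -> tuple[int, int]:
        return (self.size_small, self.size_large)


@dataclass
class SimConfig:
    """Configuration of a clone-level division/fragmentation simulation.

    rounds defaults to the five mitotic rounds a mouse PGC completes before
    meiotic entry.
    """

    rounds: int = 5
    fragmentation_schedule: FragmentationSchedule = "none"
    partial_round_policy: PartialRoundPolicy = "leaf_first"
    seed: int = 0
    oocyte_min_size: int = 6

    def __post_init__(self) -> None:
        if self.rounds < 0:
            raise ValueError("rounds must be >= 0")
        if self.fragmentation_schedule not in ("none", "eight_cell", "quartet"):
            raise ValueError(
                f"unknown fragmentation_schedule {self.fragmentation_schedule!r}"
            )
        if self.partial_round_policy not in ("leaf_first", "random_subset"):
            raise ValueError(
                f"unknown partial_round_policy {self.partial_round_policy!r}"
            )


class CystGraph:
    """Tree of cyst cells connected by intercellular bridges.

    Cells are integer ids; the founder is 1 and daughters are numbered
    consecutively in creation order.  Each cell carries the round at which it
    was created (founder: 0); each bridge carries the round at which it was
    formed.  The parent map records the division history (new daughter ->
    retaining daughter), which the bridge tree alone does not distinguish.
    """

    def __init__(
        self,
        graph: nx.Graph,
        parent: dict[CellId, CellId],
        rounds_completed: int,
    ) -> None:
        self._g = graph
        self._parent = dict(parent)
        self.rounds_completed = rounds_completed

    # -- accessors ---------------------------------------------------------

    @property
    def cells(self) -> frozenset[CellId]:
        return frozenset(self._g.nodes)

    @property
    def n_cells(self) -> int:
        return self._g.number_of_nodes()

    @property
    def bridges(self) -> list[Bridge]:
        out = [
            Bridge(a, b, d["round_created"]) for a, b, d in self._g.edges(data=True)
        ]
        out.sort(key=lambda b: (b.round_created, b.cell_a, b.cell_b))
        return out

    @property
    def parent(self) -> dict[CellId, CellId]:
        return dict(self._parent)

    def generation_of(self, cell: CellId) -> int:
        return self._g.nodes[cell]["generation_created"]

    def degree_of(self, cell: CellId) -> int:
        return self._g.degree(cell)

    def max_degree_cell(self) -> CellId:
        # tie-break: smallest id
        return min(self._g.nodes, key=lambda c: (-self._g.degree(c), c))

    def neighbors(self, cell: CellId) -> list[CellId]:
        return sorted(self._g.neighbors(cell))

    def has_bridge(self, bridge: Bridge) -> bool:
        return (
            self._g.has_edge(*bridge.endpoints)
            and self._g.edges[bridge.endpoints]["round_created"]
            == bridge.round_created
        )

    def to_networkx(self) -> nx.Graph:
        return self._g.copy()

    # -- construction / modification --------------------------------------

    def copy(self) -> "CystGraph":
        return CystGraph(self._g.copy(), self._parent, self.rounds_completed)

    def validate(self) -> None:
        """Raise if the bridge network is not a connected tree."""
        n, m = self._g.number_of_nodes(), self._g.number_of_edges()
        if n == 0:
            raise ValueError("empty cyst")
        if m != n - 1 or not nx.is_connected(self._g):
            raise ValueError("cyst bridge network is not a tree")

    def split_on(self, bridge: Bridge) -> tuple["CystGraph", "CystGraph"]:
        """Remove one bridge and return the two resulting fragments.

        Fragments are ordered by (size, smallest cell id); each keeps its
        cells' original ids, generations and the surviving parent links.
        """
        if not self._g.has_edge(*bridge.endpoints):
            raise KeyError(f"bridge {bridge.endpoints} not in graph")
        h = self._g.copy()
        h.remove_edge(*bridge.endpoints)
        comps = [set(c) for c in nx.connected_components(h)]
        comps.sort(key=lambda c: (len(c), min(c)))
        frags = []
        for comp in comps:
            sub = h.subgraph(comp).copy()
            par = {c: p for c, p in self._parent.items() if c in comp and p in comp}
            frags.append(CystGraph(sub, par, self.rounds_completed))
        return frags[0], frags[1]

    def relabeled(self, mapping: dict[CellId, CellId]) -> "CystGraph":
        """Return an isomorphic copy with cell ids renamed by ``mapping``."""
        g = nx.relabel_nodes(self._g, mapping, copy=True)
        par = {mapping[c]: mapping[p] for c, p in self._parent.items()}
        return CystGraph(g, par, self.rounds_completed)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CystGraph):
            return NotImplemented
        return (
            self.cells == other.cells
            and self.bridges == other.bridges
            and self._parent == other._parent
        )

    def __repr__(self) -> str:
        return (
            f"CystGraph(n_cells={self.n_cells}, "
            f"rounds_completed={self.rounds_completed})"
        )


def founder() -> CystGraph:
    """A single primordial germ cell: one cell, no bridges."""
    g = nx.Graph()
    g.add_node(1, generation_created=0)
    return CystGraph(g, {}, 0)


def divide_round(
    g: CystGraph, dividers: Optional[Iterable[CellId]] = None
) -> CystGraph:
    """One (possibly partial) round of synchronous incomplete division.

    Every cell in ``dividers`` (default: all cells) spawns a new daughter
    connected by one new bridge; all of the divider's pre-existing bridges
    stay with the divider, which therefore keeps its id and plays the role
    of the retaining daughter.  ``rounds_completed`` advances only when the
    round is full.
    """
    cells = g.cells
    if dividers is None:
        div = sorted(cells)
    else:
        div = sorted(set(dividers))
        if not div:
            raise ValueError("a division round needs at least one divider")
        unknown = set(div) - cells
        if unknown:
            raise ValueError(f"dividers not in cyst: {sorted(unknown)}")
    round_no = g.rounds_completed + 1
    h = g.to_networkx()
    parent = g.parent
    next_id = max(cells) + 1
    for d in div:
        h.add_node(next_id, generation_created=round_no)
        h.add_edge(d, next_id, round_created=round_no)
        parent[next_id] = d
        next_id += 1
    completed = g.rounds_completed + (1 if set(div) == cells else 0)
    return CystGraph(h, parent, completed)


def canonical_cyst(r: int) -> CystGraph:
    """The deterministic 2**r-cell cyst after r full division rounds."""
    if r < 0:
        raise ValueError("rounds must be >= 0")
    g = founder()
    for _ in range(r):
        g = divide_round(g)
    return g


def partial_cyst(
    n_cells: int,
    policy: PartialRoundPolicy = "leaf_first",
    rng: Optional[np.random.Generator] = None,
) -> CystGraph:
    """Cyst of exactly ``n_cells`` cells, mid-way through a division round.

    Builds the canonical cyst of floor(log2 n) rounds, then lets the excess
    cells divide.  ``leaf_first`` picks dividers by (lowest bridge count,
    lowest id) and is deterministic; ``random_subset`` draws a uniform
    subset from the seeded generator.
    """
    if n_cells < 2:
        raise ValueError("a cyst needs at least 2 cells")
    r = int(math.floor(math.log2(n_cells)))
    base = canonical_cyst(r)
    extra = n_cells - base.n_cells
    if extra == 0:
        return base
    if extra > base.n_cells:
        raise ValueError(f"cannot reach {n_cells} cells with one partial round")
    cells = sorted(base.cells)
    if policy == "leaf_first":
        dividers = sorted(cells, key=lambda c: (base.degree_of(c), c))[:extra]
    elif policy == "random_subset":
        if rng is None:
            raise ValueError("random_subset policy requires a seeded rng")
        dividers = list(rng.choice(cells, size=extra, replace=False))
        dividers = [int(c) for c in dividers]
    else:
        raise ValueError(f"unknown policy {policy!r}")
    return divide_round(base, dividers)


def fragment_sizes(g: CystGraph, bridge: Bridge) -> tuple[int, int]:
    """Sizes (small, large) of the two components after removing ``bridge``."""
    small, large = g.split_on(bridge)
    return small.n_cells, large.n_cells


def enumerate_break_outcomes(g: CystGraph) -> list[BreakOutcome]:
    """One BreakOutcome per bridge: exhaustive single-bridge removal."""
    if g.n_cells < 2:
        raise ValueError("need at least 2 cells to break a bridge")
    out = []
    for b in g.bridges:
        s, l = fragment_sizes(g, b)
        out.append(BreakOutcome(b, s, l))
    return out


# -- serialization ---------------------------------------------------------


def export_edge_list(g: CystGraph) -> str:
    """Bridge list as text: one ``cell_a<TAB>cell_b<TAB>round`` line per bridge."""
    lines = [f"{b.cell_a}\t{b.cell_b}\t{b.round_created}" for b in g.bridges]
    return "\n".join(lines) + ("\n" if lines else "")


def parse_edge_list(text: str) -> CystGraph:
    """Rebuild a cyst from its edge-list text.

    The division history is recovered from bridge rounds: a non-founder
    cell's creating bridge is its earliest incident bridge, and the other
    endpoint of that bridge is its parent.
    """
    g = nx.Graph()
    max_round = 0
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        a_s, b_s, r_s = line.split("\t")
        a, b, r = int(a_s), int(b_s), int(r_s)
        g.add_edge(a, b, round_created=r)
        max_round = max(max_round, r)
    if g.number_of_nodes() == 0:
        return founder()
    # ids are assigned in creation order, so a daughter's creating bridge is
    # its earliest incident bridge and its parent is that bridge's smaller
    # endpoint; the founder has no smaller neighbor on its earliest bridge
    parent: dict[CellId, CellId] = {}
    for c in g.nodes:
        first_round, other = min(
            (d["round_created"], o) for o, d in g.adj[c].items()
        )
        if other < c:
            parent[c] = other
            g.nodes[c]["generation_created"] = first_round
        else:
            g.nodes[c]["generation_created"] = 0
    cyst = CystGraph(g, parent, max_round)
    cyst.validate()
    return cyst


def _lineage_newick(g: CystGraph, cell: CellId, after_round: int) -> str:
    children = sorted(
        (g.generation_of(c), c) for c, p in g.parent.items() if p == cell
    )
    children = [(r, c) for r, c in children if r > after_round]
    if not children:
        return str(cell)
    r, child = children[0]
    left = _lineage_newick(g, cell, r)
    right = _lineage_newick(g, child, r)
    return f"({left},{right})d{cell}r{r}"


def export_newick(g: CystGraph) -> str:
    """Division lineage as a rooted binary newick string.

    Each internal node is one division; its label ``d<cell>r<round>`` names
    the dividing cell and the round, its first child continues the retaining
    daughter's lineage and its second child is the new daughter.  Leaves are
    the final cell ids, so the parent->daughter history is recoverable.
    """
    root = 1
    if root not in g.cells:
        root = min(c for c in g.cells if c not in g.parent)
    return _lineage_newick(g, root, -1) + ";"


def to_json(g: CystGraph) -> str:
    payload = {
        "cells": [
            {"id": c, "generation_created": g.generation_of(c)}
            for c in sorted(g.cells)
        ],
        "bridges": [[b.cell_a, b.cell_b, b.round_created] for b in g.bridges],
        "parent": {str(c): p for c, p in sorted(g.parent.items())},
        "rounds_completed": g.rounds_completed,
    }
    return json.dumps(payload, indent=2)


def from_json(text: str) -> CystGraph:
    payload = json.loads(text)
    g = nx.Graph()
    for cell in payload["cells"]:
        g.add_node(cell["id"], generation_created=cell["generation_created"])
    for a, b, r in payload["bridges"]:
        g.add_edge(a, b, round_created=r)
    parent = {int(c): p for c, p in payload["parent"].items()}
    cyst = CystGraph(g, parent, payload["rounds_completed"])
    cyst.validate()
    return cyst
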