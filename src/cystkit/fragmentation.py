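"""Random and programmed cyst breakage.

Two breakage regimes are modeled.  Under the random null a single bridge is
removed uniformly at random; on the canonical 8-cell cyst only 2 of the 7
bridges then release a 6-cell group, giving the per-cyst success probability
2/7 used by the exact null test.  Under programmed breakage the broken bridge
is one whose removal releases a 6-cell fragment containing the most-branched
(fusome-enriched, pro-oocyte) cell.  At clone level, the quartet scheme cuts
the 32-cell cyst along its two oldest division rounds into four 8-cell
subtrees and then fissions each into a 6-cell and a 2-cell derivative.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

import networkx as nx
import numpy as np

from cystkit.topology import (
    Bridge,
    BreakOutcome,
    CystGraph,
    SimConfig,
    canonical_cyst,
    divide_round,
    enumerate_break_outcomes,
    founder,
)


class NoSixCellCutError(ValueError):
    """Raised when no bridge removal can release a 6-cell fragment."""


@dataclass
class ClonalOutcome:
    """Final fragments of one clone after division and fragmentation."""

    fragments: list[CystGraph]
    oocyte_count: int
    schedule_used: str

    @property
    def fragment_multiset(self) -> dict[int, int]:
        return dict(Counter(f.n_cells for f in self.fragments))

    @property
    def total_cells(self) -> int:
        return sum(f.n_cells for f in self.fragments)


def six_yielding_bridges(g: CystGraph) -> list[BreakOutcome]:
    """Break outcomes whose removal produces a fragment of exactly 6 cells."""
    return [o for o in enumerate_break_outcomes(g) if 6 in o.sizes]


def p_six(g: CystGraph) -> Fraction:
    """Probability that a uniformly random single break yields a 6-cell cyst.

    Exact rational: (# bridges releasing a 6-cell fragment) / (# bridges).
    """
    outcomes = enumerate_break_outcomes(g)
    hits = sum(1 for o in outcomes if 6 in o.sizes)
    return Fraction(hits, len(outcomes))


def random_break(
    g: CystGraph, rng: np.random.Generator
) -> tuple[CystGraph, CystGraph]:
    """Remove one bridge chosen uniformly at random; return both fragments."""
    bridges = g.bridges
    idx = int(rng.integers(len(bridges)))
    return g.split_on(bridges[idx])


def programmed_break(g: CystGraph) -> tuple[CystGraph, CystGraph]:
    """Break the bridge whose 6-cell side holds the most-branched cell.

    Among bridges releasing a 6-cell fragment, prefer those whose 6-cell
    side contains ``max_degree_cell(g)`` (the pro-oocyte candidate); ties
    are broken by (round_created, smaller endpoint id).  Returns the
    6-cell fragment first.  Raises NoSixCellCutError when the topology
    admits no 6-cell cut.
    """
    candidates = six_yielding_bridges(g)
    if not candidates:
        raise NoSixCellCutError("no six-cell cut")
    hub = g.max_degree_cell()

    def six_side_cells(outcome: BreakOutcome) -> frozenset[int]:
        small, large = g.split_on(outcome.bridge)
        side = small if small.n_cells == 6 else large
        return side.cells

    preferred = [o for o in candidates if hub in six_side_cells(o)]
    pool = preferred if preferred else candidates
    pool.sort(key=lambda o: (o.bridge.round_created, o.bridge.cell_a, o.bridge.cell_b))
    a, b = g.split_on(pool[0].bridge)
    return (a, b) if a.n_cells == 6 else (b, a)


def quartet_fragmentation(g32: CystGraph) -> ClonalOutcome:
    """Partition a canonical 32-cell clone into four 6-cell and four 2-cell cysts.

    The three bridges formed in division rounds 1-2 are removed, leaving
    four 8-cell subtrees; each then undergoes a programmed break into a
    6-cell and a 2-cell derivative.  One oocyte is counted per 6-cell cyst.
    """
    if g32.n_cells != 32:
        raise ValueError("quartet fragmentation expects a 32-cell clone")
    ref = canonical_cyst(5)
    if not nx.is_isomorphic(g32.to_networkx(), ref.to_networkx()):
        raise ValueError("quartet fragmentation expects the canonical topology")
    early = [b for b in g32.bridges if b.round_created <= 2]
    if len(early) != 3:
        raise ValueError("quartet fragmentation expects round-1/2 bridge metadata")
    pieces = [g32]
    for b in early:
        for i, frag in enumerate(pieces):
            if frag.has_bridge(b):
                a, c = frag.split_on(b)
                pieces[i : i + 1] = [a, c]
                break
    fragments: list[CystGraph] = []
    for eight in pieces:
        six, two = programmed_break(eight)
        fragments.extend([six, two])
    fragments.sort(key=lambda f: (-f.n_cells, min(f.cells)))
    oocytes = sum(1 for f in fragments if f.n_cells == 6)
    return ClonalOutcome(fragments, oocytes, "quartet")


def _break_ripe_fragments(fragments: list[CystGraph]) -> list[CystGraph]:
    """Apply programmed breaks to every fragment of >= 7 cells that has one."""
    out: list[CystGraph] = []
    queue = list(fragments)
    while queue:
        frag = queue.pop(0)
        if frag.n_cells >= 7:
            try:
                a, b = programmed_break(frag)
            except NoSixCellCutError:
                out.append(frag)
                continue
            queue.extend([a, b])
        else:
            out.append(frag)
    return out


def simulate_clone(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> ClonalOutcome:
    """Run a clone through division rounds under a fragmentation schedule.

    * ``none`` — divisions only; a single connected cyst results.
    * ``eight_cell`` — after every round, any connected fragment of >= 7
      cells that admits a 6-cell cut undergoes a programmed break.
    * ``quartet`` — all five rounds complete first, then the 32-cell clone
      is cut into four 6-cell and four 2-cell cysts.

    Oocytes are counted as fragments of at least ``config.oocyte_min_size``
    cells (default 6).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.fragmentation_schedule == "quartet":
        if config.rounds != 5:
            raise ValueError("quartet schedule requires exactly 5 rounds")
        outcome = quartet_fragmentation(canonical_cyst(5))
    elif config.fragmentation_schedule == "none":
        g = canonical_cyst(config.rounds)
        outcome = ClonalOutcome([g], 0, "none")
    else:  # eight_cell
        fragments = [founder()]
        for _ in range(config.rounds):
            fragments = [divide_round(f) for f in fragments]
            fragments = _break_ripe_fragments(fragments)
        outcome = ClonalOutcome(fragments, 0, "eight_cell")
    oocytes = sum(
        1 for f in outcome.fragments if f.n_cells >= config.oocyte_min_size
    )
    return ClonalOutcome(outcome.fragments, oocytes, config.fragmentation_schedule)
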