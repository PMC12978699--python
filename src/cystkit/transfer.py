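"""Nurse-cell activation and directional cytoplasmic transfer.

After cyst fragmentation, cells of each small cyst enter meiosis and are
progressively consumed: on average one cell per two days becomes a nurse
cell, transfers most of its cytoplasm through the bridge network toward the
future oocyte, shrinks to a remnant and dies.  The simulator draws
activation times from an exponential clock, activates peripheral (1-bridge)
cells first, moves a fraction epsilon of the donor's current content one
hop along the tree path toward the oocyte, and prunes the donor.  Because
losses compound per hop, epsilon < 1 yields oocyte enrichment below the
cell count n, while epsilon = 1 conserves everything (fold = n).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import networkx as nx
import numpy as np

from cystkit.topology import CellId, CystGraph

OrderPolicy = Literal["leaf_first", "random"]


@dataclass
class TransferParams:
    """Parameters of the nurse-cell transfer model.

    epsilon          fraction of a donor's current content passed per transfer
    rate             nurse-cell activation rate (events/day); the default
                     0.5 encodes one activation per two days
    order_policy     which current leaf activates next: deterministic
                     lowest-bridge-count-first or seeded uniform choice
    initial_content  starting organelle content per cell (arbitrary units)
    """

    epsilon: float = 0.9
    rate: float = 0.5
    order_policy: OrderPolicy = "leaf_first"
    initial_content: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if self.initial_content <= 0:
            raise ValueError("initial_content must be > 0")
        if self.order_policy not in ("leaf_first", "random"):
            raise ValueError(f"unknown order_policy {self.order_policy!r}")


@dataclass(frozen=True)
class TransferEvent:
    time_days: float
    donor: CellId
    recipient: CellId
    amount: float


@dataclass
class TransferTimeline:
    """Ordered record of one cyst's nurse-cell transfers."""

    oocyte: CellId
    events: list[TransferEvent]
    final_content: float
    fold_enrichment: float
    remnant_total: float  # content discarded with dying nurse-cell remnants


def simulate_transfer(
    fragment: CystGraph,
    params: TransferParams,
    rng: np.random.Generator,
) -> TransferTimeline:
    """Consume a cyst fragment by sequential nurse-cell transfers.

    The oocyte is the most-branched cell (smallest id on ties).  At each
    exponential inter-event time a current leaf other than the oocyte is
    activated, donates epsilon times its content to its sole neighbor (the
    next cell on the path toward the oocyte), and is removed together with
    its remnant (1 - epsilon) share.  The process ends when only the oocyte
    remains.
    """
    if fragment.n_cells < 2:
        raise ValueError("transfer needs a fragment of >= 2 cells")
    oocyte = fragment.max_degree_cell()
    tree = fragment.to_networkx()
    content: dict[CellId, float] = {
        c: params.initial_content for c in tree.nodes
    }
    events: list[TransferEvent] = []
    t = 0.0
    remnant = 0.0
    while tree.number_of_nodes() > 1:
        t += float(rng.exponential(1.0 / params.rate))
        leaves = sorted(
            c for c in tree.nodes if tree.degree(c) <= 1 and c != oocyte
        )
        if params.order_policy == "leaf_first":
            donor = min(leaves, key=lambda c: (tree.degree(c), c))
        else:
            donor = int(rng.choice(leaves))
        recipient = next(iter(tree.neighbors(donor)))
        amount = params.epsilon * content[donor]
        remnant += content[donor] - amount
        content[recipient] += amount
        events.append(TransferEvent(t, donor, recipient, amount))
        tree.remove_node(donor)
        del content[donor]
    final = content[oocyte]
    return TransferTimeline(
        oocyte=oocyte,
        events=events,
        final_content=final,
        fold_enrichment=final / params.initial_content,
        remnant_total=remnant,
    )


def expected_breakdown_time(n_cells: int, rate: float) -> float:
    """Mean days to consume an n-cell cyst: (n - 1) exponential waits of
    mean 1/rate."""
    if n_cells < 2:
        raise ValueError("breakdown needs >= 2 cells")
    if rate <= 0:
        raise ValueError("rate must be > 0")
    return (n_cells - 1) / rate
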