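"""Lineage-tree construction, breakage enumeration and serialization."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cystkit.topology import (
    Bridge,
    canonical_cyst,
    divide_round,
    enumerate_break_outcomes,
    export_edge_list,
    export_newick,
    founder,
    fragment_sizes,
    from_json,
    parse_edge_list,
    partial_cyst,
    to_json,
)

from conftest import bfs_component_sizes, brute_force_break_sizes


def degrees(g):
    return sorted(g.degree_of(c) for c in g.cells)


class TestDivision:
    def test_founder_is_a_single_cell(self):
        g = founder()
        assert g.n_cells == 1
        assert g.bridges == []
        assert g.rounds_completed == 0
        assert g.degree_of(1) == 0
        g.validate()

    def test_first_division_makes_a_two_cell_cyst(self):
        g = divide_round(founder())
        assert g.n_cells == 2
        assert len(g.bridges) == 1
        assert degrees(g) == [1, 1]
        assert g.rounds_completed == 1

    def test_retention_rule_after_two_rounds(self):
        # hand-applied: old bridges stay with the retaining daughter, so the
        # founder and its first daughter each hold two bridges
        g = divide_round(divide_round(founder()))
        assert g.n_cells == 4
        assert degrees(g) == [1, 1, 2, 2]

    def test_five_rounds_give_the_full_32_cell_cyst(self):
        g = canonical_cyst(5)
        assert g.n_cells == 32
        assert len(g.bridges) == 31

    def test_empty_divider_set_rejected(self):
        with pytest.raises(ValueError, match="at least one divider"):
            divide_round(founder(), dividers=[])

    def test_unknown_divider_rejected(self):
        with pytest.raises(ValueError, match="not in cyst"):
            divide_round(founder(), dividers=[7])

    def test_partial_round_does_not_advance_round_counter(self):
        g = canonical_cyst(2)
        h = divide_round(g, dividers=[3])
        assert h.rounds_completed == g.rounds_completed
        assert h.n_cells == 5


class TestCanonical:
    @pytest.mark.parametrize("r", range(6))
    def test_size_and_leaf_counts(self, r):
        g = canonical_cyst(r)
        g.validate()
        assert g.n_cells == 2**r
        if r >= 1:
            assert max(degrees(g)) == r
        if r >= 2:
            assert degrees(g).count(1) == 2 ** (r - 1)

    def test_eight_cell_degree_multiset(self, canonical8):
        assert degrees(canonical8) == [1, 1, 1, 1, 2, 2, 3, 3]

    def test_zero_rounds_is_the_founder(self):
        assert canonical_cyst(0) == founder()

    def test_max_degree_cell_is_the_founder(self, canonical8):
        assert canonical8.max_degree_cell() == 1
        assert canonical8.degree_of(1) == 3

    def test_handshake_lemma(self, canonical8):
        assert sum(degrees(canonical8)) == 2 * len(canonical8.bridges)


class TestPartial:
    @pytest.mark.parametrize("n", [5, 6, 7, 9, 10, 11, 13, 17, 25, 31])
    def test_partial_cyst_is_a_tree_of_requested_size(self, n):
        g = partial_cyst(n)
        g.validate()
        assert g.n_cells == n
        assert len(g.bridges) == n - 1

    def test_power_of_two_needs_no_partial_round(self, canonical8):
        assert partial_cyst(8) == canonical8

    def test_leaf_first_is_deterministic(self):
        assert partial_cyst(7) == partial_cyst(7)
        assert partial_cyst(10) == partial_cyst(10)

    def test_leaf_first_dividers_are_lowest_degree_lowest_id(self):
        # from the 4-cell base (degrees 2,2,1,1 for cells 1..4) the three
        # dividers are 3, 4 then 1; daughters numbered 5..7 in divider order
        g = partial_cyst(7)
        pairs = {(b.cell_a, b.cell_b) for b in g.bridges if b.round_created == 3}
        assert pairs == {(1, 5), (3, 6), (4, 7)}

    def test_random_subset_is_seed_reproducible(self):
        a = partial_cyst(10, "random_subset", rng=np.random.default_rng(7))
        b = partial_cyst(10, "random_subset", rng=np.random.default_rng(7))
        assert a == b

    def test_random_subset_requires_rng(self):
        with pytest.raises(ValueError, match="rng"):
            partial_cyst(10, "random_subset")

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            partial_cyst(1)


class TestBreakage:
    def test_fragment_sizes_sum_and_match_oracle(self, canonical8):
        for b in canonical8.bridges:
            sizes = fragment_sizes(canonical8, b)
            assert sum(sizes) == 8
            edges = [x.endpoints for x in canonical8.bridges]
            assert sizes == bfs_component_sizes(edges, b.endpoints)

    def test_round_one_bridge_splits_the_cyst_in_half(self, canonical8):
        (b1,) = [b for b in canonical8.bridges if b.round_created == 1]
        assert fragment_sizes(canonical8, b1) == (4, 4)

    def test_round_three_bridges_shed_single_cells(self, canonical8):
        for b in canonical8.bridges:
            if b.round_created == 3:
                assert fragment_sizes(canonical8, b) == (1, 7)

    def test_two_cell_cyst_splits_into_singletons(self):
        g = divide_round(founder())
        assert fragment_sizes(g, g.bridges[0]) == (1, 1)

    def test_missing_bridge_rejected(self, canonical8):
        with pytest.raises(KeyError):
            fragment_sizes(canonical8, Bridge(5, 8, 3))

    @pytest.mark.parametrize(
        "builder,expected",
        [
            (lambda: canonical_cyst(3), {(1, 7): 4, (2, 6): 2, (4, 4): 1}),
            (lambda: canonical_cyst(2), {(1, 3): 2, (2, 2): 1}),
            (lambda: canonical_cyst(1), {(1, 1): 1}),
        ],
    )
    def test_break_outcome_multisets(self, builder, expected):
        g = builder()
        got = Counter(o.sizes for o in enumerate_break_outcomes(g))
        assert got == Counter(expected)

    @pytest.mark.parametrize("n", [7, 8, 10, 16, 32])
    def test_enumeration_agrees_with_brute_force(self, n):
        g = partial_cyst(n)
        got = sorted(o.sizes for o in enumerate_break_outcomes(g))
        assert got == sorted(brute_force_break_sizes(g))


class TestSerialization:
    def test_edge_list_round_trip(self, canonical8):
        again = parse_edge_list(export_edge_list(canonical8))
        assert again == canonical8
        assert again.rounds_completed == canonical8.rounds_completed

    def test_edge_list_round_trip_partial(self):
        g = partial_cyst(10)
        assert parse_edge_list(export_edge_list(g)) == g

    def test_json_round_trip(self):
        g = partial_cyst(9)
        assert from_json(to_json(g)) == g

    def test_newick_lineage_is_well_formed(self, canonical8):
        dendropy = pytest.importorskip("dendropy")
        nwk = export_newick(canonical8)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        leaves = sorted(int(l.taxon.label) for l in tree.leaf_node_iter())
        assert leaves == sorted(canonical8.cells)
        # one internal node per division
        internal = sum(1 for n in tree.preorder_node_iter() if not n.is_leaf())
        assert internal == canonical8.n_cells - 1


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(
        st.one_of(st.none(), st.integers(min_value=1, max_value=4)),
        min_size=0,
        max_size=5,
    )
)
def test_any_division_sequence_yields_a_tree(plan):
    """Full or partial rounds in any order keep the bridge network a tree."""
    g = founder()
    for step in plan:
        if step is None:
            g = divide_round(g)
        else:
            cells = sorted(g.cells)
            g = divide_round(g, dividers=cells[: min(step, len(cells))])
        g.validate()
        for o in enumerate_break_outcomes(g):
            assert o.size_small + o.size_large == g.n_cells
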