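"""Segment enumeration, density, dominance and reference comparison."""

import itertools

import networkx as nx
import pytest

from segcoex import (
    DataError,
    GTSegment,
    ReferenceOperons,
    classify_strandedness,
    compare_to_reference,
    density,
    dominant_segments,
    enumerate_segments,
    match_summary,
    reachable_set,
    unique_regions,
)

from conftest import (
    brute_force_dominant,
    brute_force_segments,
    make_layout,
    make_network,
    random_instance,
)


def seg(start, members, reach):
    members = tuple(members)
    reach = frozenset(reach)
    return GTSegment(start, members, reach, len(reach) / len(members))


class TestReachableSet:
    def test_chain_through_interior(self):
        net = make_network("g1 g2 g3 g4 g5".split(), [("g1", "g3"), ("g3", "g5")])
        members = ("g1", "g2", "g3", "g4", "g5")
        assert reachable_set(members, net) == {"g1", "g3", "g5"}

    def test_disconnected_extremities_invalid(self):
        net = make_network(["g1", "g2"], [])
        assert reachable_set(("g1", "g2"), net) == frozenset()

    def test_clique_reaches_all_members(self):
        nodes = ["g1", "g2", "g3", "g4"]
        net = make_network(nodes, itertools.combinations(nodes, 2))
        assert reachable_set(tuple(nodes), net) == set(nodes)

    def test_paths_may_not_leave_the_arc(self):
        # g1-g9-g2: the bridge g9 is outside the arc, so no internal path
        net = make_network("g1 g2 g9".split(), [("g1", "g9"), ("g9", "g2")])
        assert reachable_set(("g1", "g2"), net) == frozenset()

    def test_single_member_arc_rejected(self):
        with pytest.raises(DataError):
            reachable_set(("g1",), make_network(["g1"], []))

    def test_matches_per_extremity_reachability_definition(self, rng):
        # R(S) as implemented (component of both extremities) equals the
        # literal definition: members reachable from the extremities by
        # paths internal to S.
        for _ in range(50):
            layout, net = random_instance(rng, n=int(rng.integers(4, 15)))
            order = layout.ordered_ids()
            n = len(order)
            start, k = int(rng.integers(n)), int(rng.integers(2, n))
            members = tuple(order[(start + i) % n] for i in range(k))
            got = reachable_set(members, net)
            sub = net.subgraph(members)
            first, last = members[0], members[-1]
            if not (first in sub and last in sub and nx.has_path(sub, first, last)):
                assert got == frozenset()
                continue
            literal = {
                g for g in members
                if nx.has_path(sub, first, g) and nx.has_path(sub, last, g)
            }
            assert got == literal


class TestDensity:
    def test_three_of_five(self):
        s = seg(0, ["g1", "g2", "g3", "g4", "g5"], ["g1", "g3", "g5"])
        assert density(s) == pytest.approx(0.6)

    def test_clique_density_one(self):
        s = seg(0, ["g1", "g2", "g3"], ["g1", "g2", "g3"])
        assert density(s) == 1.0

    def test_minimal_two_gene_segment(self):
        s = seg(0, ["g1", "g2"], ["g1", "g2"])
        assert density(s) == 1.0

    def test_invariants_enforced_at_construction(self):
        with pytest.raises(DataError, match="extremity"):
            GTSegment(0, ("g1", "g2", "g3"), frozenset({"g2", "g3"}), 2 / 3)
        with pytest.raises(DataError, match="density"):
            GTSegment(0, ("g1", "g2"), frozenset({"g1", "g2"}), 0.7)


class TestEnumerateSegments:
    def test_single_edge_on_six_gene_circle(self):
        layout = make_layout(6)
        net = make_network(layout.ids, [("g1", "g2")])
        segments = enumerate_segments(layout, net)
        assert len(segments) == 1
        assert segments[0].member_ids == ("g1", "g2")
        assert segments[0].density == 1.0

    def test_empty_network_gives_no_segments(self):
        layout = make_layout(6)
        assert enumerate_segments(layout, make_network(layout.ids, [])) == []

    def test_complete_network_linear_n4(self):
        layout = make_layout(4, circular=False)
        net = make_network(layout.ids, itertools.combinations(layout.ids, 2))
        segments = enumerate_segments(layout, net)
        # every arc of length 2..4, all density 1
        assert len(segments) == 3 + 2 + 1
        assert all(s.density == 1.0 for s in segments)
        assert {s.length for s in segments} == {2, 3, 4}

    def test_circular_excludes_whole_genome_arc(self):
        layout = make_layout(4, circular=True)
        net = make_network(layout.ids, itertools.combinations(layout.ids, 2))
        segments = enumerate_segments(layout, net)
        assert max(s.length for s in segments) == 3
        assert len(segments) == 4 * 2  # 4 starts x lengths {2,3}

    def test_wrapping_arcs_enumerated(self):
        layout = make_layout(5)
        net = make_network(layout.ids, [("g5", "g1")])
        segments = enumerate_segments(layout, net)
        assert any(s.member_ids == ("g5", "g1") for s in segments)

    def test_output_sorted_and_deterministic(self, rng):
        layout, net = random_instance(rng, n=15, edge_prob=0.3)
        a = enumerate_segments(layout, net)
        b = enumerate_segments(layout, net)
        assert [(s.start, s.length) for s in a] == sorted(
            (s.start, s.length) for s in a)
        assert a == b

    def test_adding_edges_never_invalidates_an_arc(self, rng):
        layout, net = random_instance(rng, n=12, edge_prob=0.2)
        before = {(s.start, s.length) for s in enumerate_segments(layout, net)}
        net2 = net.copy()
        nodes = list(net.nodes)
        for _ in range(8):
            a, b = rng.choice(nodes, size=2, replace=False)
            net2.add_edge(a, b)
        after = {(s.start, s.length) for s in enumerate_segments(layout, net2)}
        assert before <= after

    @pytest.mark.parametrize("circular", [True, False])
    def test_matches_brute_force_oracle(self, rng, circular):
        for _ in range(30):
            layout, net = random_instance(rng, circular=circular)
            got = {(s.start, s.member_ids, s.reachable) for s in
                   enumerate_segments(layout, net)}
            expected = {(s, m, r) for s, m, r, _ in
                        brute_force_segments(layout, net)}
            assert got == expected


class TestDominantSegments:
    def test_higher_density_superset_dominates(self):
        # A = [g1..g4] clique dominates the wrapping arc F = [g4, g5, g1]:
        # R(F) = {g4, g1} is nested in R(A) and d(F) = 2/3 < d(A) = 1
        a = seg(0, ["g1", "g2", "g3", "g4"], ["g1", "g2", "g3", "g4"])
        f2 = seg(3, ["g4", "g5", "g1"], ["g4", "g1"])
        out = dominant_segments([a, f2], density_min=0.0)
        assert a in out and f2 not in out

    def test_disjoint_segments_both_dominant(self):
        a = seg(0, ["g1", "g2"], ["g1", "g2"])
        b = seg(3, ["g4", "g5"], ["g4", "g5"])
        assert dominant_segments([a, b]) == sorted([a, b], key=lambda s: s.start)

    def test_equal_density_nested_reach_no_domination(self):
        a = seg(0, ["g1", "g2"], ["g1", "g2"])
        b = seg(0, ["g1", "g2", "g3", "g4"], ["g1", "g2", "g3", "g4"])
        out = dominant_segments([a, b])
        assert a in out and b in out

    def test_density_filter_applied_before_dominance(self):
        low = seg(0, ["g1", "g2", "g3", "g4", "g5"], ["g1", "g5"])  # d=0.4
        high = seg(0, ["g1", "g2"], ["g1", "g2"])
        out = dominant_segments([low, high], density_min=0.6)
        assert out == [high]

    def test_reported_segments_respect_density_min(self, rng):
        layout, net = random_instance(rng, n=20, edge_prob=0.3)
        segments = enumerate_segments(layout, net)
        for s in dominant_segments(segments, density_min=0.6):
            assert s.density >= 0.6

    def test_matches_brute_force_all_pairs(self, rng):
        for _ in range(30):
            layout, net = random_instance(rng)
            segments = enumerate_segments(layout, net)
            got = {(s.member_ids, s.reachable) for s in
                   dominant_segments(segments, density_min=0.6)}
            brute = brute_force_dominant(
                [(s.start, s.member_ids, s.reachable, s.density)
                 for s in segments], density_min=0.6)
            expected = {(m, r) for _, m, r, _ in brute}
            assert got == expected


class TestStrandedness:
    def test_all_plus_is_same_direction(self):
        layout = make_layout(3, strands=["+", "+", "+"])
        s = seg(0, ["g1", "g2", "g3"], ["g1", "g2", "g3"])
        assert classify_strandedness(s, layout) == "same_direction"

    def test_one_minus_makes_mixed(self):
        layout = make_layout(3, strands=["+", "-", "+"])
        s = seg(0, ["g1", "g2", "g3"], ["g1", "g2", "g3"])
        assert classify_strandedness(s, layout) == "mixed"


class TestCompareToReference:
    def setup_method(self):
        self.layout = make_layout(10)
        self.ref = ReferenceOperons([
            ("g1", "g2", "g3"), ("g5", "g6"), ("g7", "g8"),
        ])

    def test_exact_match(self):
        s = seg(0, ["g1", "g2", "g3"], ["g1", "g2", "g3"])
        table = compare_to_reference([s], self.ref, self.layout)
        assert list(table["category"]) == ["exact"]

    def test_contained_in_operon(self):
        s = seg(0, ["g1", "g2"], ["g1", "g2"])
        table = compare_to_reference([s], self.ref, self.layout)
        assert list(table["category"]) == ["contained_in_operon"]

    def test_segment_spanning_two_operons_counts_once_as_overlap(self):
        s = seg(5, ["g6", "g7"], ["g6", "g7"])
        table = compare_to_reference([s], self.ref, self.layout)
        assert list(table["category"]) == ["overlap"]
        assert match_summary(table)["overlap"] == 1

    def test_contains_operon(self):
        s = seg(4, ["g5", "g6", "g7", "g8"], ["g5", "g6", "g7", "g8"])
        table = compare_to_reference([s], self.ref, self.layout)
        assert list(table["category"]) == ["contains_operon"]

    def test_unknown_id_rejected(self):
        s = seg(0, ["g1", "gX"], ["g1", "gX"])
        with pytest.raises(DataError, match="gX"):
            compare_to_reference([s], self.ref, self.layout)


class TestUniqueRegions:
    def test_overlapping_segments_collapse_transitively(self):
        a = seg(0, ["g1", "g2"], ["g1", "g2"])
        b = seg(1, ["g2", "g3"], ["g2", "g3"])
        c = seg(5, ["g6", "g7"], ["g6", "g7"])
        regions = sorted(unique_regions([a, b, c]), key=sorted)
        assert regions == [frozenset({"g1", "g2", "g3"}), frozenset({"g6", "g7"})]
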