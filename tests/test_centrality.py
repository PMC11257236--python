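import numpy as np
import pytest
from scipy.stats import spearmanr

from commdiff.graph import (
    Graph,
    Partition,
    community_profiles,
    modularity,
)
from commdiff.detection import map_equation_codelength
from commdiff.centrality import (
    MEASURES,
    community_based_centrality,
    community_based_mediator,
    community_hub_bridge,
    comm_centrality,
    compute_measure,
    degree_baseline,
    kshell_with_community,
    map_equation_centrality,
    modularity_vitality,
    participation_coefficient,
    rank,
)

from conftest import random_graph, random_partition
from oracles import core_numbers_by_pruning, edge_tally_profiles


def score_of(sv, graph, label):
    return sv.scores[graph.index[label]]


class TestDegreeBaseline:
    def test_star_center(self):
        g = Graph([("h", f"l{i}") for i in range(5)])
        assert score_of(degree_baseline(g), g, "h") == 5

    def test_triangle_symmetry_and_handshake(self, triangle):
        sv = degree_baseline(triangle)
        assert np.all(sv.scores == 2)
        assert sv.scores.sum() == 2 * triangle.M


class TestParticipationCoefficient:
    def test_all_internal_zero(self, two_triangles):
        g, p = two_triangles
        assert np.all(participation_coefficient(g, p).scores == 0)

    def test_even_split_half(self):
        g = Graph([("x", "a"), ("x", "b")])
        p = Partition(g, {"x": "A", "a": "A", "b": "B"})
        # x: k=2 split 1/1 across two communities -> 1 - 2*(1/2)^2 = 0.5
        assert score_of(participation_coefficient(g, p), g, "x") == pytest.approx(0.5)

    def test_hand_value_three_communities(self):
        # node m: k_by_comm {A:2, B:1, C:1}, k=4 -> 1 - (4+1+1)/16 = 0.625
        g = Graph([("m", "a1"), ("m", "a2"), ("m", "b"), ("m", "c"),
                   ("a1", "a2"), ("b", "c")])
        p = Partition(g, {"m": "A", "a1": "A", "a2": "A", "b": "B", "c": "C"})
        assert score_of(participation_coefficient(g, p), g, "m") == pytest.approx(0.625)

    def test_range_bound(self):
        rng = np.random.default_rng(2)
        g = random_graph(30, 0.3, rng)
        p = random_partition(g, 4, rng)
        scores = participation_coefficient(g, p).scores
        assert np.all(scores >= 0) and np.all(scores <= 1 - 1 / p.C + 1e-12)

    def test_isolated_node_rejected(self):
        g = Graph([("a", "b")], nodes=["z"])
        p = Partition(g, {"a": "x", "b": "x", "z": "x"})
        with pytest.raises(ValueError):
            participation_coefficient(g, p)


class TestCommunityBasedCentrality:
    def test_single_community_reduces_to_degree(self, triangle):
        p = Partition(triangle, {lab: "all" for lab in triangle.labels})
        sv = community_based_centrality(triangle, p)
        assert np.allclose(sv.scores, triangle.degrees)

    def test_hand_value(self):
        # N=7, sizes {A:3, B:4}; node with k_A=2, k_B=1 -> 2*3/7 + 1*4/7 = 10/7
        g = Graph([("a0", "a1"), ("a0", "a2"), ("a0", "b0"),
                   ("b0", "b1"), ("b1", "b2"), ("b2", "b3")])
        p = Partition(g, {"a0": "A", "a1": "A", "a2": "A",
                          "b0": "B", "b1": "B", "b2": "B", "b3": "B"})
        assert score_of(community_based_centrality(g, p), g, "a0") == pytest.approx(10 / 7)

    def test_degree_zero_node_scores_zero(self):
        g = Graph([("a", "b")], nodes=["z"])
        p = Partition(g, {"a": "x", "b": "x", "z": "x"})
        assert score_of(community_based_centrality(g, p), g, "z") == 0


class TestCommCentrality:
    def test_pure_community_top_intra_scores_r(self, two_triangles):
        g, p = two_triangles
        sv = comm_centrality(g, p, R=1.5)
        assert np.allclose(sv.scores, 1.5)  # all nodes are max-intra, no inter

    def test_automorphic_nodes_equal(self, bridged_triangles):
        g, p = bridged_triangles
        sv = comm_centrality(g, p)
        assert score_of(sv, g, "a") == pytest.approx(score_of(sv, g, "b"))
        assert score_of(sv, g, "c") == pytest.approx(score_of(sv, g, "d"))

    def test_adding_inter_edge_never_lowers_within_community_rank(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            g = random_graph(16, 0.25, rng)
            p = random_partition(g, 3, rng)
            assign = p.assignment
            # candidate inter-community non-edges
            existing = {tuple(sorted(e)) for e in g.edges()}
            cands = [
                (u, v)
                for i, u in enumerate(g.labels)
                for v in g.labels[i + 1:]
                if assign[u] != assign[v] and (u, v) not in existing
            ]
            if not cands:
                continue
            u, v = cands[rng.integers(len(cands))]
            before = comm_centrality(g, p)
            mates = [w for w in g.labels if assign[w] == assign[u] and w != u]
            rank_before = sum(
                score_of(before, g, w) > score_of(before, g, u) for w in mates
            )
            g2 = Graph(g.edges() + [(u, v)], nodes=g.labels)
            p2 = Partition(g2, assign)
            after = comm_centrality(g2, p2)
            rank_after = sum(
                score_of(after, g2, w) > score_of(after, g2, u) for w in mates
            )
            assert rank_after <= rank_before


class TestKShellWithCommunity:
    def test_two_disjoint_triangles(self, two_triangles):
        g, p = two_triangles
        sv = kshell_with_community(g, p, delta=0.5)
        # ks_intra = 2 everywhere, ks_inter = 0 -> 0.5*2 = 1.0
        assert np.allclose(sv.scores, 1.0)

    def test_delta_one_single_community_is_global_kshell(self):
        rng = np.random.default_rng(6)
        g = random_graph(25, 0.2, rng)
        p = Partition(g, {lab: "all" for lab in g.labels})
        sv = kshell_with_community(g, p, delta=1.0)
        oracle = core_numbers_by_pruning(g)
        for lab in g.labels:
            assert score_of(sv, g, lab) == oracle[lab]

    def test_intra_core_matches_pruning_oracle(self):
        rng = np.random.default_rng(8)
        g = random_graph(30, 0.2, rng)
        p = random_partition(g, 3, rng)
        assign = p.assignment
        intra_edges = [e for e in g.edges() if assign[e[0]] == assign[e[1]]]
        intra_graph = Graph(intra_edges, nodes=g.labels)
        oracle = core_numbers_by_pruning(intra_graph)
        sv = kshell_with_community(g, p, delta=1.0)
        for lab in g.labels:
            assert score_of(sv, g, lab) == oracle[lab]


class TestCommunityBasedMediator:
    def test_all_intra_zero(self, two_triangles):
        g, p = two_triangles
        assert np.all(community_based_mediator(g, p).scores == 0)

    def test_even_split_maximal_entropy(self, bridged_triangles):
        # build a node with k_intra = k_inter = 1: H = ln 2, CBM = ln2 * k/2M
        g = Graph([("a", "b"), ("a", "c"), ("b", "c"), ("c", "d")])
        p = Partition(g, {"a": "x", "b": "x", "c": "x", "d": "y"})
        sv = community_based_mediator(g, p)
        assert score_of(sv, g, "d") == 0.0  # all links inter... entropy 0
        # node c: intra 2, inter 1
        rho = np.array([2 / 3, 1 / 3])
        expect = -np.sum(rho * np.log(rho)) * 3 / (2 * g.M)
        assert score_of(sv, g, "c") == pytest.approx(expect)

    def test_hand_values_on_toy(self):
        g = Graph([("u", "v"), ("u", "w"), ("v", "w"), ("u", "x"), ("x", "y")])
        p = Partition(g, {"u": "A", "v": "A", "w": "A", "x": "B", "y": "B"})
        sv = community_based_mediator(g, p)
        # u: k=3, intra 2, inter 1
        rho = np.array([2 / 3, 1 / 3])
        h = -np.sum(rho * np.log(rho))
        assert score_of(sv, g, "u") == pytest.approx(h * 3 / 10)
        # x: k=2, intra 1, inter 1 -> H = ln 2
        assert score_of(sv, g, "x") == pytest.approx(np.log(2) * 2 / 10)


class TestCommunityHubBridge:
    def test_hand_value(self):
        # community A of size 5; node h with k_intra=3, k_inter=2 into two
        # distinct other communities -> 5*3 + 2*2 = 19
        edges = [("h", "a1"), ("h", "a2"), ("h", "a3"),
                 ("a1", "a4"), ("h", "b0"), ("h", "c0")]
        g = Graph(edges)
        p = Partition(g, {"h": "A", "a1": "A", "a2": "A", "a3": "A", "a4": "A",
                          "b0": "B", "c0": "C"})
        assert score_of(community_hub_bridge(g, p), g, "h") == 19

    def test_pure_internal_node(self, two_triangles):
        g, p = two_triangles
        sv = community_hub_bridge(g, p)
        assert np.all(sv.scores == 3 * 2)  # n_c * k_intra

    def test_nnc_matches_brute_force(self):
        rng = np.random.default_rng(10)
        g = random_graph(30, 0.15, rng)
        p = random_partition(g, 4, rng)
        prof = community_profiles(g, p)
        expected = edge_tally_profiles(g, p)
        for lab in g.labels:
            assert prof[lab].nnc == expected[lab][4]


class TestModularityVitality:
    def test_bridge_negative_interior_positive(self, bridged_triangles):
        g, p = bridged_triangles
        trio = modularity_vitality(g, p)
        v = trio["MV+"].scores
        for lab in ("c", "d"):
            assert v[g.index[lab]] < 0
        for lab in ("a", "b", "e", "f"):
            assert v[g.index[lab]] > 0

    def test_incremental_equals_full_recomputation(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            g = random_graph(20, 0.2, rng)
            if g.M < 2:
                continue
            p = random_partition(g, 3, rng)
            trio = modularity_vitality(g, p)
            q_full = modularity(g, p)
            for lab in g.labels:
                i = g.index[lab]
                sub = g.subgraph_without(i)
                if sub.M < 1:
                    continue
                subp = Partition(sub, {l: p.assignment[l] for l in sub.labels})
                brute = q_full - modularity(sub, subp)
                assert trio["MV+"].scores[i] == pytest.approx(brute, abs=1e-12)

    def test_variant_relationships(self, bridged_triangles):
        g, p = bridged_triangles
        trio = modularity_vitality(g, p)
        assert np.allclose(trio["MV-"].scores, -trio["MV+"].scores)
        assert np.allclose(trio["|MV|"].scores, np.abs(trio["MV+"].scores))
        top = rank(trio["|MV|"]).ordered[0]
        assert np.abs(trio["MV+"].scores[g.index[top]]) == pytest.approx(
            np.abs(trio["MV+"].scores).max()
        )


class TestMapEquationCentrality:
    def test_automorphic_nodes_equal(self, two_triangles):
        g, p = two_triangles
        sv = map_equation_centrality(g, p)
        assert np.allclose(sv.scores, sv.scores[0])

    def test_vitality_equals_two_full_evaluations(self, bridged_triangles):
        g, p = bridged_triangles
        sv = map_equation_centrality(g, p)
        l_full = map_equation_codelength(g, p).L
        for lab in g.labels:
            i = g.index[lab]
            sub = g.subgraph_without(i)
            subp = Partition(sub, {l: p.assignment[l] for l in sub.labels})
            brute = l_full - map_equation_codelength(sub, subp).L
            assert sv.scores[i] == pytest.approx(brute, abs=1e-9)

    def test_correlates_with_intra_degree_on_strong_communities(self, lfr_strong):
        g, p = lfr_strong
        prof = community_profiles(g, p)
        sv = map_equation_centrality(g, p, prof)
        assert spearmanr(sv.scores, prof.k_intra).statistic > 0


class TestRanking:
    def test_tie_broken_by_label(self):
        g = Graph([("a", "b"), ("b", "c")])
        from commdiff.centrality import ScoreVector
        sv = ScoreVector("x", g.labels, np.array([2.0, 2.0, 1.0]))
        assert rank(sv).ordered == ["a", "b", "c"]

    def test_all_equal_lexicographic(self):
        g = Graph([("b", "a"), ("c", "a")])
        sv = degree_baseline(g)
        sv.scores[:] = 1.0
        assert rank(sv).ordered == sorted(g.labels)

    def test_nan_rejected(self):
        g = Graph([("a", "b")])
        sv = degree_baseline(g)
        sv.scores[0] = np.nan
        with pytest.raises(ValueError):
            rank(sv)

    def test_file_order_irrelevant(self, tmp_path):
        lines = ["a b", "b c", "c d", "a d", "a c"]
        from commdiff.graph import read_edge_list
        f1, f2 = tmp_path / "g1.txt", tmp_path / "g2.txt"
        f1.write_text("\n".join(lines) + "\n")
        f2.write_text("\n".join(reversed(lines)) + "\n")
        g1, g2 = read_edge_list(f1), read_edge_list(f2)
        assert rank(degree_baseline(g1)).ordered == rank(degree_baseline(g2)).ordered


class TestAllMeasures:
    @pytest.mark.parametrize("measure", [m for m in MEASURES])
    def test_deterministic_and_finite(self, bridged_triangles, measure):
        g, p = bridged_triangles
        sv1 = compute_measure(measure, g, p)
        sv2 = compute_measure(measure, g, p)
        assert np.array_equal(sv1.scores, sv2.scores)
        assert np.all(np.isfinite(sv1.scores))

    @pytest.mark.parametrize("measure", [m for m in MEASURES])
    def test_automorphism_invariance(self, two_triangles, measure):
        # every node of the two-triangle graph is structurally equivalent
        g, p = two_triangles
        sv = compute_measure(measure, g, p)
        assert np.allclose(sv.scores, sv.scores[0])
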