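"""KR distance properties, oracles, LCAs and pairwise matrices."""

import numpy as np
import pytest
from scipy.optimize import linprog

from phylobin import (
    distance_to_node,
    kr_distance,
    lca_separation,
    pairwise_matrix,
    placement_lca,
    simulate_tree,
    to_mass,
)
from phylobin.errors import UsageError
from phylobin.treegraph import TreePoint

from conftest import make_record, point_mass, random_mass


def transport_oracle(tree, P, Q):
    """Brute-force minimum-cost transport over the point-to-point matrix."""
    n, m = len(P.points), len(Q.points)
    cost = np.array(
        [[tree.path_distance(p, q) for q in Q.points] for p in P.points]
    ).ravel()
    a_eq = []
    for i in range(n):  # row sums = P weights
        row = np.zeros(n * m)
        row[i * m : (i + 1) * m] = 1
        a_eq.append(row)
    for j in range(m):  # col sums = Q weights
        col = np.zeros(n * m)
        col[j::m] = 1
        a_eq.append(col)
    b_eq = np.concatenate([P.weights, Q.weights])
    res = linprog(cost, A_eq=np.array(a_eq), b_eq=b_eq, bounds=(0, None), method="highs")
    assert res.success
    return res.fun


class TestKRExamples:
    def test_point_masses_equal_path_distance(self, toy_tree):
        P, Q = point_mass(toy_tree, 0), point_mass(toy_tree, 1)
        assert kr_distance(toy_tree, P, Q) == pytest.approx(0.3, abs=1e-12)

    def test_identity(self, toy_tree):
        rng = np.random.default_rng(0)
        for _ in range(10):
            P = random_mass(toy_tree, rng)
            assert kr_distance(toy_tree, P, P) == 0.0

    def test_half_split_transport(self, toy_tree):
        from phylobin import MassDistribution

        P = point_mass(toy_tree, 0)
        Q = MassDistribution(
            (TreePoint(0, 0.0), TreePoint(1, 0.0)), np.array([0.5, 0.5])
        )
        assert kr_distance(toy_tree, P, Q) == pytest.approx(0.15, abs=1e-12)

    def test_exponent_below_one_rejected(self, toy_tree):
        with pytest.raises(UsageError):
            kr_distance(toy_tree, point_mass(toy_tree, 0), point_mass(toy_tree, 1), exponent=0.5)


class TestKRProperties:
    def test_point_mass_degenerates_to_path_distance(self):
        tree = simulate_tree(60, seed=4)
        rng = np.random.default_rng(4)
        edges = [e for e, v in tree.edge_to_node.items() if v != tree.root]
        for _ in range(100):
            pts = []
            for _ in range(2):
                e = int(rng.choice(edges))
                bl = float(tree.branch_length[tree.node_of_edge(e)])
                pts.append(TreePoint(e, float(rng.uniform(0, bl))))
            P, Q = (point_mass(tree, p.edge_number, p.offset) for p in pts)
            assert kr_distance(tree, P, Q) == pytest.approx(
                tree.path_distance(*pts), abs=1e-9
            )

    def test_matches_lp_transport_oracle(self):
        tree = simulate_tree(40, seed=9)
        rng = np.random.default_rng(9)
        for _ in range(40):
            P = random_mass(tree, rng, max_points=6)
            Q = random_mass(tree, rng, max_points=6)
            assert kr_distance(tree, P, Q) == pytest.approx(
                transport_oracle(tree, P, Q), abs=1e-8
            )

    def test_symmetry_and_triangle(self):
        tree = simulate_tree(50, seed=12)
        rng = np.random.default_rng(12)
        dists = [random_mass(tree, rng) for _ in range(12)]
        for i in range(len(dists)):
            for j in range(i + 1, len(dists)):
                assert kr_distance(tree, dists[i], dists[j]) == kr_distance(
                    tree, dists[j], dists[i]
                )
        for _ in range(100):
            a, b, c = rng.choice(len(dists), size=3, replace=False)
            dab = kr_distance(tree, dists[a], dists[b])
            dbc = kr_distance(tree, dists[b], dists[c])
            dac = kr_distance(tree, dists[a], dists[c])
            assert dac <= dab + dbc + 1e-9

    def test_root_independence(self):
        tree = simulate_tree(40, seed=21)
        rng = np.random.default_rng(21)
        pairs = [(random_mass(tree, rng), random_mass(tree, rng)) for _ in range(10)]
        internal = [v for v in range(tree.n_nodes) if tree.children[v]]
        for _ in range(5):
            new_root = int(rng.choice(internal))
            rerooted, flipped = tree.reroot(new_root, with_flips=True)
            for P, Q in pairs:
                P2, Q2 = (_remap(rerooted, flipped, X) for X in (P, Q))
                d0 = kr_distance(tree, P, Q)
                d1 = kr_distance(rerooted, P2, Q2)
                assert d1 == pytest.approx(d0, abs=1e-9)

    def test_pendant_mode_adds_weighted_pendants(self, toy_tree):
        a = make_record("a", [(0, 1.0, 0.0, 0.03)])
        b = make_record("b", [(1, 1.0, 0.0, 0.05)])
        ma, mb = to_mass(a, toy_tree), to_mass(b, toy_tree)
        assert kr_distance(toy_tree, ma, mb, include_pendant=True) == pytest.approx(
            0.3 + 0.03 + 0.05
        )
        assert kr_distance(toy_tree, ma, ma, include_pendant=True) == 0.0


def _remap(rerooted, flipped, mass):
    from phylobin import MassDistribution

    pts = []
    for p in mass.points:
        bl = float(rerooted.branch_length[rerooted.node_of_edge(p.edge_number)])
        off = bl - p.offset if p.edge_number in flipped else p.offset
        pts.append(TreePoint(p.edge_number, off))
    return MassDistribution(tuple(pts), mass.weights.copy())


class TestPlacementLCA:
    def test_rows_within_cherry(self, toy_tree):
        rec = make_record("r", [(0, 0.6), (1, 0.4)])
        assert placement_lca(toy_tree, [rec]) == toy_tree.node_of_edge(2)

    def test_spanning_clades_gives_root(self, toy_tree):
        recs = [make_record("r1", [(0, 1.0)]), make_record("r2", [(3, 1.0)])]
        assert placement_lca(toy_tree, recs) == toy_tree.root

    def test_single_edge_gives_distal_node(self, toy_tree):
        rec = make_record("r", [(0, 1.0)])
        assert placement_lca(toy_tree, [rec]) == toy_tree.name_to_leaf["A"]

    def test_separation_between_cherries(self, toy_tree):
        ga = [make_record("a", [(0, 0.5), (1, 0.5)])]
        gb = [make_record("b", [(3, 0.5), (4, 0.5)])]
        assert lca_separation(toy_tree, ga, gb) == pytest.approx(0.9, abs=1e-12)
        assert lca_separation(toy_tree, ga, ga) == 0.0

    def test_nested_separation(self, toy_tree):
        ga = [make_record("a", [(0, 0.5), (1, 0.5)])]  # LCA at A/B parent
        gb = [make_record("b", [(0, 0.5), (3, 0.5)])]  # LCA at root
        assert lca_separation(toy_tree, ga, gb) == pytest.approx(0.3, abs=1e-12)


class TestDistanceToNode:
    def test_point_on_target_is_zero(self, toy_tree):
        a = toy_tree.name_to_leaf["A"]
        assert distance_to_node(toy_tree, point_mass(toy_tree, 0), a) == 0.0

    def test_point_to_root(self, toy_tree):
        assert distance_to_node(toy_tree, point_mass(toy_tree, 0), toy_tree.root) == pytest.approx(0.4)

    def test_weighted_mean_identity(self, toy_tree):
        from phylobin import MassDistribution

        M = MassDistribution((TreePoint(0, 0.0), TreePoint(1, 0.0)), np.array([0.5, 0.5]))
        node = toy_tree.node_of_edge(2)
        assert distance_to_node(toy_tree, M, node) == pytest.approx(0.15, abs=1e-12)

    def test_matches_kr_to_point_mass(self):
        tree = simulate_tree(30, seed=3)
        rng = np.random.default_rng(3)
        for _ in range(30):
            P = random_mass(tree, rng)
            node = int(rng.integers(tree.n_nodes))
            want = kr_distance(tree, P, _node_mass(tree, node))
            assert distance_to_node(tree, P, node) == pytest.approx(want, abs=1e-9)

    def test_unknown_node_rejected(self, toy_tree):
        with pytest.raises(KeyError):
            distance_to_node(toy_tree, point_mass(toy_tree, 0), 999)


def _node_mass(tree, node):
    from phylobin import MassDistribution

    return MassDistribution((tree.node_point(node),), np.array([1.0]))


class TestPairwiseMatrix:
    def test_single_record(self, toy_tree):
        m = pairwise_matrix(toy_tree, [make_record("a", [(0, 1.0)])])
        assert m.shape == (1, 1) and m.iloc[0, 0] == 0.0

    def test_two_point_masses(self, toy_tree):
        m = pairwise_matrix(
            toy_tree,
            [make_record("a", [(0, 1.0)]), make_record("b", [(1, 1.0)])],
        )
        assert m.loc["a", "b"] == pytest.approx(0.3, abs=1e-12)

    def test_symmetric_zero_diagonal(self, toy_tree):
        rng = np.random.default_rng(7)
        from conftest import random_pset

        pset = random_pset(toy_tree, rng, 8)
        m = pairwise_matrix(toy_tree, list(pset.records.values()))
        arr = m.to_numpy()
        assert np.allclose(arr, arr.T, atol=1e-12)
        assert np.all(np.diag(arr) == 0)
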