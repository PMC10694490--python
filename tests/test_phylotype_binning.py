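"""Pre-grouping, LCA merging, clustering, naming, and the brute-force oracle."""

import pytest
from sklearn.metrics import adjusted_rand_score

from phylobin import (
    PlacementSet,
    bin_phylotypes,
    brute_force_bin,
    cluster_group,
    merge_pregroups,
    name_phylotypes,
    pregroup,
    simulate_placements,
    simulate_tree,
)
from phylobin.errors import UsageError
from phylobin.phylotype_binning import PhylotypeModel, _make_pregroup

from conftest import make_record


def pset_of(tree, recs):
    pset = PlacementSet(tree=tree, records={r.asv_id: r for r in recs})
    pset.validate()
    return pset


class TestPregroup:
    def test_shared_edge_joins(self, toy_tree):
        pset = pset_of(
            toy_tree,
            [
                make_record("r1", [(0, 1.0)]),
                make_record("r2", [(0, 0.5), (1, 0.5)]),
                make_record("r3", [(3, 1.0)]),
            ],
        )
        groups = pregroup(pset)
        assert sorted(sorted(g.members) for g in groups) == [["r1", "r2"], ["r3"]]

    def test_disjoint_edges_give_singletons(self, toy_tree):
        pset = pset_of(
            toy_tree,
            [make_record(f"r{i}", [(e, 1.0)]) for i, e in enumerate([0, 1, 3, 4])],
        )
        assert all(len(g.members) == 1 for g in pregroup(pset))

    def test_transitive_chain(self, toy_tree):
        pset = pset_of(
            toy_tree,
            [
                make_record("r1", [(0, 0.5), (1, 0.5)]),
                make_record("r2", [(1, 0.5), (2, 0.5)]),
                make_record("r3", [(2, 0.5), (5, 0.5)]),
            ],
        )
        groups = pregroup(pset)
        assert len(groups) == 1 and groups[0].members == {"r1", "r2", "r3"}

    def test_group_metadata(self, toy_tree):
        pset = pset_of(toy_tree, [make_record("r1", [(0, 0.5), (1, 0.5)])])
        (g,) = pregroup(pset)
        assert g.mass_edges == {0, 1}
        assert g.lca_node == toy_tree.node_of_edge(2)


class TestMergePregroups:
    def _two_cherry_groups(self, toy_tree):
        ga = _make_pregroup(toy_tree, [make_record("a", [(0, 0.5), (1, 0.5)])])
        gb = _make_pregroup(toy_tree, [make_record("b", [(3, 0.5), (4, 0.5)])])
        return [ga, gb]

    def test_far_groups_unchanged(self, toy_tree):
        groups = self._two_cherry_groups(toy_tree)
        # LCA separation 0.9 >= 0.1: no merge
        assert len(merge_pregroups(toy_tree, groups, 0.1)) == 2

    def test_close_groups_merge(self, toy_tree):
        groups = self._two_cherry_groups(toy_tree)
        merged = merge_pregroups(toy_tree, groups, 1.0)  # 0.9 < 1.0
        assert len(merged) == 1
        assert merged[0].members == {"a", "b"}
        assert merged[0].lca_node == toy_tree.root

    def test_single_group_unchanged(self, toy_tree):
        groups = self._two_cherry_groups(toy_tree)[:1]
        assert merge_pregroups(toy_tree, groups, 0.5) == groups


class TestClusterGroup:
    def test_singleton(self, toy_tree):
        pset = pset_of(toy_tree, [make_record("a", [(0, 1.0)])])
        (g,) = pregroup(pset)
        assert cluster_group(toy_tree, g, pset, 0.5) == [["a"]]

    @pytest.mark.parametrize(
        "threshold,expected", [(0.5, [["a", "b"]]), (0.1, [["a"], ["b"]])]
    )
    def test_threshold_cuts_pair(self, toy_tree, threshold, expected):
        # point masses at A and B: KR distance 0.3
        pset = pset_of(
            toy_tree, [make_record("a", [(0, 1.0)]), make_record("b", [(1, 1.0)])]
        )
        g = _make_pregroup(toy_tree, list(pset.records.values()))
        assert cluster_group(toy_tree, g, pset, threshold) == expected


class TestBinPhylotypes:
    def test_two_separated_alleles_recovered(self):
        tree = simulate_tree(60, seed=30, branch_scale=0.2)
        pset, truth = simulate_placements(
            tree, 2, dispersion=0.005, min_separation=0.9, seed=31
        )
        model = bin_phylotypes(pset, 0.1)
        assert len(model.phylotypes) == 2
        for members in model.phylotypes.values():
            assert len({truth.origin[a][0] for a in members}) == 1

    def test_huge_threshold_single_phylotype(self, toy_tree):
        pset = pset_of(
            toy_tree, [make_record("a", [(0, 1.0)]), make_record("b", [(3, 1.0)])]
        )
        model = bin_phylotypes(pset, 9.9)
        assert len(model.phylotypes) == 1

    def test_single_record(self, toy_tree):
        pset = pset_of(toy_tree, [make_record("a", [(0, 1.0)])])
        model = bin_phylotypes(pset, 0.1)
        assert list(model.phylotypes.values()) == [["a"]]

    def test_partition_property(self):
        tree = simulate_tree(80, seed=40)
        pset, _ = simulate_placements(tree, 15, dispersion=0.02, min_separation=0.3, seed=41)
        model = bin_phylotypes(pset, 0.1)
        all_members = [a for m in model.phylotypes.values() for a in m]
        assert sorted(all_members) == sorted(pset.records)
        assert all(model.phylotypes.values())

    def test_threshold_monotonicity_single_linkage(self):
        tree = simulate_tree(80, seed=50)
        pset, _ = simulate_placements(tree, 15, dispersion=0.02, min_separation=0.3, seed=51)
        counts = [
            len(bin_phylotypes(pset, t).phylotypes)
            for t in (0.01, 0.05, 0.1, 0.3, 0.5, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_determinism_byte_identical(self):
        tree = simulate_tree(50, seed=60)
        pset, _ = simulate_placements(tree, 8, dispersion=0.01, min_separation=0.3, seed=61)
        a = bin_phylotypes(pset, 0.1).to_json()
        b = bin_phylotypes(pset, 0.1).to_json()
        assert a == b

    def test_model_round_trip(self):
        tree = simulate_tree(50, seed=70)
        pset, _ = simulate_placements(tree, 5, dispersion=0.01, min_separation=0.3, seed=71)
        model = bin_phylotypes(pset, 0.5)
        again = PhylotypeModel.from_json(model.to_json())
        assert again == model


class TestBruteForceOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_divide_and_conquer_matches(self, seed):
        tree = simulate_tree(100, seed=seed)
        pset, _ = simulate_placements(
            tree, 20, dispersion=0.005, min_separation=0.3, seed=seed + 500
        )
        thr = 0.1
        m1 = bin_phylotypes(pset, thr)
        m2 = brute_force_bin(pset, thr)
        ids = sorted(pset.records)
        ari = adjusted_rand_score(
            [m1.asv_to_phylotype[a] for a in ids],
            [m2.asv_to_phylotype[a] for a in ids],
        )
        assert ari == 1.0
        assert m1.phylotypes == m2.phylotypes

    def test_cross_group_distances_bounded_below(self):
        """Records in disjoint clades are at least their LCA separation apart.

        The containment LCA (the one the merge step uses) is the deepest
        node whose subtree holds the group's mass, so every cross-pair path
        passes through both LCAs — the bound that justifies skipping
        cross-group distance computations.
        """
        from phylobin import kr_distance, placement_lca, to_mass

        dispersion = 0.005
        tree = simulate_tree(80, seed=3)
        pset, truth = simulate_placements(
            tree, 10, dispersion=dispersion, min_separation=0.4, seed=4
        )
        by_allele = {}
        for asv, (allele, _) in truth.origin.items():
            by_allele.setdefault(allele, []).append(pset.records[asv])
        alleles = sorted(by_allele)
        checked = 0
        for i in range(len(alleles)):
            for j in range(i + 1, len(alleles)):
                ga, gb = by_allele[alleles[i]], by_allele[alleles[j]]
                la = placement_lca(tree, ga, containment=True)
                lb = placement_lca(tree, gb, containment=True)
                sep = tree.node_distance(la, lb)
                # bound applies to disjoint (non-nested) clades
                if tree.lca([la, lb]) in (la, lb):
                    continue
                dmin = min(
                    kr_distance(tree, to_mass(a, tree), to_mass(b, tree))
                    for a in ga
                    for b in gb
                )
                assert dmin >= sep - 1e-9
                checked += 1
        assert checked > 10

    def test_size_guard(self, toy_tree):
        recs = {f"r{i}": make_record(f"r{i}", [(0, 1.0)]) for i in range(3)}
        pset = PlacementSet(tree=toy_tree, records=recs)
        import phylobin.phylotype_binning as pbn

        old = pbn.BRUTE_FORCE_MAX
        pbn.BRUTE_FORCE_MAX = 2
        try:
            with pytest.raises(UsageError, match="force"):
                brute_force_bin(pset, 0.1)
            brute_force_bin(pset, 0.1, force=True)
        finally:
            pbn.BRUTE_FORCE_MAX = old


def placement_lca_nodes(tree, records):
    from phylobin import placement_lca

    return placement_lca(tree, records)


class TestNaming:
    def test_threshold_codes(self):
        part = [["a"], ["b", "c"]]
        assert list(name_phylotypes(part, 0.5)) == ["pt05__00001", "pt05__00002"]
        assert list(name_phylotypes(part, 0.1))[0].startswith("pt01__")
        assert list(name_phylotypes(part, 1.0))[0].startswith("pt10__")

    def test_abundance_ordering_with_counts(self):
        part = [["a"], ["b", "c"]]
        named = name_phylotypes(part, 0.1, counts={"a": 100, "b": 5, "c": 5})
        assert named["pt01__00001"] == ["a"]

    def test_member_count_ordering_without_counts(self):
        named = name_phylotypes([["z"], ["a", "b"]], 0.1)
        assert named["pt01__00001"] == ["a", "b"]

    def test_tie_break_lexicographic(self):
        named = name_phylotypes([["m"], ["k"]], 0.1)
        assert named["pt01__00001"] == ["k"]

    def test_threshold_overflow(self):
        with pytest.raises(UsageError, match="2-digit"):
            name_phylotypes([["a"]], 10.0)
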