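"""Shared fixtures and random-instance builders for the test suite."""

import numpy as np
import pytest

from phylobin import (
    MassDistribution,
    PhyloTree,
    PlacementRecord,
    PlacementRow,
    PlacementSet,
    parse_edge_numbered_newick,
)
from phylobin.treegraph import TreePoint

#: four-leaf tree used throughout: A/B under edge {2}, C/D under edge {5}
TOY_NEWICK = "((A:0.1{0},B:0.2{1}):0.3{2},(C:0.4{3},D:0.5{4}):0.6{5}):0{6};"


@pytest.fixture
def toy_tree() -> PhyloTree:
    return parse_edge_numbered_newick(TOY_NEWICK)


def point_mass(tree: PhyloTree, edge: int, offset: float = 0.0) -> MassDistribution:
    return MassDistribution((TreePoint(edge, offset),), np.array([1.0]))


def make_record(asv_id: str, rows, multiplicity: float = 1.0) -> PlacementRecord:
    """rows: iterable of (edge_num, lwr) or (edge_num, lwr, distal, pendant)."""
    full = []
    for r in rows:
        e, lwr, distal, pendant = (tuple(r) + (0.0, 0.0))[:4]
        full.append(PlacementRow(int(e), -100.0, float(lwr), float(distal), float(pendant)))
    return PlacementRecord(asv_id, tuple(full), multiplicity)


def random_mass(tree: PhyloTree, rng: np.random.Generator, max_points: int = 4) -> MassDistribution:
    """Random distribution on 1..max_points non-root edges of the tree."""
    edges = [e for e, v in tree.edge_to_node.items() if v != tree.root]
    k = int(rng.integers(1, max_points + 1))
    chosen = rng.choice(len(edges), size=k, replace=False)
    pts = []
    for i in chosen:
        e = edges[int(i)]
        bl = float(tree.branch_length[tree.node_of_edge(e)])
        pts.append(TreePoint(e, float(rng.uniform(0, bl))))
    w = rng.dirichlet(np.ones(k))
    return MassDistribution(tuple(pts), w)


def mass_to_record(asv_id: str, mass: MassDistribution) -> PlacementRecord:
    rows = tuple(
        PlacementRow(p.edge_number, -100.0, float(w), p.offset, 0.0)
        for p, w in zip(mass.points, mass.weights)
    )
    return PlacementRecord(asv_id, rows)


def random_pset(tree: PhyloTree, rng: np.random.Generator, n_records: int) -> PlacementSet:
    records = {}
    for i in range(n_records):
        asv = f"asv{i:04d}"
        records[asv] = mass_to_record(asv, random_mass(tree, rng))
    pset = PlacementSet(tree=tree, records=records)
    pset.validate()
    return pset
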