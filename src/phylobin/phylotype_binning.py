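"""Divide-and-conquer binning of placed ASVs into phylotypes.

A *phylotype* is a taxonomy-independent bin of ASVs whose placements lie
within a chosen phylogenetic distance of each other on a common reference
tree.  Exhaustive O(n²) pairwise KR distances are intractable for the
hundreds of thousands of ASVs a meta-analysis accumulates, so binning
proceeds in three stages:

1. **Pre-group** — union ASVs that share at least one mass-bearing placement
   edge (connected components of the shared-edge graph).
2. **Merge** — union pre-groups whose placement LCAs are closer together than
   the clustering threshold; any cross-pair that could fall under the
   threshold is thereby kept inside one group.
3. **Cluster** — within each merged group only, compute the full pairwise KR
   matrix and cut an agglomerative clustering at the threshold.

Phylotypes are named ``pt<code>__<index>`` where ``code`` is the threshold
×10, zero-padded to two digits (0.1 → ``pt01``, 0.5 → ``pt05``, 1.0 →
``pt10``) and ``index`` is a five-digit rank, most abundant phylotype first.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .errors import ConsistencyError, UsageError
from .jplace_io import PlacementRecord, PlacementSet
from .placement_metric import pairwise_matrix, placement_lca
from .treegraph import PhyloTree

__all__ = [
    "PreGroup",
    "PhylotypeModel",
    "pregroup",
    "merge_pregroups",
    "cluster_group",
    "bin_phylotypes",
    "brute_force_bin",
    "name_phylotypes",
]

logger = logging.getLogger(__name__)

LINKAGES = ("single", "average", "complete")

#: brute-force guard — refuse larger inputs unless forced
BRUTE_FORCE_MAX = 5000

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class PreGroup:
    """Connected component of ASVs sharing mass-bearing edges."""

    members: frozenset[str]
    mass_edges: frozenset[int]
    lca_node: int


@dataclass
class PhylotypeModel:
    """A fitted binning: thresholds, membership, per-phylotype LCA."""

    threshold: float
    linkage: str
    tree_digest: str
    phylotypes: dict[str, list[str]]  # name -> sorted member ASV ids
    phylotype_lca: dict[str, int]

    @property
    def asv_to_phylotype(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for name, members in self.phylotypes.items():
            for a in members:
                if a in out:
                    raise ConsistencyError(f"ASV {a!r} in two phylotypes")
                out[a] = name
        return out

    def to_json(self) -> str:
        doc = {
            "format_version": MODEL_FORMAT_VERSION,
            "threshold": self.threshold,
            "linkage": self.linkage,
            "tree_digest": self.tree_digest,
            "phylotypes": self.phylotypes,
            "phylotype_lca": self.phylotype_lca,
        }
        return json.dumps(doc, indent=1)

    def save(self, path: str | os.PathLike) -> None:
        tmp = f"{path}.tmp.{os.getpid()}"
        with open(tmp, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())
        os.replace(tmp, path)

    @classmethod
    def from_json(cls, text: str) -> "PhylotypeModel":
        doc = json.loads(text)
        return cls(
            threshold=float(doc["threshold"]),
            linkage=str(doc["linkage"]),
            tree_digest=str(doc["tree_digest"]),
            phylotypes={k: list(v) for k, v in doc["phylotypes"].items()},
            phylotype_lca={k: int(v) for k, v in doc["phylotype_lca"].items()},
        )

    @classmethod
    def load(cls, path: str | os.PathLike) -> "PhylotypeModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json(fh.read())


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def groups(self) -> list[list]:
        out: dict = {}
        for x in self.parent:
            out.setdefault(self.find(x), []).append(x)
        return [sorted(v) for v in sorted(out.values(), key=min)]


def _make_pregroup(tree: PhyloTree, records: Sequence[PlacementRecord]) -> PreGroup:
    # containment LCA: the merge bound needs every group's mass confined to
    # its LCA's subtree (a row part-way up an edge sits above the distal node)
    edges = frozenset(e for r in records for e in r.edges)
    return PreGroup(
        members=frozenset(r.asv_id for r in records),
        mass_edges=edges,
        lca_node=placement_lca(tree, records, containment=True),
    )


def pregroup(pset: PlacementSet) -> list[PreGroup]:
    """Connected components of the "shares a mass-bearing edge" relation."""
    if not pset.records:
        raise UsageError("pregroup of an empty placement set")
    uf = _UnionFind(pset.records)
    by_edge: dict[int, str] = {}
    for asv, rec in pset.records.items():
        for e in rec.edges:
            if e in by_edge:
                uf.union(asv, by_edge[e])
            else:
                by_edge[e] = asv
    return [
        _make_pregroup(pset.tree, [pset.records[a] for a in grp])
        for grp in uf.groups()
    ]


def merge_pregroups(
    tree: PhyloTree,
    groups: Sequence[PreGroup],
    threshold: float,
    pset: "PlacementSet | None" = None,
) -> list[PreGroup]:
    """Union pre-groups whose LCA separation is strictly below threshold.

    Merging is transitive (union-find); merged groups get a fresh LCA.
    For *disjoint* clades the LCA separation lower-bounds every cross-pair
    distance, so staying apart is sound.  When one LCA is ancestral to the
    other that bound is invalid (the ancestor group's mass may lie right
    next to the descendant clade); given ``pset``, such nested pairs fall
    back to the exact minimum cross-pair KR distance (early exit on the
    first pair under threshold).  Without ``pset`` nesting is only logged.
    """
    if threshold <= 0:
        raise UsageError("threshold must be positive")
    groups = list(groups)
    profiles: dict[str, object] = {}

    def _min_cross_below(a: PreGroup, b: PreGroup) -> bool:
        from .jplace_io import to_mass
        from .placement_metric import _kr_profiles, _profile

        for asv in sorted(a.members | b.members):
            if asv not in profiles:
                profiles[asv] = _profile(tree, to_mass(pset.records[asv], tree))
        for x in sorted(a.members):
            for y in sorted(b.members):
                if _kr_profiles(tree, profiles[x], profiles[y], 1.0) < threshold:
                    return True
        return False

    uf = _UnionFind(range(len(groups)))
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            la, lb = groups[i].lca_node, groups[j].lca_node
            sep = tree.node_distance(la, lb)
            if sep < threshold:
                uf.union(i, j)
            elif tree.lca([la, lb]) in (la, lb):
                if pset is not None:
                    if _min_cross_below(groups[i], groups[j]):
                        uf.union(i, j)
                else:
                    logger.info(
                        "pre-groups with nested LCAs (nodes %d, %d) left "
                        "unmerged; divide-and-conquer may deviate from brute "
                        "force here",
                        la,
                        lb,
                    )
    merged: dict[int, list[int]] = {}
    for i in range(len(groups)):
        merged.setdefault(uf.find(i), []).append(i)
    out = []
    for idxs in sorted(merged.values(), key=lambda ix: min(min(groups[i].members) for i in ix)):
        if len(idxs) == 1:
            out.append(groups[idxs[0]])
        else:
            members = sorted(set().union(*(groups[i].members for i in idxs)))
            edges = frozenset().union(*(groups[i].mass_edges for i in idxs))
            out.append(
                PreGroup(
                    members=frozenset(members),
                    mass_edges=edges,
                    lca_node=tree.lca([groups[i].lca_node for i in idxs]),
                )
            )
    return out


def _cut_linkage(dmat: np.ndarray, ids: list[str], threshold: float, linkage: str) -> list[list[str]]:
    """Flat clusters merging while linkage distance < threshold (strict)."""
    n = len(ids)
    if n == 1:
        return [list(ids)]
    Z = scipy_linkage(squareform(dmat, checks=False), method=linkage)
    uf = _UnionFind(range(n))
    reps = {i: i for i in range(n)}  # cluster id -> any member
    next_id = n
    for a, b, dist, _ in Z:
        ia, ib = reps[int(a)], reps[int(b)]
        if dist < threshold:
            uf.union(ia, ib)
        reps[next_id] = ia
        next_id += 1
    clusters: dict[int, list[str]] = {}
    for i in range(n):
        clusters.setdefault(uf.find(i), []).append(ids[i])
    return [sorted(v) for v in sorted(clusters.values(), key=min)]


def cluster_group(
    tree: PhyloTree,
    group: PreGroup,
    pset: PlacementSet,
    threshold: float,
    linkage: str = "single",
    **metric_kw,
) -> list[list[str]]:
    """Agglomerative clustering of one (merged) pre-group at the threshold."""
    if linkage not in LINKAGES:
        raise UsageError(f"linkage must be one of {LINKAGES}")
    if threshold <= 0:
        raise UsageError("threshold must be positive")
    ids = sorted(group.members)
    if len(ids) == 1:
        return [ids]
    recs = [pset.records[a] for a in ids]
    dmat = pairwise_matrix(tree, recs, **metric_kw).to_numpy()
    return _cut_linkage(dmat, ids, threshold, linkage)


def name_phylotypes(
    partition: Sequence[Sequence[str]],
    threshold: float,
    counts: "Mapping[str, float] | None" = None,
    start_index: int = 1,
) -> dict[str, list[str]]:
    """Name a partition ``pt<code>__<index>``; most abundant first.

    ``counts`` maps ASV id → total reads; without it, member count ranks the
    phylotypes.  Ties break on the lexicographically smallest member id.
    """
    if not partition:
        raise UsageError("cannot name an empty partition")
    if threshold >= 10:
        raise UsageError("threshold >= 10 overflows the 2-digit name code")
    code = int(round(threshold * 10))

    def weight(members) -> float:
        if counts is None:
            return float(len(members))
        return float(sum(counts.get(a, 0.0) for a in members))

    ordered = sorted(
        (sorted(members) for members in partition),
        key=lambda m: (-weight(m), m[0]),
    )
    out: dict[str, list[str]] = {}
    for i, members in enumerate(ordered, start=start_index):
        out[f"pt{code:02d}__{i:05d}"] = members
    return out


def _finalize_model(
    pset: PlacementSet,
    partition: Sequence[Sequence[str]],
    threshold: float,
    linkage: str,
    counts=None,
) -> PhylotypeModel:
    named = name_phylotypes(partition, threshold, counts=counts)
    lcas = {
        name: placement_lca(pset.tree, [pset.records[a] for a in members])
        for name, members in named.items()
    }
    return PhylotypeModel(
        threshold=float(threshold),
        linkage=linkage,
        tree_digest=pset.tree.digest(),
        phylotypes=named,
        phylotype_lca=lcas,
    )


def bin_phylotypes(
    pset: PlacementSet,
    threshold: float,
    linkage: str = "single",
    counts: "Mapping[str, float] | None" = None,
    **metric_kw,
) -> PhylotypeModel:
    """Full divide-and-conquer binning: pre-group → merge → cluster → name."""
    if not pset.records:
        raise UsageError("cannot bin an empty placement set")
    groups = merge_pregroups(pset.tree, pregroup(pset), threshold, pset=pset)
    partition: list[list[str]] = []
    for g in groups:
        partition.extend(cluster_group(pset.tree, g, pset, threshold, linkage, **metric_kw))
    return _finalize_model(pset, partition, threshold, linkage, counts)


def brute_force_bin(
    pset: PlacementSet,
    threshold: float,
    linkage: str = "single",
    counts: "Mapping[str, float] | None" = None,
    force: bool = False,
    **metric_kw,
) -> PhylotypeModel:
    """Exhaustive O(n²) binning over *all* records — the verification oracle
    the divide-and-conquer stage is checked against on small inputs."""
    if not pset.records:
        raise UsageError("cannot bin an empty placement set")
    if len(pset.records) > BRUTE_FORCE_MAX and not force:
        raise UsageError(
            f"brute_force_bin refuses n > {BRUTE_FORCE_MAX} (pass force=True)"
        )
    ids = sorted(pset.records)
    recs = [pset.records[a] for a in ids]
    dmat = pairwise_matrix(pset.tree, recs, **metric_kw).to_numpy()
    partition = _cut_linkage(dmat, ids, threshold, linkage)
    return _finalize_model(pset, partition, threshold, linkage, counts)
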