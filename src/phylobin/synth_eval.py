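"""Synthetic placements with known allele of origin, plus accuracy metrics.

Real validation of phylotype binning needs amplicons whose source organism
is known.  This module emulates that design *geometrically*: instead of
simulating sequences and running a placement engine, it draws a random
reference tree, picks well-separated "source allele" leaves, and for each
(allele, primer) pair emits one ASV whose placement mass lies within a
controlled dispersion of the source leaf.  The same-allele multi-primer
amplicons of real data place to the same small subclade; the ``dispersion``
parameter (default on the order of 0.005–0.02 substitutions/site) controls
how tight that subclade is.  Read-count tables mimic gut-like rank-abundance
structure (log-normal allele abundances, multinomial sampling at a fixed
read depth; 5,000–50,000 reads/specimen are the realistic platform depths).

Two accuracy metrics summarize a binning against the truth map: mean
*alleles-per-phylotype* (lumping; ideal 1) and mean *phylotypes-per-allele*
(splitting; ideal 1).  A rarefaction helper measures feature granularity as
a function of read depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConsistencyError, GenerationError, UsageError
from .jplace_io import PlacementRecord, PlacementRow, PlacementSet
from .count_tables import CountTable
from .treegraph import PhyloTree, TreePoint

__all__ = [
    "TruthMap",
    "simulate_tree",
    "simulate_placements",
    "simulate_counts",
    "alleles_per_phylotype",
    "phylotypes_per_allele",
    "rarefaction_curve",
]

logger = logging.getLogger(__name__)

#: the five variable-region primer sets emulated by default
DEFAULT_PRIMERS = ("27fmod-338r", "U515f-806r", "27f-357r", "357f-926r", "968f-1492r")


@dataclass
class TruthMap:
    """asv_id → (source allele leaf name, primer label)."""

    origin: dict[str, tuple[str, str]]

    def alleles(self) -> list[str]:
        return sorted({a for a, _ in self.origin.values()})

    def to_frame(self) -> pd.DataFrame:
        rows = [(k, a, p) for k, (a, p) in sorted(self.origin.items())]
        return pd.DataFrame(rows, columns=["asv_id", "allele", "primer"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TruthMap":
        return cls({r.asv_id: (r.allele, r.primer) for r in df.itertuples()})


def simulate_tree(n_leaves: int, seed: int, branch_scale: float = 0.1) -> PhyloTree:
    """Random bifurcating tree: Yule-style leaf splitting, exponential
    branch lengths with mean ``branch_scale`` (substitutions/site)."""
    if n_leaves < 2:
        raise UsageError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    # children[v] empty => leaf; grow by splitting a uniformly chosen leaf
    children: list[list[int]] = [[1, 2], [], []]
    leaves = [1, 2]
    while len(leaves) < n_leaves:
        i = int(rng.integers(len(leaves)))
        v = leaves[i]
        a, b = len(children), len(children) + 1
        children.append([])
        children.append([])
        children[v] = [a, b]
        leaves[i] = a
        leaves.append(b)
    lengths = rng.exponential(branch_scale, size=len(children))

    leaf_counter = 0
    edge_counter = 0

    def emit(v: int) -> str:
        nonlocal leaf_counter, edge_counter
        if children[v]:
            body = "(" + ",".join(emit(c) for c in children[v]) + ")"
        else:
            leaf_counter += 1
            body = f"L{leaf_counter:04d}"
        if v == 0:
            return body
        e = edge_counter
        edge_counter += 1
        return body + ":%.12g{%d}" % (lengths[v], e)

    return PhyloTree.from_newick(emit(0) + ";")


def _select_separated_leaves(
    tree: PhyloTree, n: int, min_separation: float, rng: np.random.Generator,
    attempts: int = 60,
) -> list[int]:
    leaf_ids = list(tree.leaves)
    for _ in range(attempts):
        order = rng.permutation(len(leaf_ids))
        chosen: list[int] = []
        for i in order:
            v = leaf_ids[int(i)]
            if all(tree.node_distance(v, u) >= min_separation for u in chosen):
                chosen.append(v)
                if len(chosen) == n:
                    return chosen
    raise GenerationError(
        f"could not pick {n} leaves pairwise >= {min_separation} apart; "
        "use fewer alleles, a larger tree, or a smaller min_separation"
    )


def _point_near_leaf(
    tree: PhyloTree, leaf: int, dist: float, rng: np.random.Generator
) -> TreePoint:
    """A TreePoint at path distance exactly ``dist`` from ``leaf`` when
    possible (clamped at the root), wandering off the root path into sibling
    subtrees with probability 1/2 at each junction."""
    cur = leaf
    remaining = float(dist)
    while True:
        if cur == tree.root:
            if tree.edge_number[cur] is not None and tree.branch_length[cur] > 0:
                return TreePoint(
                    int(tree.edge_number[cur]),
                    min(remaining, float(tree.branch_length[cur])),
                )
            c = tree.children[cur][0]
            return TreePoint(int(tree.edge_number[c]), float(tree.branch_length[c]))
        bl = float(tree.branch_length[cur])
        if remaining <= bl:
            return TreePoint(int(tree.edge_number[cur]), remaining)
        parent = int(tree.parent[cur])
        remaining -= bl
        sibs = [c for c in tree.children[parent] if c != cur]
        if sibs and rng.random() < 0.5:
            s = sibs[int(rng.integers(len(sibs)))]
            bls = float(tree.branch_length[s])
            down = min(remaining, bls)
            return TreePoint(int(tree.edge_number[s]), bls - down)
        cur = parent


def simulate_placements(
    tree: PhyloTree,
    n_alleles: int,
    primers: tuple[str, ...] = DEFAULT_PRIMERS,
    dispersion: float = 0.005,
    points_per_placement: int = 3,
    min_separation: float = 0.5,
    seed: int = 0,
    pendant_length: float = 0.01,
    allele_leaves: "list[str] | None" = None,
    asv_prefix: str = "asv",
) -> tuple[PlacementSet, TruthMap]:
    """One ASV per (allele, primer), mass within ``dispersion`` of the
    source leaf; allele leaves are pairwise at least ``min_separation``
    apart (rejection sampling).  Passing ``allele_leaves`` (leaf names)
    skips the selection — useful for re-amplifying the same alleles in a
    follow-up study."""
    if n_alleles > len(tree.leaves):
        raise UsageError("more alleles than leaves")
    if dispersion < 0:
        raise UsageError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    if allele_leaves is not None:
        if len(allele_leaves) != n_alleles:
            raise UsageError("allele_leaves length must equal n_alleles")
        allele_leaves = [tree.name_to_leaf[nm] for nm in allele_leaves]
    else:
        allele_leaves = _select_separated_leaves(tree, n_alleles, min_separation, rng)
    records: dict[str, PlacementRecord] = {}
    origin: dict[str, tuple[str, str]] = {}
    k = 0
    for leaf in allele_leaves:
        allele = tree.leaf_name[leaf]
        for primer in primers:
            k += 1
            asv = f"{asv_prefix}{k:05d}"
            npts = 1 if dispersion == 0 else points_per_placement
            if dispersion == 0:
                pts = [TreePoint(int(tree.edge_number[leaf]), 0.0)]
            else:
                dists = rng.uniform(0.0, dispersion, size=npts)
                pts = [_point_near_leaf(tree, leaf, d, rng) for d in dists]
            w = rng.dirichlet(np.ones(npts))
            rows = tuple(
                PlacementRow(
                    edge_num=pt.edge_number,
                    likelihood=float(-1000.0 + rng.uniform(0, 10)),
                    like_weight_ratio=float(wi),
                    distal_length=float(pt.offset),
                    pendant_length=pendant_length,
                )
                for pt, wi in zip(pts, w)
            )
            records[asv] = PlacementRecord(asv, rows)
            origin[asv] = (allele, primer)
    pset = PlacementSet(tree=tree, records=records)
    pset.validate()
    return pset, TruthMap(origin)


def simulate_counts(
    truth: TruthMap,
    n_specimens: int,
    depth: int,
    seed: int = 0,
    abundance_sigma: float = 2.0,
) -> CountTable:
    """Specimen-ASV counts: per specimen, log-normal allele abundances and
    a multinomial read draw at exactly ``depth`` reads; each specimen is
    sequenced with one primer (round-robin), so its reads land on that
    primer's ASVs."""
    if depth <= 0:
        raise UsageError("depth must be positive")
    rng = np.random.default_rng(seed)
    alleles = truth.alleles()
    primers = sorted({p for _, p in truth.origin.values()})
    asv_of = {(a, p): asv for asv, (a, p) in truth.origin.items()}
    asv_ids = sorted(truth.origin)
    data = np.zeros((n_specimens, len(asv_ids)), dtype=np.int64)
    col = {a: i for i, a in enumerate(asv_ids)}
    for s in range(n_specimens):
        primer = primers[s % len(primers)]
        abund = rng.lognormal(0.0, abundance_sigma, size=len(alleles))
        reads = rng.multinomial(depth, abund / abund.sum())
        for allele, r in zip(alleles, reads):
            if r and (allele, primer) in asv_of:
                data[s, col[asv_of[(allele, primer)]]] += r
    specimens = [f"sp{s + 1:04d}" for s in range(n_specimens)]
    return CountTable(pd.DataFrame(data, index=specimens, columns=asv_ids))


def _check_truth_cover(assignment: dict[str, str], truth: TruthMap) -> None:
    missing = [a for a in assignment if a not in truth.origin]
    if missing:
        raise ConsistencyError(f"ASVs missing from truth map: {missing[:5]}")


def alleles_per_phylotype(
    assignment: dict[str, str], truth: TruthMap
) -> tuple[float, pd.DataFrame]:
    """Lumping metric: distinct source alleles per phylotype (ideal 1)."""
    _check_truth_cover(assignment, truth)
    rows: dict[str, set[str]] = {}
    for asv, pt in assignment.items():
        rows.setdefault(pt, set()).add(truth.origin[asv][0])
    table = pd.DataFrame(
        sorted((pt, len(al)) for pt, al in rows.items()),
        columns=["phylotype", "n_alleles"],
    )
    return float(table["n_alleles"].mean()), table


def phylotypes_per_allele(
    assignment: dict[str, str], truth: TruthMap
) -> tuple[float, pd.DataFrame]:
    """Splitting metric: distinct phylotypes per source allele (ideal 1)."""
    _check_truth_cover(assignment, truth)
    rows: dict[str, set[str]] = {}
    for asv, pt in assignment.items():
        rows.setdefault(truth.origin[asv][0], set()).add(pt)
    table = pd.DataFrame(
        sorted((al, len(pts)) for al, pts in rows.items()),
        columns=["allele", "n_phylotypes"],
    )
    return float(table["n_phylotypes"].mean()), table


def rarefaction_curve(
    counts: CountTable,
    depths: list[int],
    reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean number of unique features recovered at each subsampling depth.

    Reads are pooled across specimens and subsampled without replacement
    (multivariate hypergeometric).  Depths above the total read count are
    capped with a warning.
    """
    if any(d <= 0 for d in depths):
        raise UsageError("depths must be positive")
    rng = np.random.default_rng(seed)
    totals = counts.df.sum(axis=0).to_numpy(dtype=np.int64)
    grand = int(totals.sum())
    out = []
    for depth in depths:
        d = depth
        if d > grand:
            logger.warning("depth %d exceeds total reads %d; capped", d, grand)
            d = grand
        if d == grand:
            mean = float((totals > 0).sum())
        else:
            vals = [
                int((rng.multivariate_hypergeometric(totals, d) > 0).sum())
                for _ in range(reps)
            ]
            mean = float(np.mean(vals))
        out.append((depth, mean))
    return pd.DataFrame(out, columns=["depth", "mean_unique_features"])
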