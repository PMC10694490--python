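"""Reference tree with jplace ``{N}`` edge numbering.

Phylogenetic placement tools report, for each query sequence, likelihoods of
attachment to *edges* of a fixed reference tree.  The tree travels inside the
jplace file as a newick string in which every edge carries a bracketed integer
label, e.g. ``(A:0.1{0},B:0.2{1}):0{2};``.  This module parses that dialect
into an array-backed rooted tree and provides the geometric primitives the
rest of the package builds on: lowest common ancestors, path distances
between arbitrary attachment points, tip-to-root depths and re-rooting.

Coordinate convention
---------------------
An attachment point (:class:`TreePoint`) lives on the edge identified by its
jplace number, at ``offset`` substitutions/site measured from the *distal*
(child, leaf-ward) end of that edge — the same convention as the jplace
``distal_length`` field.  Offsets overshooting the branch length by at most
``CLAMP_TOL`` are clamped (placement engines emit tiny overshoots); larger
overshoots raise.
"""

from __future__ import annotations

import hashlib
import re
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, UsageError

__all__ = ["TreePoint", "PhyloTree", "parse_edge_numbered_newick"]

#: tolerated overshoot of an attachment offset beyond its branch length
CLAMP_TOL = 1e-6


class TreePoint(NamedTuple):
    """A point on a tree edge: ``offset`` from the distal (child) end."""

    edge_number: int
    offset: float


_ANNOT_RE = re.compile(
    r"^(?P<name>[^:{}]*)"
    r"(?:\{(?P<e1>\d+)\})?"
    r"(?::(?P<len>[-+0-9.eE]+))?"
    r"(?:\{(?P<e2>\d+)\})?$"
)


class PhyloTree:
    """Rooted tree with branch lengths and unique per-edge jplace numbers.

    Nodes are integers 0..n-1 in preorder (root = 0), which makes identifiers
    deterministic for a given newick string.  The edge *above* node ``v``
    carries ``branch_length[v]`` and ``edge_number[v]``.  The root may also
    carry an edge number (jplace files frequently number a zero-length root
    edge); if that root edge has positive length, points on it are handled as
    lying "above" the root.
    """

    def __init__(
        self,
        parent: Sequence[int],
        branch_length: Sequence[float],
        edge_number: Sequence[object],
        leaf_name: dict[int, str],
    ):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.branch_length = np.asarray(branch_length, dtype=np.float64)
        self.edge_number = list(edge_number)  # int or None (root without edge)
        self.leaf_name = dict(leaf_name)
        self.n_nodes = len(self.parent)
        self._validate_and_index()

    # -- construction -----------------------------------------------------

    def _validate_and_index(self) -> None:
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise FormatError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        if np.any(self.branch_length[np.arange(self.n_nodes) != self.root] < 0):
            raise FormatError("negative branch length")
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes):
            p = int(self.parent[v])
            if p >= 0:
                self.children[p].append(v)
        # preorder/postorder (iterative; trees can be deep)
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self.children[v]))
        if len(order) != self.n_nodes:
            raise FormatError("tree contains a cycle or unreachable node")
        self.preorder = np.asarray(order, dtype=np.int64)
        self.postorder = self.preorder[::-1].copy()
        # depths
        self.depth = np.zeros(self.n_nodes)
        self.depth_edges = np.zeros(self.n_nodes, dtype=np.int64)
        for v in order:
            p = int(self.parent[v])
            if p >= 0:
                self.depth[v] = self.depth[p] + self.branch_length[v]
                self.depth_edges[v] = self.depth_edges[p] + 1
        # edge number index
        self.edge_to_node: dict[int, int] = {}
        for v, e in enumerate(self.edge_number):
            if e is None:
                continue
            if e in self.edge_to_node:
                raise FormatError(f"duplicate edge number {{{e}}}")
            self.edge_to_node[int(e)] = v
        for v in range(self.n_nodes):
            if v != self.root and self.edge_number[v] is None:
                raise FormatError(f"edge above node {v} lacks an {{N}} number")
        # leaf names
        self.leaves = [v for v in range(self.n_nodes) if not self.children[v]]
        names = [self.leaf_name.get(v) for v in self.leaves]
        if any(n is None or n == "" for n in names):
            raise FormatError("every leaf must be named")
        if len(set(names)) != len(names):
            raise FormatError("leaf names are not unique")
        self.name_to_leaf = {self.leaf_name[v]: v for v in self.leaves}
        # binary lifting table for LCA
        self._build_lca_table()

    def _build_lca_table(self) -> None:
        max_k = max(1, int(np.ceil(np.log2(max(2, int(self.depth_edges.max()) + 1)))))
        up = np.zeros((max_k, self.n_nodes), dtype=np.int64)
        par = self.parent.copy()
        par[self.root] = self.root
        up[0] = par
        for k in range(1, max_k):
            up[k] = up[k - 1][up[k - 1]]
        self._up = up

    # -- parsing / serialization ------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return parse_edge_numbered_newick(text)

    def to_newick(self) -> str:
        """Serialize with 12-significant-digit lengths and ``{N}`` labels."""

        out: list[str] = []

        def fmt(v: int) -> str:
            if self.children[v]:
                body = "(" + ",".join(fmt(c) for c in self.children[v]) + ")"
            else:
                body = self.leaf_name[v]
            if v == self.root:
                if self.edge_number[v] is not None:
                    body += ":%.12g{%d}" % (self.branch_length[v], self.edge_number[v])
                return body
            return body + ":%.12g{%d}" % (self.branch_length[v], self.edge_number[v])

        out.append(fmt(self.root))
        return "".join(out) + ";"

    def digest(self) -> str:
        """Stable hash of the serialized tree; used to refuse cross-tree mixes."""
        return hashlib.sha256(self.to_newick().encode()).hexdigest()

    # -- queries -----------------------------------------------------------

    def is_leaf(self, v: int) -> bool:
        return not self.children[v]

    def node_of_edge(self, edge_number: int) -> int:
        try:
            return self.edge_to_node[int(edge_number)]
        except KeyError:
            raise KeyError(f"edge number {{{edge_number}}} not in tree") from None

    def leaf_point(self, name: str) -> TreePoint:
        """The TreePoint sitting exactly on the named leaf."""
        v = self.name_to_leaf[name]
        return TreePoint(int(self.edge_number[v]), 0.0)

    def node_point(self, v: int) -> TreePoint:
        """A TreePoint at node ``v`` (offset 0 on its edge; root → offset
        branch_length on a child edge when the root has no own edge)."""
        if self.edge_number[v] is not None:
            return TreePoint(int(self.edge_number[v]), 0.0)
        if v != self.root or not self.children[v]:
            raise UsageError(f"node {v} has no edge")
        c = self.children[v][0]
        return TreePoint(int(self.edge_number[c]), float(self.branch_length[c]))

    def lca(self, nodes: Iterable[int]) -> int:
        """Lowest common ancestor of a non-empty node set."""
        it = list(nodes)
        if not it:
            raise UsageError("lca of an empty node set")
        a = int(it[0])
        for b in it[1:]:
            a = self._lca2(a, int(b))
        return a

    def _lca2(self, a: int, b: int) -> int:
        da, db = int(self.depth_edges[a]), int(self.depth_edges[b])
        if da < db:
            a, b, da, db = b, a, db, da
        diff = da - db
        k = 0
        while diff:
            if diff & 1:
                a = int(self._up[k, a])
            diff >>= 1
            k += 1
        if a == b:
            return a
        for k in range(self._up.shape[0] - 1, -1, -1):
            if self._up[k, a] != self._up[k, b]:
                a = int(self._up[k, a])
                b = int(self._up[k, b])
        return int(self.parent[a])

    def node_distance(self, u: int, v: int) -> float:
        a = self._lca2(int(u), int(v))
        return float(self.depth[u] + self.depth[v] - 2.0 * self.depth[a])

    def clamp_offset(self, edge_number: int, offset: float) -> float:
        v = self.node_of_edge(edge_number)
        bl = float(self.branch_length[v])
        if offset < 0:
            if offset < -CLAMP_TOL:
                raise FormatError(f"negative offset {offset} on edge {{{edge_number}}}")
            return 0.0
        if offset > bl:
            if offset - bl > CLAMP_TOL:
                raise FormatError(
                    f"offset {offset} exceeds branch length {bl} on edge {{{edge_number}}}"
                )
            return bl
        return float(offset)

    def _resolve(self, p: TreePoint) -> tuple[int, float, bool]:
        """→ (anchor node, height above anchor, above_root flag)."""
        v = self.node_of_edge(p.edge_number)
        t = self.clamp_offset(p.edge_number, p.offset)
        return v, t, v == self.root

    def path_distance(self, p: TreePoint, q: TreePoint) -> float:
        """Total branch length along the unique path between two points."""
        cp, tp, p_above = self._resolve(p)
        cq, tq, q_above = self._resolve(q)
        if p_above and q_above:
            return abs(tp - tq)
        if p_above:
            return tp + float(self.depth[cq]) - tq
        if q_above:
            return tq + float(self.depth[cp]) - tp
        if cp == cq:
            return abs(tp - tq)
        a = self._lca2(cp, cq)
        dp = float(self.depth[cp]) - tp
        dq = float(self.depth[cq]) - tq
        if a == cq:
            return dp - dq
        if a == cp:
            return dq - dp
        return dp + dq - 2.0 * float(self.depth[a])

    def point_node_distance(self, p: TreePoint, v: int) -> float:
        """Path distance from a point to a node (no TreePoint needed for v)."""
        cp, tp, above = self._resolve(p)
        v = int(v)
        if above:
            return tp + float(self.depth[v])
        a = self._lca2(cp, v)
        dp = float(self.depth[cp]) - tp
        dv = float(self.depth[v])
        if a == cp:  # cp ancestor-or-self of v: path climbs from v past the point
            return dv - dp
        if a == v:  # v strict ancestor of cp: point descends to v's depth
            return dp - dv
        return dp + dv - 2.0 * float(self.depth[a])

    def tip_to_root_depths(self) -> pd.DataFrame:
        """One row per leaf: (leaf_name, depth) with depth = Σ branch lengths.

        A numbered root edge counts toward the depth (it is part of the
        tree's edge set even though nothing sits above it).
        """
        root_bl = float(self.branch_length[self.root]) if self.edge_number[self.root] is not None else 0.0
        rows = [(self.leaf_name[v], float(self.depth[v]) + root_bl) for v in self.leaves]
        return pd.DataFrame(rows, columns=["leaf_name", "depth"])

    # -- rerooting ---------------------------------------------------------

    def reroot(self, new_root: int, with_flips: bool = False):
        """Return a copy rooted at ``new_root``.

        Edge numbers and lengths follow the (undirected) edges.  A numbered
        root edge of the original tree (a half-edge with no node above) is
        dropped, so only trees whose placements avoid that edge should be
        rerooted; path distances between surviving points are unchanged.

        With ``with_flips`` also returns the set of edge numbers whose
        orientation reversed — offsets on those edges are measured from the
        opposite end after rerooting (``offset' = length − offset``).
        """
        if not (0 <= new_root < self.n_nodes):
            raise UsageError(f"unknown node {new_root}")
        adj: dict[int, list[tuple[int, float, int]]] = {v: [] for v in range(self.n_nodes)}
        for v in range(self.n_nodes):
            p = int(self.parent[v])
            if p >= 0:
                e = int(self.edge_number[v])
                bl = float(self.branch_length[v])
                adj[v].append((p, bl, e))
                adj[p].append((v, bl, e))
        order = [new_root]
        parent = {new_root: -1}
        blen = {new_root: 0.0}
        enum: dict[int, object] = {new_root: None}
        i = 0
        while i < len(order):
            u = order[i]
            i += 1
            for w, bl, e in adj[u]:
                if w not in parent:
                    parent[w] = u
                    blen[w] = bl
                    enum[w] = e
                    order.append(w)
        # renumber nodes in the new preorder; keep leaf names
        remap = {old: new for new, old in enumerate(order)}
        n = len(order)
        par = [remap[parent[o]] if parent[o] >= 0 else -1 for o in order]
        bls = [blen[o] for o in order]
        ens = [enum[o] for o in order]
        leaf_names = {
            remap[o]: nm for o, nm in self.leaf_name.items() if o != new_root
        }
        rerooted = PhyloTree(par, bls, ens, leaf_names)
        if not with_flips:
            return rerooted
        flipped = {
            int(self.edge_number[v])
            for v in range(self.n_nodes)
            if int(self.parent[v]) >= 0 and parent.get(int(self.parent[v])) == v
        }
        return rerooted, flipped


def parse_edge_numbered_newick(text: str) -> PhyloTree:
    """Parse a newick string whose every edge carries a ``{N}`` label.

    Accepts the label either before or after the branch length (engines
    differ).  Branch lengths are mandatory on non-root edges; the root may
    optionally carry a length and edge number of its own.
    """
    s = text.strip()
    if not s.endswith(";"):
        raise FormatError("newick string must end with ';'")
    s = s[:-1]

    parents: list[int] = []
    blens: list[float] = []
    enums: list[object] = []
    names: dict[int, str] = {}
    kids: list[list[int]] = []

    def new_node(parent: int) -> int:
        parents.append(parent)
        blens.append(0.0)
        enums.append(None)
        kids.append([])
        if parent >= 0:
            kids[parent].append(len(parents) - 1)
        return len(parents) - 1

    pos = 0
    n = len(s)

    def read_annotation() -> str:
        nonlocal pos
        start = pos
        while pos < n and s[pos] not in ",()":
            pos += 1
        return s[start:pos]

    def apply_annotation(v: int, raw: str, is_root: bool, is_leaf: bool) -> None:
        m = _ANNOT_RE.match(raw.strip())
        if not m:
            raise FormatError(f"cannot parse node annotation {raw!r}")
        name = m.group("name")
        if is_leaf:
            if not name:
                raise FormatError("leaf without a name")
            names[v] = name
        e = m.group("e1") or m.group("e2")
        if m.group("e1") and m.group("e2"):
            raise FormatError(f"two edge numbers in annotation {raw!r}")
        ln = m.group("len")
        if e is None:
            if not is_root:
                where = name or f"node #{v}"
                raise FormatError(f"edge above {where} lacks an {{N}} edge number")
        else:
            enums[v] = int(e)
        if ln is None:
            if not is_root:
                where = name or f"node #{v}"
                raise FormatError(f"edge above {where} lacks a branch length")
            blens[v] = 0.0
        else:
            bl = float(ln)
            if bl < 0:
                where = name or f"node #{v}"
                raise FormatError(f"negative branch length on edge above {where}")
            blens[v] = bl

    def parse_clade(parent: int, is_root: bool) -> int:
        nonlocal pos
        v = new_node(parent)
        if pos < n and s[pos] == "(":
            pos += 1
            while True:
                parse_clade(v, False)
                if pos >= n:
                    raise FormatError("unbalanced parentheses")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise FormatError(f"unexpected character {s[pos]!r} at {pos}")
            raw = read_annotation()
            apply_annotation(v, raw, is_root, is_leaf=False)
        else:
            raw = read_annotation()
            apply_annotation(v, raw, is_root, is_leaf=True)
        return v

    parse_clade(-1, True)
    if pos != n:
        raise FormatError(f"trailing characters after tree: {s[pos:]!r}")

    # reorder nodes into preorder so identifiers are deterministic
    order: list[int] = []
    stack = [0]
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(reversed(kids[v]))
    remap = {old: new for new, old in enumerate(order)}
    par = [remap[parents[o]] if parents[o] >= 0 else -1 for o in order]
    bls = [blens[o] for o in order]
    ens = [enums[o] for o in order]
    nms = {remap[o]: nm for o, nm in names.items()}
    return PhyloTree(par, bls, ens, nms)
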