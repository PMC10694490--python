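"""Reading and writing jplace (phylogenetic placement) files.

A jplace file is JSON with a ``tree`` (newick with ``{N}`` edge numbers),
a ``placements`` list, a ``fields`` list naming the per-row columns, and a
``version``.  Each placement names one or more query sequences (``"n"`` or
``"nm"`` with multiplicity) and carries a ``"p"`` array of rows, one per
candidate attachment edge.

The mass view
-------------
Downstream distance computations operate on a normalized
:class:`MassDistribution`: one weighted point per placement row at
``TreePoint(edge_num, distal_length)`` with weight proportional to
``like_weight_ratio``.  Weights are renormalized to sum to one because
placement engines omit low-likelihood edges, which would otherwise leave
records on different trees/regions incomparable.  ``pendant_length`` is kept
on the side: by default it does not contribute to inter-record distances
(it reflects amplicon-versus-reference divergence, which varies by primer,
not by source organism), but it can be switched on for sensitivity analyses.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
import numpy as np

from .errors import ConsistencyError, FormatError
from .treegraph import PhyloTree, TreePoint

__all__ = [
    "PlacementRow",
    "PlacementRecord",
    "PlacementSet",
    "MassDistribution",
    "read_jplace",
    "write_jplace",
    "to_mass",
]

REQUIRED_FIELDS = ("edge_num", "like_weight_ratio", "distal_length", "pendant_length")
DEFAULT_FIELDS = (
    "edge_num",
    "likelihood",
    "like_weight_ratio",
    "distal_length",
    "pendant_length",
)


@dataclass(frozen=True)
class PlacementRow:
    edge_num: int
    likelihood: float
    like_weight_ratio: float
    distal_length: float
    pendant_length: float


@dataclass
class PlacementRecord:
    """All candidate attachments of one ASV, plus its multiplicity."""

    asv_id: str
    rows: tuple[PlacementRow, ...]
    multiplicity: float = 1.0

    def validate(self, tree: PhyloTree) -> None:
        if not self.rows:
            raise FormatError(f"placement {self.asv_id!r} has no rows")
        total = 0.0
        for r in self.rows:
            if r.edge_num not in tree.edge_to_node:
                raise ConsistencyError(
                    f"ASV {self.asv_id!r} references edge {{{r.edge_num}}} absent from tree"
                )
            if not (-1e-9 <= r.like_weight_ratio <= 1 + 1e-6):
                raise FormatError(
                    f"ASV {self.asv_id!r}: like_weight_ratio {r.like_weight_ratio} outside [0, 1]"
                )
            if r.distal_length < 0 or r.pendant_length < 0:
                raise FormatError(f"ASV {self.asv_id!r}: negative length field")
            total += r.like_weight_ratio
        if total <= 0:
            raise FormatError(f"ASV {self.asv_id!r}: like_weight_ratio sum is not positive")
        if total > 1 + 1e-6:
            raise FormatError(f"ASV {self.asv_id!r}: like_weight_ratio sum {total} > 1")

    @property
    def edges(self) -> frozenset[int]:
        """Mass-bearing edge numbers (rows with positive weight)."""
        return frozenset(r.edge_num for r in self.rows if r.like_weight_ratio > 0)


@dataclass
class MassDistribution:
    """Unit mass spread over tree points; optional per-point pendant lengths."""

    points: tuple[TreePoint, ...]
    weights: np.ndarray
    pendants: np.ndarray | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if len(self.points) != len(self.weights) or not len(self.points):
            raise FormatError("mass distribution needs matching non-empty points/weights")
        if np.any(self.weights <= 0):
            raise FormatError("mass weights must be positive")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise FormatError("mass weights must sum to 1")

    @property
    def pendant_mass(self) -> float:
        """Weighted mean pendant length (the pendant term in distances)."""
        if self.pendants is None:
            return 0.0
        return float(np.dot(self.weights, self.pendants))


@dataclass
class PlacementSet:
    tree: PhyloTree
    records: dict[str, PlacementRecord]
    fields_order: tuple[str, ...] = DEFAULT_FIELDS
    version: int = 3
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        for r in self.records.values():
            r.validate(self.tree)

    def __len__(self) -> int:
        return len(self.records)


def _rows_from_p(p_rows, fields: list[str], asv_id: str) -> tuple[PlacementRow, ...]:
    idx = {f: i for i, f in enumerate(fields)}
    rows = []
    for raw in p_rows:
        if len(raw) != len(fields):
            raise FormatError(f"ASV {asv_id!r}: row length does not match fields")
        get = lambda f, default=None: raw[idx[f]] if f in idx else default
        rows.append(
            PlacementRow(
                edge_num=int(get("edge_num")),
                likelihood=float(get("likelihood", 0.0)),
                like_weight_ratio=float(get("like_weight_ratio")),
                distal_length=float(get("distal_length")),
                pendant_length=float(get("pendant_length")),
            )
        )
    return tuple(rows)


def read_jplace(path: str | os.PathLike) -> PlacementSet:
    """Read and validate a jplace (version 2/3) file."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    for key in ("tree", "placements", "fields", "version"):
        if key not in doc:
            raise FormatError(f"jplace file lacks required key {key!r}")
    fields = list(doc["fields"])
    missing = [f for f in REQUIRED_FIELDS if f not in fields]
    if missing:
        raise FormatError(
            f"jplace fields lack {missing}; available fields: {fields}"
        )
    tree = PhyloTree.from_newick(doc["tree"])
    records: dict[str, PlacementRecord] = {}
    for pl in doc["placements"]:
        rows_raw = pl.get("p")
        if rows_raw is None:
            raise FormatError("placement without 'p' rows")
        if "nm" in pl:
            named = [(str(n), float(m)) for n, m in pl["nm"]]
        elif "n" in pl:
            named = [(str(n), 1.0) for n in pl["n"]]
        else:
            raise FormatError("placement lacks both 'n' and 'nm'")
        for name, mult in named:
            if name in records:
                raise FormatError(f"duplicate ASV id {name!r} in jplace file")
            rec = PlacementRecord(name, _rows_from_p(rows_raw, fields, name), mult)
            rec.validate(tree)
            records[name] = rec
    return PlacementSet(
        tree=tree,
        records=records,
        fields_order=tuple(fields),
        version=int(doc["version"]),
        metadata=doc.get("metadata", {}),
    )


def write_jplace(pset: PlacementSet, path: str | os.PathLike) -> None:
    """Write a PlacementSet as jplace version 3 (atomically)."""
    pset.validate()
    fields = list(pset.fields_order)
    for f in REQUIRED_FIELDS:
        if f not in fields:
            fields.append(f)
    placements = []
    for rec in pset.records.values():
        p_rows = []
        for r in rec.rows:
            vals = {
                "edge_num": r.edge_num,
                "likelihood": r.likelihood,
                "like_weight_ratio": r.like_weight_ratio,
                "distal_length": r.distal_length,
                "pendant_length": r.pendant_length,
            }
            p_rows.append([vals.get(f, 0.0) for f in fields])
        placements.append({"p": p_rows, "nm": [[rec.asv_id, rec.multiplicity]]})
    doc = {
        "version": 3,
        "tree": pset.tree.to_newick(),
        "fields": fields,
        "placements": placements,
        "metadata": pset.metadata or {"software": "phylobin"},
    }
    tmp = f"{path}.tmp.{os.getpid()}"
    with open(tmp, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)
    os.replace(tmp, path)


def to_mass(
    record: PlacementRecord,
    tree: PhyloTree,
    lwr_floor: float = 0.0,
    best_only: bool = False,
) -> MassDistribution:
    """Normalized mass distribution of one record.

    ``lwr_floor`` prunes rows below the given like_weight_ratio before
    normalization (off by default).  ``best_only`` collapses the record to a
    unit point mass at its highest-weight row.
    """
    rows = [r for r in record.rows if r.like_weight_ratio > max(0.0, lwr_floor)]
    if not rows:
        rows = [r for r in record.rows if r.like_weight_ratio > 0]
    if not rows:
        raise FormatError(f"ASV {record.asv_id!r}: all like_weight_ratios are zero")
    if best_only:
        rows = [max(rows, key=lambda r: r.like_weight_ratio)]
    pts = tuple(
        TreePoint(r.edge_num, tree.clamp_offset(r.edge_num, r.distal_length))
        for r in rows
    )
    w = np.array([r.like_weight_ratio for r in rows], dtype=np.float64)
    w = w / w.sum()
    pend = np.array([r.pendant_length for r in rows], dtype=np.float64)
    return MassDistribution(points=pts, weights=w, pendants=pend)
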