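"""Post-hoc integration of newly placed ASVs into an existing phylotype set.

New studies (or single clinical specimens) are placed onto the *same*
reference tree and folded into an existing :class:`PhylotypeModel` without
disturbing it:

1. the LCA of each existing phylotype's placements is (re)computed;
2. each new ASV's distance to every phylotype LCA is measured (weighted mean
   path distance from its mass points to the node);
3. the ASV joins the closest phylotype if that distance is below the
   threshold, otherwise it stays unassigned — unassigned ASVs can be binned
   into brand-new phylotypes appended to the model.

Phylotypes are only comparable when generated against the same tree, so all
entry points verify the model's tree digest before doing anything.
"""

from __future__ import annotations

from .errors import CompatibilityError, ConsistencyError, UsageError
from .jplace_io import PlacementSet, to_mass
from .phylotype_binning import PhylotypeModel, bin_phylotypes, name_phylotypes
from .placement_metric import distance_to_node, placement_lca

__all__ = ["phylotype_lcas", "assign_new", "spawn_new_phylotypes"]


def _check_tree(model: PhylotypeModel, pset: PlacementSet) -> None:
    if model.tree_digest != pset.tree.digest():
        raise CompatibilityError(
            "placement set was made on a different reference tree than the "
            "phylotype model; phylotypes do not transfer across trees"
        )


def phylotype_lcas(model: PhylotypeModel, seed_pset: PlacementSet) -> dict[str, int]:
    """Per-phylotype placement LCA recomputed from the seed placements."""
    _check_tree(model, seed_pset)
    out: dict[str, int] = {}
    for name, members in model.phylotypes.items():
        missing = [a for a in members if a not in seed_pset.records]
        if missing:
            raise ConsistencyError(
                f"phylotype {name!r} members missing from placements: {missing[:5]}"
            )
        out[name] = placement_lca(
            seed_pset.tree, [seed_pset.records[a] for a in members]
        )
    return out


def assign_new(
    model: PhylotypeModel,
    new_pset: PlacementSet,
    threshold: float | None = None,
    nearest_member: bool = False,
    seed_pset: PlacementSet | None = None,
) -> tuple[dict[str, str], set[str]]:
    """Assign each new ASV to the nearest phylotype below the threshold.

    Default mode measures distance to each phylotype's LCA node.  The
    ``nearest_member`` sensitivity mode instead takes the minimum KR distance
    to any member record and therefore needs ``seed_pset``.  Ties go to the
    phylotype with the lowest index.  Returns ``(assignments, unassigned)``.
    """
    _check_tree(model, new_pset)
    thr = model.threshold if threshold is None else float(threshold)
    if thr <= 0:
        raise UsageError("assignment threshold must be positive")
    tree = new_pset.tree
    names = list(model.phylotypes)  # index order == name order
    if nearest_member and seed_pset is None:
        raise UsageError("nearest_member mode requires the seed placement set")

    assignments: dict[str, str] = {}
    unassigned: set[str] = set()
    for asv in sorted(new_pset.records):
        mass = to_mass(new_pset.records[asv], tree)
        best_name, best_d = None, None
        for name in names:
            if nearest_member:
                from .placement_metric import kr_distance  # local: optional path

                d = min(
                    kr_distance(tree, mass, to_mass(seed_pset.records[m], tree))
                    for m in model.phylotypes[name]
                )
            else:
                d = distance_to_node(tree, mass, model.phylotype_lca[name])
            if best_d is None or d < best_d:
                best_name, best_d = name, d
        if best_d is not None and best_d < thr:
            assignments[asv] = best_name
        else:
            unassigned.add(asv)
    return assignments, unassigned


def spawn_new_phylotypes(
    model: PhylotypeModel, unassigned_pset: PlacementSet
) -> PhylotypeModel:
    """Bin unassigned ASVs at the model threshold and append the result.

    Existing phylotypes are untouched (append-only); new names continue the
    index sequence.
    """
    if not unassigned_pset.records:
        return PhylotypeModel(
            threshold=model.threshold,
            linkage=model.linkage,
            tree_digest=model.tree_digest,
            phylotypes={k: list(v) for k, v in model.phylotypes.items()},
            phylotype_lca=dict(model.phylotype_lca),
        )
    _check_tree(model, unassigned_pset)
    existing = set(model.asv_to_phylotype)
    overlap = existing & set(unassigned_pset.records)
    if overlap:
        raise UsageError(f"ASVs already in the model: {sorted(overlap)[:5]}")
    fresh = bin_phylotypes(
        unassigned_pset, model.threshold, linkage=model.linkage
    )
    start = 1 + max(
        (int(name.rsplit("__", 1)[1]) for name in model.phylotypes), default=0
    )
    renamed = name_phylotypes(
        list(fresh.phylotypes.values()), model.threshold, start_index=start
    )
    phylotypes = {k: list(v) for k, v in model.phylotypes.items()}
    lcas = dict(model.phylotype_lca)
    for name, members in renamed.items():
        if name in phylotypes:
            raise ConsistencyError(f"phylotype name collision: {name}")
        phylotypes[name] = members
        lcas[name] = placement_lca(
            unassigned_pset.tree,
            [unassigned_pset.records[a] for a in members],
        )
    return PhylotypeModel(
        threshold=model.threshold,
        linkage=model.linkage,
        tree_digest=model.tree_digest,
        phylotypes=phylotypes,
        phylotype_lca=lcas,
    )
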