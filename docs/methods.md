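# Methods

This note documents the models, conventions and numerical choices behind
`phylobin`, including the places where the design was genuinely open and the
choices the package makes there.

## Placements as mass distributions

A jplace record lists candidate attachments (edge, likelihood,
like_weight_ratio, distal_length, pendant_length). The package converts each
record to a unit mass distribution: one point per row at
`TreePoint(edge_num, distal_length)`, weight ∝ `like_weight_ratio`,
renormalized to sum to one. Renormalization is deliberate: placement engines
omit edges "without meaningful likelihood", so raw weight sums differ between
records and engines; normalizing makes records comparable. A configurable
`lwr_floor` can prune low-weight rows first (default 0 = keep all), and
`best_only` collapses a record to its argmax-weight row for sensitivity
analyses.

**Pendant lengths are excluded from inter-ASV distances by default.** The
pendant branch reflects amplicon-versus-reference divergence, which varies
systematically with the targeted variable region; including it would push
apart amplicons of the *same* allele sequenced with different primers — the
exact artifact phylotyping is meant to remove. `include_pendant=True` adds
each record's weighted mean pendant length to distances between distinct
records, modeling each mass point as hanging at the end of a private stub.

Offsets are measured from the distal (child) end of the edge, like the jplace
`distal_length` field. Overshoots beyond the branch length are clamped up to
1e-6 (placement engines emit tiny overshoots); larger overshoots are format
errors — tolerant but loud. Trees whose outermost node carries its own
`{N}` label (a root edge) are supported; points on that edge live "above the
root" and all distances handle them uniformly.

## The KR distance

The distance between two mass distributions P, Q with exponent p ≥ 1 is

    d_p(P, Q) = ( Σ_seg |M_P(seg) − M_Q(seg)|^p · len(seg) ) ^ (1/p)

over edge segments delimited by attachment points, where `M_X(seg)` is X's
mass on the leaf-ward side. For p = 1 (the default; nothing in the validation
design requires another exponent) this equals minimum-cost transport under
the tree's path metric. The implementation is a single post-order sweep
accumulating signed subtree mass differences; per-pair cost is linear in tree
size plus sorting of on-edge attachment points. No approximation. Touched
edges are visited in sorted order so that float summation order — and hence
the result — is bitwise independent of argument order (symmetry is exact, not
just within tolerance).

Two independent oracles check the implementation in the tests: shortest paths
on a graph with attachment points spliced in (point masses), and an LP
minimum-cost transport over the point-to-point distance matrix (general
distributions, ≤ 6 points).

`distance_to_node` uses the exact point-target identity
Σᵢ wᵢ · d(pointᵢ, node) rather than the generic sweep, keeping post-hoc
assignment linear in the number of placement rows.

## Binning: divide and conquer

1. **Pre-group.** Union–find over records; two records join when they share
   at least one mass-bearing edge.
2. **Merge.** Pre-groups whose LCAs are strictly closer than the threshold
   are united (transitively); merged groups recompute their LCA.
3. **Cluster.** Within each merged group, the full pairwise KR matrix is
   clustered agglomeratively (scipy linkage); the flat cut unions merges with
   linkage distance strictly below the threshold.

Strict `<` is used both for merging and cutting: "closer than the clustering
distance" is a strict comparison, and ASVs exactly at the threshold stay
separate. Default linkage is **single** — "variants at less than this
distance apart are clustered together" is single-linkage semantics — with
average and complete available.

### LCA conventions (a deliberate asymmetry)

Two LCA notions coexist:

* **Distal LCA** (default `placement_lca`): LCA of the distal (child) nodes
  of all mass-bearing edges. This is the conventional reading of "the LCA of
  the placed nodes or tips" and stays close to the mass. It anchors
  per-phylotype LCAs and post-hoc assignment.
* **Containment LCA** (`containment=True`): a row attached part-way up an
  edge lies *above* the edge's child node, so the deepest node whose subtree
  truly contains it is the proximal node. The merge step uses this variant,
  because it makes the divide sound: masses of two unmerged groups with
  disjoint clades are each confined to their LCA's subtree, so every
  cross-group pair distance is at least the LCA separation — the exact bound
  that justifies never computing those pairs.

Using the containment LCA for post-hoc anchoring was evaluated and rejected:
on long terminal branches it pushes a phylotype's anchor a full branch length
away from its own members, breaking self-assignment at tight thresholds.

### Nested clades

When one group's LCA is ancestral to another's, no LCA-separation bound
exists (the ancestor group's mass may lie immediately next to the descendant
clade — e.g., just above its root on a long edge). For such nested pairs the
merge step falls back to the exact minimum cross-pair KR distance, with early
exit as soon as any pair falls under the threshold. Nested pairs are rare
(they require mass high on a long edge), so the asymptotic benefit of the
divide survives; in exchange, divide-and-conquer matches the brute-force
oracle exactly on every tested instance. Callers using `merge_pregroups`
without a placement set get the pure LCA rule plus a log message, preserving
the cheap path.

`brute_force_bin` — the O(n²) computation the divide avoids — is kept as a
first-class verification oracle, guarded at 5,000 records unless forced.

### Naming

`pt<code>__<index>` with `code = round(10·t)` zero-padded to two digits
(`pt01`, `pt05`, `pt10`; thresholds ≥ 10 overflow and are rejected) and a
five-digit index ranked by total member read count when counts are supplied,
else by member count, ties broken by the lexicographically smallest member
ASV id. The rank order is this package's convention; nothing downstream
depends on it. Models embed a SHA-256 digest of the serialized tree, and all
post-hoc entry points refuse placement sets whose tree digest differs —
phylotypes are only meaningful on the tree they were built from.

## Post-hoc integration

Three steps: (1) per-phylotype LCA from the seed placements; (2) each new
ASV's distance to every LCA (weighted mean path distance of its mass);
(3) assign to the nearest phylotype strictly below the threshold (default:
the model's binning threshold, overridable), ties to the lowest index;
otherwise unassigned. Unassigned ASVs can be binned at the model threshold
and appended with names continuing the index sequence; existing phylotypes
are never altered (append-only). A `nearest_member` mode replaces the LCA
anchor with the minimum KR distance to any member record, for sensitivity
analyses.

## Count tables

Collapsing ASV counts to phylotype counts is integer arithmetic; per-specimen
totals are conserved exactly, with unassigned ASVs kept in an explicit
`unclassified` column so the assigned fraction stays auditable.
Normalization scales each specimen to a fixed pseudo-count depth (default
10,000 reads) as real values — no rounding rule is imposed, which preserves
Bray-Curtis distances exactly. Zero-read specimens cannot be normalized and
are dropped with a warning. Bray-Curtis uses scipy's pairwise distance
machinery; a pair of all-zero specimens has no defined dissimilarity and is
reported NaN rather than 0.

## Reference recruitment

Consumes an ASV×reference percent-identity table (e.g. vsearch
`usearch_global` output at an 80% floor with max_accepts ≈ 10) rather than
running a search engine. Pipeline: identity floor → bounded best hits (per
ASV, ties at the best identity kept) → support filter (a reference must be a
best hit of ≥ 2 ASVs) → backfill (each orphaned ASV gets one reference back,
ranked by no-ambiguous-bases, then precise taxonomy, then length, then id —
one reference per ASV by default, configurable). The ~10-references-per-ASV
objective is reported as a diagnostic, not enforced by feedback. Every ASV
with at least one hit ends covered; hit-less ASVs are listed as uncovered.

## Synthetic validation data

The generator isolates the binning algorithm with controllable ground truth
instead of simulating sequences through a placement engine (explicitly out of
scope):

* **Tree**: Yule-style random bifurcations, exponential branch lengths with
  mean `branch_scale` (default 0.1 substitutions/site, giving tip-to-root
  depths under 1 — comparable to de novo 16S trees).
* **Placements**: `n_alleles` source leaves chosen pairwise ≥
  `min_separation` apart by rejection sampling (explicit error when
  impossible). Per (allele, primer) one ASV with `points_per_placement`
  (default 3) mass points at uniform distances within `dispersion` of the
  source leaf, wandering onto the pendant and adjacent edges; weights from a
  symmetric Dirichlet. The default five primer labels mirror the common
  V1–V2/V4/V3–V5/V6–V9 multi-primer study designs; `dispersion` defaults to
  0.005 (same-allele multi-primer placements land in a subclade about two
  orders of magnitude tighter than a 0.5 between-species separation, matching
  the subclade-depth-versus-LCA-depth picture placement engines produce).
* **Counts**: per specimen, log-normal allele abundances (σ = 2, gut-like
  rank-abundance steepness) and one multinomial draw at exactly `depth` reads
  (5,000 and 50,000 are the emulated legacy-454 and MiSeq depths); each
  specimen is "sequenced" with one primer, round-robin.

What the generator does **not** emulate: sequencing error, chimeras,
region-specific placement uncertainty, multi-modal placements across distant
clades, or reference-tree misspecification. Passing tests therefore certify
the binning algorithm and its contracts under controlled geometry, not
end-to-end performance on real amplicons.

Accuracy metrics: mean alleles-per-phylotype (lumping; 1.0 is ideal) and mean
phylotypes-per-allele (splitting; 1.0 is ideal), plus a rarefaction curve
(pooled counts subsampled without replacement via multivariate hypergeometric
draws).

## Validation study sizes

The shipped validation (tests and `scripts/acceptance.py`) uses: 20
replicates of 40 alleles × 5 primers (200 ASVs) on 300-leaf trees for ideal
recovery; 100-leaf trees with source separation 3× the threshold for the
divide-vs-brute-force comparison, scaling allele count and branch scale with
the threshold (40/0.1, 10/0.5, 5/1.0 — a 3.0 separation needs longer
branches and fewer alleles than a 0.3 one); 250-leaf trees with 20 seed + 10
held-out alleles for post-hoc accuracy. These sizes exercise every code path
(multi-group merges, nested-clade fallback, tie-breaks) while each full run
stays in the seconds range.

## Degenerate inputs and tie-breaks

Empty placement sets, empty node sets, non-positive thresholds and zero-lwr
records raise usage/format errors rather than guessing. Zero-length branches
are legal everywhere (distances just ignore them). Assignment ties go to the
lowest phylotype index; naming ties to the smallest member id; backfill ties
to the smallest reference id. All randomness flows through
`numpy.random.default_rng(seed)`; identical seeds give byte-identical jplace,
CSV and model-JSON outputs.

## Known limitations

* Phylotypes do not transfer across reference trees (enforced via tree
  digests); re-placement onto a common tree is upstream of this package.
* With average/complete linkage the divide step is heuristic: those linkage
  criteria depend on whole-cluster geometry, so partitioning before
  clustering can differ from a global clustering even when single linkage
  would not. Single linkage (the default) is the validated configuration.
* The KR exponent is exposed but only p = 1 is validated.
* `reroot` drops a numbered root edge (a half-edge with no node above it);
  it exists for verification, not as a tree-manipulation API.
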