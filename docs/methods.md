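# Methods

## Representation

A chain is an ordered list of labeled Cα points (`CaStructure`). Labels
come from a table mapping 3-letter residue codes to integers; the
shipped default assigns the 20 standard residues, alphabetically, to
4..23 and sets the alphabet size m = 23, so every (label − 1) < m and
the key formula below is a bijection. Common modified residues are
resolved through a configurable alias table (MSE→MET, TPO→THR, SEP→SER,
PTR→TYR, TYN→TYR, …); residues with no label after aliasing are skipped
and counted. Altloc conflicts keep the highest-occupancy Cα, first in
file on ties. One `CaStructure` holds exactly one chain; multi-chain
comparisons build one per chain.

## Key generation

Every unordered Cα triple becomes one triangle. Vertices are put into
canonical positions l₁/l₂/l₃ by, in order: larger label first; for a
label-tied pair, greater distance to the remaining vertex first; for
three equal labels, the longer *maximum* incident edge first and then
the longer *other* incident edge; any residual tie falls back to
ascending sequence index. The two-level edge comparison in the
all-equal case matters: the two endpoints of a triangle's longest edge
always tie on their maximum incident edge, and an ordering that
resolved them by record position would leak residue order into the
signed keys. With the refinement, a residual *geometric* tie implies an
isosceles symmetry under which both candidate orderings yield identical
key digits (the unfolded angle is then exactly 90°), so the sequence
fallback never affects a key.

Geometry digits: MaxDist is the longest edge; θ₁ is the angle at the
midpoint of the l₁–l₂ edge, computed by the law of cosines with the
arccos argument clamped to [−1, 1], and Theta = θ₁ folded to ≤ 90°.
Triangles with a base edge or midpoint height below 10⁻⁹ Å (collinear
or coincident points) are skipped and counted, not keyed; an ideal
extended strand, whose alternate residues are collinear, shows this
path routinely. Keys are packed positionally (Theta bin lowest order,
then MaxDist bin, then the three labels) in exact integer arithmetic.

Because every digit is a function of labels and pairwise distances
only, key vectors are invariant under all isometries — proper *and*
improper — and under any permutation of residue records. This is the
basis of the method's indifference to superposition and to substructure
rearrangement, and it equally means a mirror-image *structure* has
identical keys. The "mirror" signing (below) distinguishes something
else: non-congruent triangle pairs whose unfolded angles are
supplementary.

### Mirror-image keys

The ≤ 90° fold assigns a triangle with θ₁ = 70° and one with θ₁ = 110°
(same labels, same MaxDist bin) the same key. In mirror mode the key
keeps its magnitude but takes a negative sign when θ₁ > 90°, splitting
such pairs. Exact right angles stay positive; a tolerance of 10⁻¹² on
the arccos argument (~10⁻¹⁰ degrees) absorbs rounding at the boundary.
Signed vectors treat +k and −k as distinct keys everywhere
(similarity, set algebra, motif search).

## Discretization

Theta (degrees, (0, 90]) and MaxDist (Å, open-ended above) are binned
with 1-based, right-closed bins; values beyond the last cut clamp into
the final bin. Boundary fitting is adaptive equal-frequency: cuts live
only in the gaps between distinct values (tied values are never split),
each cut targets its equal-frequency count and snaps to the nearest
admissible gap, equally-near gaps are resolved by the lower total
within-bin variance (population variance, summed per bin, unweighted),
and cuts are revisited iteratively — each re-balancing its two adjacent
bins — until stable or 100 passes. On all-distinct data this reduces
to equal-frequency binning with at most one element of deviation per
bin. A variance-first descent was rejected because it happily starves
bins (e.g. splitting {1,2,3} | {100} three-to-one), defeating the
equal-occupancy goal of the discretization.

The bin-count survey (`select_bin_counts`) fits each candidate count on
each sample set, ranks by within-bin variance with ties toward more
bins, keeps the five best, retains the two largest counts of those
five, and summarizes the pooled retained counts (min/median/max/mode,
modal ties again toward more bins — finer bins distinguish smaller
structural differences).

Shipped presets cover Theta ∈ {7, 15, 21, 29} × MaxDist ∈ {12, 26, 35}
with 29/35 the default, fitted once on the packaged synthetic sample:
4 helices + 4 strands + 4 coils of 40 residues each, fixed seeds,
≈ 118 000 triangles pooled. Any preset can be overridden by plain-text
boundary files (one ascending cut per line).

## Similarity

Generalized Jaccard Σ min / Σ max over the union of keys; the modified
variant divides Σ min by min(Σ max, max(N₁, N₂)) where N is a protein's
total key count *with multiplicity* (= its kept-triangle count; a
distinct-count mode is available). The modified measure is never
smaller than the plain one. Comparing two empty vectors is an error,
not 1. Distance is 1 − similarity. Merging keys by any surjection on
key space — amino-acid grouping, coarsening to nested boundaries — can
only increase min-sums at least as fast as max-sums, so similarity is
monotone non-decreasing under grouping and bin coarsening.

## Key-set analytics and motifs

Set computations use distinct keys (frequencies ignored): *common*
keys of several classes lie in every class union; *specific* keys of a
class lie in no other class's union; *Common* keys of one class lie in
every member protein. Venn regions are enumerated exhaustively up to 6
classes (2⁶ − 1 regions), pairwise + all-common beyond. Key feature
statistics (mean Theta/MaxDist) use decoded bin midpoints when only
keys are known — the open-ended last MaxDist bin takes its left
neighbour's width, the last Theta bin is capped at 90° — or raw
per-triangle values when a triangle table is supplied.

Motif search matches a query key if the vector holds a key with the
same sign, identical (l₁, l₂, l₃, d) digits and a Theta bin within the
tolerance (default ±1). The tolerance acts on the decoded Theta digit,
not the raw integer, to avoid wrapping into a neighbouring MaxDist bin
at Theta bin 1 or θ_T; a `raw` mode reproduces the literal key ± 1
behaviour, and the two agree everywhere except at that wrap (verified
exhaustively on a small scheme).

## Feature selection

Secondary structure comes from HELIX/SHEET records (or programmatic
annotation on fixtures). IESS triangles have all three residues inside
helix or strand segments, any segments and types; IASS triangles lie
within one single segment (default) or, in the alternate mode, share
one SS type across segments. IASS ⊆ IESS ⊆ all keys as multisets, per
structure. The default amino-acid grouping merges {S,T}, {D,E}, {N,Q},
{K,R}, {I,L,V}, {F,Y,W} — chemically conservative substitution groups,
of which Ser/Thr is the canonical example — each group labeled by its
smallest member label; the table is fully user-overridable.

## Synthetic data

Fixtures generate: ideal α-helix traces (rise 1.5 Å, 100°/residue,
radius 2.3 Å, consecutive Cα ≈ 3.83 Å), extended strand zigzags
(3.3 Å axial step, ±0.95 Å offset), and self-avoiding random-walk
coils (3.8 Å virtual bonds, 3.0 Å clash cutoff) with i.i.d. uniform
random sequences; transformations cover Gaussian perturbation,
x-negation, random rigid motion, N-terminal block rearrangement and
rigid 3-residue motif planting with uniform jitter. For motif
experiments, `stable_motif_geometry` picks the widest Theta and MaxDist
bins of a scheme (within physical ranges) and places the motif at their
midpoints, mirroring how a real recurring motif is only detectable as a
shared key when its geometry is not straddling a bin edge.

These fixtures reproduce realistic Cα spacing and triangle-geometry
distributions but not side-chain packing, hydrogen bonding, loop
closure, or evolutionary sequence conservation. Passing tests
demonstrate the representation's algebraic and geometric contracts,
discrimination of idealized folds, and motif recoverability — not
classification accuracy on real PDB families, which additionally
depends on the label table and boundaries used.

## Verification scales and numerical choices

The test suite and `scripts/acceptance.py` use: the full
29·35·23³ = 12 349 505-code digit space for bijectivity; 10⁵ random
triangles against an independent vector-angle oracle (agreement to
10⁻⁹ degrees; the two arccos formulations differ only in rounding);
100 structures of 12 residues for invariance batches; chains of 3..50
residues for triangle conservation; 1000 random vector pairs against a
`collections.Counter` multiset oracle; 500 pairs for coarsening
monotonicity; 10 + 10 structures of 20 residues for motif planting;
and 6 + 6 chains of 25 residues for two-family clustering. These sizes
exercise every code path at full combinatorial coverage where the
property is exact, and at sample sizes chosen to keep the whole
verification run in well under a minute of compute.

Degenerate-input policy: < 3 residues is an error; all-degenerate
triangle sets give an empty vector (comparing two empty vectors is an
error); negative values cannot be binned; non-finite coordinates are
rejected at construction.

## Known limitations

- Absolute key integers depend on the label table and boundaries;
  published key values from other implementations are reproducible only
  with their exact mapping and cuts, which are not public.
- Keys are blind to improper isometries: a structure and its mirror
  image are indistinguishable even in mirror mode, which separates
  supplementary-angle triangle pairs, not reflected structures.
- Key 0 (all digits 1) cannot carry a mirror sign; with the default
  label table (labels ≥ 4) it never occurs.
- k-means on a distance matrix runs on an MDS embedding (k-means needs
  coordinates), so its partitions inherit MDS seed sensitivity; average
  linkage is fully deterministic.
- The discretization survey can return different selections on samples
  with heavy ties, where several bin counts are infeasible or
  variance-degenerate.
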