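# Methods

## Pipeline and assumptions

The toolkit classifies the shape of a *single isolated molecule*, never the
periodic packing.  From a CIF the asymmetric-unit content is taken as-is (no
symmetry expansion); bonds are perceived from Cordero covalent radii with a
0.4 Å tolerance; only the heaviest bonded component is kept (this removes
solvent, counter-ions and duplicate cages, and incidentally most disorder);
fully linear molecules — no cycle in the bond graph — are dropped, since a
molecule without a closed path can enclose neither window nor cavity.
Missing hydrogens are only *flagged* (C/N/O atoms below single-bond
valence); the flag over-reports on unsaturated systems by construction and
is meant for triage.  Hydrogen presence is immaterial downstream: at the
filtration scale used, H atoms sit well inside existing simplices.

Coordinates enter the filtration in one of two modes.  `as_stored`
reproduces the reference pipeline literally: fractional coordinates are
used raw, with plain Euclidean distance in fractional space and no
cell-metric correction.  For oblique cells this distance is not the physical
one; the alternative `normalized_cartesian` mode converts through the cell
and rescales the bounding-box diagonal to 1 so the same defaults apply.  A
molecule wrapped across a cell boundary would distort fractional distances;
the reader warns when any bonded pair is more than 0.5 apart along a
fractional axis rather than guessing an unwrap.

## Persistence computation

Simplices are built to dimension 3 (the minimum needed for B2 deaths) at
filtration value equal to their diameter; ties are broken lexicographically
for platform-independent determinism.  Coefficients are GF(2).  The pairing
is computed by reducing each dimension's *coboundary* matrix with the
clearing optimisation — the persistent-cohomology route, which produces the
identical pairing to classic boundary-matrix reduction but avoids the
zero-column reductions that dominate Rips complexes; dimension-0 pairs come
from a union-find sweep.  Columns are stored as Python integers used as
bitsets, so column addition is a single word-parallel XOR.  A literal
global boundary-matrix reduction (`cagetda.reference`) is kept as an
independent oracle and the test suite requires exact agreement on random
clouds.

The one surviving component per connected cloud (and any 1-/2-cycle that
never dies below the scale cap) is an *essential* class: its death is
recorded as `max_edge_length` and flagged, so the cap is reversible.
Essential features then participate in landscapes like ordinary features —
dropping them would discard exactly the long-lived signal the method is
after.  Zero-persistence pairs are discarded.  `betti_at` recomputes Betti
numbers from GF(2) boundary ranks of the sublevel complex, a second
independent route used for consistency checks; it is exponential-ish in
complex size and intended for small inputs.

## Landscape sampling

The 2500 samples per homology dimension decompose as 5 levels × 500 uniform
grid points on [0, max_edge_length]; both factors are configuration keys
constrained to multiply to 2500.  Few levels carry nearly all variance in
practice — molecular diagrams rarely have more than a handful of
simultaneously alive persistent features — and a fixed grid (rather than a
data-dependent one) keeps fingerprints of different structures directly
comparable.

## Bottleneck distance and noise removal

The bottleneck distance is exact: binary search over the finite candidate
set (all cross sup-norm distances plus all diagonal projection costs) with
a bipartite perfect-matching feasibility test per candidate.  "Similar by
95 %" is made precise as 1 − d_B/max_edge_length ≥ 0.95, with d_B the
maximum of the dimension-1 and dimension-2 distances — max_edge_length is
the pipeline's only natural scale, and matching features across homology
dimensions would be meaningless.  At defaults this removes candidates
within d_B ≤ 0.04 of any archetype.  Three grid archetypes ship with the
package (single 4×4 grid, four stacked grids, a denser 5×5 lattice),
mirroring the single-grid / quadruple-grid / extended-lattice motifs that
pollute cage candidate sets; by diagram stability, clouds jittered by ≤ ε
stay within 2ε in bottleneck distance, so near-clones of an archetype are
removed robustly.

## Clustering and the purity rule

Ward linkage on raw (unstandardised) Euclidean fingerprint distances, via
SciPy's agglomerative implementation; a brute-force minimal-variance-
increase agglomeration in `cagetda.reference` serves as the oracle.  Cut
selection is deliberately manual (a cluster count or a height), mirroring
the dendrogram-inspection workflow the method is designed around; re-running
the clustering on one branch's members supports the "zoom" refinement.  The
purity rule uses strict inequalities — exactly 40 % or 60 % stays
unclassified — and the accuracy report counts correct members of classified
clusters, with true cages inside non-cage clusters listed as false
negatives.

## Supervised protocol

A 100-tree random forest (library defaults otherwise) on an 85/15 split.
The split is stratified — a deliberate tightening of the plain random
split, protecting the minority class in small fixture populations — and
both overall and class-balanced held-out accuracies are recorded.  The
decision threshold is the majority vote; no calibration.  Models persist
via joblib with a JSON metadata sidecar and reload with bit-identical
decision behaviour.

## Synthetic study population

Fixtures live in the unit box so the production scale applies unchanged.
Defaults per family: ring 24 points at radius 0.3 (B1 feature born near the
point spacing, dead at √3 × radius ≈ 0.52); hollow Fibonacci sphere of 36
points at radius 0.3 (B2 from shell closure ≈ 0.25 to diameter 0.6);
polyhedral cages (tetrahedron/cube/octahedron/dodecahedron, default
octahedron with edge midpoints, 18 points); hemisphere bowl (24); planar
4×4 grid at 0.2 spacing; 10-point chain.  Gaussian jitter sigma defaults to
0.01 — about 3 % of the shape radius, comparable to coordinate scatter in
real fractional data.  Point counts were sized so one cloud's persistence
costs well under a second on a single core; the end-to-end study population
used by the tests and the acceptance script is 300 shapes (60 per family,
excluding bowls, whose open cavity intentionally straddles the cage/ring
boundary).  The coarse labels map spheres and polyhedra to *cage*, rings to
*ring*, and bowls/grids/chains to *non_cage*; the binary classifier merges
cage+ring into the positive class, matching the convention that both 2D and
3D cages belong in the mined dataset.

What the fixtures do **not** emulate: chemically realistic bond-length
geometry, element diversity, partial occupancy/disorder, or the long tail
of ambiguous in-between shapes in real databases.  Passing the synthetic
separation tests therefore demonstrates that the machinery is correct and
that the fingerprint separates idealised shape classes — not that real-data
accuracy matches the synthetic one.

## Screening conventions

Selectivity uses a 20/80 Xe/Kr bulk mixture at 298 K (uptakes arrive as
data; adsorption simulation is out of scope).  The 1–10 selectivity band is
read as the closed interval; zero Kr uptake yields an infinite-selectivity
sentinel with a warning (near-zero Kr uptake is a known variance inflator),
and both-zero records are excluded with a warning.  Per-cluster boxplot
statistics cover only structures with s > 10, with Tukey 1.5×IQR outliers
listed separately — the outlier convention is an explicit assumption.

## Known limitations

* Raw fractional distances ignore the cell metric in `as_stored` mode (by
  design, for fidelity); use `normalized_cartesian` when correctness in Å
  matters.
* The missing-hydrogen heuristic false-positives on all unsaturated atoms.
* Exact bottleneck matching is O(n² · matching) per candidate cost — fine
  for molecular diagrams (tens of features), not for thousands of features.
* `betti_at` and everything in `cagetda.reference` are validation tools,
  not production paths.
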