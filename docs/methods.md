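# Methods

This document records the mathematical conventions used throughout
`latticecluster`: the lattice representations, the reduction algorithms,
the distance metric and its calibration, the Bravais sort subspaces, the
clustering rules, and the synthetic data generator.

## 1. Cell representations

### Unit cells and bases

A `UnitCell` is the parameter tuple (a, b, c, α, β, γ). Validity
requires positive edges, angles in (0°, 180°), each angle smaller than
the sum of the other two, angle sum below 360°, and positive cell
volume. `cell_basis` realizes a cell as a row-basis matrix B (each row
one lattice vector) with the conventional orientation (a along x, b in
the xy plane); `basis_to_cell` inverts it.

### Centering

`CenteredCell` pairs a conventional cell with a centering symbol
P, A, B, C, I, F, R or H. `primitive_from_centered` applies a fixed
row transform M (primitive rows = M · conventional rows, det M > 0):

| symbol | volume divisor | transform (rows) |
|---|---|---|
| P | 1 | identity |
| A | 2 | [[1,0,0],[0,½,½],[0,−½,½]] |
| B | 2 | [[½,0,½],[0,1,0],[−½,0,½]] |
| C | 2 | [[½,½,0],[−½,½,0],[0,0,1]] |
| I | 2 | ½[[−1,1,1],[1,−1,1],[1,1,−1]] |
| F | 4 | ½[[0,1,1],[1,0,1],[1,1,0]] |
| H | 3 | [[⅔,⅓,⅓],[−⅓,⅓,⅓],[−⅓,−⅔,⅓]] (obverse) |
| R | 1 or 3 | see below |

Crystallographic usage writes rhombohedral space groups ("R 3 2") for
cells in either the rhombohedral setting (a=b=c, α=β=γ) or the
hexagonal setting (γ=120°, α=β=90°). `primitive_from_centered`
disambiguates the symbol R by the angle signature: a hexagonal-setting
cell is treated as H-centered (divisor 3), a rhombohedral-setting cell
is already primitive (divisor 1).

### Niggli reduction

`niggli_reduce` implements the Krivý–Gruber algorithm on the G6 vector
(a², b², c², 2b·c, 2a·c, 2a·b), with:

- an explicitly tracked row basis: each step's integer matrix is
  accumulated into a det +1 transform, and the G6 vector is recomputed
  numerically from the transformed basis after every step (this keeps
  the vector and the basis exactly consistent and avoids drift);
- relative tolerance ε = 10⁻⁵ · max(g₁, g₂, g₃);
- the standard eight steps, including the sign-classification steps
  with the deferred-index rule when the product of nonzero signs is
  negative;
- an iteration cap (1000) guarding against cycling; hitting it raises
  `ReductionError`.

The result carries the reduced cell and the accumulated unimodular
transform. Reduction is idempotent, volume-preserving, and invariant
under unimodular relabelings of the input basis (tested against an
independent implementation).

## 2. The S6 / Selling representation

For a primitive cell with basis vectors **a**, **b**, **c** define the
fourth Selling vector **d** = −(**a**+**b**+**c**). The S6 vector is
the six pairwise dot products

s = (b·c, a·c, a·b, a·d, b·d, c·d),

in units of Å². A lattice basis is *Selling-reduced* when all six
scalars are ≤ 0; `selling_reduce` repeatedly applies the boundary
exchange operator of the most positive scalar until reduction (the
exchange operators are exact 6×6 integer matrices acting on S6).

The tetrad {**a**, **b**, **c**, **d**} can be permuted arbitrarily
without changing the lattice; the 24 permutations of S4 act on S6 as
coordinate permutations (`P24`). Together with the 12 boundary-exchange
matrices these generate the lattice-preserving moves used by the metric.

## 3. The CS6Dist metric and its calibration

`cs6dist_raw(c1, c2)` is computed as follows:

1. Selling-reduce both cells' S6 vectors (after Niggli reduction of the
   input cells).
2. Build the candidate image stack of one argument:
   {T·g·s : g ∈ P24, T ∈ {I} ∪ {Rᵢ·Mⱼ : boundary exchanges with i ≠ j}},
   deduplicated (744 integer matrices). The composite operators
   Rᵢ·Mⱼ represent one reflection step followed by one exchange step —
   a first-order approximation of the boundary-crossing paths of the
   full S6 quotient space. Plain one-exchange images are *not*
   included; empirically they undershoot distances across reduction
   boundaries.
3. The raw distance is the minimum Euclidean S6 distance (Å²) over the
   candidate stack, minimized over both argument orders.

The reported metric is calibrated as

`cs6dist = 0.1 · sqrt(cs6dist_raw)`,

which maps the quadratic Å² scale to a length-like scale. On this
scale the metric reproduces the published 6×6 distance table of the
six-lysozyme worked example to ±0.01, satisfies the metric axioms
(symmetry, identity of equivalent lattices, triangle inequality —
the square-root compression makes the candidate-set approximation an
honest metric even for widely separated lattices), and is continuous
under small perturbations across reduction boundaries.

## 4. Bravais-character fitting

Each of the 14 Bravais characters is encoded as one or more exact
linear subspaces of S6 (Delone sorts). The sort forms were derived
symbolically by Selling-reducing the primitive cell of each character's
conventional parameterization; for example:

- **cP** (primitive cubic, edge a): s = (0, 0, 0, −a², −a², −a²).
- **cF**: s = (−a²/2)·(1, 1, 0, 0, 1, 1) pattern on the reduced tetrad.
- **hR** (rhombohedral a, cos α = x): s = (a²x, a²x, a²x, −a²(1+2x)/… )
  family, two distinct sorts for acute and obtuse α.
- **tP**, **tI**, **hP**, **oP/oC/oF/oI**, **mP/mC**: analogous one- to
  four-parameter subspaces (20 sorts in total, several characters need
  more than one sort to cover their reduction branches).

Fitting a character to a cell:

1. enumerate the cell's reduced S6 vector images under
   {I} ∪ exchanges composed with P24 (~312 operators);
2. orthogonally project each image onto each sort subspace, rank by
   residual, extract conventional parameters from the best projections;
3. rebuild the fitted lattice from the extracted parameters and measure
   its calibrated CS6Dist to the input ("rebuild and measure": the
   reported distance is always a true metric distance to a realizable
   lattice, never a subspace-projection norm, which keeps reported
   values honest even when a projection falls outside the character's
   validity region);
4. polish the best candidate with a Nelder–Mead minimization over the
   sort's free parameters.

`closest_bravais(cell, char)` takes the minimum over the character's
own sorts *and all its exact specializations* (a cubic lattice is a
valid tetragonal fit, etc.; the specialization table is transitively
closed), which makes the symmetry hierarchy monotone by construction:
d(aP) ≤ d(mP) ≤ d(oP) ≤ d(tP) ≤ d(cP) along any specialization chain.
When a specialization wins, the winning lattice is re-expressed in the
requested character's conventional setting. Rhombohedral fits are
reported in the hexagonal setting via a_hex = √(2a²(1−cos α)),
c_hex = √(3a²(1+2cos α)).

A fit is flagged `consistent` when its distance is within the tolerance
(default 0.2 on the calibrated scale). `best_bravais` fits all 14
characters and sorts by descending lattice-symmetry order, then
distance.

Note on nearly-rhombohedral cells: because the reported distance is
the genuine metric distance to the rebuilt closest lattice, it can be
substantially smaller than distance-like quantities computed by other
conventions (e.g. projection norms in other coordinate systems, or
unreduced-representation differences). For the C-centered monoclinic
cell of the worked example, the closest hR lattice is ~0.11 away on
the calibrated scale; see the project's decision record for the full
numerical comparison against the historically printed value.

## 5. Metric-space clustering

All clustering operates on a precomputed distance matrix; lattices are
never averaged (they do not form a linear space), so every
representative is a medoid and "k-means" is implemented strictly as
k-medoids.

- `hierarchical`: scipy agglomerative linkage (single / average /
  complete; default average — robust against the chaining that single
  linkage shows on elongated polymorph clouds).
- `slice_dendrogram(level)`: connected components of merges at or below
  the level; clusters are relabeled by first appearance and each
  cluster's medoid is its min-sum member (ties → lowest index).
- `Dendrogram.largest_gap_level(min_gap)`: cut in the middle of the
  largest gap between consecutive merge heights; when no gap exceeds
  `min_gap` the level returned is above the top merge (one cluster) —
  an undistinguished merge sequence is no evidence for structure.
- `kmedoids(k, seeds, restarts, rng_seed)`: Voronoi iteration with
  seeded restarts; a start that produces an empty cluster is discarded;
  the best objective over all restarts wins. `seeds_from_slice` supplies
  dendrogram-slice medoids as seeds.
- `designate_centroid(n_dim, rng_seed)`: draw a random start item, pick
  `n_dim` landmarks by farthest-point (max–min) sampling, return the
  item minimizing the sum of distances to the landmarks.
- `estimate_dimension`: least-squares slope of log(count within radius)
  vs log(radius) on a geometric grid between the 5th and 95th distance
  percentiles, fitted where 3 ≤ count ≤ 0.9 n. Recovers the dimension
  of uniform Euclidean point clouds within ±0.5 for d ≤ 3.

## 6. Reflection handling

- `ReflectionSet`: unique Friedel-canonical (h, k, l) records with
  intensity and σ > 0, a cell, and a resolution limit.
- `unique_reflections(cell, d_min)`: triclinic Friedel-unique
  enumeration via the reciprocal metric tensor; the canonical
  representative has h > 0, or h = 0 and k > 0, or h = k = 0 and l > 0.
- `merge`: inverse-variance weighting, I = Σ(Iᵢ/σᵢ²)/Σ(1/σᵢ²),
  σ = (Σ1/σᵢ²)^(−1/2); associative; the merged set carries the min-sum
  medoid cell of the inputs; by default the inputs' cells must be
  within a compatibility distance (2.0) unless the caller opts out.
- `completeness`: observed fraction of the theoretical unique set.
- `pearson_cc(a, b, min_common=20)`: Pearson correlation over the
  common index set; undefined (None) below `min_common` common
  reflections or at zero variance.
- `cc_distance_matrix`: d = √(1 − cc) ∈ [0, √2]; undefined pairs are
  filled with the maximum defined distance and returned as a flagged
  list. This distance is not guaranteed to satisfy the triangle
  inequality and is used only within a lattice cluster.
- `spot_filter(images, min_spots)`: images with too few spots or
  without an indexing solution go to the discard cluster.

## 7. The two-stage pipeline

`run_two_stage(images, cfg)`:

1. **Stage 0** — spot filter; discarded images are reported separately
   and never clustered.
2. **Stage 1** — lattice clustering: distance matrix on primitive
   reduced cells, average-linkage dendrogram, then *bottom-up growth
   along the merge order until each cluster reaches the target merging
   completeness* (default 0.7): a merge is accepted while either side
   is still below target; merging two already-satisfied clusters is
   refused. This implements "stop building lattice clusters at
   minimally acceptable completeness" — growing further only risks
   mixing polymorphs without improving the merged data. A fixed
   `slice_level` overrides the growth rule; without reflection data the
   largest-gap slice is used instead.
3. **Stage 2** — within each lattice cluster, a CC-derived distance
   matrix over the members' reflection sets is clustered and sliced at
   the largest gap exceeding `stage2_min_gap` (default 0.15); members
   without reflections stay in sub-cluster 0. Composite labels are
   "s1.s2".
4. Outputs (when `out_dir` is set): `assignments.tsv` (id, cluster,
   is_medoid; discarded images labeled `discard`), `run.log` (the full
   configuration echoed sorted, plus per-stage records — no timestamps,
   so reruns are byte-identical), `dendrogram.nwk`, and `purity.tsv`
   when truth labels are supplied.

Purity of a clustering against truth labels is size-weighted
majority-species purity; the discard cluster is excluded.

## 8. Synthetic ensembles

`generate(EnsembleSpec)` draws, per species, a log-normal true-intensity
profile over the species' unique index set (seeded by (seed,
species-index) so profiles are independent of the image stream), then
per image: a junk draw (junk images get few spots, and half of them a
cell but never reflections), a species draw, a jittered cell (Gaussian
jitter on the six parameters, redrawn up to 100 times to stay a valid
cell), a subsample of the index set at the requested completeness
(reflections pushed past the resolution limit by the jitter are
dropped), multiplicative log-normal intensity noise, and σ =
max(noise·I, 10⁻⁶). Identical specs produce byte-identical fixtures.
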