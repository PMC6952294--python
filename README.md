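# latticecluster

Clustering of crystallographic unit cells for serial and high data-rate
macromolecular crystallography.

Serial crystallography experiments produce thousands of diffraction
snapshots, each with its own indexed unit cell. Before merging, the
images must be grouped into clusters that correspond to distinct crystal
forms (polymorphs). Simple approaches — comparing the six cell
parameters directly, or pre-sorting by assigned space group — fail in
well-documented ways: nearly identical lattices can be indexed in
different space groups or in different (but equivalent) cell settings,
and cell parameters do not form a vector space.

`latticecluster` implements the clustering workflow recommended for this
problem:

1. **Reduce** every cell to a canonical primitive form (centered-to-
   primitive conversion, then Niggli reduction) so that equivalent
   lattices get identical coordinates.
2. **Measure** lattice distances with a Selling/S6-based metric
   (`cs6dist`) that is continuous across reduction boundaries: tiny
   physical perturbations always give tiny distances, even when they
   flip the reduced-cell representation.
3. **Identify** the closest Bravais lattice of each form (all 14
   characters, e.g. the closest rhombohedral lattice of an
   almost-rhombohedral C-centered monoclinic cell).
4. **Cluster** hierarchically in the metric, growing lattice clusters
   only until a target merging completeness is reached, then split each
   lattice cluster by reflection-intensity correlation (two-stage
   clustering). This separates polymorphs that share the same lattice
   but differ in content.

A seeded synthetic polymorph-ensemble generator is included for testing
and benchmarking the pipeline end to end.

## Library quick start

```python
from latticecluster import (
    UnitCell, CenteredCell, primitive_from_centered, niggli_reduce,
    cs6dist, distance_matrix,
)
from latticecluster.bravais import closest_bravais, best_bravais
from latticecluster.cluster import hierarchical, slice_dendrogram

# reduce a published H-centered hexagonal cell to its primitive reduced cell
cc = CenteredCell(UnitCell(80.36, 80.36, 99.44, 90, 90, 120), "H")
prim = niggli_reduce(primitive_from_centered(cc)).cell
# -> (57.02, 57.02, 57.02, 89.605, 89.605, 89.605)

# lattice distance between two cells (calibrated CS6Dist)
d = cs6dist(prim, UnitCell(57.98, 57.98, 57.98, 92.02, 92.02, 92.02))

# closest rhombohedral lattice, reported in the hexagonal setting
fit = closest_bravais(prim, "hR")
fit.fitted_cell, fit.distance, fit.consistent

# cluster a list of cells
dm = distance_matrix([prim, ...], "cs6dist")
dg = hierarchical(dm, "average")
assignment = slice_dendrogram(dg, dg.largest_gap_level(), dm)
```

Two-stage pipeline on a manifest of images:

```python
from latticecluster.pipeline import PipelineConfig, run_two_stage
from latticecluster.reflections import read_manifest

images = read_manifest("fixture/manifest.csv")
cfg = PipelineConfig(min_spots=10, d_min=10.0, completeness_target=0.7,
                     out_dir="out")
result = run_two_stage(images, cfg)
result.labels      # image id -> "stage1.stage2" composite cluster label
result.discarded   # image ids in the discard cluster
```

## Command line

```sh
latticecluster reduce cells.csv                  # primitive reduced cells
latticecluster dist cells.csv --out dm.csv       # pairwise lattice distances
latticecluster bravais cells.csv --character hR  # closest Bravais lattices
latticecluster cluster cells.csv --level 1.0     # dendrogram slice
latticecluster cluster cells.csv --kmeans 2      # k-medoids (k-means alias)
latticecluster cc fixture/manifest.csv           # reflection-CC distances
latticecluster run --manifest fixture/manifest.csv --out out/
latticecluster purity out/assignments.tsv fixture/labels.csv
latticecluster simulate --spec spec.yaml --out fixture/
```

`cells.csv` columns: `id,a,b,c,alpha,beta,gamma,centering` (the
centering column accepts a bare symbol or a full space-group string such
as `C 1 2 1`; the leading letter is used). A manifest lists images with
spot counts, cells, and per-image reflection files.

## Determinism

Every stochastic operation takes an explicit seed, ties are broken by
lowest input index, and a pipeline rerun with identical configuration
and inputs produces byte-identical output files.

## Documentation

See `docs/methods.md` for the mathematical conventions: the S6/Selling
representation, the metric's candidate-image set and calibration, the
Bravais sort subspaces, the clustering and completeness-growth rules,
and the synthetic generator's sampling scheme.

## Testing

```sh
python -m pytest
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
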