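# dearray

De-arraying of tissue microarray (TMA) slide thumbnails: segment the tissue
cores of a downsampled whole-slide scan, assign each core its logical
(row, column) grid index with a Delaunay-triangulation traveling algorithm
that is robust to missing cores, grid rotation and stretching, and map the
indices to core names from a TMAMap spreadsheet.

The pipeline has three phases:

1. **Segmentation** — CLAHE contrast enhancement, sharpening with the
   negative of a Laplacian kernel, Otsu thresholding and morphological
   closing; per-object digital convex hulls with a 10 px speck filter;
   broken-core detection by a quartile area/distance rule over Delaunay
   neighbours and centroid-line joining; boundary smoothing with a truncated
   pair of forward/inverse Fourier descriptors; a final 200 px size filter.
2. **Gridding** — Delaunay triangulation over core centroids; edge-length
   filtering (shortest 2/3 plus an upper Tukey fence) and edge-angle
   filtering (5-cluster seeded 1-D k-means, which also estimates the grid
   rotation); the traveling algorithm chains near-horizontal edges
   left-to-right into rows, bridging gaps with sector searches and imaginary
   vertices; rows are sorted and columns aligned by median-residual shift
   matching; post-processing merges collapsed rows, fills gaps, adopts stray
   vertices and trims imaginary borders.
3. **Mapping** — a TMAMap (CSV/XLSX) is re-oriented (8 possible slide
   orientations, user-supplied), names are attached per cell (`U` for
   unoccupied positions, `M` for missing cores, `A` for artefacts) and
   thumbnail coordinates are scaled to the original slide resolution
   (×100 per axis by default).

A built-in simulator (`dearray.pseudo_sim`) generates binary pseudo-slide
thumbnails with ground truth — a 9×14 template of 126 near-circular ~30 px
cores at 50 px pitch, plus five distortion case sets (26 missing-core,
31 rotation, 13 horizontal-stretch, 16 vertical-stretch, 27 mixed;
113 slides in total) used for evaluation.

## CLI

```sh
# de-array one thumbnail with a TMAMap
dearray run --image slide.png --map tmamap.xlsx --orientation R0 --out out/

# generate the 113-case pseudo suite (PNG masks + truth CSVs + manifest)
dearray simulate --suite --seed 1 --out suite/

# score gridding accuracy over a suite (from disk, or regenerated in memory)
dearray eval --suite-dir suite/
dearray eval --seed 1
```

`run` writes `records.csv` (names, logical indices, thumbnail- and
slide-scale bounding boxes), `grid.csv`, a 16-bit labeled mask, an annotated
overlay PNG and a JSON run report. Parameters can be set in a flat
`key = value` config file (`--config`) or overridden per key with
`--param key=value`; unknown keys are rejected.

## Library

```python
import dearray

slide = dearray.make_template(dearray.PseudoSpec(seed=1))
records, grid, report = dearray.run_dearray(slide.render())
print(grid.n_rows, grid.n_cols, report.theta)
```

## Tests

```sh
python -m pytest -q tests/
```

The suite includes brute-force oracles (exhaustive digital-segment closure
for convex hulls, empty-circumcircle checking for the triangulation, a
direct-sum DFT for the boundary descriptors) and `tests/test_acceptance.py`,
which regenerates the full 113-slide pseudo suite and requires 100% gridding
accuracy (a few minutes of runtime).

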