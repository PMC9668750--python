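# perturbmap

Cell-type and spatial prioritization of perturbation responses in
transcriptomics data.

Given expression profiles from two experimental conditions, `perturbmap`
quantifies how transcriptionally separable the conditions are — per cell
type, or per spatial location — as the cross-validated AUC of a random
forest trained to predict the condition label:

- **Cell-type prioritization** (`perturbmap.celltype`): for each cell type,
  repeatedly draw balanced subsamples of cells from both conditions, select
  variable genes, and score a stratified-CV random forest. Fixed-size
  subsampling makes AUCs comparable across cell types of different
  abundance.
- **Spatial prioritization** (`perturbmap.spatial`): for each spatial
  barcode, take its k nearest neighbours from each condition (k = 20 per
  condition by default), score condition separability within that
  neighbourhood by 3-fold CV repeated 50 times, and emit an AUC map over
  the common coordinate system.
- **Simulation** (`perturbmap.simulate`): a Splat-style gamma–Poisson
  simulator that lays a configurable fraction of DE genes (10% by default)
  over 2D spatial intensity patterns (sharp border, linear gradient, radial
  focus, graded foci, ring, null), with full ground truth for validation.
- **Post-processing** (`perturbmap.postprocess`): 2D locally weighted
  (loess) smoothing of AUC maps, recovery scoring against simulation truth,
  and concordance between cell-type and spatial scores.
- **Data model** (`perturbmap.datamodel`): Matrix Market / dense TSV
  readers, positions tables, QC filters (min 200 genes per cell, max 5%
  mitochondrial reads, min 3 cells per gene, min 5,000 UMIs per spatial
  barcode), log1p-CPM normalization, and x-axis mirroring for bilaterally
  symmetric tissues.

The per-neighbourhood classifier is a numba-compiled random forest
specialized for tiny training sets (tests cross-check it against
scikit-learn); this is what makes scoring thousands of barcodes tractable
on one CPU.

## CLI

```sh
# simulate a two-condition spatial dataset with a sharp-border perturbation
perturbmap simulate --pattern half_border --n-barcodes 5000 --n-genes 5000 \
    --de-prob 0.10 --de-fac-loc 1.0 --seed 1 --out sim/

# spatial prioritization (writes barcode, x, y, mean_auc, ... TSV)
perturbmap prioritize-spatial --counts sim/matrix.mtx --positions sim/positions.tsv \
    --condition-a A --condition-b B -k 20 --repeats 50 --seed 7 --out map.tsv

# cell-type prioritization
perturbmap prioritize-celltypes --counts counts.mtx --meta meta.tsv \
    --condition-a control --condition-b treated --out scores.tsv

# smooth a map, evaluate against simulation truth, or run the full
# six-pattern validation
perturbmap smooth --map map.tsv --out smoothed.tsv
perturbmap evaluate --map map.tsv --truth sim/truth_barcodes.tsv --out report.json
perturbmap validate-suite --scaled-down --seed 1 --out validation/
```

Every command writes a `.provenance.json` next to its output recording the
parameters, seed and input hashes. A `--velocity` flag on the prioritize
commands treats the input matrix as RNA velocity (no normalization).

## Input formats

- Counts: Matrix Market triplet (`matrix.mtx` + `features.tsv` +
  `barcodes.tsv`) or dense TSV (genes × barcodes, first column gene IDs).
- Positions: TSV/CSV with header `barcode,x,y,section,condition`.
- Metadata: TSV with `barcode`, `condition`, optional `cell_type`,
  `n_genes_detected`, `mito_fraction`, `n_umis`.
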