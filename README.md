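# voxelparcel

Spatial parcellation of voxel-level gene-expression atlases by
non-negative matrix factorization, with a synthetic-atlas generator for
planted-truth validation.

Registered in-situ-hybridization compendia (such as the Allen Brain
Atlas grid data) quantify "expression energy" for thousands of genes on
a common 3-D voxel grid, giving a non-negative genes × voxels matrix
*A* whose columns are spatially registered but whose analysis is done
entirely in gene space. `voxelparcel` partitions such data into
"genomic territories" — groups of voxels sharing a characteristic
signature expression profile — and extracts the genes that define each
territory. It is aimed at anyone studying the molecular anatomy of a
brain structure (or any spatially mapped tissue) who wants data-driven,
genome-scale subdivisions rather than marker-by-marker histology.

## The method

The core model is the low-rank approximation

&nbsp;&nbsp;&nbsp;&nbsp;**A ≈ W H**,&nbsp;&nbsp;A ∈ ℝ₊^(m×n), W ∈ ℝ₊^(m×s), H ∈ ℝ₊^(s×n)

with *m* genes, *n* voxels, and a small subspace size *s* (the number
of territories). The factorization is computed by alternating least
squares with negative-clamping — per iteration:

1. solve (WᵀW) H = Wᵀ A for H, set negative elements of H to 0;
2. solve (H Hᵀ) Wᵀ = H Aᵀ for W, set negative elements of W to 0;

run for a fixed cap of 1000 iterations (optionally stopping early when
the reconstruction error plateaus), best of several random restarts.
Because NMF weight columns are near-categorical, voxels are clustered
by the argmax over the rows of H, and the cluster labels are registered
back onto the 3-D grid through the voxel lookup table. The columns of W
are sparse signature profiles; ranking genes by their coefficient in a
column yields the defining gene list of that territory.

Around the factorization the package provides:

- **`synthetic_data`** — atlases with planted, spatially contiguous
  domains, per-domain signature genes, gamma/lognormal/truncated-normal
  noise, and paired replicate matrices with controlled per-gene
  reproducibility; every generated atlas ships with its ground truth.
- **`atlas_io`** — the `ExpressionAtlas` container, region/slice/gene
  selection, CSV/HDF5 readers and writers, NRRD label volumes.
- **`qc`** — per-gene cross-replicate Pearson correlation with
  lowest-quartile discard (the "remaining 75%" filter).
- **`factorization`** — ALS-NMF as above.
- **`parcellation`** — argmax clustering, block-diagonal weight
  sorting, per-block polar profiles, basis-vector dendrograms, and
  cluster-recovery evaluation (optimal label matching, accuracy versus
  gene count).
- **`enrichment`** — two-region differential-enrichment screen with a
  k-standard-deviation outlier flag (default 4 SD).
- **`profiles`** — per-cluster rank-ordered gene lists, Hoyer
  sparseness, log-binned profile histograms.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from voxelparcel import (SyntheticAtlasParams, generate_atlas, als_nmf,
                         assign_clusters, best_label_accuracy, rank_genes,
                         sparseness)

params = SyntheticAtlasParams(grid_shape=(12, 12, 4), n_regions=4,
                              n_signature_genes_per_region=10,
                              n_background_genes=80,
                              noise_dispersion=1.0, seed=7)
atlas, truth = generate_atlas(params)
print(f"atlas: {atlas.n_genes} genes x {atlas.n_voxels} voxels")

res = als_nmf(atlas.matrix, s=4, tol=1e-6, seed=0, restarts=5)
print(f"relative error: {res.relative_error:.4f} after {res.iterations_run} iterations")

assignment = assign_clusters(res.H)
ari = adjusted_rand_score(truth.voxel_domain_labels, assignment.labels)
print(f"adjusted Rand index vs planted domains: {ari:.3f}")

print("top 5 genes of cluster 1:", rank_genes(res.W, 1, atlas.gene_ids).top(5))
print(f"sparseness of basis 1: {sparseness(res.W[:, 0]):.3f}")
```

Output:

```
atlas: 120 genes x 576 voxels
relative error: 0.3813 after 20 iterations
adjusted Rand index vs planted domains: 1.000
top 5 genes of cluster 1: ['sig_r2_001', 'sig_r2_007', 'sig_r2_009', 'sig_r2_006', 'sig_r2_004']
sparseness of basis 1: 0.568
```

The atlas plants four block domains of 144 voxels each with ten
signature genes per domain over an 80-gene ubiquitous background, at a
10:1 expression contrast under gamma noise. The s = 4 decomposition
leaves a substantial relative error (the noise floor — NMF is a
denoiser here, not an interpolator) yet the argmax clustering recovers
the planted domains perfectly (adjusted Rand index 1.0), and the top
genes of cluster 1 are exactly members of one planted signature set
(cluster numbering is arbitrary; here cluster 1 recovered domain 2).

The same pipeline is available from the shell:

```bash
voxelparcel simulate --grid 20,20,10 --regions 4 --sig-genes 20 \
    --bg-genes 200 --seed 7 --replicates --out atlas/
voxelparcel qc --replicate-a atlas/replicate_a --replicate-b atlas/replicate_b --out qc.csv
voxelparcel nmf --in atlas/ --s 2..5 --restarts 10 --seed 1 --out nmf/
voxelparcel cluster --in atlas/ --weights nmf/H_s4.csv --out labels.nrrd
voxelparcel profiles --weights nmf/W_s4.csv --out-dir rankings/
voxelparcel enrich --in atlas/ --split-axis x --k-sd 4 --out enrichment.csv
```

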