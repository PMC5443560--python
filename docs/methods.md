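# Methods

## Model and scope

`voxelparcel` treats a spatially registered expression compendium as a
non-negative matrix A (m genes × n voxels) and seeks a rank-s
approximation A ≈ W H with W ≥ 0 (m × s) and H ≥ 0 (s × n). The
interpretation is anatomical: each column of W is a signature
expression profile defining one genomic territory, each column of H
gives a voxel's weights on those profiles, and the parcellation is the
argmax of each weight column. All computation is blind to voxel
position; spatial structure enters only through a lookup table used to
select sub-matrices (named regions, single grid planes) and to paint
cluster labels back into a 3-D volume.

The model's assumptions: expression is non-negative and approximately a
sum of a few non-negative spatial programs; a voxel is dominated by one
program (otherwise the argmax clustering blurs); and the territories of
interest are expressed in a sparse minority of genes over a ubiquitous
background (otherwise W's columns are dense and uninformative as gene
lists).

## ALS-NMF

Each iteration solves the two normal-equation systems
(WᵀW)H = WᵀA and (HHᵀ)Wᵀ = HAᵀ and clamps negative entries of the
just-solved factor to zero. Numerical choices:

- **Solver.** The systems are solved as minimum-norm least-squares
  problems (`lstsq` on the factor itself) rather than by inverting
  WᵀW / HHᵀ: clamping can make a factor rank-deficient, in which case
  the normal equations as written are singular but the least-squares
  step is still well defined.
- **Initialization.** W entries i.i.d. uniform(0, 1) scaled by mean(A).
  Uniform-positive initialization is the conventional ALS default; the
  scaling makes the first H solve well-conditioned across input scales.
- **Stopping.** The default is a fixed cap of 1000 iterations with no
  early stop (`tol = 0`). A tolerance on the absolute change in
  relative reconstruction error between iterations can be set for
  speed; on the synthetic atlases used throughout the tests the error
  plateaus within a few tens of iterations, so validation runs use
  `tol` between 1e-6 and 1e-12, which is indistinguishable from the
  fixed cap at much lower cost.
- **Degeneracy.** ALS can collapse a row of H (or column of W) to
  exactly zero, silently reducing the rank. A collapsed row/column is
  re-seeded once with small positive noise (1e-3 × mean(A)); a second
  collapse in the same run marks that restart degenerate. A run where
  all restarts degenerate is an error, not a silent fallback.
- **Restarts.** ALS is non-convex; `als_nmf` runs 10 independently
  initialized restarts by default and returns the lowest-error one.
  Restart seeds derive deterministically from the master seed, so a
  given (A, s, seed, restarts) is bit-reproducible.

Reconstruction quality is reported as ‖A − WH‖_F / ‖A‖_F.

## Identifiability

Exact NMF is not unique for dense strictly positive factors: if
A = W₀H₀ with W₀, H₀ dense, there is a continuum of invertible Q with
W₀Q ≥ 0 and Q⁻¹H₀ ≥ 0, all giving the same A. In our own validation on
random uniform factors (m = 30, n = 50), runs reaching relative error
~1e-13 still return bases whose worst matched-column cosine against the
planted factors ranges from 0.85 to 0.999; the effect grows with s.
Planted factors are reliably recovered only when the data carry
separable structure — e.g. the synthetic atlases' signature blocks —
which is the regime the method is designed for. Factor comparisons use
cosine similarity after optimal (Hungarian) column matching, which is
invariant to the permutation/positive-rescaling ambiguity that remains
even in the identifiable case.

## Synthetic-atlas generator

The generator emulates the structure of a registered expression-energy
atlas with known ground truth. Defaults define the standard validation
atlas and were fixed once:

| parameter | default | rationale |
|---|---|---|
| grid_shape | 20 × 20 × 10 (2 000 µm-scale voxels, unit = one voxel) | large enough for 4 clearly 3-D domains, small enough for seconds-scale runs |
| n_regions | 4 | a mid-granularity parcellation (s values of interest are 2–7) |
| n_signature_genes_per_region | 20 | sparse signatures: 10% of the gene panel per domain |
| n_background_genes | 200 | background-dominated panel, mimicking near-ubiquitous expression |
| signature_mean / background_mean | 10 / 1 | a 10:1 contrast, a strong but not trivial marker-gene enrichment |
| noise_model | gamma | non-negative by construction; with shape = mean/dispersion the variance is mean × dispersion, Poisson-like |
| noise_dispersion | 1 | variance equal to the mean: per-voxel CV of 1 on background, ~0.3 on signatures |
| replicate_corr_range | (0, 1) | spans unreproducible to perfect genes so the QC filter has signal to find |

Domains default to axis-aligned slabs along the grid's longest axis —
contiguous by construction with analytically known voxel counts. An
optional Voronoi mode grows domains from random seed voxels and is
re-drawn until every cell is 6-connected. Lognormal noise matches the
gamma mean/variance; truncated-normal clips a normal of that variance
at zero, which biases the realized mean slightly upward when
mean²/variance is small (documented, not corrected).

Replicate pairs ("sagittal/coronal") share each gene's deterministic
spatial mean pattern plus a mixture of shared and independent normal
noise, clipped at zero. The mixing weight w solves
ρ = (V_M + w σ²)/(V_M + σ²) per gene, where V_M is the spatial variance
of the mean pattern and σ² the noise variance; w is clamped to [−1, 1]
and the achievable correlation is returned as truth. Clipping at zero
perturbs the induced correlation slightly; the Monte-Carlo tolerance in
the tests (±0.1 on a mean over ≥100 genes) absorbs it.

What the generator does **not** emulate: ISH image formation and
segmentation artifacts, spatial autocorrelation of noise, gene–gene
correlation beyond the planted programs, partial-volume effects at
domain boundaries, and realistic gene identities. Passing tests
therefore demonstrate that the pipeline recovers planted structure of
the assumed form, not that real atlases satisfy those assumptions.

## QC filter

Per-gene Pearson correlation between matched voxels of the two
replicates; genes in the lowest quartile of the correlation
distribution are discarded and the remaining 75% retained. Conventions
the procedure leaves open, fixed here: the cutoff is the empirical 25th
percentile under linear interpolation; ties at the cutoff are retained
(matching "the remaining 75%" at least as closely as discarding them);
genes with zero variance in either replicate have undefined correlation
and are discarded with an explicit `undefined_r` reason. The quartile
is computed over scorable genes only.

## Parcellation and evaluation

- Argmax ties are broken toward the lowest cluster index and flagged;
  all-zero weight columns go to cluster 1 with an `empty` flag.
- The block-diagonal display order groups columns by argmax row
  (ascending) and sorts within a group by descending peak value, via a
  stable sort so exact ties keep input order.
- The basis-vector dendrogram fixes only the distance (Euclidean
  between columns of W); linkage defaults to complete and is
  configurable, as the linkage is a reporting choice.
- Cluster labels are arbitrary, so evaluation against known labels
  first solves the accuracy-maximizing label assignment (Hungarian
  algorithm on the confusion matrix) — exact for the s ≤ 7 regime used
  here, and verified against exhaustive permutation search in tests.
- In the accuracy-versus-gene-count curve, a "perfectly classified
  voxel" is one classified correctly in every repetition at a given
  gene count; the per-repetition accuracies are retained alongside so
  a per-repetition reading can be recomputed.

## Enrichment screen

The screen contrasts per-gene mean expression between two disjoint
voxel sets. The default score is the normalized contrast
(mean_A − mean_B)/(mean_A + mean_B + ε), bounded in [−1, 1],
antisymmetric, and invariant to global rescaling; ε is the smallest
positive double and only guards 0/0. The raw difference is stored
alongside since the bounded and raw conventions order extreme genes
differently when absolute expression varies widely. Flagging is
two-sided: |z| > k SD (default k = 4) of the empirical score
distribution — enriched genes on both sides of zero are reported. The
anterior/posterior style bisection of a region is a half-split at the
coordinate median along a configurable axis; it requires both halves
non-empty and makes no attempt to follow curved anatomical boundaries.

This is a descriptive outlier rule, not an inference procedure: no
multiple-testing control is applied, and the SD is estimated from a
distribution that includes the outliers it flags (with ≥500 genes and
~2% planted asymmetry the inflation is negligible, as the calibration
tests show).

## Profiles

Sparseness is summarized by the Hoyer measure
(√m − ‖w‖₁/‖w‖₂)/(√m − 1): exactly 1 for one-hot, 0 for constant,
scale-invariant. Gene rankings sort by descending coefficient with
lexicographic gene-id tie-break; exports are one CSV per cluster
(rank, gene_id, coefficient) plus a combined file.

## Validation problem sizes

The test suite and acceptance script run on scaled-down instances
chosen to exercise every code path in seconds: exact-factorization
checks at 30 × 50, parcellation recovery on the default 280 × 4000
atlas over 10 seeds (restarts = 3, tol = 1e-6), the accuracy curve on
an 80 × 120 two-domain atlas with 20 repetitions per gene count, and
the enrichment calibration on 510 × 120 atlases. These sizes are the
package's validation conditions, fixed in the acceptance script and
tests.

## Known limitations

- Dense, non-separable data admit many equally good factorizations
  (see Identifiability); cluster boundaries can then vary across seeds.
- The subspace size s is user-chosen; the package reports
  reconstruction error per s but implements no model-selection rule.
- The argmax clustering ignores weight magnitudes below the maximum; a
  voxel with two near-equal weights is assigned, flagged as a tie only
  on exact equality.
- CSV matrix I/O is fixed at 6 significant digits; HDF5 is the
  lossless path.
- The NRRD writer emits ASCII encoding only — human-readable and
  adequate for label volumes, but not for large dense matrices.
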