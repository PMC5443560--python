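"""Synthetic expression atlases with planted spatial domains.

Real voxel-level expression atlases (registered in-situ-hybridization
compendia such as the Allen Brain Atlas grid data) are too large to ship
and carry no ground truth. This module generates small atlases that
emulate their structure while planting a known truth:

* a 3-D labeled voxel grid partitioned into spatially contiguous
  domains (axis-aligned blocks by default, optionally Voronoi cells);
* per-domain *signature* genes whose expected expression is elevated
  inside their domain and at background level elsewhere;
* a large pool of near-ubiquitously expressed *background* genes;
* non-negative noise (gamma by default) around those means;
* paired "sagittal/coronal" replicate matrices with controlled
  per-gene cross-replicate correlation, for testing the replicate-
  consistency QC filter.

Every generated atlas is returned together with a :class:`SyntheticTruth`
recording the planted domain labels and signature-gene memberships, so
downstream parcellation and ranking results can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage

from .atlas_io import ExpressionAtlas, GeneAnnotation, VoxelRecord

NoiseModel = Literal["gamma", "lognormal", "truncated-normal"]
DomainGeometry = Literal["blocks", "voronoi"]

#: 6-neighbor (face) connectivity structure for 3-D grids
SIX_CONNECTIVITY = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class SyntheticAtlasParams:
    """Parameters of the synthetic-atlas generator.

    Defaults describe the standard validation atlas: a 20×20×10 grid
    carved into 4 block domains, 20 signature genes per domain at mean
    expression 10 over a background mean of 1 (a 10:1 contrast), 200
    background genes, and gamma noise with dispersion 1 (variance equal
    to the mean, Poisson-like).
    """

    grid_shape: tuple[int, int, int] = (20, 20, 10)
    n_regions: int = 4
    n_signature_genes_per_region: int = 20
    n_background_genes: int = 200
    signature_mean: float = 10.0
    background_mean: float = 1.0
    noise_model: NoiseModel = "gamma"
    noise_dispersion: float = 1.0
    replicate_corr_range: tuple[float, float] = (0.0, 1.0)
    seed: int = 0
    domain_geometry: DomainGeometry = "blocks"

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(int(s) < 1 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be a positive triple, got {self.grid_shape}")
        if sum(int(s) >= 2 for s in self.grid_shape) == 0:
            raise ValueError("grid_shape needs at least one dimension >= 2")
        for name in ("n_regions", "n_signature_genes_per_region", "n_background_genes"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.signature_mean < 0 or self.background_mean < 0:
            raise ValueError("expression means must be non-negative")
        if self.noise_dispersion < 0:
            raise ValueError("noise_dispersion must be >= 0")
        lo, hi = self.replicate_corr_range
        if not (-1.0 <= lo <= hi <= 1.0):
            raise ValueError(
                "replicate_corr_range must be an ordered pair within [-1, 1], "
                f"got {self.replicate_corr_range}"
            )
        if self.noise_model not in ("gamma", "lognormal", "truncated-normal"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.domain_geometry not in ("blocks", "voronoi"):
            raise ValueError(f"unknown domain_geometry {self.domain_geometry!r}")

    @property
    def n_genes(self) -> int:
        return self.n_regions * self.n_signature_genes_per_region + self.n_background_genes

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a generated atlas.

    ``voxel_domain_labels`` holds one integer in ``1..n_regions`` per
    atlas column (same order); ``signature_gene_map`` maps each domain
    to the set of row indices of its planted signature genes.
    """

    voxel_domain_labels: np.ndarray
    signature_gene_map: dict[int, set[int]]
    params: SyntheticAtlasParams
    label_volume: np.ndarray = field(repr=False, default=None)


# ----------------------------------------------------------------------
# domain geometry
# ----------------------------------------------------------------------

def _block_domains(params: SyntheticAtlasParams) -> np.ndarray:
    """Partition the grid into contiguous slabs along its longest axis."""
    shape = params.grid_shape
    k = params.n_regions
    axis = int(np.argmax(shape))
    extent = shape[axis]
    if extent < k:
        raise ValueError(
            f"grid {shape} cannot host {k} block domains: longest axis has "
            f"only {extent} voxels"
        )
    # slab boundaries as equal as possible
    edges = np.linspace(0, extent, k + 1).round().astype(int)
    volume = np.zeros(shape, dtype=np.int32)
    idx = np.arange(extent)
    slab_of = np.searchsorted(edges[1:], idx, side="right") + 1
    shape_b = [1, 1, 1]
    shape_b[axis] = extent
    volume += slab_of.reshape(shape_b)
    return volume


def _voronoi_domains(params: SyntheticAtlasParams, rng: np.random.Generator) -> np.ndarray:
    """Nearest-center partition from random seed voxels; retried until
    every cell is 6-connected."""
    shape = params.grid_shape
    k = params.n_regions
    if params.n_voxels < k:
        raise ValueError(f"grid {shape} has fewer voxels than domains ({k})")
    grid = np.indices(shape).reshape(3, -1).T  # (n, 3)
    for _ in range(50):
        centers = grid[rng.choice(len(grid), size=k, replace=False)]
        d2 = ((grid[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1).astype(np.int32) + 1
        volume = labels.reshape(shape)
        if len(np.unique(labels)) == k and all(
            domain_is_connected(volume, r) for r in range(1, k + 1)
        ):
            return volume
    raise ValueError(
        f"failed to place {k} connected Voronoi domains on grid {shape} "
        "after 50 attempts"
    )


def domain_is_connected(label_volume: np.ndarray, region: int) -> bool:
    """True if the voxels labeled ``region`` form one 6-connected component."""
    mask = label_volume == region
    if not mask.any():
        return False
    _, n_comp = ndimage.label(mask, structure=SIX_CONNECTIVITY)
    return n_comp == 1


# ----------------------------------------------------------------------
# noise
# ----------------------------------------------------------------------

def _sample_noise(
    mean: np.ndarray, model: NoiseModel, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw non-negative values with the given elementwise expectation.

    Under ``gamma`` and ``lognormal`` the variance is ``dispersion * mean``
    exactly; ``truncated-normal`` clips a normal of that variance at zero,
    which biases the realized mean slightly upward for low mean/dispersion
    ratios. Zero-mean entries and ``dispersion == 0`` are returned exactly.
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return mean.copy()
    out = np.zeros_like(mean)
    pos = mean > 0
    m = mean[pos]
    if model == "gamma":
        # shape k = m/dispersion, scale = dispersion -> E = m, Var = m*dispersion
        out[pos] = rng.gamma(shape=m / dispersion, scale=dispersion)
    elif model == "lognormal":
        sigma2 = np.log1p(dispersion / m)
        out[pos] = rng.lognormal(mean=np.log(m) - sigma2 / 2, sigma=np.sqrt(sigma2))
    elif model == "truncated-normal":
        out[pos] = np.clip(rng.normal(loc=m, scale=np.sqrt(dispersion * m)), 0, None)
    else:  # pragma: no cover - validated upstream
        raise ValueError(model)
    return out


# ----------------------------------------------------------------------
# atlas assembly
# ----------------------------------------------------------------------

def _mean_matrix(params: SyntheticAtlasParams, labels: np.ndarray) -> tuple[np.ndarray, dict[int, set[int]], list[GeneAnnotation]]:
    """Expected-expression matrix, signature map, and gene annotations."""
    k = params.n_regions
    nsig = params.n_signature_genes_per_region
    genes: list[GeneAnnotation] = []
    sig_map: dict[int, set[int]] = {}
    M = np.full((params.n_genes, labels.size), params.background_mean, dtype=float)
    row = 0
    for r in range(1, k + 1):
        members = set()
        in_domain = labels == r
        for j in range(nsig):
            genes.append(GeneAnnotation(gene_id=f"sig_r{r}_{j:03d}", symbol=f"Sig{r}.{j}"))
            M[row, in_domain] = params.signature_mean
            members.add(row)
            row += 1
        sig_map[r] = members
    for j in range(params.n_background_genes):
        genes.append(GeneAnnotation(gene_id=f"bg_{j:04d}", symbol=f"Bg{j}"))
        row += 1
    return M, sig_map, genes


def _make_lookup(params: SyntheticAtlasParams, labels: np.ndarray) -> list[VoxelRecord]:
    coords = np.indices(params.grid_shape).reshape(3, -1).T
    width = len(str(labels.size))
    return [
        VoxelRecord(
            voxel_id=f"v{j:0{width}d}",
            coord=(int(x), int(y), int(z)),
            region_label=f"domain_{labels[j]}",
        )
        for j, (x, y, z) in enumerate(coords)
    ]


def plant_domains(params: SyntheticAtlasParams, rng: np.random.Generator | None = None) -> np.ndarray:
    """Return the 3-D integer label volume of the planted domains."""
    if params.domain_geometry == "blocks":
        return _block_domains(params)
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    return _voronoi_domains(params, rng)


def generate_atlas(params: SyntheticAtlasParams) -> tuple[ExpressionAtlas, SyntheticTruth]:
    """Generate one noisy expression atlas with planted domains.

    Returns the atlas (genes ordered signature-first, grouped by domain,
    then background; voxels in C order over the grid) and the matching
    :class:`SyntheticTruth`. Identical ``params`` (including ``seed``)
    give bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    volume = plant_domains(params, rng)
    labels = volume.ravel(order="C")
    M, sig_map, genes = _mean_matrix(params, labels)
    A = _sample_noise(M, params.noise_model, params.noise_dispersion, rng)
    atlas = ExpressionAtlas(
        matrix=A,
        genes=genes,
        lookup=_make_lookup(params, labels),
        grid_shape=params.grid_shape,
    )
    truth = SyntheticTruth(
        voxel_domain_labels=labels.astype(int),
        signature_gene_map=sig_map,
        params=params,
        label_volume=volume,
    )
    return atlas, truth


# ----------------------------------------------------------------------
# replicate pairs for the QC filter
# ----------------------------------------------------------------------

def generate_replicate_pair(
    params: SyntheticAtlasParams,
) -> tuple[ExpressionAtlas, ExpressionAtlas, np.ndarray]:
    """Two replicate atlases with controlled per-gene reproducibility.

    Emulates paired sagittal/coronal acquisitions of the same grid: each
    gene's two replicates share its spatial mean pattern plus a mixture
    of shared and independent noise. The mixing weight is solved per
    gene so the population Pearson correlation across voxels equals a
    target drawn uniformly from ``params.replicate_corr_range``; where
    the target is unattainable for a gene (its deterministic spatial
    pattern already fixes a correlation floor/ceiling) the weight is
    clamped and the achievable value is reported instead.

    Returns ``(replicate_a, replicate_b, true_corr)`` where
    ``true_corr[g]`` is the induced population correlation for gene
    ``g``; genes whose correlation is undefined (zero signal and noise
    variance) carry ``NaN``.

    Noise here is normal, clipped at zero after mixing: clipping keeps
    the expression non-negative and perturbs the induced correlations
    only slightly at the default mean/dispersion settings.
    """
    rng = np.random.default_rng(params.seed)
    volume = plant_domains(params, rng)
    labels = volume.ravel(order="C")
    M, _, genes = _mean_matrix(params, labels)
    n = labels.size

    lo, hi = params.replicate_corr_range
    targets = rng.uniform(lo, hi, size=M.shape[0]) if hi > lo else np.full(M.shape[0], lo)

    sigma2 = params.noise_dispersion * M.mean(axis=1)  # per-gene noise variance
    v_signal = M.var(axis=1)  # deterministic spatial variance

    A = np.empty_like(M)
    B = np.empty_like(M)
    true_corr = np.empty(M.shape[0])
    for g in range(M.shape[0]):
        s2, vm, rho = sigma2[g], v_signal[g], targets[g]
        if s2 == 0:
            A[g] = M[g]
            B[g] = M[g]
            true_corr[g] = 1.0 if vm > 0 else np.nan
            continue
        # corr(Xa, Xb) = (vm + w*s2) / (vm + s2); solve for w, clamp to [-1, 1]
        w = np.clip((rho * (vm + s2) - vm) / s2, -1.0, 1.0)
        true_corr[g] = (vm + w * s2) / (vm + s2)
        shared = rng.standard_normal(n)
        ea = rng.standard_normal(n)
        eb = rng.standard_normal(n)
        aw = np.sqrt(abs(w))
        res = np.sqrt(1.0 - abs(w))
        na = aw * shared + res * ea
        nb = np.sign(w) * aw * shared + res * eb if w != 0 else aw * shared + res * eb
        sd = np.sqrt(s2)
        A[g] = np.clip(M[g] + sd * na, 0, None)
        B[g] = np.clip(M[g] + sd * nb, 0, None)

    lookup = _make_lookup(params, labels)
    atlas_a = ExpressionAtlas(matrix=A, genes=genes, lookup=lookup, grid_shape=params.grid_shape)
    atlas_b = ExpressionAtlas(
        matrix=B, genes=list(genes), lookup=list(lookup), grid_shape=params.grid_shape
    )
    return atlas_a, atlas_b, true_corr


def with_seed(params: SyntheticAtlasParams, seed: int) -> SyntheticAtlasParams:
    """Copy of ``params`` with a different seed."""
    return replace(params, seed=seed)
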