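"""Expression-atlas data model, selection operations, and on-disk formats.

The central container is :class:`ExpressionAtlas`: a non-negative
genes × voxels matrix of "expression energy" together with per-gene
annotations and a voxel lookup table tying each matrix column to an
integer 3-D grid coordinate and an anatomical region label. All matrix
operations downstream (factorization, clustering) work purely in gene
space; the lookup table is what registers results back onto the grid.

Coordinates are 0-based integer grid indices. The physical voxel pitch
(200 µm in the Allen Brain Atlas convention) is metadata only and never
enters any computation.

On-disk formats:

* matrix — CSV/TSV with genes as rows (``gene_id`` index, voxel-ID
  header) at 6 significant digits, or lossless HDF5;
* lookup table — CSV with columns ``voxel_id, x, y, z, region_label``;
* gene table — CSV with columns ``gene_id, symbol, gene_class``;
* label volumes — ASCII NRRD (see :mod:`voxelparcel.nrrd_io`).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import TYPE_CHECKING, Callable, Iterable, Literal

import h5py
import numpy as np
import pandas as pd

from .nrrd_io import read_nrrd, write_nrrd

if TYPE_CHECKING:  # pragma: no cover
    from .parcellation import ClusterAssignment

Axis = Literal["x", "y", "z", 0, 1, 2]

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2, 0: 0, 1: 1, 2: 2}

GENE_CLASSES = ("ion_channel", "gpcr", "other")

#: decimal precision of the CSV matrix writer (significant digits)
CSV_SIG_DIGITS = 6


def _axis_index(axis: Axis) -> int:
    try:
        return _AXIS_INDEX[axis]
    except KeyError:
        raise ValueError(f"axis must be one of x/y/z or 0/1/2, got {axis!r}") from None


@dataclass(frozen=True)
class GeneAnnotation:
    """Identity and optional functional class of one gene."""

    gene_id: str
    symbol: str = ""
    gene_class: str | None = None

    def __post_init__(self):
        if self.gene_class is not None and self.gene_class not in GENE_CLASSES:
            raise ValueError(
                f"gene_class must be one of {GENE_CLASSES} or None, "
                f"got {self.gene_class!r}"
            )


@dataclass(frozen=True)
class VoxelRecord:
    """One voxel: its ID, integer grid coordinate, and region label."""

    voxel_id: str
    coord: tuple[int, int, int]
    region_label: str

    def __post_init__(self):
        if len(self.coord) != 3 or any(c < 0 for c in self.coord):
            raise ValueError(
                f"voxel {self.voxel_id}: coord must be a non-negative integer "
                f"triple, got {self.coord!r}"
            )


@dataclass
class ExpressionAtlas:
    """Non-negative genes × voxels expression matrix with metadata.

    Parameters
    ----------
    matrix
        2-D non-negative float array, one row per gene, one column per
        voxel.
    genes
        Per-row :class:`GeneAnnotation` records; ``gene_id`` must be
        unique.
    lookup
        Per-column :class:`VoxelRecord` records; ``voxel_id`` must be
        unique.
    grid_shape
        Declared extent of the 3-D grid. If omitted, the tight bounding
        box of the lookup coordinates is used.
    """

    matrix: np.ndarray
    genes: list[GeneAnnotation]
    lookup: list[VoxelRecord]
    grid_shape: tuple[int, int, int] | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (genes x voxels)")
        m, n = self.matrix.shape
        if len(self.genes) != m:
            raise ValueError(
                f"matrix has {m} rows but {len(self.genes)} gene annotations"
            )
        if len(self.lookup) != n:
            raise ValueError(
                f"matrix has {n} columns but {len(self.lookup)} voxel records"
            )
        neg = np.argwhere(self.matrix < 0)
        if neg.size:
            i, j = neg[0]
            raise ValueError(
                f"negative expression value {self.matrix[i, j]} for gene "
                f"{self.genes[i].gene_id!r} at voxel {self.lookup[j].voxel_id!r}"
            )
        gene_ids = [g.gene_id for g in self.genes]
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("duplicate gene_id in gene annotations")
        voxel_ids = [v.voxel_id for v in self.lookup]
        if len(set(voxel_ids)) != len(voxel_ids):
            raise ValueError("duplicate voxel_id in lookup table")
        if self.grid_shape is None:
            if n:
                coords = np.array([v.coord for v in self.lookup])
                self.grid_shape = tuple(int(c) + 1 for c in coords.max(axis=0))
            else:
                self.grid_shape = (1, 1, 1)
        else:
            self.grid_shape = tuple(int(s) for s in self.grid_shape)
            for v in self.lookup:
                if any(c >= s for c, s in zip(v.coord, self.grid_shape)):
                    raise ValueError(
                        f"voxel {v.voxel_id} coord {v.coord} outside declared "
                        f"grid {self.grid_shape}"
                    )

    # ------------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    @property
    def voxel_ids(self) -> list[str]:
        return [v.voxel_id for v in self.lookup]

    @property
    def region_labels(self) -> list[str]:
        return [v.region_label for v in self.lookup]

    @property
    def coords(self) -> np.ndarray:
        """(n_voxels, 3) integer coordinate array."""
        return np.array([v.coord for v in self.lookup], dtype=int).reshape(-1, 3)

    def lookup_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "voxel_id": self.voxel_ids,
                "x": [v.coord[0] for v in self.lookup],
                "y": [v.coord[1] for v in self.lookup],
                "z": [v.coord[2] for v in self.lookup],
                "region_label": self.region_labels,
            }
        )

    def gene_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "symbol": [g.symbol for g in self.genes],
                "gene_class": [g.gene_class or "" for g in self.genes],
            }
        )

    # -- column / row subsetting (non-mutating) ------------------------
    def take_voxels(self, idx: Iterable[int]) -> "ExpressionAtlas":
        idx = list(idx)
        return ExpressionAtlas(
            matrix=self.matrix[:, idx].copy(),
            genes=list(self.genes),
            lookup=[self.lookup[i] for i in idx],
            grid_shape=self.grid_shape,
        )

    def take_genes(self, idx: Iterable[int]) -> "ExpressionAtlas":
        idx = list(idx)
        return ExpressionAtlas(
            matrix=self.matrix[idx, :].copy(),
            genes=[self.genes[i] for i in idx],
            lookup=list(self.lookup),
            grid_shape=self.grid_shape,
        )


# ----------------------------------------------------------------------
# selection operations
# ----------------------------------------------------------------------

def select_regions(atlas: ExpressionAtlas, region_labels: Iterable[str]) -> ExpressionAtlas:
    """Sub-atlas of the columns whose region label is in ``region_labels``.

    Labels are matched exactly (case-sensitive); original column order
    is preserved. Raises ``ValueError`` if the selection is empty.
    """
    wanted = set(region_labels)
    idx = [j for j, v in enumerate(atlas.lookup) if v.region_label in wanted]
    if not idx:
        raise ValueError(
            f"no voxels match region labels {sorted(wanted)}; atlas has "
            f"{sorted(set(atlas.region_labels))}"
        )
    return atlas.take_voxels(idx)


def select_slice(atlas: ExpressionAtlas, axis: Axis, index: int) -> ExpressionAtlas:
    """Sub-atlas of the voxels lying in one grid plane (``coord[axis] == index``)."""
    ax = _axis_index(axis)
    if not (0 <= index < atlas.grid_shape[ax]):
        raise ValueError(
            f"slice index {index} out of range for axis {axis!r} "
            f"(grid extent {atlas.grid_shape[ax]})"
        )
    idx = [j for j, v in enumerate(atlas.lookup) if v.coord[ax] == index]
    if not idx:
        raise ValueError(f"no voxels in slice {axis}={index}")
    return atlas.take_voxels(idx)


def select_genes(
    atlas: ExpressionAtlas, predicate: Callable[[GeneAnnotation], bool]
) -> ExpressionAtlas:
    """Row-subset atlas of the genes for which ``predicate`` is true."""
    idx = [i for i, g in enumerate(atlas.genes) if predicate(g)]
    if not idx:
        raise ValueError("gene predicate selected no genes")
    return atlas.take_genes(idx)


# ----------------------------------------------------------------------
# registration back onto the grid
# ----------------------------------------------------------------------

def register_labels(assignment: "ClusterAssignment", atlas: ExpressionAtlas) -> np.ndarray:
    """Paint per-voxel cluster labels into a 3-D integer volume.

    Cluster ``k`` (1-based) maps to voxel value ``k``; grid cells not
    covered by the atlas keep the reserved background value 0.
    """
    labels = np.asarray(assignment.labels)
    if labels.shape[0] != atlas.n_voxels:
        raise ValueError(
            f"assignment covers {labels.shape[0]} voxels but atlas has "
            f"{atlas.n_voxels} columns"
        )
    volume = np.zeros(atlas.grid_shape, dtype=np.int32)
    coords = atlas.coords
    volume[coords[:, 0], coords[:, 1], coords[:, 2]] = labels
    return volume


def write_label_slice_png(
    path: str | os.PathLike, volume: np.ndarray, axis: Axis = "z", index: int = 0
) -> None:
    """Render one plane of a label volume as a PNG image.

    The colormap is fixed by cluster index (tab10, background black), so
    the same cluster keeps the same color across slices and runs.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap

    volume = np.asarray(volume)
    ax_i = _axis_index(axis)
    if not (0 <= index < volume.shape[ax_i]):
        raise ValueError(f"slice index {index} out of range on axis {axis!r}")
    plane = np.take(volume, index, axis=ax_i)
    n_labels = int(volume.max())
    base = plt.get_cmap("tab10")
    colors = ["black"] + [base(k % 10) for k in range(n_labels)]
    cmap = ListedColormap(colors)
    norm = BoundaryNorm(np.arange(-0.5, n_labels + 1), cmap.N)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(plane.T, origin="lower", cmap=cmap, norm=norm, interpolation="nearest")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=100)
    plt.close(fig)


def write_label_volume(path: str | os.PathLike, volume: np.ndarray) -> None:
    write_nrrd(path, np.asarray(volume, dtype=np.int32))


def read_label_volume(path: str | os.PathLike) -> np.ndarray:
    return read_nrrd(path)


# ----------------------------------------------------------------------
# readers / writers
# ----------------------------------------------------------------------

def _sep_for(path: os.PathLike | str) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def write_atlas_csv(
    atlas: ExpressionAtlas,
    matrix_path: str | os.PathLike,
    lookup_path: str | os.PathLike,
    gene_path: str | os.PathLike,
) -> None:
    """Write matrix + lookup + gene tables as CSV/TSV.

    Matrix values are written with :data:`CSV_SIG_DIGITS` significant
    digits; HDF5 is the lossless path.
    """
    sep = _sep_for(matrix_path)
    mat = pd.DataFrame(atlas.matrix, index=atlas.gene_ids, columns=atlas.voxel_ids)
    mat.index.name = "gene_id"
    mat.to_csv(matrix_path, sep=sep, float_format=f"%.{CSV_SIG_DIGITS}g")
    atlas.lookup_frame().to_csv(lookup_path, index=False)
    atlas.gene_frame().to_csv(gene_path, index=False)


def read_atlas(
    matrix_path: str | os.PathLike,
    lookup_path: str | os.PathLike,
    gene_path: str | os.PathLike | None = None,
    grid_shape: tuple[int, int, int] | None = None,
) -> ExpressionAtlas:
    """Read an atlas from CSV/TSV matrix + lookup (+ optional gene) tables.

    The three files must be mutually consistent: one gene row per matrix
    row, one lookup row per matrix column, matching IDs in order.
    Negative matrix entries are a hard error naming the offending gene
    and voxel.
    """
    sep = _sep_for(matrix_path)
    mat = pd.read_csv(matrix_path, sep=sep, index_col=0)
    lut = pd.read_csv(lookup_path, dtype={"voxel_id": str})
    required = {"voxel_id", "x", "y", "z", "region_label"}
    if not required.issubset(lut.columns):
        raise ValueError(
            f"lookup table missing columns {sorted(required - set(lut.columns))}"
        )
    if len(lut) != mat.shape[1]:
        raise ValueError(
            f"dimension mismatch: matrix has {mat.shape[1]} voxel columns but "
            f"lookup table has {len(lut)} rows"
        )
    if list(lut["voxel_id"]) != [str(c) for c in mat.columns]:
        raise ValueError("voxel IDs in matrix header and lookup table disagree")

    if gene_path is not None:
        gdf = pd.read_csv(gene_path, dtype=str).fillna("")
        if len(gdf) != mat.shape[0]:
            raise ValueError(
                f"dimension mismatch: matrix has {mat.shape[0]} gene rows but "
                f"gene table has {len(gdf)} rows"
            )
        if list(gdf["gene_id"]) != [str(i) for i in mat.index]:
            raise ValueError("gene IDs in matrix index and gene table disagree")
        genes = [
            GeneAnnotation(
                gene_id=r.gene_id,
                symbol=getattr(r, "symbol", "") or "",
                gene_class=(getattr(r, "gene_class", "") or None),
            )
            for r in gdf.itertuples()
        ]
    else:
        genes = [GeneAnnotation(gene_id=str(i)) for i in mat.index]

    lookup = [
        VoxelRecord(
            voxel_id=str(r.voxel_id),
            coord=(int(r.x), int(r.y), int(r.z)),
            region_label=str(r.region_label),
        )
        for r in lut.itertuples()
    ]
    return ExpressionAtlas(
        matrix=mat.to_numpy(dtype=float),
        genes=genes,
        lookup=lookup,
        grid_shape=grid_shape,
    )


def write_atlas_hdf5(atlas: ExpressionAtlas, path: str | os.PathLike) -> None:
    """Write the full atlas losslessly into one HDF5 file."""
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        f.create_dataset("matrix", data=atlas.matrix)
        f.create_dataset("gene_id", data=atlas.gene_ids, dtype=str_dt)
        f.create_dataset("gene_symbol", data=[g.symbol for g in atlas.genes], dtype=str_dt)
        f.create_dataset(
            "gene_class", data=[g.gene_class or "" for g in atlas.genes], dtype=str_dt
        )
        f.create_dataset("voxel_id", data=atlas.voxel_ids, dtype=str_dt)
        f.create_dataset("coords", data=atlas.coords)
        f.create_dataset("region_label", data=atlas.region_labels, dtype=str_dt)
        f.attrs["grid_shape"] = atlas.grid_shape


def read_atlas_hdf5(path: str | os.PathLike) -> ExpressionAtlas:
    with h5py.File(path, "r") as f:
        matrix = f["matrix"][()]
        gene_ids = [s.decode() for s in f["gene_id"][()]]
        symbols = [s.decode() for s in f["gene_symbol"][()]]
        classes = [s.decode() or None for s in f["gene_class"][()]]
        voxel_ids = [s.decode() for s in f["voxel_id"][()]]
        coords = f["coords"][()]
        region = [s.decode() for s in f["region_label"][()]]
        grid_shape = tuple(int(s) for s in f.attrs["grid_shape"])
    genes = [
        GeneAnnotation(gene_id=i, symbol=s, gene_class=c)
        for i, s, c in zip(gene_ids, symbols, classes)
    ]
    lookup = [
        VoxelRecord(voxel_id=v, coord=tuple(int(c) for c in xyz), region_label=r)
        for v, xyz, r in zip(voxel_ids, coords, region)
    ]
    return ExpressionAtlas(matrix=matrix, genes=genes, lookup=lookup, grid_shape=grid_shape)
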