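import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from voxelparcel import ExpressionAtlas, GeneAnnotation, VoxelRecord

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def make_atlas(matrix, region_labels=None, gene_classes=None, coords=None, grid_shape=None):
    """Small hand-built atlas for contract tests."""
    matrix = np.asarray(matrix, dtype=float)
    m, n = matrix.shape
    if region_labels is None:
        region_labels = ["R"] * n
    if gene_classes is None:
        gene_classes = [None] * m
    if coords is None:
        coords = [(j, 0, 0) for j in range(n)]
    genes = [
        GeneAnnotation(gene_id=f"g{i}", symbol=f"G{i}", gene_class=gene_classes[i])
        for i in range(m)
    ]
    lookup = [
        VoxelRecord(voxel_id=f"v{j}", coord=tuple(coords[j]), region_label=region_labels[j])
        for j in range(n)
    ]
    return ExpressionAtlas(matrix=matrix, genes=genes, lookup=lookup, grid_shape=grid_shape)


@pytest.fixture
def toy_atlas():
    """3 genes x 5 voxels, two regions, mixed gene classes."""
    matrix = [
        [1.0, 2.0, 3.0, 4.0, 5.0],
        [0.5, 0.5, 0.5, 0.5, 0.5],
        [2.0, 0.0, 1.0, 3.0, 0.0],
    ]
    return make_atlas(
        matrix,
        region_labels=["OB", "OB", "OB", "CTX", "CTX"],
        gene_classes=["ion_channel", "gpcr", None],
    )
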