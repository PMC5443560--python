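"""Two-region differential-enrichment screen.

Given two disjoint voxel sets A and B (for example the anterior and
posterior halves of the accessory olfactory bulb), each gene gets a
per-region mean expression, an enrichment score contrasting the two,
and a flag when its score is an outlier of the score distribution.

Score conventions
-----------------
The default score is the normalized contrast

    score = (mean_A − mean_B) / (mean_A + mean_B + ε)

which is bounded in [−1, 1], antisymmetric under swapping A and B, and
invariant to rescaling the whole expression matrix; ε is a machine-tiny
constant that only guards the 0/0 case. The raw difference
``mean_A − mean_B`` is computed and stored alongside so screens can be
re-run under either convention.

A gene is flagged when its score lies more than ``k_sd`` standard
deviations (default 4) from the mean of the empirical score
distribution, on either side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas_io import Axis, ExpressionAtlas, _axis_index

DEFAULT_K_SD = 4.0

_EPS = np.finfo(float).tiny


@dataclass
class EnrichmentTable:
    """Per-gene two-region enrichment results."""

    gene_ids: list[str]
    mean_a: np.ndarray
    mean_b: np.ndarray
    score: np.ndarray       # normalized contrast, in [-1, 1]
    score_raw: np.ndarray   # mean_a - mean_b
    z: np.ndarray
    flagged: np.ndarray
    k_sd: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "mean_a": self.mean_a,
                "mean_b": self.mean_b,
                "score_norm": self.score,
                "score_raw": self.score_raw,
                "z": self.z,
                "flagged": self.flagged,
            }
        )


def region_means(
    atlas: ExpressionAtlas,
    voxel_set_a: Sequence[int],
    voxel_set_b: Sequence[int],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mean expression over two disjoint voxel (column) sets."""
    a = np.asarray(voxel_set_a, dtype=int)
    b = np.asarray(voxel_set_b, dtype=int)
    if a.size == 0 or b.size == 0:
        raise ValueError("both voxel sets must be non-empty")
    if set(a.tolist()) & set(b.tolist()):
        raise ValueError("voxel sets must be disjoint")
    n = atlas.n_voxels
    if a.max() >= n or b.max() >= n or a.min() < 0 or b.min() < 0:
        raise ValueError("voxel indices out of range")
    return atlas.matrix[:, a].mean(axis=1), atlas.matrix[:, b].mean(axis=1)


def split_region_voxels(
    atlas: ExpressionAtlas, axis: Axis = "x", region_label: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Bisect a region's voxels at the coordinate median along one axis.

    Returns (indices below the median, indices at or above it) — a
    simple anterior/posterior style half-split when the chosen axis is
    the rostro-caudal one. Raises if either half would be empty.
    """
    ax = _axis_index(axis)
    if region_label is None:
        idx = np.arange(atlas.n_voxels)
    else:
        idx = np.array(
            [j for j, v in enumerate(atlas.lookup) if v.region_label == region_label],
            dtype=int,
        )
        if idx.size == 0:
            raise ValueError(f"no voxels with region label {region_label!r}")
    coords = atlas.coords[idx, ax]
    median = np.median(coords)
    side_a = idx[coords < median]
    side_b = idx[coords >= median]
    if side_a.size == 0 or side_b.size == 0:
        raise ValueError(
            f"median split along axis {axis!r} leaves an empty half "
            f"(coordinates span {coords.min()}..{coords.max()})"
        )
    return side_a, side_b


def enrichment_scores(
    mean_a: np.ndarray,
    mean_b: np.ndarray,
    gene_ids: list[str] | None = None,
    k_sd: float = DEFAULT_K_SD,
) -> EnrichmentTable:
    """Score and flag per-gene expression asymmetry between two regions.

    ``z`` standardizes the normalized-contrast scores by the empirical
    mean and SD of the score distribution; ``flagged`` marks |z| > k_sd.
    Requires at least 4 genes and a non-degenerate score distribution.
    """
    mean_a = np.asarray(mean_a, dtype=float)
    mean_b = np.asarray(mean_b, dtype=float)
    if mean_a.shape != mean_b.shape:
        raise ValueError("mean_a and mean_b must have equal length")
    if mean_a.size < 4:
        raise ValueError("need means for at least 4 genes (SD needs spread)")
    if (mean_a < 0).any() or (mean_b < 0).any():
        raise ValueError("region means must be non-negative")
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(mean_a.size)]

    score = (mean_a - mean_b) / (mean_a + mean_b + _EPS)
    score_raw = mean_a - mean_b
    sd = score.std(ddof=1)
    if sd == 0:
        raise ValueError("all enrichment scores identical; SD is zero")
    z = (score - score.mean()) / sd
    flagged = np.abs(z) > k_sd
    return EnrichmentTable(
        gene_ids=list(gene_ids),
        mean_a=mean_a,
        mean_b=mean_b,
        score=score,
        score_raw=score_raw,
        z=z,
        flagged=flagged,
        k_sd=float(k_sd),
    )


def score_histogram(
    scores: np.ndarray, bins: int = 50, log_counts: bool = False
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Fixed-width histogram of enrichment scores.

    Returns ``(counts, bin_edges, meta)``; ``meta['log_counts']``
    records whether the count axis is meant to be drawn on a log scale
    (the counts themselves are untouched). Counts always sum to the
    number of scores.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("need at least one score")
    lo, hi = scores.min(), scores.max()
    if lo == hi:  # all identical: a single occupied bin
        lo, hi = lo - 0.5, hi + 0.5
    counts, edges = np.histogram(scores, bins=bins, range=(lo, hi))
    return counts, edges, {"log_counts": bool(log_counts)}
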