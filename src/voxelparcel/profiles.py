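"""Signature-profile inspection: gene ranking, sparseness, histograms.

Each column of the basis matrix W is a genome-length "signature
expression profile" defining one genomic territory. These profiles tend
to be sparse — a handful of strong gene hits over a near-zero
background — and their most useful product is the rank-ordered gene
list per cluster.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class GeneRanking:
    """Rank-ordered genes of one cluster's basis vector."""

    cluster: int
    table: pd.DataFrame  # columns: rank, gene_id, coefficient

    def top(self, n: int) -> list[str]:
        return self.table["gene_id"].head(n).tolist()


def rank_genes(W: np.ndarray, cluster_index: int, gene_ids: list[str]) -> GeneRanking:
    """Rank all genes by their coefficient in one basis column.

    ``cluster_index`` is 1-based. Genes are sorted by descending
    coefficient; exact ties are broken by gene_id lexicographic order.
    Every gene appears exactly once.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2:
        raise ValueError("W must be 2-D (genes x s)")
    m, s = W.shape
    if not (1 <= cluster_index <= s):
        raise ValueError(f"cluster_index must lie in 1..{s}, got {cluster_index}")
    if len(gene_ids) != m:
        raise ValueError("gene_ids length must match W rows")
    w = W[:, cluster_index - 1]
    order = np.lexsort((np.asarray(gene_ids, dtype=str), -w))
    table = pd.DataFrame(
        {
            "rank": np.arange(1, m + 1),
            "gene_id": [gene_ids[i] for i in order],
            "coefficient": w[order],
        }
    )
    return GeneRanking(cluster=cluster_index, table=table)


def sparseness(w: np.ndarray) -> float:
    """Hoyer sparseness of a non-negative vector, in [0, 1].

    Defined as (√m − ‖w‖₁/‖w‖₂) / (√m − 1): exactly 1 for a one-hot
    vector, exactly 0 for a constant vector, and invariant to positive
    rescaling.
    """
    w = np.asarray(w, dtype=float).ravel()
    if w.size < 2:
        raise ValueError("sparseness needs a vector of length >= 2")
    if (w < 0).any():
        raise ValueError("w must be non-negative")
    l2 = np.linalg.norm(w)
    if l2 == 0:
        raise ValueError("sparseness undefined for the zero vector")
    sqrt_m = np.sqrt(w.size)
    return float((sqrt_m - w.sum() / l2) / (sqrt_m - 1))


def profile_histogram(
    w: np.ndarray, bins: int = 30, log_x: bool = False
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Histogram of one basis vector's coefficients.

    With ``log_x`` the positive values are binned on a log10 axis and
    zeros are pooled into a dedicated zero-bin reported separately in
    the metadata (log bins cannot hold them). Counts (including the
    zero-bin) always sum to the vector length.
    """
    w = np.asarray(w, dtype=float).ravel()
    if (w < 0).any():
        raise ValueError("w must be non-negative")
    if not log_x:
        counts, edges = np.histogram(w, bins=bins)
        return counts, edges, {"log_x": False, "zero_bin": 0}
    pos = w[w > 0]
    n_zero = int(w.size - pos.size)
    if pos.size == 0:
        return np.zeros(bins, dtype=int), np.array([]), {"log_x": True, "zero_bin": n_zero}
    lo, hi = np.log10(pos.min()), np.log10(pos.max())
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.logspace(lo, hi, bins + 1)
    # guard against float round-off excluding the extremes
    edges[0] = min(edges[0], pos.min())
    edges[-1] = max(edges[-1], pos.max())
    counts, edges = np.histogram(pos, bins=edges)
    return counts, edges, {"log_x": True, "zero_bin": n_zero}


def export_rankings(
    W: np.ndarray, gene_ids: list[str], out_dir: str | os.PathLike
) -> list[str]:
    """Write one rank-ordered CSV per cluster plus a combined bundle.

    Per-cluster files are ``cluster_<k>_genes.csv`` with columns
    (rank, gene_id, coefficient); ``all_clusters_genes.csv`` stacks them
    with a leading ``cluster`` column. Returns the written paths.
    """
    W = np.asarray(W, dtype=float)
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    combined = []
    for k in range(1, W.shape[1] + 1):
        ranking = rank_genes(W, k, gene_ids)
        path = os.path.join(out_dir, f"cluster_{k}_genes.csv")
        ranking.table.to_csv(path, index=False)
        paths.append(path)
        combined.append(ranking.table.assign(cluster=k))
    bundle = os.path.join(out_dir, "all_clusters_genes.csv")
    pd.concat(combined, ignore_index=True)[
        ["cluster", "rank", "gene_id", "coefficient"]
    ].to_csv(bundle, index=False)
    paths.append(bundle)
    return paths
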