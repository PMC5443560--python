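"""From NMF weights to voxel parcellations, and their evaluation.

NMF weight columns are near-categorical: a voxel tends to load on one
basis vector to the relative exclusion of the others, so clustering is
simply the argmax over the weight rows. This module implements that
assignment, the block-diagonal column ordering used to visualize H,
per-block mean weight profiles (polar-plot summaries), a dendrogram of
Euclidean distances between basis vectors, and cluster-recovery
evaluation against known labels (optimal label matching, accuracy
versus number of genes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist

from .atlas_io import ExpressionAtlas
from .factorization import als_nmf


@dataclass
class ClusterAssignment:
    """Per-voxel cluster membership derived from a weight matrix.

    ``labels`` are 1-based cluster indices in ``1..s``. ``tie`` flags
    voxels whose maximum weight was attained by more than one cluster
    (broken toward the lowest index); ``empty`` flags all-zero weight
    columns (assigned cluster 1 by convention).
    """

    labels: np.ndarray
    tie: np.ndarray
    empty: np.ndarray
    s: int

    def __post_init__(self):
        if not (len(self.labels) == len(self.tie) == len(self.empty)):
            raise ValueError("labels/tie/empty must have equal length")
        if len(self.labels) and not ((self.labels >= 1) & (self.labels <= self.s)).all():
            raise ValueError(f"labels must lie in 1..{self.s}")


@dataclass
class AccuracyCurve:
    """Classification accuracy versus number of genes used.

    ``perfect_fraction[i]`` is the fraction of voxels classified
    correctly in *every* repetition at ``gene_counts[i]``;
    ``mean_accuracy[i]`` is the mean over repetitions of the
    post-matching overall accuracy. ``rep_accuracy`` keeps the raw
    per-repetition accuracies so alternative summaries can be derived.
    """

    gene_counts: np.ndarray
    perfect_fraction: np.ndarray
    mean_accuracy: np.ndarray
    reps: int
    seed: int | None
    rep_accuracy: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if not (
            len(self.gene_counts) == len(self.perfect_fraction) == len(self.mean_accuracy)
        ):
            raise ValueError("curve arrays must share length")
        for arr in (self.perfect_fraction, self.mean_accuracy):
            if len(arr) and ((np.asarray(arr) < 0) | (np.asarray(arr) > 1)).any():
                raise ValueError("fractions must lie in [0, 1]")


def assign_clusters(H: np.ndarray) -> ClusterAssignment:
    """Cluster each voxel by its largest weight (argmax over rows of H).

    Ties are broken toward the lowest row index and flagged; all-zero
    columns are assigned cluster 1 and flagged empty (not tied).
    """
    H = np.asarray(H, dtype=float)
    if H.ndim != 2:
        raise ValueError("H must be 2-D (s x n)")
    if (H < 0).any():
        raise ValueError("H must be non-negative")
    s, n = H.shape
    peak = H.max(axis=0)
    labels = H.argmax(axis=0) + 1  # argmax returns the lowest index on ties
    empty = peak == 0
    tie = ((H == peak).sum(axis=0) > 1) & ~empty
    labels[empty] = 1
    return ClusterAssignment(labels=labels, tie=tie, empty=empty, s=s)


def sort_weights_by_peak(H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column order that exposes the block-diagonal structure of H.

    Columns are grouped by their argmax row (ascending) and ordered
    within each group by descending peak value; the values themselves
    are untouched. Returns ``(perm, H[:, perm])`` with ``perm`` 0-based.
    """
    H = np.asarray(H, dtype=float)
    if (H < 0).any():
        raise ValueError("H must be non-negative")
    block = H.argmax(axis=0)
    peak = H.max(axis=0)
    # lexsort: last key is primary; stable, so equal (block, peak) keep input order
    perm = np.lexsort((-peak, block))
    return perm, H[:, perm]


def block_profiles(
    H: np.ndarray, assignment: ClusterAssignment, clusters: list[int] | None = None
) -> dict[int, np.ndarray]:
    """Mean weight vector of each cluster's member voxels.

    The result is the length-s "polar plot" profile per block; for a
    categorical decomposition each profile peaks on its own dimension.
    """
    H = np.asarray(H, dtype=float)
    if H.shape[1] != len(assignment.labels):
        raise ValueError("H and assignment cover different numbers of voxels")
    if clusters is None:
        clusters = sorted(set(assignment.labels.tolist()))
    out: dict[int, np.ndarray] = {}
    for k in clusters:
        members = assignment.labels == k
        if not members.any():
            raise ValueError(f"cluster {k} has no member voxels")
        out[k] = H[:, members].mean(axis=1)
    return out


def basis_dendrogram(
    W: np.ndarray, linkage: str = "complete"
) -> tuple[np.ndarray, list[int], np.ndarray]:
    """Agglomerative tree over the s basis vectors.

    Distances are Euclidean between the columns of W. Returns
    ``(Z, leaf_order, pairwise_distances)`` with ``Z`` in SciPy linkage
    format. Complete linkage is the default; only the distance metric is
    fixed by the method, the linkage is a reporting choice.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[1] < 2:
        raise ValueError("need at least 2 basis vectors for a dendrogram")
    dists = pdist(W.T, metric="euclidean")
    Z = hierarchy.linkage(dists, method=linkage)
    leaves = hierarchy.leaves_list(Z).tolist()
    return Z, leaves, dists


# ----------------------------------------------------------------------
# evaluation against known labels
# ----------------------------------------------------------------------

def best_label_accuracy(
    pred: np.ndarray, truth: np.ndarray
) -> tuple[float, dict[int, int]]:
    """Accuracy under the accuracy-maximizing cluster→truth relabeling.

    Cluster labels are arbitrary, so predicted and true labels are
    matched by solving the optimal assignment over the confusion matrix
    (Hungarian algorithm) before scoring. Returns ``(accuracy, mapping)``
    where ``mapping[pred_label] = truth_label``.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    p_vals = np.unique(pred)
    t_vals = np.unique(truth)
    k = max(len(p_vals), len(t_vals))
    conf = np.zeros((k, k), dtype=int)
    p_index = {v: i for i, v in enumerate(p_vals)}
    t_index = {v: i for i, v in enumerate(t_vals)}
    for p, t in zip(pred, truth):
        conf[p_index[p], t_index[t]] += 1
    rows, cols = linear_sum_assignment(-conf)
    accuracy = conf[rows, cols].sum() / pred.size
    mapping = {
        int(p_vals[r]): int(t_vals[c])
        for r, c in zip(rows, cols)
        if r < len(p_vals) and c < len(t_vals)
    }
    return float(accuracy), mapping


def accuracy_vs_gene_count(
    atlas: ExpressionAtlas,
    truth_labels: np.ndarray,
    gene_counts: list[int],
    reps: int,
    s: int,
    seed: int | None = None,
    **nmf_kwargs,
) -> AccuracyCurve:
    """Cluster-recovery accuracy as a function of how many genes are used.

    For each gene count g and repetition: draw g genes uniformly without
    replacement, factorize the row-subset matrix at subspace size s,
    assign clusters by argmax weight, and score against ``truth_labels``
    after optimal label matching. Gene draws and NMF seeds are derived
    per (count, rep) from the master seed.
    """
    truth_labels = np.asarray(truth_labels)
    if len(np.unique(truth_labels)) != s:
        raise ValueError(
            f"truth has {len(np.unique(truth_labels))} classes but s={s}"
        )
    if truth_labels.size != atlas.n_voxels:
        raise ValueError("truth labels must cover every atlas voxel")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    gene_counts = [int(g) for g in gene_counts]
    if any(g < s or g > atlas.n_genes for g in gene_counts):
        raise ValueError(
            f"gene counts must lie in [s={s}, m={atlas.n_genes}]"
        )

    master = np.random.default_rng(seed)
    n = atlas.n_voxels
    rep_acc = np.zeros((len(gene_counts), reps))
    perfect = np.zeros(len(gene_counts))
    for i, g in enumerate(gene_counts):
        correct_all = np.ones(n, dtype=bool)
        for rep in range(reps):
            rng = np.random.default_rng(master.integers(0, 2**31 - 1))
            rows = rng.choice(atlas.n_genes, size=g, replace=False)
            sub = atlas.matrix[np.sort(rows), :]
            res = als_nmf(sub, s=s, seed=int(rng.integers(0, 2**31 - 1)), **nmf_kwargs)
            pred = assign_clusters(res.H).labels
            acc, mapping = best_label_accuracy(pred, truth_labels)
            rep_acc[i, rep] = acc
            mapped = np.array([mapping.get(int(p), -1) for p in pred])
            correct_all &= mapped == truth_labels
        perfect[i] = correct_all.mean()
    return AccuracyCurve(
        gene_counts=np.asarray(gene_counts),
        perfect_fraction=perfect,
        mean_accuracy=rep_acc.mean(axis=1),
        reps=reps,
        seed=seed,
        rep_accuracy=rep_acc,
    )
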