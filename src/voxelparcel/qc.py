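"""Replicate-consistency gene quality control.

Voxel-registered ISH atlases are assembled from two independent image
series per gene (sagittal and coronal acquisitions). A gene whose two
series disagree spatially is unreliable, so the filter computes the
per-gene Pearson correlation between matched voxels of the two
replicates and discards the lowest quartile of the correlation
distribution, keeping the remaining 75%.

Conventions (the tie rules the original procedure leaves open):

* the cutoff is the empirical 25th percentile of the scorable
  correlations under linear interpolation;
* genes with r exactly at the cutoff are retained (ties kept);
* genes whose correlation is undefined (zero variance in either
  replicate) cannot be scored and are discarded with an explicit
  ``undefined_r`` reason rather than silently kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas_io import ExpressionAtlas

QUARTILE_PERCENT = 25.0


@dataclass
class QcReport:
    """Per-gene QC outcome."""

    gene_ids: list[str]
    r: np.ndarray  # NaN where undefined
    quartile_cutoff: float
    retained: np.ndarray  # bool
    reason: list[str]  # "ok", "low_correlation", "undefined_r"

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "r": self.r,
                "retained": self.retained,
                "reason": self.reason,
            }
        )


def replicate_correlations(
    atlas_a: ExpressionAtlas, atlas_b: ExpressionAtlas
) -> np.ndarray:
    """Per-gene Pearson r between matched voxels of two replicates.

    Genes with zero variance in either replicate get ``NaN`` (their
    correlation is undefined); they are never silently dropped.
    """
    if atlas_a.gene_ids != atlas_b.gene_ids:
        raise ValueError("replicates have different gene lists")
    if atlas_a.voxel_ids != atlas_b.voxel_ids:
        raise ValueError("replicates cover different voxel sets")
    A = atlas_a.matrix
    B = atlas_b.matrix
    A_c = A - A.mean(axis=1, keepdims=True)
    B_c = B - B.mean(axis=1, keepdims=True)
    num = (A_c * B_c).sum(axis=1)
    den = np.sqrt((A_c**2).sum(axis=1) * (B_c**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r[den == 0] = np.nan
    return np.clip(r, -1.0, 1.0, out=r)


def quartile_filter(
    r: np.ndarray, gene_ids: list[str] | None = None
) -> QcReport:
    """Discard the lowest quartile of the per-gene correlation distribution.

    Requires at least 4 scorable (non-NaN) correlations. The cutoff is
    the 25th percentile (linear interpolation); genes with r >= cutoff
    are retained, unscorable genes are discarded with reason
    ``undefined_r``.
    """
    r = np.asarray(r, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(r.size)]
    if len(gene_ids) != r.size:
        raise ValueError("gene_ids length does not match r")
    scorable = ~np.isnan(r)
    if scorable.sum() < 4:
        raise ValueError(
            f"need at least 4 scorable genes to estimate the quartile, "
            f"got {int(scorable.sum())}"
        )
    cutoff = float(np.percentile(r[scorable], QUARTILE_PERCENT))
    retained = scorable & (r >= cutoff)
    reason = [
        "ok" if keep else ("undefined_r" if not ok else "low_correlation")
        for keep, ok in zip(retained, scorable)
    ]
    return QcReport(
        gene_ids=list(gene_ids),
        r=r,
        quartile_cutoff=cutoff,
        retained=retained,
        reason=reason,
    )


def apply_qc(atlas: ExpressionAtlas, report: QcReport) -> ExpressionAtlas:
    """Row-subset an atlas to the genes a QC report retained."""
    if report.gene_ids != atlas.gene_ids:
        raise ValueError("QC report gene list does not match atlas")
    return atlas.take_genes(np.flatnonzero(report.retained))
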