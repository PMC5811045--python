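"""Cell quality control, normalization and the correlated-gene filter.

The gene filter retains a gene only if its Spearman correlation exceeds a
threshold (default r > 0.4, strict) with at least ``min_partners`` other
genes (default 2), computed on log-normalized data over all retained
cells.  Constant genes have undefined rank correlation and are dropped.
Spike-in controls, recognized by id prefix, never enter the filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import spearman_rows
from .matrix import ExpressionMatrix

__all__ = [
    "QcThresholds",
    "qc_filter_cells",
    "normalize",
    "correlation_filter_genes",
    "SPIKE_PREFIXES",
]

#: gene-id prefixes treated as spike-in controls and excluded from filtering
SPIKE_PREFIXES = ("ERCC-", "ArrayControl")


@dataclass(frozen=True)
class QcThresholds:
    """Per-cell quality thresholds; values are config, not constants."""

    min_total_counts: float = 0.0
    min_genes_detected: int = 0
    max_fraction_top_gene: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.min_total_counts) or self.min_total_counts < 0:
            raise ValueError("min_total_counts must be finite and nonnegative")
        if self.min_genes_detected < 0:
            raise ValueError("min_genes_detected must be nonnegative")
        if not (0.0 < self.max_fraction_top_gene <= 1.0):
            raise ValueError("max_fraction_top_gene must be in (0, 1]")


def qc_report(m: ExpressionMatrix, th: QcThresholds) -> pd.DataFrame:
    """Per-cell QC metrics and pass/fail flags (one row per input cell)."""
    v = m.values
    totals = v.sum(axis=0)
    genes_detected = (v > 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        top_frac = np.where(totals > 0, v.max(axis=0) / np.where(totals == 0, 1, totals), 1.0)
    passed = (
        (totals >= th.min_total_counts)
        & (genes_detected >= th.min_genes_detected)
        & (top_frac <= th.max_fraction_top_gene)
    )
    return pd.DataFrame(
        {
            "total_counts": totals,
            "genes_detected": genes_detected,
            "top_gene_fraction": top_frac,
            "pass": passed,
        },
        index=pd.Index(m.cell_ids, name="cell_id"),
    )


def qc_filter_cells(
    m: ExpressionMatrix, th: QcThresholds
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Drop cells failing any threshold; return filtered matrix + report."""
    if m.layer != "counts":
        raise ValueError("qc_filter_cells expects a counts matrix")
    report = qc_report(m, th)
    keep = report.index[report["pass"]].tolist()
    if not keep:
        raise ValueError("all cells fail the QC thresholds")
    return m.subset_cells(keep), report


def normalize(m: ExpressionMatrix, target_total: float | None = None) -> ExpressionMatrix:
    """Scale every cell to a common total, then apply log(1 + x).

    ``target_total`` defaults to the median per-cell total.  Within-cell
    gene rank order is preserved (the map is monotone per cell).
    """
    if m.layer != "counts":
        raise ValueError("normalize expects a counts matrix")
    totals = m.values.sum(axis=0)
    zero = np.where(totals == 0)[0]
    if zero.size:
        bad = [m.cell_ids[i] for i in zero[:5]]
        raise ValueError(f"cells with zero total counts cannot be normalized: {bad}")
    if target_total is None:
        target_total = float(np.median(totals))
    scaled = m.values * (target_total / totals)[None, :]
    return ExpressionMatrix(
        np.log1p(scaled), list(m.gene_ids), list(m.cell_ids),
        layer="lognorm", cell_meta=m.cell_meta, strict=False,
    )


def _is_spike(gene_id: str, prefixes: tuple[str, ...]) -> bool:
    return any(gene_id.startswith(p) for p in prefixes)


def correlation_filter_genes(
    m: ExpressionMatrix,
    r_min: float = 0.4,
    min_partners: int = 2,
    iterative: bool = False,
    spike_prefixes: tuple[str, ...] = SPIKE_PREFIXES,
) -> list[str]:
    """Gene ids correlated (rho strictly > ``r_min``) with >= ``min_partners`` others.

    Single pass by default; with ``iterative=True`` the filter is re-applied
    on the surviving set until a pass removes nothing.
    """
    if m.layer != "lognorm":
        raise ValueError("correlation_filter_genes expects a lognorm matrix")
    candidates = [g for g in m.gene_ids if not _is_spike(g, spike_prefixes)]
    if len(candidates) < 3:
        raise ValueError("need at least 3 non-spike genes to filter")

    current = candidates
    while True:
        idx = m.gene_index(current)
        corr = spearman_rows(m.values[idx])
        np.fill_diagonal(corr, np.nan)
        partners = (corr > r_min).sum(axis=1)  # NaN (constant gene) compares False
        keep_mask = partners >= min_partners
        kept = [g for g, k in zip(current, keep_mask) if k]
        if not iterative or len(kept) == len(current) or len(kept) == 0:
            return kept
        current = kept
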