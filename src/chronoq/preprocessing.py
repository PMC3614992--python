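"""Gene filtering ahead of ordering.

Two steps: (1) drop genes with any missing measurement; (2) keep only the
genes whose expression profile has absolute Pearson correlation with the
per-sample time signal (survival time, or the known sampling time for a
time series) strictly above a threshold. The default threshold of 0.6 is
deliberately high: the point of the filter is a radical reduction of
dimensionality, keeping only genes that carry a clear monotone trend
along the quantity the ordering should recover.

Genes with zero variance carry no ordering signal; their correlation is
undefined and the filter treats it as 0, so they are always dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset_io import ExpressionMatrix, SampleTimes
from .errors import InputError

__all__ = [
    "FilterReport",
    "remove_incomplete_genes",
    "pearson",
    "filter_genes_by_time_correlation",
]


@dataclass
class FilterReport:
    """Bookkeeping of one filtering pass.

    ``kept + dropped_missing + dropped_low_correlation`` equals the initial
    gene count; every kept gene satisfies ``|r| > threshold``.
    """

    threshold: float
    kept_gene_ids: list[str]
    dropped_missing: int
    dropped_low_correlation: int
    correlations: dict[str, float] = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return len(self.kept_gene_ids)


def remove_incomplete_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Drop every gene with at least one missing entry, preserving order."""
    complete = ~np.isnan(matrix.values).any(axis=1)
    if not complete.any():
        raise InputError("every gene has a missing entry; nothing left to order")
    return ExpressionMatrix(
        [g for g, ok in zip(matrix.gene_ids, complete) if ok],
        list(matrix.sample_ids),
        matrix.values[complete],
    )


def pearson(x, y) -> float:
    """Product-moment correlation of two equal-length vectors.

    Raises :class:`InputError` when either vector has zero variance (the
    correlation is undefined); the gene filter maps that case to 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("pearson expects two equal-length 1-d vectors")
    if x.size < 2:
        raise InputError("pearson needs at least 2 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        raise InputError("undefined correlation: zero variance")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def filter_genes_by_time_correlation(
    matrix: ExpressionMatrix,
    times: SampleTimes,
    threshold: float = 0.6,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Keep genes with ``|pearson(gene, time)| > threshold`` (strict).

    The matrix must already be free of missing entries. Returns the
    filtered matrix together with a :class:`FilterReport`; an empty kept
    set raises :class:`InputError` so the caller can lower the threshold.
    """
    if not 0.0 <= threshold <= 1.0:
        raise InputError(f"threshold must lie in [0, 1], got {threshold}")
    if matrix.has_missing():
        raise InputError("matrix has missing entries; run remove_incomplete_genes first")
    t = times.vector_for(matrix.sample_ids)
    keep = np.zeros(matrix.n_genes, dtype=bool)
    correlations: dict[str, float] = {}
    for k, gid in enumerate(matrix.gene_ids):
        try:
            r = pearson(matrix.values[k], t)
        except InputError:
            r = 0.0  # zero-variance gene: no ordering signal
        correlations[gid] = r
        keep[k] = abs(r) > threshold
    report = FilterReport(
        threshold=threshold,
        kept_gene_ids=[g for g, ok in zip(matrix.gene_ids, keep) if ok],
        dropped_missing=0,
        dropped_low_correlation=int((~keep).sum()),
        correlations=correlations,
    )
    if not keep.any():
        raise InputError(
            f"no gene exceeds |r| > {threshold}; lower the threshold or "
            "check the time signal"
        )
    filtered = ExpressionMatrix(
        report.kept_gene_ids, list(matrix.sample_ids), matrix.values[keep]
    )
    return filtered, report


def preprocess(
    matrix: ExpressionMatrix,
    times: SampleTimes,
    threshold: float = 0.6,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Missing-gene removal followed by the correlation filter."""
    n0 = matrix.n_genes
    complete = remove_incomplete_genes(matrix)
    filtered, report = filter_genes_by_time_correlation(complete, times, threshold)
    report.dropped_missing = n0 - complete.n_genes
    return filtered, report
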