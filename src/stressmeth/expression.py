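"""Expression normalization and differential-expression calling.

Counts are log2(x + 1) transformed and quantile normalized (all samples
forced onto the cross-sample rank-mean distribution; ties within a sample
receive the mean of the reference values they span), then fit with the same
moderated linear model used for methylation: expression ~ stress score + age
+ batch.  Features with moderated p below the threshold are called, and the
unique differentially expressed gene set is the union of genes called at the
gene level and parent genes of called isoforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dml import fit_locus_models, moderate_variances
from .errors import ConfigurationError

log = logging.getLogger(__name__)


def log_transform(counts: pd.DataFrame) -> pd.DataFrame:
    if (counts.to_numpy() < 0).any():
        raise ConfigurationError("counts must be non-negative")
    return np.log2(counts.astype(float) + 1.0)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the shared reference distribution (the mean
    across columns of the order statistics at each rank)."""
    x = matrix.to_numpy(float)
    n, k = x.shape
    if k == 1:
        return matrix.copy()
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(k):
        col = x[:, j]
        if np.ptp(col) == 0.0:
            log.warning("column %s has zero variance; all entries tie", matrix.columns[j])
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n)
        assigned[order] = reference
        # ties share the mean of the reference values they span
        sorted_vals = col[order]
        i = 0
        while i < n:
            j2 = i
            while j2 + 1 < n and sorted_vals[j2 + 1] == sorted_vals[i]:
                j2 += 1
            if j2 > i:
                assigned[order[i : j2 + 1]] = reference[i : j2 + 1].mean()
            i = j2 + 1
        out[:, j] = assigned
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(count + 1) followed by quantile normalization."""
    return quantile_normalize(log_transform(counts))


@dataclass
class DeResult:
    """Per-feature statistics and the derived unique DE gene set."""

    gene_stats: pd.DataFrame | None
    isoform_stats: pd.DataFrame | None
    threshold: float
    unique_genes: set[str]

    @property
    def n_unique_genes(self) -> int:
        return len(self.unique_genes)


def fit_de(
    normalized: pd.DataFrame,
    samples: pd.DataFrame,
    level: str = "gene",
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Moderated linear model per feature; adds a ``called`` flag at the raw
    moderated p threshold (no multiple-testing correction at this stage)."""
    if level not in ("gene", "isoform"):
        raise ValueError(f"unknown level {level!r}")
    stats_df = moderate_variances(fit_locus_models(normalized, samples))
    stats_df["level"] = level
    stats_df["called"] = stats_df["p_mod"] < threshold
    return stats_df


def unique_de_genes(
    gene_stats: pd.DataFrame | None,
    isoform_stats: pd.DataFrame | None,
    isoform_to_gene: pd.Series | dict[str, str] | None = None,
) -> set[str]:
    """Genes called at gene level union parent genes of called isoforms."""
    genes: set[str] = set()
    if gene_stats is not None:
        genes |= set(gene_stats.index[gene_stats["called"]])
    if isoform_stats is not None:
        mapping = dict(isoform_to_gene) if isoform_to_gene is not None else {}
        for iso in isoform_stats.index[isoform_stats["called"]]:
            genes.add(mapping.get(iso, iso.rsplit(".", 1)[0]))
    return genes


def run_expression_de(
    gene_counts: pd.DataFrame | None,
    isoform_counts: pd.DataFrame | None,
    samples: pd.DataFrame,
    threshold: float = 0.05,
    isoform_to_gene: pd.Series | dict[str, str] | None = None,
) -> DeResult:
    """Normalize and test both count matrices, then build the unique DE gene
    union."""
    gene_stats = iso_stats = None
    if gene_counts is not None:
        gene_stats = fit_de(normalize_counts(gene_counts), samples, "gene", threshold)
    if isoform_counts is not None:
        iso_stats = fit_de(normalize_counts(isoform_counts), samples, "isoform", threshold)
    return DeResult(
        gene_stats=gene_stats,
        isoform_stats=iso_stats,
        threshold=threshold,
        unique_genes=unique_de_genes(gene_stats, iso_stats, isoform_to_gene),
    )
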