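"""Gene-level integration of methylation, expression and curated lists.

DMLs are assigned to their nearest gene (containment first, then minimum
distance to either gene boundary, same chromosome only), aggregated into
direction-classified gene sets, overlapped with the unique differentially
expressed genes and a curated stress-gene list (three-way Venn counts), and
tested for list enrichment with a Yates-corrected chi-square on the 2x2
membership table against the gene universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenomeAnnotation
from .errors import PipelineError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# nearest gene

def nearest_gene(
    genome: GenomeAnnotation, chrom: str, pos: int, mode: str = "span"
) -> str | None:
    """Nearest gene on the same chromosome; None when the chromosome carries
    no genes.  ``mode='span'`` measures containment then boundary distance;
    ``'tss'`` measures distance to the transcription start site.  Ties break
    to the alphabetically first gene id."""
    genes = genome.genes[genome.genes["chrom"] == chrom]
    if genes.empty:
        return None
    best_id: str | None = None
    best_dist = np.inf
    for row in genes.itertuples(index=False):
        if mode == "span":
            if row.start <= pos <= row.end:
                dist = 0
            else:
                dist = min(abs(pos - row.start), abs(pos - row.end))
        else:
            tss = row.start if row.strand == "+" else row.end
            dist = abs(pos - tss)
        if dist < best_dist or (dist == best_dist and (best_id is None or row.gene_id < best_id)):
            best_dist = dist
            best_id = row.gene_id
    return best_id


def map_nearest_gene(
    dml_calls: pd.DataFrame, genome: GenomeAnnotation, mode: str = "span"
) -> pd.Series:
    """Gene assignment per DML row (index = probe id, needs chrom/pos
    columns); probes on geneless chromosomes are left unassigned (NaN) with
    a warning."""
    out = {}
    for pid, row in dml_calls.iterrows():
        gene = nearest_gene(genome, row["chrom"], int(row["pos"]), mode)
        if gene is None:
            log.warning("probe %s on %s has no gene on its chromosome; unassigned",
                        pid, row["chrom"])
        out[pid] = gene
    return pd.Series(out, name="gene_id")


# ---------------------------------------------------------------------------
# gene sets

@dataclass
class GeneSets:
    """Direction-classified differentially methylated gene sets.  A gene
    enters ``positive`` if it hosts at least one positively correlated DML
    (likewise ``negative``); genes hosting both kinds appear in both."""

    positive: set[str]
    negative: set[str]
    dml_count: dict[str, int] = field(default_factory=dict)

    @property
    def both(self) -> set[str]:
        return self.positive & self.negative

    @property
    def union(self) -> set[str]:
        return self.positive | self.negative

    def verify(self) -> None:
        if len(self.union) != len(self.positive) + len(self.negative) - len(self.both):
            raise PipelineError("inclusion-exclusion identity violated")  # unreachable
        if any(self.dml_count.get(g, 0) < 1 for g in self.union):
            raise PipelineError("a methylation gene has no recorded DML")


def aggregate_genes(assignments: pd.Series, directions: pd.Series) -> GeneSets:
    """Build GeneSets from per-DML gene assignments and directions
    (unassigned DMLs are dropped)."""
    positive: set[str] = set()
    negative: set[str] = set()
    counts: dict[str, int] = {}
    for pid, gene in assignments.items():
        if gene is None or (isinstance(gene, float) and np.isnan(gene)):
            continue
        counts[gene] = counts.get(gene, 0) + 1
        if directions.loc[pid] == "positive":
            positive.add(gene)
        else:
            negative.add(gene)
    sets = GeneSets(positive=positive, negative=negative, dml_count=counts)
    sets.verify()
    return sets


# ---------------------------------------------------------------------------
# overlaps

@dataclass
class OverlapReport:
    """Three-way Venn region counts (methylation / expression / curated)."""

    regions: dict[str, int]
    dropped_outside_universe: int
    universe_size: int

    def total(self) -> int:
        return sum(self.regions.values())


def overlap_sets(
    meth_genes: set[str],
    de_genes: set[str],
    curated_list: set[str],
    universe: set[str],
) -> OverlapReport:
    """Seven Venn region counts; members outside the universe are logged and
    dropped."""
    if not universe:
        raise ValueError("gene universe is empty")
    dropped = 0
    clipped = []
    for s in (meth_genes, de_genes, curated_list):
        outside = s - universe
        if outside:
            log.warning("%d genes outside the universe dropped", len(outside))
            dropped += len(outside)
        clipped.append(s & universe)
    m, e, c = clipped
    regions = {
        "meth_only": len(m - e - c),
        "expr_only": len(e - m - c),
        "curated_only": len(c - m - e),
        "meth_expr": len((m & e) - c),
        "meth_curated": len((m & c) - e),
        "expr_curated": len((e & c) - m),
        "all_three": len(m & e & c),
    }
    report = OverlapReport(regions, dropped, len(universe))
    if report.total() != len(m | e | c):
        raise PipelineError("Venn region counts do not sum to the union")  # unreachable
    return report


def chisq_list_enrichment(
    gene_set: set[str], curated_list: set[str], universe: set[str]
) -> tuple[float, float, np.ndarray]:
    """Yates-corrected chi-square on the 2x2 table membership-in-set x
    membership-in-list over the universe.  The correction term is
    min(0.5, |O - E|), so the corrected statistic never exceeds the
    uncorrected one.  Returns (statistic, p, table)."""
    if not universe:
        raise ValueError("gene universe is empty")
    s = gene_set & universe
    c = curated_list & universe
    a = len(s & c)
    b = len(s - c)
    cc = len(c - s)
    d = len(universe) - a - b - cc
    table = np.array([[a, b], [cc, d]], dtype=float)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    for name, margin in (("set", row[0]), ("non-set", row[1]), ("list", col[0]),
                         ("non-list", col[1])):
        if margin == 0:
            raise ValueError(f"zero margin in the 2x2 table: {name}")
    expected = np.outer(row, col) / n
    diff = np.abs(table - expected)
    stat = float((np.maximum(diff - 0.5, 0.0) ** 2 / expected).sum())
    p = float(stats.chi2.sf(stat, df=1))
    return stat, p, table


# ---------------------------------------------------------------------------
# consolidated report

@dataclass
class IntegrationReport:
    gene_sets: GeneSets
    de_genes: set[str]
    curated_list: set[str]
    overlap: OverlapReport
    functional_genes: dict[str, int]  # both differentially methylated and expressed
    chisq: dict[str, tuple[float, float]]
    de_on_list: int
    de_off_list: int
    mqtl_summary: dict[str, int] | None

    def summary_lines(self) -> list[str]:
        lines = [
            f"differentially methylated genes: {len(self.gene_sets.union)} "
            f"(positive {len(self.gene_sets.positive)}, negative "
            f"{len(self.gene_sets.negative)}, both {len(self.gene_sets.both)})",
            f"differentially expressed genes: {len(self.de_genes)} "
            f"({self.de_on_list} on the curated list, {self.de_off_list} off)",
            f"methylated & expressed genes: {len(self.functional_genes)}",
        ]
        if self.mqtl_summary is not None:
            lines.append(
                f"DMLs within mQTL distance: {self.mqtl_summary['near']}, "
                f"beyond: {self.mqtl_summary['far']}"
            )
        for name, (stat, p) in self.chisq.items():
            lines.append(f"chi-square ({name} vs curated list): X2={stat:.3f}, p={p:.3g}")
        return lines


def integrate_report(
    gene_sets: GeneSets,
    de_genes: set[str],
    curated_list: set[str],
    universe: set[str],
    mqtl_summary: dict[str, int] | None = None,
) -> IntegrationReport:
    """Consolidate gene sets, overlaps, chi-square enrichments and mQTL
    counts, re-verifying every set-arithmetic identity (a violation aborts
    the run: it indicates an upstream bug)."""
    gene_sets.verify()
    meth = gene_sets.union
    overlap = overlap_sets(meth, de_genes, curated_list, universe)
    functional = {
        g: gene_sets.dml_count.get(g, 0) for g in sorted(meth & de_genes)
    }
    chisq: dict[str, tuple[float, float]] = {}
    for name, s in (("methylation", meth), ("expression", de_genes),
                    ("overlap", meth & de_genes)):
        try:
            stat, p, _ = chisq_list_enrichment(s, curated_list, universe)
            chisq[name] = (stat, p)
        except ValueError as exc:
            log.warning("chi-square for %s skipped: %s", name, exc)
    de_on = len(de_genes & curated_list)
    report = IntegrationReport(
        gene_sets=gene_sets,
        de_genes=de_genes,
        curated_list=curated_list,
        overlap=overlap,
        functional_genes=functional,
        chisq=chisq,
        de_on_list=de_on,
        de_off_list=len(de_genes) - de_on,
        mqtl_summary=mqtl_summary,
    )
    if report.de_on_list + report.de_off_list != len(de_genes):
        raise PipelineError("DE list partition identity violated")  # unreachable
    if mqtl_summary is not None and min(mqtl_summary.values()) < 0:
        raise PipelineError("negative mQTL count")
    return report
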