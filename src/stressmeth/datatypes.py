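"""Core in-memory containers shared across pipeline stages.

Tabular objects are plain :class:`pandas.DataFrame` with documented column
conventions (the idiom of this field's tooling); the dataclasses below bundle
matrices that must travel together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

#: Gene-model annotation categories a probe may carry, in display order.
STRUCTURES = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR", "Intergenic")

#: CpG-island relation categories (450k manifest vocabulary).
ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")

MANIFEST_COLUMNS = (
    "probe_id",
    "chrom",
    "pos",
    "structures",
    "island_relation",
    "snp_flag",
    "crossreactive_flag",
    "flank",
)

SAMPLE_COLUMNS = ("sample_id", "lsi_score", "age", "batch")


@dataclass
class GenomeAnnotation:
    """A miniature genome: chromosome sizes, a non-overlapping gene model and
    CpG-island intervals (all coordinates 1-based, inclusive)."""

    chromosomes: list[tuple[str, int]]
    genes: pd.DataFrame  # gene_id, chrom, strand, start, end
    islands: pd.DataFrame  # chrom, start, end

    def chrom_length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    def validate(self) -> None:
        if self.genes["gene_id"].duplicated().any():
            raise ConfigurationError("duplicate gene ids in genome annotation")
        sizes = dict(self.chromosomes)
        for df, what in ((self.genes, "gene"), (self.islands, "island")):
            for row in df.itertuples():
                length = sizes.get(row.chrom)
                if length is None:
                    raise ConfigurationError(f"{what} on unknown chromosome {row.chrom}")
                if not (1 <= row.start <= row.end <= length):
                    raise ConfigurationError(
                        f"{what} interval [{row.start}, {row.end}] outside chromosome "
                        f"{row.chrom} [1, {length}]"
                    )


@dataclass
class MethylationMatrix:
    """Beta values with matched detection p-values, probes x samples.

    Both frames are indexed by probe id with sample ids as columns; shapes and
    orderings are identical by construction.
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame

    def __post_init__(self) -> None:
        if self.beta.shape != self.detection_p.shape:
            raise ConfigurationError("beta and detection_p shapes differ")
        if not self.beta.index.equals(self.detection_p.index):
            raise ConfigurationError("beta and detection_p probe ids differ")
        b = self.beta.to_numpy()
        if np.any(b < 0) or np.any(b > 1):
            raise ConfigurationError("beta values must lie in [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns


@dataclass
class TruthTable:
    """Planted ground truth for a synthetic dataset.

    ``probes`` has columns probe_id, chrom, pos, effect (bool), effect_size
    (slope on the M-value scale per unit stress score; exactly 0 where effect
    is False).  ``features`` has feature_id, level ({gene, isoform}), gene_id,
    de (bool), effect_size (log-scale slope).  ``meth_genes`` is the set of
    genes hosting effect probes (filled once expression is generated) and
    ``motif`` the planted flank motif, if any.
    """

    probes: pd.DataFrame
    features: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["feature_id", "level", "gene_id", "de", "effect_size"]
        )
    )
    meth_genes: set[str] = field(default_factory=set)
    motif: str = ""

    def effect_probe_ids(self) -> list[str]:
        return self.probes.loc[self.probes["effect"], "probe_id"].tolist()
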