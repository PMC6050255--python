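"""On-disk formats for every pipeline stage.

Matrices travel as TSV with feature ids in the first column and sample ids
as the header; the probe manifest packs the structure list into a
semicolon-joined field; SNP tables are BED (0-based half-open); flanks are
FASTA; configuration is YAML.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .datatypes import GenomeAnnotation, MethylationMatrix, TruthTable
from .errors import PipelineError


# matrices ------------------------------------------------------------------

def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label=df.index.name or "feature_id")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_methylation(matrix: MethylationMatrix, beta_path, detection_path) -> None:
    write_matrix(matrix.beta, beta_path)
    write_matrix(matrix.detection_p, detection_path)


def read_methylation(beta_path, detection_path) -> MethylationMatrix:
    return MethylationMatrix(
        beta=read_matrix(beta_path), detection_p=read_matrix(detection_path)
    )


# manifest ------------------------------------------------------------------

def write_manifest(manifest: pd.DataFrame, path) -> None:
    out = manifest.copy()
    out["structures"] = out["structures"].map(";".join)
    out["snp_flag"] = out["snp_flag"].astype(int)
    out["crossreactive_flag"] = out["crossreactive_flag"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    man = pd.read_csv(path, sep="\t")
    man["structures"] = man["structures"].map(lambda s: s.split(";"))
    man["snp_flag"] = man["snp_flag"].astype(bool)
    man["crossreactive_flag"] = man["crossreactive_flag"].astype(bool)
    return man


# sample sheet --------------------------------------------------------------

def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, index=False)


def read_samples(path) -> pd.DataFrame:
    samples = pd.read_csv(path)
    required = {"sample_id", "lsi_score", "age", "batch"}
    missing = required - set(samples.columns)
    if missing:
        raise PipelineError(f"sample sheet {path} lacks columns {sorted(missing)}")
    for i, value in enumerate(samples["lsi_score"]):
        try:
            float(value)
        except (TypeError, ValueError):
            raise PipelineError(
                f"sample sheet {path}: non-numeric lsi_score at line {i + 2}: {value!r}"
            ) from None
    samples["lsi_score"] = samples["lsi_score"].astype(float)
    if samples["sample_id"].duplicated().any():
        raise PipelineError(f"sample sheet {path} has duplicate sample ids")
    if samples["lsi_score"].nunique() < 2:
        raise PipelineError(f"sample sheet {path} has a constant stress score")
    return samples


# SNPs (BED, 0-based half-open) ---------------------------------------------

def write_snps(snps: pd.DataFrame, path) -> None:
    bed = pd.DataFrame(
        {"chrom": snps["chrom"], "start": snps["pos"] - 1, "end": snps["pos"]}
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_snps(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end"])
    return pd.DataFrame({"chrom": bed["chrom"], "pos": bed["start"] + 1})


# gene lists ----------------------------------------------------------------

def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gene_list(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


# genome --------------------------------------------------------------------

def write_genome(genome: GenomeAnnotation, directory) -> None:
    directory = Path(directory)
    pd.DataFrame(genome.chromosomes, columns=["chrom", "length"]).to_csv(
        directory / "chromosomes.tsv", sep="\t", index=False
    )
    genome.genes.to_csv(directory / "genes.tsv", sep="\t", index=False)
    genome.islands.to_csv(directory / "islands.tsv", sep="\t", index=False)


def read_genome(directory) -> GenomeAnnotation:
    directory = Path(directory)
    chroms = pd.read_csv(directory / "chromosomes.tsv", sep="\t")
    return GenomeAnnotation(
        chromosomes=list(chroms.itertuples(index=False, name=None)),
        genes=pd.read_csv(directory / "genes.tsv", sep="\t"),
        islands=pd.read_csv(directory / "islands.tsv", sep="\t"),
    )


# truth ---------------------------------------------------------------------

def write_truth(truth: TruthTable, directory) -> None:
    directory = Path(directory)
    truth.probes.to_csv(directory / "truth_probes.tsv", sep="\t", index=False)
    truth.features.to_csv(directory / "truth_features.tsv", sep="\t", index=False)
    meta = {"motif": truth.motif, "meth_genes": sorted(truth.meth_genes)}
    (directory / "truth_meta.yaml").write_text(yaml.safe_dump(meta))


def read_truth(directory) -> TruthTable:
    directory = Path(directory)
    meta = yaml.safe_load((directory / "truth_meta.yaml").read_text())
    return TruthTable(
        probes=pd.read_csv(directory / "truth_probes.tsv", sep="\t"),
        features=pd.read_csv(directory / "truth_features.tsv", sep="\t"),
        meth_genes=set(meta["meth_genes"]),
        motif=meta["motif"] or "",
    )


# config --------------------------------------------------------------------

def read_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise PipelineError(f"config {path} is not a mapping")
    return cfg
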