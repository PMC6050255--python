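"""Synthetic dataset generation with planted truth.

Generates a miniature genome, a 450k-style probe manifest with flanking
sequence, a sample sheet carrying a continuous stress-exposure score, beta
values whose base-2 logit is linear in the score inside planted probe
clusters (with AR(1) noise along genomic order to mimic the local correlation
of methylation levels), negative-binomial expression counts sharing a planted
gene set, a curated-style gene list enriched for true-effect genes, SNP
positions, and an optional motif planted into probe flanks.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .datatypes import GenomeAnnotation, MethylationMatrix, TruthTable
from .errors import ConfigurationError

_BASES = np.array(list("ACGT"))
_LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# genome

def generate_genome(
    n_chromosomes: int, genes_per_chromosome: int, seed: int
) -> GenomeAnnotation:
    """Lay out non-overlapping genes (>= 2 kb intergenic space) and CpG
    islands on ``n_chromosomes`` chromosomes."""
    if n_chromosomes < 1 or genes_per_chromosome < 1:
        raise ConfigurationError("chromosome and gene counts must be positive")
    rng = np.random.default_rng(seed)
    chroms: list[tuple[str, int]] = []
    gene_rows = []
    island_rows = []
    gene_counter = 0
    for ci in range(n_chromosomes):
        name = f"chr{ci + 1}"
        cursor = 1 + int(rng.integers(2000, 6001))
        for _ in range(genes_per_chromosome):
            length = int(rng.integers(2000, 10001))
            start = cursor
            end = start + length - 1
            strand = "+" if rng.random() < 0.5 else "-"
            gene_counter += 1
            gene_rows.append((f"G{gene_counter:04d}", name, strand, start, end))
            # CpG island near the promoter for most genes
            if rng.random() < 0.7:
                ilen = int(rng.integers(300, 1501))
                tss = start if strand == "+" else end
                istart = max(1, tss - ilen // 2)
                island_rows.append((name, istart, istart + ilen - 1))
            cursor = end + 1 + int(rng.integers(2000, 8001))
        chroms.append((name, cursor + 5000))
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "strand", "start", "end"])
    islands = pd.DataFrame(island_rows, columns=["chrom", "start", "end"])
    # enforce non-overlap of islands per chromosome (drop later conflicting ones)
    kept = []
    for chrom, sub in islands.groupby("chrom", sort=False):
        prev_end = -1
        for row in sub.sort_values("start").itertuples(index=False):
            if row.start > prev_end:
                kept.append(row)
                prev_end = row.end
    islands = pd.DataFrame(kept, columns=["chrom", "start", "end"])
    genome = GenomeAnnotation(chroms, genes, islands)
    genome.validate()
    return genome


# ---------------------------------------------------------------------------
# probes

def _gene_structures(pos: int, start: int, end: int, strand: str) -> list[str]:
    """Annotation of ``pos`` relative to one gene (1-based coordinates).

    Upstream windows follow the array-manifest convention: TSS200 covers the
    200 bp immediately upstream of the transcription start, TSS1500 the next
    1300 bp.  The gene span is split by fractional distance from the TSS into
    5'UTR (first 10%), first exon (next 10%), body, and 3'UTR (last 10%).
    """
    out = []
    if strand == "+":
        upstream = start - pos  # > 0 when pos is 5' of the TSS
    else:
        upstream = pos - end
    if 1 <= upstream <= 200:
        out.append("TSS200")
    elif 201 <= upstream <= 1500:
        out.append("TSS1500")
    if start <= pos <= end:
        span = end - start
        f = (pos - start) / span if strand == "+" else (end - pos) / span
        if f < 0.1:
            out.append("5UTR")
        elif f < 0.2:
            out.append("1stExon")
        elif f < 0.9:
            out.append("Body")
        else:
            out.append("3UTR")
    return out


def _island_relation(pos: int, islands: pd.DataFrame) -> str:
    """Closest-feature CpG-island relation (Island > Shore > Shelf > OpenSea).
    N_* is the lower-coordinate side."""
    best = "OpenSea"
    rank = {"Island": 0, "N_Shore": 1, "S_Shore": 1, "N_Shelf": 2, "S_Shelf": 2, "OpenSea": 3}
    for row in islands.itertuples(index=False):
        if row.start <= pos <= row.end:
            return "Island"
        if row.start - 2000 <= pos < row.start:
            cand = "N_Shore"
        elif row.end < pos <= row.end + 2000:
            cand = "S_Shore"
        elif row.start - 4000 <= pos < row.start - 2000:
            cand = "N_Shelf"
        elif row.end + 2000 < pos <= row.end + 4000:
            cand = "S_Shelf"
        else:
            continue
        if rank[cand] < rank[best]:
            best = cand
    return best


def annotate_position(genome: GenomeAnnotation, chrom: str, pos: int) -> tuple[list[str], str]:
    """Structures and island relation for a single genomic position."""
    structures: list[str] = []
    for row in genome.genes[genome.genes["chrom"] == chrom].itertuples(index=False):
        structures.extend(_gene_structures(pos, row.start, row.end, row.strand))
    if not structures:
        structures = ["Intergenic"]
    rel = _island_relation(pos, genome.islands[genome.islands["chrom"] == chrom])
    return structures, rel


def generate_probes(
    genome: GenomeAnnotation,
    n_probes: int,
    flag_rates: dict[str, float] | None = None,
    seed: int = 0,
    flank_halfwidth: int = 250,
) -> pd.DataFrame:
    """Place probes uniformly along the genome, annotate each to every gene
    structure its position overlaps plus its island relation, draw SNP /
    cross-reactive flags independently, and attach a random flanking sequence
    of length ``2 * flank_halfwidth + 1``."""
    if n_probes < 1:
        raise ConfigurationError("n_probes must be >= 1")
    flag_rates = dict(flag_rates or {})
    for key, rate in flag_rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ConfigurationError(f"flag rate {key}={rate} outside [0, 1]")
    total = sum(length for _, length in genome.chromosomes)
    if n_probes > total:
        raise ConfigurationError(
            f"n_probes={n_probes} exceeds the {total} CpG-eligible positions"
        )
    rng = np.random.default_rng(seed)
    # allocate probes to chromosomes proportionally to length
    lengths = np.array([length for _, length in genome.chromosomes], dtype=float)
    alloc = np.floor(n_probes * lengths / lengths.sum()).astype(int)
    for i in range(n_probes - alloc.sum()):
        alloc[i % len(alloc)] += 1
    rows = []
    for (chrom, length), k in zip(genome.chromosomes, alloc):
        if k == 0:
            continue
        positions = np.sort(rng.choice(length, size=k, replace=False)) + 1
        for pos in positions:
            structures, rel = annotate_position(genome, chrom, int(pos))
            rows.append((chrom, int(pos), structures, rel))
    rows.sort(key=lambda r: (int(r[0][3:]), r[1]))
    n = len(rows)
    snp = rng.random(n) < flag_rates.get("snp", 0.0)
    xr = rng.random(n) < flag_rates.get("crossreactive", 0.0)
    flank_len = 2 * flank_halfwidth + 1
    flanks = rng.integers(0, 4, size=(n, flank_len))
    manifest = pd.DataFrame(
        {
            "probe_id": [f"cg{i + 1:06d}" for i in range(n)],
            "chrom": [r[0] for r in rows],
            "pos": [r[1] for r in rows],
            "structures": [r[2] for r in rows],
            "island_relation": [r[3] for r in rows],
            "snp_flag": snp,
            "crossreactive_flag": xr,
            "flank": ["".join(_BASES[row]) for row in flanks],
        }
    )
    return manifest


# ---------------------------------------------------------------------------
# samples

def generate_samples(
    n_samples: int = 22,
    score_range: tuple[float, float] = (1.0, 5.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Sample sheet: stress scores spanning ``score_range`` (half the cohort
    in the lower half of the range, half in the upper, mirroring a
    normative/high-stress design), ages 9-12, alternating batch labels."""
    if n_samples < 4:
        raise ConfigurationError(
            "n_samples must be >= 4 (regression has 3 covariate columns)"
        )
    lo, hi = float(score_range[0]), float(score_range[1])
    if not lo < hi:
        raise ConfigurationError("score_range must have distinct endpoints")
    rng = np.random.default_rng(seed)
    scores = np.linspace(lo, hi, n_samples)
    jitter = rng.uniform(-0.08, 0.08, n_samples) * (hi - lo)
    scores[1:-1] = np.clip(scores[1:-1] + jitter[1:-1], lo, hi)
    ages = np.round(rng.uniform(9.0, 12.0, n_samples), 1)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:02d}" for i in range(n_samples)],
            "lsi_score": np.round(scores, 3),
            "age": ages,
            "batch": ["chip1" if i % 2 == 0 else "chip2" for i in range(n_samples)],
        }
    )


# ---------------------------------------------------------------------------
# methylation

@dataclass
class MethylationEffectConfig:
    """Planted-effect and noise model for the beta-value generator.

    Effects are slopes on the M-value (base-2 logit) scale per unit stress
    score, constant-sign within each planted cluster.  Noise is AR(1) along
    probe order within each chromosome with marginal SD ``noise_sd``.
    """

    n_clusters: int = 10
    cluster_width: int = 12
    effect_low: float = 0.2
    effect_high: float = 0.5
    noise_sd: float = 0.35
    ar_rho: float = 0.3
    age_sd: float = 0.01
    batch_sd: float = 0.05
    detection_fail_rate: float = 0.002
    baseline_mean_abs: float = 3.0
    baseline_sd: float = 1.0


def _place_clusters(
    manifest: pd.DataFrame, n_clusters: int, width: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Non-overlapping, non-adjacent runs of ``width`` probes, each within a
    single chromosome (so truth clusters are contiguous in genomic order)."""
    segments = []  # (global start index, segment length)
    idx = 0
    for _, sub in manifest.groupby("chrom", sort=False):
        segments.append((idx, len(sub)))
        idx += len(sub)
    eligible = [(s, n) for s, n in segments if n >= width]
    if not eligible:
        raise ConfigurationError("no chromosome holds enough probes for a cluster")
    taken: list[tuple[int, int]] = []
    clusters = []
    for _ in range(n_clusters):
        for _attempt in range(2000):
            weights = np.array([n for _, n in eligible], dtype=float)
            s, n = eligible[rng.choice(len(eligible), p=weights / weights.sum())]
            start = s + int(rng.integers(0, n - width + 1))
            stop = start + width
            if all(stop < a or start > b + 1 for a, b in taken):
                taken.append((start, stop - 1))
                clusters.append(np.arange(start, stop))
                break
        else:
            raise ConfigurationError(
                f"could not place {n_clusters} disjoint clusters of width {width}"
            )
    return clusters


def generate_methylation(
    manifest: pd.DataFrame,
    samples: pd.DataFrame,
    effect_config: MethylationEffectConfig | None = None,
    seed: int = 0,
) -> tuple[MethylationMatrix, TruthTable]:
    """Beta values whose M-value is linear in stress score inside planted
    clusters, plus matched detection p-values and the truth table."""
    cfg = effect_config or MethylationEffectConfig()
    if cfg.noise_sd < 0:
        raise ConfigurationError("noise_sd must be non-negative")
    if not -1 < cfg.ar_rho < 1:
        raise ConfigurationError("ar_rho must lie in (-1, 1)")
    rng = np.random.default_rng(seed)
    n_probes = len(manifest)
    n_samples = len(samples)
    lsi = samples["lsi_score"].to_numpy(float)
    age = samples["age"].to_numpy(float)
    batch = (samples["batch"] != samples["batch"].iloc[0]).to_numpy(float)

    effect = np.zeros(n_probes, dtype=bool)
    effect_size = np.zeros(n_probes)
    if cfg.n_clusters > 0:
        for cluster in _place_clusters(manifest, cfg.n_clusters, cfg.cluster_width, rng):
            sign = 1.0 if rng.random() < 0.5 else -1.0
            effect[cluster] = True
            effect_size[cluster] = sign * rng.uniform(
                cfg.effect_low, cfg.effect_high, size=len(cluster)
            )

    hyper = rng.random(n_probes) < 0.5
    baseline = np.where(
        hyper,
        rng.normal(cfg.baseline_mean_abs, cfg.baseline_sd, n_probes),
        rng.normal(-cfg.baseline_mean_abs, cfg.baseline_sd, n_probes),
    )
    age_coef = rng.normal(0.0, cfg.age_sd, n_probes) if cfg.age_sd > 0 else np.zeros(n_probes)
    batch_coef = (
        rng.normal(0.0, cfg.batch_sd, n_probes) if cfg.batch_sd > 0 else np.zeros(n_probes)
    )

    noise = np.zeros((n_probes, n_samples))
    if cfg.noise_sd > 0:
        innov_scale = cfg.noise_sd * math.sqrt(1.0 - cfg.ar_rho**2)
        start = 0
        for _, sub in manifest.groupby("chrom", sort=False):
            seg = len(sub)
            e = np.empty((seg, n_samples))
            e[0] = rng.normal(0.0, cfg.noise_sd, n_samples)
            eta = rng.normal(0.0, innov_scale, (seg - 1, n_samples)) if seg > 1 else None
            for t in range(1, seg):
                e[t] = cfg.ar_rho * e[t - 1] + eta[t - 1]
            noise[start : start + seg] = e
            start += seg

    m = (
        baseline[:, None]
        + effect_size[:, None] * lsi[None, :]
        + age_coef[:, None] * age[None, :]
        + batch_coef[:, None] * batch[None, :]
        + noise
    )
    beta = expit(m * _LN2)  # inverse base-2 logit
    eps = 1e-12
    beta = np.clip(beta, eps, 1.0 - eps)

    det = rng.uniform(0.0, 0.01, (n_probes, n_samples))
    if cfg.detection_fail_rate > 0:
        fail = rng.random((n_probes, n_samples)) < cfg.detection_fail_rate
        det[fail] = rng.uniform(0.01, 1.0, int(fail.sum()))

    index = pd.Index(manifest["probe_id"], name="probe_id")
    cols = pd.Index(samples["sample_id"], name="sample_id")
    matrix = MethylationMatrix(
        beta=pd.DataFrame(beta, index=index, columns=cols),
        detection_p=pd.DataFrame(det, index=index, columns=cols),
    )
    truth = TruthTable(
        probes=pd.DataFrame(
            {
                "probe_id": manifest["probe_id"].to_numpy(),
                "chrom": manifest["chrom"].to_numpy(),
                "pos": manifest["pos"].to_numpy(),
                "effect": effect,
                "effect_size": effect_size,
            }
        )
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# expression

@dataclass
class ExpressionConfig:
    """Negative-binomial count model: log2 mean linear in stress score for
    differentially expressed features (base-2 so planted slopes live on the
    same scale the DE stage fits after its log2 transform)."""

    de_fraction: float = 0.1
    overlap_fraction: float = 0.5  # share of DE genes drawn from methylation-effect genes
    dispersion: float = 0.1
    mean_depth: float = 500.0
    effect_low: float = 0.2  # |log2-scale slope| per unit stress score
    effect_high: float = 0.5
    size_factor_sd: float = 0.2
    max_isoforms: int = 3


def _host_genes(truth: TruthTable, genome: GenomeAnnotation) -> set[str]:
    """Genes hosting (containing or nearest to) the planted effect probes."""
    from .integrate import nearest_gene  # local import avoids a cycle at import time

    hosts = set()
    eff = truth.probes[truth.probes["effect"]]
    for row in eff.itertuples(index=False):
        gene = nearest_gene(genome, row.chrom, int(row.pos))
        if gene is not None:
            hosts.add(gene)
    return hosts


def generate_expression(
    genome: GenomeAnnotation,
    samples: pd.DataFrame,
    truth: TruthTable,
    de_config: ExpressionConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthTable]:
    """Gene- and isoform-level count matrices; a configured fraction of DE
    genes coincides with genes hosting methylation-effect probes."""
    cfg = de_config or ExpressionConfig()
    if cfg.dispersion <= 0:
        raise ConfigurationError("dispersion must be positive")
    if not 0.0 <= cfg.de_fraction <= 1.0 or not 0.0 <= cfg.overlap_fraction <= 1.0:
        raise ConfigurationError("de_fraction and overlap_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    gene_ids = genome.genes["gene_id"].tolist()
    n_genes = len(gene_ids)
    lsi = samples["lsi_score"].to_numpy(float)
    lsi_c = lsi - lsi.mean()

    meth_genes = _host_genes(truth, genome)
    n_de = int(round(cfg.de_fraction * n_genes))
    n_from_meth = min(int(round(cfg.overlap_fraction * n_de)), len(meth_genes), n_de)
    meth_pool = sorted(meth_genes)
    other_pool = [g for g in gene_ids if g not in meth_genes]
    de_genes = list(rng.choice(meth_pool, n_from_meth, replace=False)) if n_from_meth else []
    n_rest = n_de - len(de_genes)
    if n_rest > len(other_pool):
        raise ConfigurationError("requested more DE genes than available")
    de_genes += list(rng.choice(other_pool, n_rest, replace=False)) if n_rest else []
    de_set = set(de_genes)

    size_f = rng.normal(0.0, cfg.size_factor_sd, n_genes)
    slopes = np.zeros(n_genes)
    for i, g in enumerate(gene_ids):
        if g in de_set:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            slopes[i] = sign * rng.uniform(cfg.effect_low, cfg.effect_high)

    mu = cfg.mean_depth * 2.0 ** (size_f[:, None] + slopes[:, None] * lsi_c[None, :])
    nb_n = 1.0 / cfg.dispersion
    gene_counts = rng.negative_binomial(nb_n, nb_n / (nb_n + mu))

    iso_rows = []
    iso_ids = []
    iso_parent = []
    feature_rows = []
    for i, g in enumerate(gene_ids):
        feature_rows.append((g, "gene", g, g in de_set, slopes[i]))
        k = int(rng.integers(1, cfg.max_isoforms + 1))
        shares = rng.dirichlet(np.ones(k))
        for j in range(k):
            iso_mu = mu[i] * shares[j]
            iso_rows.append(rng.negative_binomial(nb_n, nb_n / (nb_n + iso_mu)))
            iso_id = f"{g}.{j + 1}"
            iso_ids.append(iso_id)
            iso_parent.append(g)
            feature_rows.append((iso_id, "isoform", g, g in de_set, slopes[i]))

    cols = pd.Index(samples["sample_id"], name="sample_id")
    gene_df = pd.DataFrame(gene_counts, index=pd.Index(gene_ids, name="feature_id"), columns=cols)
    iso_df = pd.DataFrame(
        np.vstack(iso_rows), index=pd.Index(iso_ids, name="feature_id"), columns=cols
    )
    truth.features = pd.DataFrame(
        feature_rows, columns=["feature_id", "level", "gene_id", "de", "effect_size"]
    )
    truth.meth_genes = meth_genes
    return gene_df, iso_df, truth


# ---------------------------------------------------------------------------
# gene list, SNPs, motif

def generate_gene_list(
    genes: list[str],
    truth: TruthTable,
    enrichment_factor: float = 3.0,
    seed: int = 0,
    base_rate: float = 0.2,
) -> list[str]:
    """A curated-style gene list: true-effect genes (methylation hosts or DE
    genes) enter at ``enrichment_factor`` times the base rate, capped at 1."""
    if not genes:
        raise ConfigurationError("gene universe is empty")
    if enrichment_factor < 1:
        raise ConfigurationError("enrichment_factor must be >= 1")
    rng = np.random.default_rng(seed)
    de_genes = set(
        truth.features.loc[truth.features["de"], "gene_id"]
    ) if len(truth.features) else set()
    hot = truth.meth_genes | de_genes
    p_hot = min(1.0, base_rate * enrichment_factor)
    draws = rng.random(len(genes))
    return [
        g
        for g, u in zip(genes, draws)
        if u < (p_hot if g in hot else base_rate)
    ]


def generate_snps(genome: GenomeAnnotation, n_snps: int, seed: int = 0) -> pd.DataFrame:
    """Uniformly placed SNP positions (the mQTL proximity-filter input)."""
    if n_snps < 0:
        raise ConfigurationError("n_snps must be non-negative")
    rng = np.random.default_rng(seed)
    lengths = np.array([length for _, length in genome.chromosomes], dtype=float)
    alloc = rng.multinomial(n_snps, lengths / lengths.sum())
    rows = []
    for (chrom, length), k in zip(genome.chromosomes, alloc):
        positions = np.sort(rng.choice(length, size=min(k, length), replace=False)) + 1
        rows.extend((chrom, int(p)) for p in positions)
    return pd.DataFrame(rows, columns=["chrom", "pos"])


def plant_motif(
    manifest: pd.DataFrame,
    motif: str,
    fraction: float,
    which_probes: list[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Insert ``motif`` (replacing bases, length preserved) at a random offset
    in the flanks of ``round(fraction * n)`` of the designated probes."""
    motif = motif.upper()
    if not 4 <= len(motif) <= 12 or set(motif) - set("ACGT"):
        raise ConfigurationError("motif must be a DNA string of length 4-12")
    if not 0.0 <= fraction <= 1.0:
        raise ConfigurationError("fraction must lie in [0, 1]")
    out = manifest.copy()
    ids = list(which_probes) if which_probes is not None else out["probe_id"].tolist()
    flank_len = len(out["flank"].iloc[0]) if len(out) else 0
    if len(motif) > flank_len:
        raise ConfigurationError("motif longer than the stored flank")
    count = int(round(fraction * len(ids)))
    if count == 0:
        return out
    rng = np.random.default_rng(seed)
    chosen = rng.permutation(ids)[:count]
    flank_col = out.columns.get_loc("flank")
    lookup = {pid: i for i, pid in enumerate(out["probe_id"])}
    for pid in chosen:
        i = lookup[pid]
        flank = out.iat[i, flank_col]
        off = int(rng.integers(0, len(flank) - len(motif) + 1))
        out.iat[i, flank_col] = flank[:off] + motif + flank[off + len(motif):]
    return out


# ---------------------------------------------------------------------------
# one-call dataset

@dataclass
class SimulationConfig:
    """Full-dataset configuration with study-scale defaults: 22 samples with
    stress scores on a 1-5 scale, 2000 probes across 4 chromosomes, 10 planted
    clusters of 12 probes."""

    n_chromosomes: int = 4
    genes_per_chromosome: int = 25
    n_probes: int = 2000
    n_samples: int = 22
    score_range: tuple[float, float] = (1.0, 5.0)
    flag_rates: dict = field(default_factory=lambda: {"snp": 0.02, "crossreactive": 0.01})
    n_snps: int = 300
    methylation: MethylationEffectConfig = field(default_factory=MethylationEffectConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    list_enrichment_factor: float = 3.0
    list_base_rate: float = 0.2
    motif: str = ""  # planted into effect-probe flanks when non-empty
    motif_fraction: float = 0.3


@dataclass
class Dataset:
    genome: GenomeAnnotation
    manifest: pd.DataFrame
    samples: pd.DataFrame
    methylation: MethylationMatrix
    gene_counts: pd.DataFrame
    isoform_counts: pd.DataFrame
    gene_list: list[str]
    snps: pd.DataFrame
    truth: TruthTable


def simulate_dataset(config: SimulationConfig | None = None, seed: int = 0) -> Dataset:
    """Run every generator with sub-seeds derived from ``seed``."""
    cfg = config or SimulationConfig()
    ss = np.random.SeedSequence(seed).spawn(7)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    genome = generate_genome(cfg.n_chromosomes, cfg.genes_per_chromosome, sub[0])
    manifest = generate_probes(genome, cfg.n_probes, cfg.flag_rates, sub[1])
    samples = generate_samples(cfg.n_samples, cfg.score_range, sub[2])
    meth, truth = generate_methylation(manifest, samples, cfg.methylation, sub[3])
    gene_counts, iso_counts, truth = generate_expression(
        genome, samples, truth, cfg.expression, sub[4]
    )
    gene_list = generate_gene_list(
        genome.genes["gene_id"].tolist(),
        truth,
        cfg.list_enrichment_factor,
        sub[5],
        cfg.list_base_rate,
    )
    snps = generate_snps(genome, cfg.n_snps, sub[6])
    if cfg.motif:
        manifest = plant_motif(
            manifest, cfg.motif, cfg.motif_fraction, truth.effect_probe_ids(), sub[1]
        )
        truth.motif = cfg.motif
    return Dataset(
        genome, manifest, samples, meth, gene_counts, iso_counts, gene_list, snps, truth
    )
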