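"""End-to-end validation studies on synthetic data with planted truth.

These routines run the pipeline under its default study conditions (22
samples, 2,000 probes, 10 planted clusters of 12 probes) and measure
operating characteristics: realized false-discovery proportion of the
aLIS procedure, power against probe-wise Benjamini-Hochberg at matched
realized FDR, direction-classification fidelity, null calibration of the
expression stage, agreement of the permutation test with its closed-form
hypergeometric special case, and planted-motif recovery.  They back both the
test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import simulate as sim
from .dml import call_dmls, classify_direction
from .enrichment import permute_structures
from .expression import fit_de, normalize_counts
from .integrate import GeneSets, integrate_report
from .motif import kmer_enrichment, shuffle_background
from .preprocess import filter_probes


def _sub_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# FDR / power / direction replicates

def bh_matched_recall(
    p: np.ndarray, truth: np.ndarray, target_fdp: float
) -> tuple[float, float]:
    """Recall and realized FDP of the largest p-value-ordered rejection
    prefix whose realized false-discovery proportion does not exceed
    ``target_fdp`` (probe-wise BH given the most favourable threshold)."""
    order = np.argsort(p, kind="stable")
    is_true = truth[order]
    fp = np.cumsum(~is_true)
    k = np.arange(1, len(p) + 1)
    fdp = fp / k
    ok = np.where(fdp <= target_fdp + 1e-12)[0]
    if len(ok) == 0:
        return 0.0, 0.0
    best = ok[-1]
    tp = int(is_true[: best + 1].sum())
    return tp / max(1, int(truth.sum())), float(fdp[best])


def run_replicate(seed: int, alpha: float = 0.05) -> dict[str, float]:
    """One default-condition replicate: simulate, filter, call DMLs, and
    score calls against the planted truth."""
    cfg = sim.SimulationConfig()
    ds = sim.simulate_dataset(cfg, seed)
    filtered, _ = filter_probes(ds.methylation, ds.manifest)
    result = call_dmls(filtered, ds.manifest, ds.samples, alpha=alpha, seed=seed)
    table = result.table
    truth = ds.truth.probes.set_index("probe_id")
    is_true = truth.loc[table.index, "effect"].to_numpy(bool)
    called = table["called"].to_numpy(bool)
    n_called = int(called.sum())
    tp = int((called & is_true).sum())
    fdp = 0.0 if n_called == 0 else 1.0 - tp / n_called
    n_true = int(is_true.sum())
    recall = tp / max(1, n_true)
    usable = table["p_mod"].notna().to_numpy()
    bh_recall, bh_fdp = bh_matched_recall(
        table.loc[usable, "p_mod"].to_numpy(), is_true[usable], fdp
    )
    # direction fidelity among called true-effect probes
    agree = np.nan
    called_true = table.index[(called & is_true)]
    if len(called_true):
        signs = np.sign(truth.loc[called_true, "effect_size"].to_numpy(float))
        dirs = table.loc[called_true, "direction"].map(
            {"positive": 1.0, "negative": -1.0}
        ).to_numpy()
        agree = float((signs == dirs).mean())
    return {
        "n_called": n_called,
        "fdp": fdp,
        "recall": recall,
        "bh_recall": bh_recall,
        "bh_fdp": bh_fdp,
        "direction_agreement": agree,
    }


def fdr_power_study(n_replicates: int = 20, seed: int = 0) -> pd.DataFrame:
    """Replicated operating characteristics of the default study."""
    return pd.DataFrame([run_replicate(s) for s in _sub_seeds(seed, n_replicates)])


# ---------------------------------------------------------------------------
# noiseless direction fidelity

def noiseless_direction_agreement(seed: int = 0) -> float:
    """Direction classification on noiseless planted effects (beta exactly
    monotone in the score): agreement with the planted slope sign."""
    cfg = sim.SimulationConfig()
    cfg.methylation = sim.MethylationEffectConfig(
        noise_sd=0.0, age_sd=0.0, batch_sd=0.0, detection_fail_rate=0.0
    )
    genome = sim.generate_genome(cfg.n_chromosomes, cfg.genes_per_chromosome, seed)
    manifest = sim.generate_probes(genome, cfg.n_probes, {}, seed + 1)
    samples = sim.generate_samples(cfg.n_samples, cfg.score_range, seed + 2)
    matrix, truth = sim.generate_methylation(manifest, samples, cfg.methylation, seed + 3)
    effect_ids = truth.effect_probe_ids()
    dirs = classify_direction(matrix.beta, samples, effect_ids)
    signs = truth.probes.set_index("probe_id").loc[effect_ids, "effect_size"]
    expected = np.where(signs.to_numpy(float) > 0, "positive", "negative")
    return float((dirs["direction"].to_numpy() == expected).mean())


# ---------------------------------------------------------------------------
# expression null calibration

def de_null_calibration(n_seeds: int = 20, seed: int = 0) -> dict[str, float]:
    """No planted DE: per-seed called fraction at p < 0.05 and a pooled
    Kolmogorov-Smirnov comparison of the p-values with Uniform(0, 1)."""
    fracs = []
    pool: list[float] = []
    for s in _sub_seeds(seed, n_seeds):
        genome = sim.generate_genome(2, 100, s)
        samples = sim.generate_samples(22, (1.0, 5.0), s + 1)
        truth = sim.TruthTable(probes=pd.DataFrame(
            columns=["probe_id", "chrom", "pos", "effect", "effect_size"]))
        counts, _, _ = sim.generate_expression(
            genome, samples, truth, sim.ExpressionConfig(de_fraction=0.0), s + 2
        )
        stats_df = fit_de(normalize_counts(counts), samples)
        fracs.append(float(stats_df["called"].mean()))
        pool.extend(stats_df["p_mod"].tolist())
    ks = stats.kstest(pool, "uniform")
    return {
        "mean_called_fraction": float(np.mean(fracs)),
        "ks_statistic": float(ks.statistic),
        "ks_p": float(ks.pvalue),
    }


# ---------------------------------------------------------------------------
# permutation vs hypergeometric oracle

def perm_hypergeom_agreement(
    n_universe: int = 200,
    n_category: int = 40,
    n_draws: int = 20,
    actual: int = 15,
    reps: int = 10_000,
    seed: int = 0,
) -> dict[str, float]:
    """Single-annotation universe where the permutation enrichment p has the
    closed form P(X >= actual), X ~ Hypergeom(N, K, n)."""
    universe = ["Island"] * n_category + ["Body"] * (n_universe - n_category)
    res = permute_structures(universe, n_draws, {"Island": actual}, reps=reps, seed=seed)
    p_perm = float(res.loc[res["category"] == "Island", "p_enrich"].iloc[0])
    p_exact = float(stats.hypergeom.sf(actual - 1, n_universe, n_category, n_draws))
    return {"p_perm": p_perm, "p_exact": p_exact, "abs_diff": abs(p_perm - p_exact)}


# ---------------------------------------------------------------------------
# motif recovery

def motif_recovery_study(
    motif: str = "TACGTA",
    n_sequences: int = 200,
    fraction: float = 0.3,
    n_seeds: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Fraction of seeds in which the planted 6-mer (or its reverse
    complement) is the minimum-E k-mer against a dinucleotide-shuffled
    background."""
    from .motif import revcomp

    wins = 0
    for s in _sub_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        bases = np.array(list("ACGT"))
        seqs = {
            f"seq{i}": "".join(bases[rng.integers(0, 4, 501)]) for i in range(n_sequences)
        }
        n_plant = int(round(fraction * n_sequences))
        for name in list(seqs)[:n_plant]:
            seq = seqs[name]
            off = int(rng.integers(0, len(seq) - len(motif) + 1))
            seqs[name] = seq[:off] + motif + seq[off + len(motif):]
        bg = shuffle_background(seqs, "dinucleotide", s + 1)
        results = kmer_enrichment(seqs, bg, 4, 8, e_cutoff=np.inf)
        if results and results[0].kmer in (motif, revcomp(motif)):
            wins += 1
    return {"wins": wins, "n_seeds": n_seeds, "recovery_rate": wins / n_seeds}


# ---------------------------------------------------------------------------
# worked-example fixture at published cardinalities

def reference_count_example() -> dict[str, int]:
    """Set-arithmetic worked example at the scale of a published saliva
    methylome study: 550 DMLs (357 positive, 193 negative) mapping onto 84
    positively and 50 negatively correlated genes with 12 genes carrying
    both kinds, 1,405 DE genes of which 349 sit on a curated stress list,
    and 456 of the 550 DMLs beyond 200 bp of any catalogued SNP.  Everything
    reported is recomputed through the aggregation/report operations."""
    n_pos_dml, n_neg_dml = 357, 193
    n_pos_gene, n_neg_gene, n_both = 84, 50, 12
    pos_only = [f"GP{i:04d}" for i in range(n_pos_gene - n_both)]
    neg_only = [f"GN{i:04d}" for i in range(n_neg_gene - n_both)]
    both = [f"GB{i:04d}" for i in range(n_both)]
    pos_genes = pos_only + both
    neg_genes = neg_only + both
    assignments: dict[str, str] = {}
    directions: dict[str, str] = {}
    for i in range(n_pos_dml):
        pid = f"cgp{i:05d}"
        assignments[pid] = pos_genes[i % len(pos_genes)]
        directions[pid] = "positive"
    for i in range(n_neg_dml):
        pid = f"cgn{i:05d}"
        assignments[pid] = neg_genes[i % len(neg_genes)]
        directions[pid] = "negative"
    from .integrate import aggregate_genes

    sets = aggregate_genes(pd.Series(assignments), pd.Series(directions))

    meth_genes = sets.union
    n_de, n_de_on_list = 1405, 349
    de_genes = {f"GE{i:05d}" for i in range(n_de - n_de_on_list)} | {
        f"GL{i:05d}" for i in range(n_de_on_list)
    }
    curated = {f"GL{i:05d}" for i in range(4286)}
    universe = meth_genes | de_genes | curated | {
        f"GU{i:05d}" for i in range(23_407 - len(meth_genes | de_genes | curated))
    }
    mqtl_summary = {"near": 550 - 456, "far": 456}
    report = integrate_report(sets, de_genes, curated, universe, mqtl_summary)
    return {
        "total_dmls": n_pos_dml + n_neg_dml,
        "positive_dmls": n_pos_dml,
        "negative_dmls": n_neg_dml,
        "meth_genes_positive": len(report.gene_sets.positive),
        "meth_genes_negative": len(report.gene_sets.negative),
        "meth_genes_both": len(report.gene_sets.both),
        "meth_genes_union": len(report.gene_sets.union),
        "de_genes": len(report.de_genes),
        "de_genes_on_list": report.de_on_list,
        "de_genes_off_list": report.de_off_list,
        "dmls_far_from_mqtl": report.mqtl_summary["far"],
        "dmls_near_mqtl": report.mqtl_summary["near"],
    }
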