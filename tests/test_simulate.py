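"""Generator correctness: determinism, interval containment, planted truth
structure, and the statistical moments the downstream stages rely on."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from stressmeth import simulate as sim
from stressmeth.datatypes import TruthTable
from stressmeth.errors import ConfigurationError


class TestGenome:
    def test_deterministic_for_fixed_seed(self):
        a = sim.generate_genome(1, 5, seed=7)
        b = sim.generate_genome(1, 5, seed=7)
        assert a.chromosomes == b.chromosomes
        pd.testing.assert_frame_equal(a.genes, b.genes)
        pd.testing.assert_frame_equal(a.islands, b.islands)

    def test_intervals_within_bounds_exhaustive(self):
        g = sim.generate_genome(3, 10, seed=3)
        assert len(g.genes) == 30
        sizes = dict(g.chromosomes)
        for row in g.genes.itertuples():  # brute-force containment scan
            assert 1 <= row.start <= row.end <= sizes[row.chrom]
        # non-overlap and >= 2 kb intergenic spacing per chromosome
        for _, sub in g.genes.groupby("chrom"):
            s = sub.sort_values("start")
            gaps = s["start"].to_numpy()[1:] - s["end"].to_numpy()[:-1]
            assert (gaps >= 2000).all()

    @pytest.mark.parametrize("args", [(2, 0), (0, 5), (-1, 3)])
    def test_degenerate_counts_rejected(self, args):
        with pytest.raises(ConfigurationError):
            sim.generate_genome(*args, seed=1)


class TestProbes:
    def test_tss200_window(self, toy_genome):
        structures, _ = sim.annotate_position(toy_genome, "chr1", 4900)  # TSS-100
        assert "TSS200" in structures

    def test_tss1500_window(self, toy_genome):
        structures, _ = sim.annotate_position(toy_genome, "chr1", 4000)  # TSS-1000
        assert "TSS1500" in structures

    def test_shore_one_kb_beyond_island(self, toy_genome):
        _, rel = sim.annotate_position(toy_genome, "chr1", 7400)  # 1 kb past island end
        assert rel == "S_Shore"

    def test_island_and_body_both_annotated(self, toy_genome):
        structures, rel = sim.annotate_position(toy_genome, "chr1", 6200)
        assert rel == "Island"
        assert "Body" in structures

    def test_intergenic_fallback(self, toy_genome):
        structures, rel = sim.annotate_position(toy_genome, "chr1", 15000)
        assert structures == ["Intergenic"]
        assert rel == "OpenSea"

    def test_flag_rate_binomial_tolerance(self, genome):
        man = sim.generate_probes(genome, 1000, {"snp": 0.05}, seed=2)
        assert abs(man["snp_flag"].mean() - 0.05) <= 0.02

    def test_positions_sorted_and_ids_unique(self, genome):
        man = sim.generate_probes(genome, 500, {}, seed=4)
        assert man["probe_id"].is_unique
        for _, sub in man.groupby("chrom"):
            assert sub["pos"].is_monotonic_increasing
        assert man["flank"].str.len().eq(501).all()
        assert man["flank"].str.fullmatch("[ACGTN]+").all()

    def test_too_many_probes_rejected(self, toy_genome):
        with pytest.raises(ConfigurationError):
            sim.generate_probes(toy_genome, 10**6, {}, seed=1)


class TestSamples:
    def test_defaults_match_study_design(self):
        s = sim.generate_samples(22, (1, 5), seed=1)
        assert len(s) == 22
        assert s["age"].between(9, 12).all()
        assert s["lsi_score"].min() == 1 and s["lsi_score"].max() == 5
        assert set(s["batch"]) == {"chip1", "chip2"}

    def test_underdetermined_design_rejected(self):
        with pytest.raises(ConfigurationError):
            sim.generate_samples(3, (1, 5), seed=1)

    def test_constant_score_rejected(self):
        with pytest.raises(ConfigurationError):
            sim.generate_samples(22, (2, 2), seed=1)


class TestMethylation:
    def _noiseless(self, genome, seed=5):
        cfg = sim.MethylationEffectConfig(
            n_clusters=3, cluster_width=5, noise_sd=0.0, age_sd=0.0,
            batch_sd=0.0, detection_fail_rate=0.0,
        )
        man = sim.generate_probes(genome, 300, {}, seed=seed)
        samples = sim.generate_samples(12, (1, 5), seed=seed)
        return man, samples, *sim.generate_methylation(man, samples, cfg, seed=seed)

    def test_noiseless_slope_recovery_machine_precision(self, genome):
        man, samples, matrix, truth = self._noiseless(genome)
        m = np.log2(matrix.beta / (1 - matrix.beta)).to_numpy()
        x = np.column_stack([
            np.ones(len(samples)), samples["lsi_score"], samples["age"],
            (samples["batch"] != "chip1").astype(float),
        ])
        slopes = np.linalg.lstsq(x, m.T, rcond=None)[0][1]
        np.testing.assert_allclose(slopes, truth.probes["effect_size"], atol=1e-8)

    def test_planted_cluster_count_and_contiguity(self, genome):
        man = sim.generate_probes(genome, 2000, {}, seed=6)
        samples = sim.generate_samples(22, (1, 5), seed=6)
        cfg = sim.MethylationEffectConfig(n_clusters=10, cluster_width=12)
        _, truth = sim.generate_methylation(man, samples, cfg, seed=6)
        eff = truth.probes["effect"].to_numpy()
        assert eff.sum() == 120
        boundaries = np.flatnonzero(np.diff(np.r_[0, eff.astype(int), 0]) != 0)
        assert len(boundaries) == 2 * 10  # run-length scan: 10 contiguous runs
        assert (truth.probes.loc[~truth.probes["effect"], "effect_size"] == 0).all()

    def test_zero_clusters_means_no_effects(self, genome):
        man = sim.generate_probes(genome, 200, {}, seed=7)
        samples = sim.generate_samples(8, (1, 5), seed=7)
        cfg = sim.MethylationEffectConfig(n_clusters=0)
        _, truth = sim.generate_methylation(man, samples, cfg, seed=7)
        assert not truth.probes["effect"].any()

    def test_betas_strictly_inside_unit_interval(self, small_dataset):
        b = small_dataset.methylation.beta.to_numpy()
        assert (b > 0).all() and (b < 1).all()

    def test_negative_noise_rejected(self, genome):
        man = sim.generate_probes(genome, 120, {}, seed=8)
        samples = sim.generate_samples(8, (1, 5), seed=8)
        with pytest.raises(ConfigurationError):
            sim.generate_methylation(
                man, samples, sim.MethylationEffectConfig(noise_sd=-0.1), seed=8
            )


class TestExpression:
    def test_negative_binomial_mean(self, genome):
        samples = sim.generate_samples(22, (1, 5), seed=9)
        truth = TruthTable(probes=pd.DataFrame(
            columns=["probe_id", "chrom", "pos", "effect", "effect_size"]))
        counts, _, _ = sim.generate_expression(
            genome, samples, truth,
            sim.ExpressionConfig(mean_depth=500, dispersion=0.1, de_fraction=0.1),
            seed=9,
        )
        assert abs(counts.to_numpy().mean() - 500) <= 50

    def test_no_de_means_no_score_dependence(self, genome):
        samples = sim.generate_samples(10, (1, 5), seed=10)
        truth = TruthTable(probes=pd.DataFrame(
            columns=["probe_id", "chrom", "pos", "effect", "effect_size"]))
        _, _, truth = sim.generate_expression(
            genome, samples, truth, sim.ExpressionConfig(de_fraction=0.0), seed=10
        )
        assert not truth.features["de"].any()
        assert (truth.features["effect_size"] == 0).all()

    def test_full_overlap_includes_all_methylation_genes(self, small_dataset):
        cfg = sim.ExpressionConfig(de_fraction=0.3, overlap_fraction=1.0)
        ds = small_dataset
        _, _, truth = sim.generate_expression(
            ds.genome, ds.samples, ds.truth, cfg, seed=12
        )
        de_genes = set(truth.features.loc[truth.features["de"], "gene_id"])
        n_requested = round(0.3 * len(ds.genome.genes))
        expected = min(len(truth.meth_genes), n_requested)
        assert len(truth.meth_genes & de_genes) == expected

    def test_nonpositive_dispersion_rejected(self, genome):
        samples = sim.generate_samples(8, (1, 5), seed=13)
        truth = TruthTable(probes=pd.DataFrame(
            columns=["probe_id", "chrom", "pos", "effect", "effect_size"]))
        with pytest.raises(ConfigurationError):
            sim.generate_expression(
                genome, samples, truth, sim.ExpressionConfig(dispersion=0.0), seed=13
            )


class TestGeneList:
    def test_factor_one_is_null_over_seeds(self, small_dataset):
        # membership independent of truth: chi-square significant in <= a
        # handful of 50 seeds at alpha = 0.01
        ds = small_dataset
        genes = ds.genome.genes["gene_id"].tolist()
        hot = ds.truth.meth_genes | set(
            ds.truth.features.loc[ds.truth.features["de"], "gene_id"]
        )
        n_sig = 0
        for s in range(50):
            lst = set(sim.generate_gene_list(genes, ds.truth, 1.0, seed=s))
            a = len(lst & hot)
            b = len(hot - lst)
            c = len(lst - hot)
            d = len(set(genes) - lst - hot)
            _, p, *_ = chi2_contingency([[a, b], [c, d]], correction=True)
            n_sig += p < 0.01
        assert n_sig <= 5

    def test_large_factor_caps_inclusion_at_one(self, small_dataset):
        ds = small_dataset
        genes = ds.genome.genes["gene_id"].tolist()
        hot = ds.truth.meth_genes | set(
            ds.truth.features.loc[ds.truth.features["de"], "gene_id"]
        )
        lst = set(sim.generate_gene_list(genes, ds.truth, 1000.0, seed=3))
        assert hot <= lst

    def test_deterministic(self, small_dataset):
        ds = small_dataset
        genes = ds.genome.genes["gene_id"].tolist()
        assert sim.generate_gene_list(genes, ds.truth, 1.0, seed=5) == \
            sim.generate_gene_list(genes, ds.truth, 1.0, seed=5)

    def test_empty_universe_rejected(self, small_dataset):
        with pytest.raises(ConfigurationError):
            sim.generate_gene_list([], small_dataset.truth, 1.0, seed=1)


class TestPlantMotif:
    def test_fraction_zero_is_identity(self, small_dataset):
        man = small_dataset.manifest
        out = sim.plant_motif(man, "TACGTA", 0.0, seed=1)
        pd.testing.assert_frame_equal(out, man)

    def test_fraction_one_plants_everywhere(self, small_dataset):
        man = small_dataset.manifest.head(100)
        out = sim.plant_motif(man, "TACGTA", 1.0, seed=1)
        assert out["flank"].str.contains("TACGTA").all()
        assert out["flank"].str.len().eq(501).all()

    def test_rounded_count_rule(self, small_dataset):
        man = small_dataset.manifest.head(200).copy()
        # strip pre-existing occurrences so the planted count is exact
        man["flank"] = man["flank"].str.replace("TACGTA", "TACGAA")
        man["flank"] = man["flank"].str.replace("TACGTA", "TACGAA")  # revcomp overlap-safe
        out = sim.plant_motif(man, "TACGTA", 0.3, seed=2)
        planted = out["flank"].str.contains("TACGTA").sum()
        assert planted == round(0.3 * 200) == 60

    @pytest.mark.parametrize("motif", ["ACG", "A" * 13, "TAXGTA"])
    def test_bad_motifs_rejected(self, small_dataset, motif):
        with pytest.raises(ConfigurationError):
            sim.plant_motif(small_dataset.manifest, motif, 0.5, seed=1)


def test_full_dataset_byte_identical_for_fixed_seed(tmp_path):
    cfg = sim.SimulationConfig(n_chromosomes=1, genes_per_chromosome=10, n_probes=200,
                               n_samples=8,
                               methylation=sim.MethylationEffectConfig(n_clusters=2,
                                                                       cluster_width=5))
    a = sim.simulate_dataset(cfg, seed=42)
    b = sim.simulate_dataset(cfg, seed=42)
    assert a.methylation.beta.to_csv() == b.methylation.beta.to_csv()
    assert a.manifest.to_csv() == b.manifest.to_csv()
    assert a.gene_counts.to_csv() == b.gene_counts.to_csv()
    assert a.gene_list == b.gene_list
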