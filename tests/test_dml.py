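"""Per-probe regression, variance moderation (with the Bioconductor limma
oracle), z-transform, aLIS adjustment, direction and mQTL proximity."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stressmeth.dml import (
    adjust_lis,
    classify_direction,
    estimate_prior,
    fit_locus_models,
    moderate_variances,
    mqtl_proximity,
    p_to_z,
)
from stressmeth.errors import ConfigurationError, PipelineError


def _samples(n=8, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "lsi_score": np.linspace(1, 5, n),
            "age": rng.uniform(9, 12, n),
            "batch": ["chip1", "chip2"] * (n // 2),
        }
    )


def _m_matrix(n_probes, samples, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(0, 1, (n_probes, len(samples))),
        index=pd.Index([f"cg{i}" for i in range(n_probes)], name="probe_id"),
        columns=samples["sample_id"],
    )


class TestLocusModels:
    def test_matches_normal_equations_oracle(self):
        samples = _samples(8)
        m = _m_matrix(5, samples, seed=1)
        out = fit_locus_models(m, samples)
        # independent oracle: explicit (X'X)^-1 X'y per probe
        x = np.column_stack([
            np.ones(8), samples["lsi_score"], samples["age"],
            (samples["batch"] == "chip2").astype(float),
        ])
        for i, pid in enumerate(m.index):
            beta_hat = np.linalg.solve(x.T @ x, x.T @ m.iloc[i].to_numpy())
            resid = m.iloc[i].to_numpy() - x @ beta_hat
            s2 = resid @ resid / (8 - 4)
            se = np.sqrt(s2 * np.linalg.inv(x.T @ x)[1, 1])
            assert out.loc[pid, "coef"] == pytest.approx(beta_hat[1], abs=1e-10)
            assert out.loc[pid, "se"] == pytest.approx(se, abs=1e-10)
            t = beta_hat[1] / se
            assert out.loc[pid, "p"] == pytest.approx(2 * stats.t.sf(abs(t), 4), abs=1e-12)

    def test_constant_probe_gets_na_p(self, caplog):
        samples = _samples(8)
        m = _m_matrix(12, samples, seed=2)
        m.iloc[0] = 3.0
        with caplog.at_level("WARNING"):
            out = fit_locus_models(m, samples)
        assert np.isnan(out.iloc[0]["p"])
        assert "zero residual variance" in caplog.text

    def test_collinear_design_named(self):
        samples = _samples(8)
        samples["age"] = samples["lsi_score"]  # exact collinearity
        with pytest.raises(PipelineError, match="lsi_score|age"):
            fit_locus_models(_m_matrix(3, samples), samples)

    def test_residual_df(self):
        samples = _samples(10, seed=3)
        out = fit_locus_models(_m_matrix(4, samples, seed=3), samples)
        assert (out["df"] == 10 - 4).all()


class TestModeration:
    def _stats(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        samples = _samples(12, seed)
        m = _m_matrix(n, samples, seed)
        m *= rng.uniform(0.3, 3.0, (n, 1))  # heterogeneous variances
        return fit_locus_models(m, samples)

    def test_zero_prior_df_reproduces_raw_t(self):
        out = moderate_variances(self._stats(), prior_df=0.0)
        np.testing.assert_allclose(out["t_mod"], out["t"], rtol=0, atol=0)
        np.testing.assert_allclose(
            out["p_mod"], 2 * stats.t.sf(np.abs(out["t"]), out["df"]), atol=1e-15
        )

    def test_infinite_prior_df_equalizes_posterior_variances(self):
        st_df = self._stats()
        out = moderate_variances(st_df, prior_df=np.inf)
        # posterior variance identical for all probes: t_mod proportional to
        # coef/se * s with one shared scale
        implied_post = st_df["sigma2"] * (out["t"] / out["t_mod"]) ** 2
        assert implied_post.std() == pytest.approx(0.0, abs=1e-12)

    def test_prior_matches_limma_squeezevar(self, tmp_path):
        rscript = shutil.which("Rscript")
        assert rscript, "Rscript is part of the supported environment"
        rng = np.random.default_rng(42)
        df = 18.0
        s2 = 0.04 * 8.0 / rng.chisquare(8.0, 50) * rng.chisquare(df, 50) / df
        np.savetxt(tmp_path / "s2.txt", s2)
        d0, s0 = estimate_prior(s2, df)
        r_out = subprocess.run(
            [rscript, "-e",
             "suppressMessages(library(limma));"
             f"s2 <- scan('{tmp_path / 's2.txt'}', quiet=TRUE);"
             "out <- squeezeVar(s2, df=18);"
             "cat(sprintf('%.12g %.12g', out$df.prior, out$var.prior))"],
            capture_output=True, text=True, check=True,
        )
        d0_r, s0_r = map(float, r_out.stdout.split())
        assert d0 == pytest.approx(d0_r, rel=1e-6)
        assert s0 == pytest.approx(s0_r, rel=1e-6)

    def test_too_few_probes_rejected(self):
        with pytest.raises(PipelineError):
            estimate_prior(np.ones(5), 10.0)


class TestPToZ:
    def test_null_median_maps_to_zero(self):
        assert p_to_z(1.0, 1.0) == 0.0

    def test_standard_quantile(self):
        assert p_to_z(0.05, 1.0) == pytest.approx(1.959964, abs=1e-6)
        assert p_to_z(0.05, -1.0) == pytest.approx(-1.959964, abs=1e-6)

    def test_sign_follows_coefficient(self):
        z = p_to_z(np.array([0.01, 0.01]), np.array([2.5, -2.5]))
        assert z[0] > 0 > z[1]
        assert z[0] == -z[1]

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.5])
    def test_out_of_range_p_rejected(self, p):
        with pytest.raises(ValueError):
            p_to_z(p, 1.0)

    def test_extreme_p_stays_finite(self):
        assert np.isfinite(p_to_z(1e-320, 1.0))


class TestAdjustLis:
    def test_running_mean_hand_example(self):
        out = adjust_lis(np.array([0.01, 0.02, 0.30]), alpha=0.05)
        np.testing.assert_allclose(out["alis"], [0.01, 0.015, 0.11])
        assert out["called"].tolist() == [True, True, False]

    def test_all_zero_lis_all_called(self):
        out = adjust_lis(np.zeros(5))
        assert out["called"].all()

    def test_alis_is_cumulative_mean_along_ranking(self, rng):
        lis = rng.random(100)
        out = adjust_lis(lis)
        order = np.argsort(lis, kind="stable")
        expected = np.cumsum(lis[order]) / np.arange(1, 101)
        np.testing.assert_allclose(out["alis"].to_numpy()[order], expected)
        assert (np.diff(expected) >= -1e-15).all()  # non-decreasing along ranking

    def test_called_set_is_prefix_of_ranking(self, rng):
        for _ in range(10):
            lis = rng.random(200)
            out = adjust_lis(lis, alpha=0.3)
            order = np.argsort(lis, kind="stable")
            called_ranked = out["called"].to_numpy()[order]
            if called_ranked.any():
                last = np.flatnonzero(called_ranked)[-1]
                assert called_ranked[: last + 1].all()

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            adjust_lis(np.array([0.5, 1.2]))
        with pytest.raises(ConfigurationError):
            adjust_lis(np.array([0.5]), alpha=1.0)


class TestDirection:
    def _beta(self, rows, samples):
        return pd.DataFrame(
            rows,
            index=pd.Index([f"cg{i}" for i in range(len(rows))], name="probe_id"),
            columns=samples["sample_id"],
        )

    def test_perfect_linear_relations(self):
        samples = _samples(8)
        lsi = samples["lsi_score"].to_numpy()
        beta = self._beta([0.1 + 0.05 * lsi, 0.9 - 0.05 * lsi], samples)
        out = classify_direction(beta, samples, ["cg0", "cg1"])
        assert out.loc["cg0", "pearson_r"] == pytest.approx(1.0)
        assert out.loc["cg0", "direction"] == "positive"
        assert out.loc["cg1", "pearson_r"] == pytest.approx(-1.0)
        assert out.loc["cg1", "direction"] == "negative"

    def test_matches_textbook_formula(self, rng):
        samples = _samples(10, seed=4)
        rows = rng.uniform(0.1, 0.9, (20, 10))
        beta = self._beta(list(rows), samples)
        out = classify_direction(beta, samples, beta.index)
        lsi = samples["lsi_score"].to_numpy()
        for i, pid in enumerate(beta.index):
            x, y = rows[i], lsi
            r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
                ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
            )
            assert out.loc[pid, "pearson_r"] == pytest.approx(r, abs=1e-12)

    def test_constant_row_falls_back_to_coefficient_sign(self, caplog):
        samples = _samples(8)
        beta = self._beta([np.full(8, 0.4)], samples)
        coefs = pd.Series({"cg0": -1.0})
        with caplog.at_level("WARNING"):
            out = classify_direction(beta, samples, ["cg0"], coefs=coefs)
        assert out.loc["cg0", "direction"] == "negative"
        assert "zero beta variance" in caplog.text


class TestMqtlProximity:
    def _calls(self, positions):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": positions,
                "called": True,
            },
            index=pd.Index([f"cg{i}" for i in range(len(positions))], name="probe_id"),
        )

    @pytest.mark.parametrize(
        "snp_pos,expected",
        [(1150, True), (1250, False), (1200, True)],  # 150 <= 200, 250 > 200, boundary
    )
    def test_distance_rule_boundary_inclusive(self, snp_pos, expected):
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [snp_pos]})
        out, summary = mqtl_proximity(self._calls([1000]), snps, max_distance=200)
        assert out["mqtl_near"].iloc[0] == expected
        assert summary == ({"near": 1, "far": 0} if expected else {"near": 0, "far": 1})

    def test_other_chromosome_never_near(self):
        snps = pd.DataFrame({"chrom": ["chr2"], "pos": [1000]})
        out, _ = mqtl_proximity(self._calls([1000]), snps, max_distance=200)
        assert not out["mqtl_near"].iloc[0]

    def test_malformed_record_skipped_with_warning(self, caplog):
        snps = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [np.nan, 1100]})
        with caplog.at_level("WARNING"):
            out, _ = mqtl_proximity(self._calls([1000]), snps)
        assert out["mqtl_near"].iloc[0]
        assert "malformed SNP record" in caplog.text
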