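"""Per-probe fit vs independent oracles, moderation, BH, inflation factor."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import statsmodels.api as sm

from repeatmeth import (
    DifferentialMethylationModel,
    MethylationDataset,
    SignificanceConfig,
    adjust_pvalues,
    call_significant,
    fit_probe_models,
    genomic_inflation,
    moderate_variances,
)
from repeatmeth.dma import build_design_matrix, fit_variance_prior


def two_group_dataset(carrier_values, non_carrier_values, probe="p1"):
    vals = list(carrier_values) + list(non_carrier_values)
    idx = [f"s{i}" for i in range(len(vals))]
    m = pd.DataFrame({probe: vals, "p_pad": np.arange(len(vals), dtype=float)}, index=idx)
    carrier = pd.Series(
        ["carrier"] * len(carrier_values) + ["non_carrier"] * len(non_carrier_values),
        index=idx,
    )
    return MethylationDataset(m_values=m, carrier=carrier)


class TestProbeModelOracle:
    def test_hand_computed_two_group_fit(self):
        """8-sample toy: coef is the mean difference, pooled-variance t.

        Carriers [2,3,4,3] vs non-carriers [0,1,1,0]: difference of means
        2.5, pooled s^2 = 0.5, se = 0.5, t = 5 on 6 df, p = 0.0024523...
        (frozen from the closed-form two-sample computation).
        """
        ds = two_group_dataset([2, 3, 4, 3], [0, 1, 1, 0])
        res = fit_probe_models(ds)
        row = res.table.loc["p1"]
        assert row["coef"] == pytest.approx(2.5, abs=1e-12)
        assert row["se"] == pytest.approx(0.5, abs=1e-12)
        assert row["t"] == pytest.approx(5.0, abs=1e-12)
        assert row["df_total"] == 6
        assert row["p"] == pytest.approx(0.002452341760758551, rel=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_least_squares_with_covariates(self, seed):
        """<=10-sample instances agree with statsmodels OLS to 1e-8 relative."""
        rng = np.random.default_rng(seed)
        n = 10
        idx = [f"s{i}" for i in range(n)]
        m = pd.DataFrame(
            rng.normal(size=(n, 4)), index=idx, columns=list("abcd")
        )
        cov = pd.DataFrame(
            {"age": rng.normal(60, 8, n), "sex": rng.integers(0, 2, n)}, index=idx
        )
        carrier = pd.Series(
            np.where(rng.permutation(n) < 4, "carrier", "non_carrier"), index=idx
        )
        ds = MethylationDataset(m_values=m, covariates=cov, carrier=carrier)
        res = fit_probe_models(ds)
        X = build_design_matrix(ds).to_numpy()
        for probe in m.columns:
            fit = sm.OLS(m[probe].to_numpy(), X).fit()
            row = res.table.loc[probe]
            assert row["coef"] == pytest.approx(fit.params[1], rel=1e-8)
            assert row["se"] == pytest.approx(fit.bse[1], rel=1e-8)
            assert row["t"] == pytest.approx(fit.tvalues[1], rel=1e-8)
            assert row["p"] == pytest.approx(fit.pvalues[1], rel=1e-8)

    def test_sample_order_invariance(self, small_cohort):
        ds, _, _ = small_cohort
        res = DifferentialMethylationModel(ds).fit()
        perm = np.random.default_rng(0).permutation(ds.sample_ids)
        res_perm = DifferentialMethylationModel(ds.subset_samples(perm)).fit()
        pd.testing.assert_frame_equal(res.table, res_perm.table)

    def test_zero_variance_probe_flagged_and_unranked(self):
        ds = two_group_dataset([1, 2, 3, 2], [0, 1, 0, 1])
        m = ds.m_values.copy()
        m["flat"] = 0.75
        ds2 = MethylationDataset(m, carrier=ds.carrier)
        res = fit_probe_models(ds2)
        row = res.table.loc["flat"]
        assert row["zero_variance"]
        assert row["coef"] == 0.0
        assert np.isnan(row["p"])
        assert "flat" not in res.call_significant(
            SignificanceConfig(literature_threshold=0.999)
        ).index

    def test_collinear_design_names_columns(self, small_cohort):
        ds, _, _ = small_cohort
        cov = ds.covariates.copy()
        cov["batch"] = np.where(ds.carrier == "carrier", "b1", "b2")
        bad = MethylationDataset(ds.m_values, cov, ds.carrier)
        with pytest.raises(ValueError, match="rank deficient"):
            DifferentialMethylationModel(bad)

    def test_too_few_samples_rejected(self):
        ds = two_group_dataset([1.0, 2.0], [0.0])
        with pytest.raises(ValueError, match="at least"):
            DifferentialMethylationModel(ds)


class TestModeration:
    def make_fit(self, n_probes=1000, n=40, seed=0, sd_spread=0.6):
        rng = np.random.default_rng(seed)
        idx = [f"s{i}" for i in range(n)]
        sds = np.exp(rng.normal(np.log(0.4), sd_spread, n_probes))
        m = pd.DataFrame(
            rng.normal(0, sds, size=(n, n_probes)),
            index=idx,
            columns=[f"cg{i}" for i in range(n_probes)],
        )
        carrier = pd.Series(
            ["carrier"] * (n // 4) + ["non_carrier"] * (n - n // 4), index=idx
        )
        ds = MethylationDataset(m_values=m, carrier=carrier)
        return fit_probe_models(ds)

    def test_identical_variances_give_pooled_fit(self):
        """With no variance heterogeneity the prior df is infinite and the
        posterior variance equals the (common) sample variance."""
        res = self.make_fit(n_probes=200, sd_spread=0.0, seed=1)
        # force exactly equal residual variances
        res._s2 = np.full_like(res._s2, 0.16)
        res.table["se"] = np.sqrt(0.16) * res._unscaled_se
        mod = moderate_variances(res)
        assert np.isinf(mod.d0)
        np.testing.assert_allclose(mod.s0_sq, 0.16, rtol=1e-12)
        np.testing.assert_allclose(mod.table["se"], res.table["se"], rtol=1e-12)

    def test_disabling_moderation_recovers_plain_ols(self, small_cohort):
        ds, _, _ = small_cohort
        plain = fit_probe_models(ds)
        via_flag = DifferentialMethylationModel(ds).fit(moderate=False)
        pd.testing.assert_frame_equal(plain.table, via_flag.table)

    def test_shrinkage_reduces_log_variance_spread(self):
        res = self.make_fit(n_probes=1000, seed=3)
        mod = moderate_variances(res)
        s2 = res._s2
        s2_post = (mod.d0 * mod.s0_sq + res.df_resid * s2) / (mod.d0 + res.df_resid)
        assert np.var(np.log(s2_post)) < np.var(np.log(s2))

    def test_moderation_preserves_t_sign_and_df(self):
        res = self.make_fit(n_probes=300, seed=5)
        mod = moderate_variances(res)
        t0 = res.table["t"].to_numpy()
        t1 = mod.table["t"].to_numpy()
        assert (np.sign(t0) == np.sign(t1)).all()
        assert mod.table["df_total"].iloc[0] == pytest.approx(mod.d0 + res.df_resid)
        assert mod.d0 > 0

    def test_prior_fit_recovers_known_d0(self):
        """Variances drawn from a scaled inv-chi2 prior: d0, s0 recovered."""
        rng = np.random.default_rng(11)
        d0_true, s0_true, df = 8.0, 0.25, 30
        n = 20_000
        sigma2 = d0_true * s0_true / rng.chisquare(d0_true, n)
        s2 = sigma2 * rng.chisquare(df, n) / df
        d0, s0 = fit_variance_prior(s2, df)
        assert d0 == pytest.approx(d0_true, rel=0.15)
        assert s0 == pytest.approx(s0_true, rel=0.05)


class TestAdjustPvalues:
    def test_hand_applied_step_up(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_value_identity(self):
        assert adjust_pvalues([0.04])[0] == pytest.approx(0.04)

    def test_matches_hand_formula_on_random_input(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=37)
        order = np.argsort(p)
        m = len(p)
        # hand BH: running minimum of p_(j) * m / j from the largest rank down
        stepped = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(stepped, 1.0)
        np.testing.assert_allclose(adjust_pvalues(p), expected, rtol=1e-12)

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariance_and_bounds(self, plist):
        p = np.array(plist)
        adj = adjust_pvalues(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0 + 1e-12).all()
        perm = np.random.default_rng(0).permutation(len(p))
        adj_perm = adjust_pvalues(p[perm])
        np.testing.assert_allclose(adj_perm, adj[perm], rtol=1e-12)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.2], [np.nan]])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError):
            adjust_pvalues(bad)


class TestGenomicInflation:
    def test_all_half_is_exactly_one(self):
        assert genomic_inflation(np.full(200, 0.5)) == 1.0

    def test_uniform_null_near_one(self):
        p = np.random.default_rng(0).uniform(size=100_000)
        assert genomic_inflation(p) == pytest.approx(1.0, abs=0.02)

    def test_enrichment_inflates(self):
        rng = np.random.default_rng(1)
        p = np.concatenate([rng.uniform(size=5000), rng.uniform(0, 1e-4, 500)])
        assert genomic_inflation(p) > 1.0

    def test_degenerate_ones_warns_zero(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert genomic_inflation(np.ones(150)) == 0.0

    def test_requires_enough_pvalues(self):
        with pytest.raises(ValueError, match=">= 100"):
            genomic_inflation(np.full(10, 0.5))


class TestCallSignificant:
    def test_empty_result_empty_list(self, small_cohort):
        ds, _, _ = small_cohort
        res = DifferentialMethylationModel(ds).fit()
        hits = call_significant(res, SignificanceConfig(literature_threshold=1e-300))
        assert hits.empty

    def test_hits_sorted_and_hypermethylated(self, small_cohort):
        ds, _, truth = small_cohort
        res = DifferentialMethylationModel(ds).fit()
        hits = call_significant(res, SignificanceConfig(permutation_threshold=1e-12))
        assert (hits["p"].diff().dropna() >= 0).all()
        implanted = hits.index.intersection(list(truth.affected))
        assert (hits.loc[implanted, "direction"] == "hyper").all()

    def test_permutation_threshold_takes_precedence(self):
        sig = SignificanceConfig(permutation_threshold=4.4e-10)
        assert sig.active_threshold == 4.4e-10


def test_moderated_fit_matches_reference_implementation(tmp_path):
    """Moderated t/p and the fitted variance prior agree with the
    R/Bioconductor empirical-Bayes linear-model implementation."""
    import subprocess

    rng = np.random.default_rng(0)
    n, n_probes = 30, 200
    idx = [f"s{i}" for i in range(n)]
    sds = np.exp(rng.normal(np.log(0.4), 0.5, n_probes))
    m = pd.DataFrame(
        rng.normal(0, sds, size=(n, n_probes)),
        index=idx,
        columns=[f"cg{i}" for i in range(n_probes)],
    )
    m.iloc[:8, 0] += 2.0
    carrier = pd.Series(["carrier"] * 8 + ["non_carrier"] * (n - 8), index=idx)
    ds = MethylationDataset(m_values=m, carrier=carrier)
    res = DifferentialMethylationModel(ds).fit()

    m.T.to_csv(tmp_path / "y.tsv", sep="\t")
    build_design_matrix(ds).to_csv(tmp_path / "x.tsv", sep="\t")
    (tmp_path / "cmp.R").write_text(
        'suppressMessages(library(limma))\n'
        'y <- as.matrix(read.delim("y.tsv", row.names=1))\n'
        'x <- as.matrix(read.delim("x.tsv", row.names=1))\n'
        'fit <- eBayes(lmFit(y, x))\n'
        'write.table(data.frame(t=fit$t[,"carrier"], p=fit$p.value[,"carrier"],\n'
        '            d0=fit$df.prior, s0=fit$s2.prior),\n'
        '            "ref.tsv", sep="\\t", row.names=FALSE)\n'
    )
    subprocess.run(["Rscript", "cmp.R"], cwd=tmp_path, check=True)
    ref = pd.read_csv(tmp_path / "ref.tsv", sep="\t")
    assert res.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-9)
    assert res.s0_sq == pytest.approx(ref["s0"].iloc[0], rel=1e-9)
    np.testing.assert_allclose(res.table["t"], ref["t"], rtol=1e-9)
    np.testing.assert_allclose(res.table["p"], ref["p"], rtol=1e-9)


def test_type_one_error_calibration_on_null(null_cohort_20k):
    """On null data ~5% of probes reach p < 0.05 (within one percent)."""
    ds, _, _ = null_cohort_20k
    res = DifferentialMethylationModel(ds).fit()
    p = res.valid_pvalues()
    assert (p < 0.05).mean() == pytest.approx(0.05, abs=0.01)
    assert res.lambda_gc == pytest.approx(1.0, abs=0.05)
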