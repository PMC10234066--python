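"""Interaction regressions, nested-model F tests, simple slopes, scan, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cgskit as ck
from conftest import make_noiseless_gxe


class TestZscoreByGrade:
    def test_single_grade_plain_zscore(self, rng):
        v = rng.normal(5, 2, 100)
        z = ck.zscore_by_grade(v, np.full(100, 3))
        assert np.mean(z) == pytest.approx(0, abs=1e-12)
        assert np.std(z, ddof=1) == pytest.approx(1, abs=1e-12)

    def test_groups_centered_separately(self, rng):
        v = np.concatenate([rng.normal(0, 1, 50), rng.normal(10, 1, 50)])
        grade = np.repeat([3, 4], 50)
        z = ck.zscore_by_grade(v, grade)
        for gr in (3, 4):
            assert np.mean(z[grade == gr]) == pytest.approx(0, abs=1e-12)
            assert np.std(z[grade == gr], ddof=1) == pytest.approx(1, abs=1e-12)

    def test_shift_invariance_across_grades(self, rng):
        base = rng.normal(0, 1, 40)
        v = np.concatenate([base, base + 7.5])
        grade = np.repeat([3, 4], 40)
        z = ck.zscore_by_grade(v, grade)
        assert np.allclose(z[:40], z[40:])

    def test_zero_variance_group_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ck.zscore_by_grade(np.array([1.0, 1.0, 2.0, 3.0]), np.array([3, 3, 4, 4]))


class TestFitGxe:
    def test_noiseless_recovery_to_machine_precision(self):
        y, pe, cgs, age, sex, truth = make_noiseless_gxe()
        fit = ck.fit_gxe(y, pe, cgs, age, sex, include_interaction=True)
        # expand the crossover form into the linear parameterization
        assert fit.coef("pe") == pytest.approx(truth.b1 + 0, rel=1e-9)
        assert fit.coef("pe_x_cgs") == pytest.approx(truth.b2, rel=1e-9)
        assert fit.coef("cgs") == pytest.approx(-truth.b2 * truth.c, rel=1e-9)
        assert fit.coef("const") == pytest.approx(truth.b0 - truth.b1 * truth.c, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations(self, rng):
        n = 120
        pe = rng.uniform(1, 6, n)
        cgs = rng.integers(5, 20, n).astype(float)
        age, sex = rng.uniform(9, 13, n), rng.integers(0, 2, n).astype(float)
        y = rng.normal(0, 1, n)
        fit = ck.fit_gxe(y, pe, cgs, age, sex, include_interaction=True)
        X = np.column_stack([np.ones(n), pe, cgs, pe * cgs, age, sex])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(fit.params, beta, rtol=1e-10)

    def test_null_estimates_center_on_zero(self):
        """Permuted score under b2=b3=0: interaction estimate unbiased at 0."""
        truth = ck.GxETruth(b0=100, b1=-5.0, b2=0.0, c=0.0, resid_sd=5.0, regime="none")
        rng = np.random.default_rng(31)
        est = []
        for rep in range(200):
            n = 300
            pe = rng.choice(np.arange(1, 6.01, 0.5), n)
            cgs = rng.binomial(26, 0.5, n).astype(float)
            age, sex = rng.uniform(9, 13, n), rng.integers(0, 2, n).astype(float)
            y = ck.simulate_gxe_phenotype(cgs, pe, age, sex, truth, seed=int(rng.integers(2**31)))
            fit = ck.fit_gxe(y, pe, rng.permutation(cgs), age, sex)
            est.append(fit.coef("pe_x_cgs"))
        mc_se = np.std(est, ddof=1) / np.sqrt(len(est))
        assert abs(np.mean(est)) < 3 * mc_se

    def test_constant_cgs_rank_deficiency_reported(self, rng):
        n = 50
        with pytest.raises(ValueError, match="rank deficient"):
            ck.fit_gxe(rng.normal(size=n), rng.uniform(1, 6, n), np.full(n, 13.0),
                       rng.uniform(9, 13, n), rng.integers(0, 2, n).astype(float))


class TestDeltaR2:
    def test_identical_fits_f_zero(self, gxe_cohort):
        _, t = gxe_cohort
        fit = ck.fit_gxe(t.reading_fluency, t.pe, t.cgs, t.age, t.sex, include_interaction=False)
        f, _, p = ck.delta_r2_test(fit, fit)
        assert f == 0.0 and p == 1.0

    def test_non_nested_rejected(self, gxe_cohort):
        _, t = gxe_cohort
        full = ck.fit_gxe(t.reading_fluency, t.pe, t.cgs, t.age, t.sex, include_interaction=True)
        reduced = ck.fit_gxe(t.reading_fluency, t.pe, t.cgs, t.age, t.sex, include_interaction=False)
        with pytest.raises(ValueError, match="nest"):
            ck.delta_r2_test(full, reduced)  # wrong order: full cannot nest in reduced

    def test_textbook_increment(self):
        """R² 0.10 -> 0.15, one added parameter, n=100, 5 params: F ≈ 5.588."""
        f = (0.05 / 1) / (0.85 / 95)
        assert f == pytest.approx(5.588, abs=0.001)
        # and the implementation reproduces the same arithmetic via its formula
        from dataclasses import replace
        base = ck.fit_gxe(*_tiny_fixture(), include_interaction=False)
        full = ck.fit_gxe(*_tiny_fixture(), include_interaction=True)
        full_mock = replace(full, r_squared=0.15, df_resid=95, n=100, df_model=4)
        base_mock = replace(base, r_squared=0.10, n=100, df_model=3)
        f_impl, dfs, _ = ck.delta_r2_test(base_mock, full_mock)
        assert f_impl == pytest.approx(f, rel=1e-12)
        assert dfs == (1, 95)

    def test_matches_rss_oracle(self, rng):
        for _ in range(5):
            n = 150
            pe = rng.uniform(1, 6, n)
            cgs = rng.integers(0, 27, n).astype(float)
            age, sex = rng.uniform(9, 13, n), rng.integers(0, 2, n).astype(float)
            y = 3 * pe - 0.2 * pe * cgs + rng.normal(0, 4, n)
            reduced = ck.fit_gxe(y, pe, cgs, age, sex, include_interaction=False)
            full = ck.fit_gxe(y, pe, cgs, age, sex, include_interaction=True)
            f, (df1, df2), p = ck.delta_r2_test(reduced, full)
            f_rss = ((reduced.rss - full.rss) / 1) / (full.rss / full.df_resid)
            assert f == pytest.approx(f_rss, rel=1e-9)
            assert p == pytest.approx(stats.f.sf(f_rss, df1, df2), rel=1e-9)

    def test_null_type_one_error(self):
        """b3 = 0 truth: the increment test rejects at ~5%."""
        truth = ck.GxETruth(b0=100, b1=-5.0, b2=0.0, c=0.0, resid_sd=8.0, regime="none")
        rng = np.random.default_rng(42)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            n = 120
            pe = rng.choice(np.arange(1, 6.01, 0.5), n)
            cgs = rng.binomial(26, 0.5, n).astype(float)
            age, sex = rng.uniform(9, 13, n), rng.integers(0, 2, n).astype(float)
            y = ck.simulate_gxe_phenotype(cgs, pe, age, sex, truth,
                                          seed=int(rng.integers(2**31)))
            reduced = ck.fit_gxe(y, pe, cgs, age, sex, include_interaction=False)
            full = ck.fit_gxe(y, pe, cgs, age, sex, include_interaction=True)
            if ck.delta_r2_test(reduced, full)[2] < 0.05:
                rejections += 1
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rejections / reps - 0.05) < 3 * se


def _tiny_fixture():
    rng = np.random.default_rng(7)
    n = 100
    return (rng.normal(size=n), rng.uniform(1, 6, n), rng.integers(0, 27, n).astype(float),
            rng.uniform(9, 13, n), rng.integers(0, 2, n).astype(float))


class TestSimpleSlopes:
    def test_no_interaction_means_equal_slopes(self):
        y, pe, cgs, age, sex, _ = make_noiseless_gxe(b2=0.6)
        fit = ck.fit_gxe(y, pe, cgs, age, sex)
        fit.params[fit.terms.index("pe_x_cgs")] = 0.0
        slopes = ck.simple_slopes(fit, {"low": 5.0, "high": 20.0})
        assert slopes.loc["low", "slope"] == slopes.loc["high", "slope"]

    def test_linear_formula_at_reported_scale(self, gxe_cohort):
        _, t = gxe_cohort
        fit = ck.fit_gxe(t.reading_fluency, t.pe, t.cgs, t.age, t.sex)
        g = float(t.cgs.mean() + t.cgs.std(ddof=1))
        slopes = ck.simple_slopes(fit, {"high": g})
        expected = fit.coef("pe") + fit.coef("pe_x_cgs") * g
        assert slopes.loc["high", "slope"] == pytest.approx(expected, rel=1e-12)

    def test_se_at_zero_level_equals_main_effect_se(self, gxe_cohort):
        _, t = gxe_cohort
        fit = ck.fit_gxe(t.reading_fluency, t.pe, t.cgs, t.age, t.sex)
        slopes = ck.simple_slopes(fit, {"zero": 0.0})
        assert slopes.loc["zero", "se"] == pytest.approx(fit.se("pe"), rel=1e-12)

    def test_requires_interaction_fit(self, gxe_cohort):
        _, t = gxe_cohort
        fit = ck.fit_gxe(t.reading_fluency, t.pe, t.cgs, t.age, t.sex, include_interaction=False)
        with pytest.raises(ValueError, match="interaction"):
            ck.simple_slopes(fit, {"low": 0.0})


class TestSnpScan:
    def test_bonferroni_thresholds(self):
        assert round(ck.bonferroni_threshold(13), 4) == 0.0038
        assert ck.bonferroni_threshold(1) == 0.05

    def test_scan_shapes_and_monomorphic_skip(self, gxe_cohort, panel):
        g, t = gxe_cohort
        geno = g.to_frame().iloc[:, :5].copy()
        geno["mono"] = 2.0
        out = ck.snp_scan(t.reading_fluency, t.pe, geno, t.age, t.sex)
        assert "mono" not in set(out.snp_id)
        assert len(out) == 5
        assert np.allclose(out.bonferroni_threshold, 0.05 / 5)

    def test_family_wise_error_controlled(self):
        """Null truth, 13 SNPs: any-significant rate stays at or below alpha."""
        rng = np.random.default_rng(99)
        panel = ck.default_panel()
        fwer_hits = 0
        reps = 400
        for _ in range(reps):
            n = 150
            g = ck.simulate_genotypes(n, panel, seed=int(rng.integers(2**31)))
            pe = rng.choice(np.arange(1, 6.01, 0.5), n)
            age, sex = rng.uniform(9, 13, n), rng.integers(0, 2, n).astype(float)
            y = rng.normal(0, 1, n)  # independent of everything
            out = ck.snp_scan(y, pe, g.to_frame(), age, sex)
            if out.significant.any():
                fwer_hits += 1
        se = np.sqrt(0.05 * 0.95 / reps)
        assert fwer_hits / reps <= 0.05 + 3 * se


class TestCorrelationMatrix:
    def test_self_correlation_is_one(self, rng):
        v = rng.normal(size=50)
        df = pd.DataFrame({"x": v, "also_x": v, "y": rng.normal(size=50)})
        report = ck.correlation_matrix(df)
        row = report[(report.var_1 == "x") & (report.var_2 == "also_x")]
        assert row.r.iloc[0] == pytest.approx(1.0)

    def test_bh_step_up_arithmetic(self):
        from statsmodels.stats.multitest import multipletests
        _, adj, _, _ = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")
        assert np.allclose(adj, 0.04)

    def test_bh_adjustment_monotone(self, rng):
        df = pd.DataFrame(rng.normal(size=(80, 6)), columns=list("abcdef"))
        report = ck.correlation_matrix(df).sort_values("p")
        assert (np.diff(report.p_adj.to_numpy()) >= -1e-15).all()

    def test_null_fdr_rate(self, rng):
        hits, total = 0, 0
        for _ in range(200):
            df = pd.DataFrame(np.random.default_rng(rng.integers(2**31)).normal(size=(100, 5)),
                              columns=list("abcde"))
            rep = ck.correlation_matrix(df)
            hits += int(rep.p_adj.lt(0.05).sum())
            total += len(rep)
        assert hits / total < 0.05  # FDR under the global null <= alpha

    def test_pairwise_complete_handling(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=30), "y": rng.normal(size=30)})
        df.loc[:4, "y"] = np.nan
        report = ck.correlation_matrix(df)
        assert report.n.iloc[0] == 25

    def test_constant_variable_rejected(self, rng):
        df = pd.DataFrame({"x": np.ones(20), "y": rng.normal(size=20)})
        with pytest.raises(ValueError, match="constant"):
            ck.correlation_matrix(df)
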