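"""Parallel mediation: path estimates, bootstrap CIs, fit indices, moderated variant."""

import numpy as np
import pandas as pd
import pytest

import cgskit as ck


def build_cohort(n, a, b, c_prime=0.1, seed=0, resid_m=1.0, resid_y=1.0):
    """Single-mediator cohort with known raw-scale paths."""
    rng = np.random.default_rng(seed)
    gene = rng.normal(0, 1, n)
    age = rng.uniform(9, 13, n)
    sex = rng.integers(0, 2, n).astype(float)
    m = a * gene + resid_m * rng.normal(size=n)
    y = c_prime * gene + b * m + resid_y * rng.normal(size=n)
    return gene, pd.DataFrame({"m": m}), y, age, sex


class TestPathModel:
    def test_noiseless_product_exact(self):
        """Mediator residual orthogonal to the design, outcome noiseless: a*b exact."""
        rng = np.random.default_rng(1)
        n, a, b = 500, 0.5, 0.4
        gene = rng.normal(0, 1, n)
        age = rng.uniform(9, 13, n)
        sex = rng.integers(0, 2, n).astype(float)
        X = np.column_stack([np.ones(n), gene, age, sex])
        e = rng.normal(size=n)
        e -= X @ np.linalg.lstsq(X, e, rcond=None)[0]  # exactly orthogonal residual
        m = a * gene + e
        y = 0.1 * gene + b * m                          # no outcome noise
        fit = ck.fit_path_model(gene, pd.DataFrame({"m": m}), y, age, sex)
        assert fit.a[0] == pytest.approx(a, abs=1e-10)
        assert fit.b[0] == pytest.approx(b, abs=1e-10)
        assert fit.total_indirect == pytest.approx(a * b, abs=1e-10)

    def test_null_a_paths_center_on_zero(self):
        est = []
        for rep in range(200):
            gene, med, y, age, sex = build_cohort(200, a=0.0, b=0.4, seed=rep)
            est.append(ck.fit_path_model(gene, med, y, age, sex).total_indirect)
        mc_se = np.std(est, ddof=1) / np.sqrt(len(est))
        assert abs(np.mean(est)) < 3 * mc_se

    def test_four_mediator_recovery_within_mc_error(self):
        """a and b paths recovered without bias at the default generating truth."""
        truth = ck.default_mediation_truth()
        reps = 200
        a_est = np.zeros((reps, 4))
        b_est = np.zeros((reps, 4))
        for rep in range(reps):
            t = ck.simulate_mediation_cohort(800, truth=truth, seed=10_000 + rep)
            fit = ck.fit_path_model(t.cgs_std, t[list(truth.mediator_names)],
                                    t.reading_fluency, t.age, t.sex)
            a_est[rep] = fit.a
            b_est[rep] = fit.b
        for est, true_vals in ((a_est, truth.a_paths), (b_est, truth.b_paths)):
            mc_se = est.std(axis=0, ddof=1) / np.sqrt(reps)
            assert np.all(np.abs(est.mean(axis=0) - np.array(true_vals)) < 3 * mc_se)

    def test_total_equals_sum_of_specific(self):
        t = ck.simulate_mediation_cohort(500, seed=3)
        names = list(ck.default_mediation_truth().mediator_names)
        fit = ck.fit_path_model(t.cgs_std, t[names], t.reading_fluency, t.age, t.sex)
        assert fit.total_indirect == pytest.approx(fit.specific_indirect.sum(), abs=0)

    def test_matches_normal_equations_oracle(self):
        gene, med, y, age, sex = build_cohort(150, a=0.3, b=0.5, seed=9)
        fit = ck.fit_path_model(gene, med, y, age, sex)
        X = np.column_stack([np.ones(150), gene, age, sex])
        a_oracle = np.linalg.solve(X.T @ X, X.T @ med["m"].to_numpy())[1]
        Xy = np.column_stack([np.ones(150), gene, med["m"], age, sex])
        beta_y = np.linalg.solve(Xy.T @ Xy, Xy.T @ y)
        assert fit.a[0] == pytest.approx(a_oracle, rel=1e-10)
        assert fit.b[0] == pytest.approx(beta_y[2], rel=1e-10)
        assert fit.c_prime == pytest.approx(beta_y[1], rel=1e-10)

    def test_collinear_mediators_reported(self):
        gene, med, y, age, sex = build_cohort(100, a=0.3, b=0.5)
        med["m2"] = med["m"] * 2.0
        with pytest.raises(ValueError, match="collinear"):
            ck.fit_path_model(gene, med, y, age, sex)

    def test_per_grade_standardization_inside_fit(self):
        t = ck.simulate_mediation_cohort(600, seed=5)
        names = list(ck.default_mediation_truth().mediator_names)
        z = ck.zscore_by_grade(t.reading_fluency.to_numpy(), t.grade.to_numpy())
        for gr in np.unique(t.grade):
            assert np.mean(z[t.grade == gr]) == pytest.approx(0, abs=1e-10)
            assert np.std(z[t.grade == gr], ddof=1) == pytest.approx(1, abs=1e-10)
        fit = ck.fit_path_model(t.cgs, t[names], t.reading_fluency, t.age, t.sex,
                                grade=t.grade, standardize="by_grade")
        assert fit.n == 600


class TestBootstrap:
    def test_same_seed_identical_cis(self):
        gene, med, y, age, sex = build_cohort(150, a=0.4, b=0.4, seed=2)
        kw = dict(replicates=200, seed=77)
        out1 = ck.bootstrap_indirect(gene, med, y, age, sex, **kw)
        out2 = ck.bootstrap_indirect(gene, med, y, age, sex, **kw)
        pd.testing.assert_frame_equal(out1, out2)

    def test_significance_calls_follow_ci(self):
        gene, med, y, age, sex = build_cohort(800, a=0.5, b=0.5, seed=4)
        out = ck.bootstrap_indirect(gene, med, y, age, sex, replicates=300, seed=1)
        strong = out[out.effect == "gene -> m -> outcome"].iloc[0]
        assert strong.ci_low > 0 and strong.significant
        # a CI straddling zero is marked not significant
        gene0, med0, y0, age0, sex0 = build_cohort(200, a=0.0, b=0.0, seed=6)
        out0 = ck.bootstrap_indirect(gene0, med0, y0, age0, sex0, replicates=300, seed=1)
        row = out0.iloc[0]
        assert (row.ci_low <= 0 <= row.ci_high) == (not row.significant)

    def test_replicate_floor_enforced(self):
        gene, med, y, age, sex = build_cohort(100, a=0.3, b=0.3)
        with pytest.raises(ValueError, match=">= 100"):
            ck.bootstrap_indirect(gene, med, y, age, sex, replicates=10)

    def test_null_coverage_of_zero_at_least_nominal(self):
        """a=b=0 truth: the product CI is conservative, covering 0 at >= the nominal rate.

        The product of two null coefficients is the non-regular case for the
        bootstrap, where the percentile interval over-covers rather than
        attaining 95% exactly.
        """
        covered = 0
        reps = 150
        for rep in range(reps):
            gene, med, y, age, sex = build_cohort(400, a=0.0, b=0.0, seed=rep)
            out = ck.bootstrap_indirect(gene, med, y, age, sex, replicates=199, seed=rep)
            row = out.iloc[0]
            covered += int(row.ci_low <= 0 <= row.ci_high)
        se = np.sqrt(0.95 * 0.05 / reps)
        assert covered / reps >= 0.95 - 3 * se


class TestFitIndices:
    def test_saturated_model_convention(self):
        t = ck.simulate_mediation_cohort(400, seed=11)
        names = list(ck.default_mediation_truth().mediator_names)
        idx = ck.fit_indices(t.cgs_std, t[names], t.reading_fluency, t.age, t.sex)
        assert idx.chi_square == 0.0 and idx.df == 0
        assert idx.cfi == 1.0 and idx.rmsea == 0.0

    def test_true_restriction_chi2_near_df(self):
        """Generating truth has no direct effect: omit-direct model fits, chi2/df ~ 1."""
        truth = ck.MediationTruth(("m1", "m2"), (0.3, 0.2), (0.4, 0.3), c_prime=0.0)
        chi2s = []
        for rep in range(100):
            t = ck.simulate_mediation_cohort(2000, truth=truth, seed=500 + rep)
            idx = ck.fit_indices(t.cgs_std, t[["m1", "m2"]], t.reading_fluency,
                                 t.age, t.sex, omit_direct=True)
            assert idx.df == 1
            chi2s.append(idx.chi_square)
        # mean of a chi2_1 sample ~ 1 within MC error
        mc_se = np.std(chi2s, ddof=1) / np.sqrt(len(chi2s))
        assert abs(np.mean(chi2s) - 1.0) < 3 * mc_se

    def test_rmsea_small_for_true_model(self):
        truth = ck.MediationTruth(("m1",), (0.3,), (0.4,), c_prime=0.0)
        t = ck.simulate_mediation_cohort(5000, truth=truth, seed=900)
        idx = ck.fit_indices(t.cgs_std, t[["m1"]], t.reading_fluency, t.age, t.sex,
                             omit_direct=True)
        assert idx.rmsea < 0.05
        assert idx.cfi > 0.95
        marks = idx.passes_conventional_cutoffs()
        assert all(marks.values())


class TestModeratedMediation:
    def test_zero_interaction_index_ci_covers_zero(self):
        rng = np.random.default_rng(13)
        n = 600
        gene = rng.normal(size=n)
        mod = rng.choice(np.arange(1, 6.01, 0.5), n)
        age, sex = rng.uniform(9, 13, n), rng.integers(0, 2, n).astype(float)
        m = 0.3 * gene + rng.normal(size=n)          # no gene x mod term
        y = 0.4 * m + rng.normal(size=n)
        paths, index, indices = ck.fit_moderated_mediation(
            gene, mod, pd.DataFrame({"m": m}), y, age, sex, replicates=300, seed=3)
        row = index.iloc[0]
        assert row.ci_low <= 0 <= row.ci_high
        assert not row.significant

    def test_nonzero_interaction_recovered(self):
        rng = np.random.default_rng(14)
        n = 3000
        gene = rng.normal(size=n)
        mod = rng.choice(np.arange(1, 6.01, 0.5), n)
        age, sex = rng.uniform(9, 13, n), rng.integers(0, 2, n).astype(float)
        a1, a3, b = 0.2, 0.15, 0.5
        m = a1 * gene + a3 * gene * mod + 0.8 * rng.normal(size=n)
        y = b * m + rng.normal(size=n)
        paths, index, indices = ck.fit_moderated_mediation(
            gene, mod, pd.DataFrame({"m": m}), y, age, sex, replicates=300, seed=4)
        est = index.index_of_moderated_mediation.iloc[0]
        assert est == pytest.approx(a3 * b, abs=0.02)
        assert index.significant.iloc[0]
        assert indices.df >= 0  # indices reported for the moderated model
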