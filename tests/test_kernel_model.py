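"""Tests of the weighted kernel regression: closed-form BLUP and Gibbs sampler."""

import numpy as np
import pytest

from sirefert import (
    KernelBLUP,
    McmcConfig,
    blup_closed_form,
    build_design,
    build_linear_kernel,
    simulate_population,
    standardize,
)

from conftest import polygenic_config


def gls_oracle(y, K, X, r, sigma_g2, sigma_e2):
    """Literal joint-normal-equations solve: V = K*sg2 + diag(se2/r)."""
    V = K * sigma_g2 + np.diag(sigma_e2 / r)
    Vi = np.linalg.inv(V)
    b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    g = sigma_g2 * K @ Vi @ (y - X @ b)
    return b, g


def tiny_instance(n=8, p=30, seed=0):
    pop = simulate_population(
        polygenic_config(n_individuals=n, n_snps=p, maf_range=(0.25, 0.5), seed=seed)
    )
    from sirefert import qc_filter

    geno, _ = qc_filter(pop.genotypes)
    K = build_linear_kernel(standardize(geno))
    y = pop.phenotypes["scr"].to_numpy()
    r = pop.phenotypes["reliability"].to_numpy()
    return y, K, r


class TestClosedFormBlup:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_literal_joint_solve(self, seed):
        y, K, r = tiny_instance(n=8, seed=seed)
        X = np.ones((8, 1))
        b, g = blup_closed_form(y, K, 4.0, 9.0, weights=r)
        b0, g0 = gls_oracle(y, K.K, X, r, 4.0, 9.0)
        np.testing.assert_allclose(b, b0, atol=1e-8)
        np.testing.assert_allclose(g, g0, atol=1e-8)

    def test_vanishing_genetic_variance_recovers_weighted_least_squares(self):
        y, K, r = tiny_instance(n=10, seed=5)
        b, g = blup_closed_form(y, K, 0.0, 9.0, weights=r)
        np.testing.assert_allclose(g, 0.0)
        wls = np.sum(r * y) / np.sum(r)  # intercept-only weighted LS
        assert b[0] == pytest.approx(wls, abs=1e-10)

    def test_masked_individuals_predicted_through_kernel_cross_block(self):
        y, K, r = tiny_instance(n=10, seed=6)
        mask = np.ones(10, bool)
        mask[7:] = False
        model = KernelBLUP(y, K, weights=r, train_mask=mask)
        res = model.fit_blup(4.0, 9.0)
        # oracle: train-only GLS, then g_test = K_ts K_tt^+ g_train
        Ktt = K.K[np.ix_(mask, mask)]
        Kst = K.K[np.ix_(~mask, mask)]
        b0, g0 = gls_oracle(y[mask], Ktt, np.ones((7, 1)), r[mask], 4.0, 9.0)
        np.testing.assert_allclose(res.params, b0, atol=1e-7)
        np.testing.assert_allclose(res.genetic_values[mask], g0, atol=1e-7)
        g_test = Kst @ np.linalg.pinv(Ktt) @ g0
        np.testing.assert_allclose(res.genetic_values[~mask], g_test, atol=1e-6)

    def test_splitting_a_record_with_half_reliability_changes_nothing(self):
        # a record duplicated with r -> r/2, r/2 carries the same total
        # precision, so the weighted likelihood (and the BLUP) is unchanged
        y, K, r = tiny_instance(n=8, seed=7)
        b1, g1 = blup_closed_form(y, K, 4.0, 9.0, weights=r)

        idx = list(range(8)) + [3]
        K2 = K.K[np.ix_(idx, idx)]
        y2 = y[idx]
        r2 = r[idx].copy()
        r2[3] = r2[8] = r[3] / 2.0
        b2, g2 = blup_closed_form(y2, K2, 4.0, 9.0, weights=r2)
        np.testing.assert_allclose(b2, b1, atol=1e-8)
        np.testing.assert_allclose(g2[:8], g1, atol=1e-8)

    def test_higher_reliability_never_increases_fitted_residual(self):
        y, K, r = tiny_instance(n=12, seed=8)
        i = 4
        resids = []
        for ri in (0.2, 0.5, 0.9):
            r2 = r.copy()
            r2[i] = ri
            _, g = blup_closed_form(y, K, 4.0, 9.0, weights=r2)
            mu = np.sum(r2 * y) / np.sum(r2)
            model = KernelBLUP(y, K, weights=r2)
            res = model.fit_blup(4.0, 9.0)
            resids.append(abs(y[i] - res.fittedvalues[i]))
        assert resids[0] >= resids[1] >= resids[2]

    def test_permutation_equivariance(self):
        y, K, r = tiny_instance(n=9, seed=9)
        perm = np.random.default_rng(0).permutation(9)
        b1, g1 = blup_closed_form(y, K, 4.0, 9.0, weights=r)
        b2, g2 = blup_closed_form(
            y[perm], K.K[np.ix_(perm, perm)], 4.0, 9.0, weights=r[perm]
        )
        np.testing.assert_allclose(b2, b1, atol=1e-8)
        np.testing.assert_allclose(g2, g1[perm], atol=1e-8)

    def test_collinear_fixed_effects_named(self):
        y, K, r = tiny_instance(n=8, seed=10)
        X, names = build_design(8, np.ones((8, 1)), ["dup_intercept"])
        with pytest.raises(np.linalg.LinAlgError, match="dup_intercept"):
            KernelBLUP(y, K, exog=X, exog_names=names, weights=r)


class TestGibbsSampler:
    def test_deterministic_under_seed(self):
        y, K, r = tiny_instance(n=15, seed=11)
        model = KernelBLUP(y, K, weights=r)
        cfg = McmcConfig(n_iter=400, burn_in=100, thin=2, seed=5)
        a = model.fit(cfg)
        b = model.fit(cfg)
        np.testing.assert_array_equal(a.genetic_values, b.genetic_values)
        np.testing.assert_array_equal(a.params, b.params)
        assert a.sigma_g2 == b.sigma_g2

    def test_fixed_variances_match_closed_form_blup(self):
        pop = simulate_population(
            polygenic_config(n_individuals=30, n_snps=200, seed=12)
        )
        K = build_linear_kernel(standardize(pop.genotypes))
        y = pop.phenotypes["scr"].to_numpy()
        r = pop.phenotypes["reliability"].to_numpy()
        sg2, se2 = pop.true_variance_components
        model = KernelBLUP(y, K, weights=r)
        res = model.fit(
            n_iter=6000, burn_in=1000, thin=1, seed=3, fixed_variances=(sg2, se2)
        )
        blup = model.fit_blup(sg2, se2)
        corr = np.corrcoef(res.genetic_values, blup.genetic_values)[0, 1]
        assert corr > 0.999

    def test_zero_genetic_variance_pins_g_at_zero_and_b_at_wls(self):
        y, K, r = tiny_instance(n=15, seed=13)
        model = KernelBLUP(y, K, weights=r)
        res = model.fit(
            n_iter=2000, burn_in=500, thin=1, seed=1, fixed_variances=(0.0, 9.0)
        )
        np.testing.assert_allclose(res.genetic_values, 0.0, atol=1e-12)
        wls = np.sum(r * y) / np.sum(r)
        mcse = res.bse[0] / np.sqrt(res.n_draws)
        assert abs(res.params[0] - wls) < 4 * mcse

    def test_lambda_is_mean_of_per_draw_ratios(self):
        y, K, r = tiny_instance(n=20, seed=14)
        model = KernelBLUP(y, K, weights=r)
        res = model.fit(n_iter=1000, burn_in=200, thin=2, seed=2, store_draws=True)
        per_draw = res.draws["sigma_e2"] / res.draws["sigma_g2"]
        assert res.lambda_ == pytest.approx(per_draw.mean(), rel=1e-10)
        assert res.lambda_ != pytest.approx(res.sigma_e2 / res.sigma_g2, rel=1e-6)

    def test_posterior_variances_positive_and_summary_renders(self):
        y, K, r = tiny_instance(n=20, seed=15)
        res = KernelBLUP(y, K, weights=r).fit(n_iter=600, burn_in=100, seed=0)
        assert res.sigma_g2 > 0 and res.sigma_e2 > 0
        text = res.summary()
        assert "sigma_g^2" in text and "intercept" in text

    def test_bad_chain_settings_rejected(self):
        with pytest.raises(ValueError):
            McmcConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            McmcConfig(thin=0)


class TestPredict:
    def test_intercept_only_prediction_is_posterior_mean_intercept(self):
        y, K, r = tiny_instance(n=15, seed=16)
        model = KernelBLUP(y, K, weights=r)
        res = model.fit(n_iter=500, burn_in=100, seed=4)
        pred = res.predict()
        np.testing.assert_allclose(
            pred["prediction"], res.params[0] + res.genetic_values, atol=1e-12
        )
        assert not pred["is_test"].any()

    def test_exchangeable_individuals_get_identical_predictions(self):
        # two individuals with identical kernel rows and identical X
        row = np.array([0.0, 1.0, 2.0, 1.0, 0.0, 2.0])
        import conftest

        g = conftest.make_genotypes(
            np.vstack([row, row, [1, 0, 2, 2, 1, 0], [2, 1, 0, 1, 2, 1]])
        )
        K = build_linear_kernel(standardize(g))
        y = np.array([1.0, 1.0, -2.0, 0.5])
        model = KernelBLUP(y, K)
        res = model.fit_blup(2.0, 3.0)
        assert res.fittedvalues[0] == pytest.approx(res.fittedvalues[1], abs=1e-10)

    def test_genotypic_twin_in_test_set_tracks_training_twin(self):
        # high-h2 cohorts: prediction for a masked genotypic twin correlates
        # strongly with the training twin's prediction across seeds
        preds_train, preds_test = [], []
        for seed in range(8):
            pop = simulate_population(
                polygenic_config(
                    n_individuals=80, n_snps=300, heritability=0.9, seed=seed
                )
            )
            K0 = build_linear_kernel(standardize(pop.genotypes)).K
            idx = list(range(80)) + [0]  # individual 0 duplicated as a twin
            K = K0[np.ix_(idx, idx)]
            y = np.append(pop.phenotypes["scr"].to_numpy(), 0.0)
            r = np.append(pop.phenotypes["reliability"].to_numpy(), 0.5)
            mask = np.ones(81, bool)
            mask[80] = False
            model = KernelBLUP(y, K, weights=r, train_mask=mask)
            res = model.fit(n_iter=1500, burn_in=300, seed=seed)
            preds_train.append(res.fittedvalues[0])
            preds_test.append(res.fittedvalues[80])
        corr = np.corrcoef(preds_train, preds_test)[0, 1]
        assert corr >= 0.9

    def test_alignment_of_ids_in_prediction_frame(self):
        y, K, r = tiny_instance(n=10, seed=17)
        mask = np.ones(10, bool)
        mask[3] = False
        model = KernelBLUP(y, K, weights=r, train_mask=mask)
        res = model.fit_blup(4.0, 9.0)
        pred = res.predict()
        assert pred.loc[3, "is_test"]
        assert pred["is_test"].sum() == 1


class TestVarianceRecovery:
    def test_moderate_cohort_recovers_generating_components(self):
        # smaller-scale version of the recovery property; the full-size
        # check lives in the acceptance suite
        ratios = []
        for seed in range(3):
            pop = simulate_population(
                polygenic_config(n_individuals=300, n_snps=1000, seed=40 + seed)
            )
            K = build_linear_kernel(standardize(pop.genotypes))
            y = pop.phenotypes["scr"].to_numpy()
            r = pop.phenotypes["reliability"].to_numpy()
            res = KernelBLUP(y, K, weights=r).fit(
                n_iter=4000, burn_in=800, thin=5, seed=seed
            )
            sg2, se2 = pop.true_variance_components
            ratios.append([res.sigma_g2 / sg2, res.sigma_e2 / se2])
        mean = np.mean(ratios, axis=0)
        assert np.all(np.abs(mean - 1.0) < 0.4)
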