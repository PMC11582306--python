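"""ML fitting: likelihood values, recovery, deviance, AIC, LR test, SEs."""

import numpy as np
import pytest

from rrbias import (
    BiasParams,
    ProfileCounts,
    TrueCategoryProbs,
    build_design_matrix,
    deviance_g2,
    fit_ml,
    forward,
    load_fixture,
    loglik,
    lr_test,
)
from rrbias.models import ProfileProbs


def exact_counts(layout, pi_values, n, *, theta=None, theta_e=None, cheater=None):
    """Expected profile frequencies n * forward(...) for known parameters."""
    if cheater is not None:
        probs = TrueCategoryProbs(pi_values, layout.true_labels, cheater_prob=cheater)
        ps = forward(layout, probs, bias_structure="cdm")
    elif theta_e is not None:
        probs = TrueCategoryProbs(pi_values, layout.true_labels)
        ps = forward(layout, probs, BiasParams(theta=theta, theta_yy_yn=theta_e),
                     bias_structure="sp_last_year")
    elif theta is not None:
        probs = TrueCategoryProbs(pi_values, layout.true_labels)
        ps = forward(layout, probs, BiasParams(theta=theta), bias_structure="sp_no")
    else:
        probs = TrueCategoryProbs(pi_values, layout.true_labels)
        ps = forward(layout, probs)
    block_n = n * np.ones(int(ps.block_index.max()) + 1)
    return ProfileCounts(ps.values * block_n[ps.block_index], ps.labels,
                         block_index=ps.block_index)


class TestLoglik:
    def test_saturated_plugin(self, ely_layout):
        n = np.array([50.0, 20, 20, 10])
        probs = ProfileProbs(n / n.sum(), ely_layout.obs_labels)
        counts = ProfileCounts(n, ely_layout.obs_labels)
        assert loglik(probs, counts) == pytest.approx(float(n @ np.log(n / n.sum())))

    def test_uniform_probs(self, ely_layout):
        counts = ProfileCounts([25, 25, 25, 25], ely_layout.obs_labels)
        probs = ProfileProbs([0.25] * 4, ely_layout.obs_labels)
        assert loglik(probs, counts) == pytest.approx(100 * np.log(0.25))

    def test_subsamples_loglik_adds_over_blocks(self, subsamples_layout):
        counts = ProfileCounts([30, 20, 10, 40], subsamples_layout.obs_labels,
                               block_index=[0, 0, 1, 1])
        probs = ProfileProbs([0.6, 0.4, 0.3, 0.7], subsamples_layout.obs_labels,
                             block_index=[0, 0, 1, 1])
        manual = 30 * np.log(0.6) + 20 * np.log(0.4) + 10 * np.log(0.3) + 40 * np.log(0.7)
        assert loglik(probs, counts) == pytest.approx(manual)

    def test_zero_prob_positive_count(self, ely_layout):
        counts = ProfileCounts([1, 1, 1, 1], ely_layout.obs_labels)
        probs = ProfileProbs([0.0, 0.5, 0.25, 0.25], ely_layout.obs_labels)
        with pytest.warns(UserWarning):
            assert loglik(probs, counts) == -np.inf


class TestSelfConsistency:
    """Fitting exact expected counts recovers the generating parameters."""

    def test_null_ely(self, ely_layout):
        counts = exact_counts(ely_layout, [0.85, 0.09, 0.06], 5000)
        fit = fit_ml(ely_layout, "null", counts, n_starts=5, seed=1)
        np.testing.assert_allclose([fit.estimates[k] for k in ("nn", "yn", "yy")],
                                   [0.85, 0.09, 0.06], atol=1e-6)
        assert fit.g2 == pytest.approx(0.0, abs=1e-8)

    def test_spno_ely(self, ely_layout):
        counts = exact_counts(ely_layout, [0.8, 0.12, 0.08], 5000, theta=0.1)
        fit = fit_ml(ely_layout, "sp_no", counts, n_starts=5, seed=1)
        assert fit.estimates["theta"] == pytest.approx(0.1, abs=1e-6)
        assert fit.estimates["nn"] == pytest.approx(0.8, abs=1e-6)

    def test_cdm_subsamples(self, subsamples_layout):
        counts = exact_counts(subsamples_layout, [0.7, 0.2], 1000, cheater=0.1)
        fit = fit_ml(subsamples_layout, "cdm", counts, n_starts=5, seed=1)
        assert fit.estimates["tau_c"] == pytest.approx(0.1, abs=1e-6)
        np.testing.assert_allclose([fit.estimates["n"], fit.estimates["y"]],
                                   [0.7, 0.2], atol=1e-6)

    def test_sply_ely_plus_q(self, ely_plus_q_layout):
        pi = [0.7, 0.05, 0.08, 0.02, 0.1, 0.05]
        counts = exact_counts(ely_plus_q_layout, pi, 20000, theta=0.08, theta_e=0.25)
        fit = fit_ml(ely_plus_q_layout, "sp_last_year", counts, n_starts=8, seed=1)
        assert fit.estimates["theta"] == pytest.approx(0.08, abs=1e-5)
        assert fit.estimates["theta_yy_yn"] == pytest.approx(0.25, abs=1e-5)

    def test_negative_theta_recovered(self, ely_layout):
        """theta is estimated on its raw scale and may go negative."""
        counts = exact_counts(ely_layout, [0.8, 0.12, 0.08], 5000, theta=-0.05)
        fit = fit_ml(ely_layout, "sp_no", counts, n_starts=5, seed=1)
        assert fit.estimates["theta"] == pytest.approx(-0.05, abs=1e-5)


class TestGridOracle:
    def test_null_matches_dense_simplex_search(self, ely_layout):
        """Optimizer equals an exhaustive simplex grid search (step 1e-3)."""
        fx = load_fixture("study1_anabolics_collapsed")
        fit = fit_ml(ely_layout, "null", fx.counts, seed=0)
        T = build_design_matrix(ely_layout).values
        n = fx.counts.counts
        step = 1e-3
        g = np.arange(0.0, 1.0 + step / 2, step)
        a, b = np.meshgrid(g, g, indexing="ij")
        keep = a + b <= 1.0 + 1e-12
        pis = np.stack([1 - a[keep] - b[keep], a[keep], b[keep]], axis=1)
        ps = pis @ T.T
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where((ps > 0).all(axis=1), np.log(np.clip(ps, 1e-300, None)) @ n, -np.inf)
        best = pis[np.argmax(ll)]
        assert fit.loglik >= ll.max() - 1e-9
        np.testing.assert_allclose([fit.estimates[k] for k in ("nn", "yn", "yy")],
                                   best, atol=2 * step)


class TestDeviance:
    def test_fitted_equals_observed(self, ely_layout):
        counts = ProfileCounts([40, 30, 20, 10], ely_layout.obs_labels)
        g2, p = deviance_g2(counts, counts.counts.copy(), df=1)
        assert g2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_count_convention(self, ely_layout):
        counts = ProfileCounts([40, 0, 40, 20], ely_layout.obs_labels)
        g2, _ = deviance_g2(counts, np.array([40.0, 5.0, 35.0, 20.0]), df=1)
        # the zero cell contributes nothing
        manual = 2 * (40 * np.log(40 / 35)) * 0 + 2 * 40 * np.log(35 / 35)
        assert np.isfinite(g2)
        assert g2 == pytest.approx(2 * 40 * np.log(40 / 35), abs=1e-10)

    def test_df_zero_has_no_p_value(self, ely_layout):
        counts = ProfileCounts([40, 30, 20, 10], ely_layout.obs_labels)
        _, p = deviance_g2(counts, counts.counts * 1.0, df=0)
        assert p is None

    def test_fitted_zero_with_observed_rejected(self, ely_layout):
        counts = ProfileCounts([40, 30, 20, 10], ely_layout.obs_labels)
        with pytest.raises(ValueError):
            deviance_g2(counts, np.array([40.0, 0.0, 30.0, 30.0]), df=1)

    def test_study_fit_g2_values(self, ely_layout):
        fx = load_fixture("study1_anabolics_collapsed")
        fit = fit_ml(ely_layout, "null", fx.counts, seed=0)
        assert fit.df == 1
        assert fit.g2 == pytest.approx(1.22, abs=0.02)

    def test_fitted_counts_reproduce_block_totals(self, subsamples_layout):
        counts = ProfileCounts([160, 40, 90, 110], subsamples_layout.obs_labels,
                               block_index=[0, 0, 1, 1])
        fit = fit_ml(subsamples_layout, "cdm", counts, n_starts=5, seed=0)
        np.testing.assert_allclose(
            [fit.fitted_counts[:2].sum(), fit.fitted_counts[2:].sum()], [200, 200])


class TestAicAndLr:
    def test_delta_aic_identity(self, ely_layout):
        """For nested models, AIC_alt - AIC_null = 2 dk - (G2_null - G2_alt)."""
        fx = load_fixture("study1_anabolics_collapsed")
        f0 = fit_ml(ely_layout, "null", fx.counts, seed=0)
        f1 = fit_ml(ely_layout, "sp_no", fx.counts, seed=0)
        assert f1.aic - f0.aic == pytest.approx(2 - (f0.g2 - f1.g2), abs=1e-6)

    def test_lr_statistic_equals_deviance_drop(self, ely_layout):
        fx = load_fixture("study1_anabolics_collapsed")
        f0 = fit_ml(ely_layout, "null", fx.counts, seed=0)
        f1 = fit_ml(ely_layout, "sp_no", fx.counts, seed=0)
        stat, df, p = lr_test(f0, f1)
        assert stat == pytest.approx(f0.g2 - f1.g2, abs=1e-8)
        assert df == 1
        # SP-no is saturated here, so the statistic is the null deviance
        assert stat == pytest.approx(f0.g2, abs=1e-6)

    def test_identical_fits(self, ely_layout):
        fx = load_fixture("study1_anabolics_collapsed")
        f0 = fit_ml(ely_layout, "null", fx.counts, seed=0)
        f1 = fit_ml(ely_layout, "sp_no", fx.counts, seed=0)
        stat, _, p1 = lr_test(f0, f1)
        assert stat >= 0
        with pytest.raises(ValueError):
            lr_test(f1, f0)  # reversed nesting


class TestStandardErrors:
    def test_root_n_scaling(self, ely_layout):
        """Quadrupling every count halves the delta-method standard errors."""
        base = exact_counts(ely_layout, [0.85, 0.09, 0.06], 2000, theta=0.05)
        big = ProfileCounts(base.counts * 4, base.labels)
        f1 = fit_ml(ely_layout, "sp_no", base, n_starts=5, seed=0)
        f4 = fit_ml(ely_layout, "sp_no", big, n_starts=5, seed=0)
        for k in f1.std_errors:
            assert f1.std_errors[k] / f4.std_errors[k] == pytest.approx(2.0, rel=0.01)

    def test_interior_optimum_positive_ses(self, ely_layout):
        fx = load_fixture("study1_anabolics_collapsed")
        fit = fit_ml(ely_layout, "sp_no", fx.counts, seed=0)
        assert fit.se_available
        assert all(v > 0 for v in fit.std_errors.values())


class TestIdentification:
    def test_spno_single_question_not_identified(self, rand08):
        from rrbias import DesignLayout, QuestionBlock
        layout = DesignLayout([QuestionBlock("single", rand08)])
        counts = ProfileCounts([60, 40], layout.obs_labels)
        with pytest.raises(ValueError):
            fit_ml(layout, "sp_no", counts)

    def test_free_per_category_theta_rejected(self, subsamples_layout):
        counts = ProfileCounts([160, 40, 90, 110], subsamples_layout.obs_labels,
                               block_index=[0, 0, 1, 1])
        with pytest.raises(ValueError):
            fit_ml(subsamples_layout, "sp_no_by_category", counts)

    def test_label_mismatch_rejected(self, ely_layout):
        counts = ProfileCounts([1, 2, 3], ["a", "b", "c"])
        with pytest.raises(ValueError):
            fit_ml(ely_layout, "null", counts)
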