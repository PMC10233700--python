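"""Robust log-scale mixed model, contrasts, retransformation, FDR."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_flat_effects
from fetalkin.stats import (
    BISQUARE_C_99,
    ModelSpec,
    analyze,
    bisquare_tuning_constant,
    bisquare_weights,
    build_contrasts,
    fdr_adjust,
    fit_mixed,
    log_transform,
    retransform_contrast,
    robust_refit,
)
from fetalkin.synthetic import (
    EffectSpec,
    generate_amt_table,
    generate_design,
)


def _table(n_subjects=40, seed=0, **effect_kwargs):
    designs = generate_design(n_subjects, seed=seed)
    effects = EffectSpec(**effect_kwargs)
    return generate_amt_table(designs, effects, seed=seed)


#: reduced model: enough structure to exercise both random effects
#: without GA-group aliasing at small n
SMALL_SPEC = ModelSpec(
    fixed_factors=("oxygen", "distance_class", "extremity", "side"),
    interactions=(),
    report_pairwise=("oxygen", "distance_class"),
)


class TestLogTransform:
    def test_natural_log_of_positive_amt(self):
        df = pd.DataFrame({"amt_s": [1.0, np.e]})
        out = log_transform(df, offset_s=1.0)
        np.testing.assert_allclose(out.log_amt, [0.0, 1.0])
        assert not out.zero_substituted.any()

    def test_zero_amt_offset_rule_uses_half_dt(self):
        df = pd.DataFrame({"amt_s": [0.0, 3.0], "dt_s": [3.0, 3.0]})
        out = log_transform(df)
        assert out.log_amt.iloc[0] == pytest.approx(np.log(1.5))
        assert bool(out.zero_substituted.iloc[0])
        assert not out.zero_substituted.iloc[1]

    def test_zero_amt_drop_rule(self):
        df = pd.DataFrame({"amt_s": [0.0, 2.0], "dt_s": [3.0, 3.0]})
        out = log_transform(df, zero_rule="drop")
        assert len(out) == 1

    def test_negative_amt_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            log_transform(pd.DataFrame({"amt_s": [-1.0]}))


class TestBisquare:
    def test_zero_residual_gets_full_weight(self):
        assert bisquare_weights(np.array([0.0]), scale=1.0)[0] == 1.0

    def test_weight_vanishes_at_support_boundary(self):
        r = np.array([BISQUARE_C_99, BISQUARE_C_99 + 1.0, -10.0])
        assert np.all(bisquare_weights(r, scale=1.0) == 0.0)

    def test_weights_in_unit_interval(self, rng):
        w = bisquare_weights(rng.normal(size=500), scale=1.0)
        assert np.all((w >= 0) & (w <= 1))

    @pytest.mark.parametrize("eff, c", [(0.95, 4.685), (0.99, 7.041)])
    def test_tuning_constant_matches_conventional_values(self, eff, c):
        assert bisquare_tuning_constant(eff) == pytest.approx(c, abs=5e-3)


class TestRetransform:
    def test_zero_coefficient_is_zero_percent(self):
        pct, se, _ = retransform_contrast(0.0, 0.1)
        assert pct == 0.0

    def test_printed_oxygen_contrast(self):
        pct, _, _ = retransform_contrast(np.log(1.207), 0.03)
        assert pct == pytest.approx(20.7)

    def test_log_scale_composition_of_joint_contrasts(self):
        beta = np.log(1.206) + np.log(1.238)
        pct, _, _ = retransform_contrast(beta, 0.0)
        assert round(pct, 1) == 49.3

    def test_order_preserving(self, rng):
        betas = np.sort(rng.normal(size=20))
        pcts = [retransform_contrast(b, 0.1)[0] for b in betas]
        assert np.all(np.diff(pcts) > 0)

    def test_delta_method_se_and_ci_endpoints(self):
        pct, se, (lo, hi) = retransform_contrast(0.2, 0.05, (0.1, 0.3))
        assert se == pytest.approx(np.exp(0.2) * 0.05 * 100)
        assert lo == pytest.approx((np.exp(0.1) - 1) * 100)
        assert hi == pytest.approx((np.exp(0.3) - 1) * 100)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            retransform_contrast(np.nan, 0.1)


def brute_force_bh(pvals, alpha=0.05):
    """Textbook step-up BH: adjusted p_(i) = min_{j>=i} m p_(j) / j."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvals[i] / rank)
        adj[i] = running
    return adj


class TestFDR:
    def _frame(self, p, effect="f"):
        return pd.DataFrame({"effect": effect, "contrast": range(len(p)), "p": p})

    def test_single_hypothesis_family_fdr_equals_p(self):
        out = fdr_adjust(self._frame([0.031]))
        assert out.fdr.iloc[0] == pytest.approx(0.031)

    def test_known_family(self):
        out = fdr_adjust(self._frame([0.01, 0.02, 0.03]))
        np.testing.assert_allclose(out.fdr, [0.03, 0.03, 0.03])

    def test_all_ones(self):
        out = fdr_adjust(self._frame([1.0, 1.0, 1.0, 1.0]))
        assert np.all(out.fdr == 1.0)

    def test_matches_brute_force_on_random_families(self, rng):
        for _ in range(50):
            m = int(rng.integers(1, 7))
            p = rng.uniform(size=m)
            out = fdr_adjust(self._frame(p))
            np.testing.assert_allclose(out.fdr, brute_force_bh(p), atol=1e-12)

    def test_families_adjusted_independently(self, rng):
        df = pd.concat(
            [self._frame([0.01, 0.04], "a"), self._frame([0.01, 0.04], "b")]
        )
        out = fdr_adjust(df)
        np.testing.assert_allclose(
            out[out.effect == "a"].fdr, out[out.effect == "b"].fdr
        )

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust(self._frame([1.5]))


class TestFitMixed:
    def test_degenerate_truth_gives_near_zero_variance_components(self):
        table = _table(150, seed=4, baseline_log_amt=2.0, sd_subject=0.0,
                       sd_scan_within_position=0.0, sd_residual=0.1)
        fit = fit_mixed(log_transform(table), SMALL_SPEC)
        assert fit.var_subject <= 1e-4
        assert fit.var_scan_within_position <= 1e-4
        assert fit.var_residual == pytest.approx(0.01, rel=0.1)

    def test_planted_variance_components_recovered(self):
        table = _table(150, seed=5, sd_subject=0.3, sd_scan_within_position=0.2,
                       sd_residual=0.5)
        fit = fit_mixed(log_transform(table), SMALL_SPEC)
        assert fit.var_subject == pytest.approx(0.09, rel=0.4)
        assert fit.var_scan_within_position == pytest.approx(0.04, rel=0.6)
        assert fit.var_residual == pytest.approx(0.25, rel=0.1)

    def test_oxygen_coefficient_recovered_within_3_se(self):
        beta = np.log(1.207)
        table = _table(100, seed=6, fixed_effects={"oxygen": {"hyperoxia": beta}})
        fit = fit_mixed(log_transform(table), SMALL_SPEC)
        est, se = fit.contrast({"oxygen": "hyperoxia"}, {"oxygen": "normoxia"})
        assert abs(est - beta) < 3 * se

    def test_duplicated_rows_leave_coefficients_unchanged(self):
        table = _table(30, seed=7)
        doubled = pd.concat([table, table], ignore_index=True)
        f1 = fit_mixed(log_transform(table), SMALL_SPEC)
        f2 = fit_mixed(log_transform(doubled), SMALL_SPEC)
        # exact sufficiency holds for the weighted fixed-effect solve;
        # REML variance components re-estimated on doubled data move the
        # GLS weighting marginally
        np.testing.assert_allclose(f1.params, f2.params, atol=1e-3)

    def test_fewer_than_two_subjects_rejected(self):
        table = _table(1, seed=8)
        with pytest.raises(ValueError, match="two subjects"):
            fit_mixed(log_transform(table), SMALL_SPEC)

    def test_singular_design_reports_aliased_columns(self):
        table = _table(12, seed=9)
        table["parity"] = table["fetal_sex"].map(
            {"male": "primipara", "female": "multipara"}
        )
        spec = ModelSpec(fixed_factors=("oxygen", "parity", "fetal_sex"),
                         interactions=(), report_pairwise=("oxygen",))
        with pytest.raises(ValueError, match="aliased"):
            fit_mixed(log_transform(table), spec)
        dropped = fit_mixed(
            log_transform(table),
            ModelSpec(fixed_factors=("oxygen", "parity", "fetal_sex"),
                      interactions=(), report_pairwise=("oxygen",),
                      on_singular="drop"),
        )
        assert len(dropped.params) < 1 + 1 + 2 + 1


class TestRobustRefit:
    def test_robust_off_returns_unit_weights_immediately(self):
        table = _table(25, seed=10)
        spec = ModelSpec(**{**SMALL_SPEC.__dict__, "robust": False})
        fit = fit_mixed(log_transform(table), spec)
        out = robust_refit(fit)
        assert out.converged and out.iterations == 0
        assert np.all(out.weights == 1.0)

    def test_clean_data_converges_quickly_with_high_weights(self):
        table = _table(40, seed=11)
        fit = robust_refit(fit_mixed(log_transform(table), SMALL_SPEC))
        assert fit.converged
        assert fit.weights.mean() > 0.9
        assert np.all((fit.weights >= 0) & (fit.weights <= 1))

    def test_gross_outliers_get_zero_weight(self):
        table = _table(40, seed=12)
        m = log_transform(table)
        m.loc[m.index[:10], "log_amt"] += 50.0
        fit = robust_refit(fit_mixed(m, SMALL_SPEC))
        assert np.all(fit.weights[np.argsort(-np.abs(fit.y - fit.X @ fit.params))[:10]] == 0)

    def test_robust_beats_plain_under_contamination(self):
        # 1% gross outliers at +10 residual SD
        beta = np.log(1.207)
        wins = 0
        for rep in range(50):
            table = _table(25, seed=100 + rep,
                           fixed_effects={"oxygen": {"hyperoxia": beta}})
            m = log_transform(table)
            rng = np.random.default_rng(rep)
            # contaminate one oxygen arm so the outliers actually load
            # on the contrast under test
            hyper = np.flatnonzero((m.oxygen == "hyperoxia").to_numpy())
            bad = rng.choice(hyper, size=max(1, len(m) // 100), replace=False)
            m.loc[m.index[bad], "log_amt"] += 10 * 0.5
            plain = fit_mixed(m, SMALL_SPEC)
            robust = robust_refit(plain)
            e_p, _ = plain.contrast({"oxygen": "hyperoxia"}, {"oxygen": "normoxia"})
            e_r, _ = robust.contrast({"oxygen": "hyperoxia"}, {"oxygen": "normoxia"})
            wins += abs(e_r - beta) < abs(e_p - beta)
        assert wins >= 45  # >= 90% of 50 replicates


class TestContrastTable:
    @pytest.fixture(scope="class")
    def fitted(self):
        designs = generate_design(60, seed=13)
        effects = EffectSpec(fixed_effects={"oxygen": {"hyperoxia": np.log(1.2)}})
        table = generate_amt_table(designs, effects, seed=13)
        fit = robust_refit(fit_mixed(log_transform(table), ModelSpec()))
        return fit, fdr_adjust(build_contrasts(fit))

    def test_two_level_factor_has_one_contrast(self, fitted):
        _, ct = fitted
        assert (ct.effect == "oxygen").sum() == 1
        assert ct[ct.effect == "oxygen"].contrast.iloc[0] == "hyperoxia-normoxia"

    def test_four_level_factor_has_six_pairwise_contrasts(self, fitted):
        _, ct = fitted
        assert (ct.effect == "maternal_position").sum() == 6

    def test_interaction_reported_per_week(self, fitted):
        fit, ct = fitted
        slices = ct[ct.effect == "ga_group:extremity"]
        assert len(slices) == len(fit.info.levels["ga_group"])
        assert slices.contrast.str.endswith("*[lower-upper]").all()

    def test_self_contrast_is_null(self, fitted):
        fit, _ = fitted
        est, se = fit.contrast({"oxygen": "hyperoxia"}, {"oxygen": "hyperoxia"})
        assert est == 0.0 and se == 0.0

    def test_ci_brackets_estimate_on_log_scale(self, fitted):
        _, ct = fitted
        assert (ct.ci_low_pct < ct.estimate_pct).all()
        assert (ct.estimate_pct < ct.ci_high_pct).all()
        assert (ct.estimate_pct > -100).all()

    def test_unknown_family_rejected(self, fitted):
        fit, _ = fitted
        with pytest.raises(KeyError):
            build_contrasts(fit, [("bogus_factor", "pairwise")])


def test_analyze_full_pipeline_smoke():
    designs = generate_design(30, seed=14)
    table = generate_amt_table(
        designs, EffectSpec(fixed_effects={"oxygen": {"hyperoxia": 0.3}}), seed=14
    )
    fit, contrasts = analyze(table, ModelSpec(on_singular="drop"))
    assert fit.converged
    assert {"estimate_pct", "fdr", "significant_fdr"} <= set(contrasts.columns)
    oxy = contrasts[contrasts.effect == "oxygen"].iloc[0]
    assert oxy.significant_fdr
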