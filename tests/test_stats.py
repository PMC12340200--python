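import numpy as np
import pandas as pd
import pytest

from synglia.stats import (
    ModelSpec,
    Transformation,
    apply_transformation,
    case_level_correlations,
    fit_lmem,
    fixed_effect_test,
    posthoc_contrasts,
    select_transformation,
    simulate_measurement_table,
)


class TestTransformations:
    def test_identity_unchanged(self):
        x = np.array([0.0, 1.5, 7.0])
        np.testing.assert_array_equal(apply_transformation(x, "identity"), x)

    def test_tukey_lambda_one_is_identity(self):
        x = np.array([0.5, 2.0, 9.0])
        tr = Transformation("tukey_ladder", lam=1.0)
        np.testing.assert_allclose(tr.apply(x), x)

    def test_arcsine_sqrt_closed_form(self):
        out = apply_transformation(np.array([0.25]), "arcsine_sqrt")
        assert out[0] == pytest.approx(np.arcsin(0.5), abs=1e-12)
        assert out[0] == pytest.approx(0.5236, abs=1e-4)

    def test_arcsine_sqrt_percent_rescaling(self):
        tr = Transformation("arcsine_sqrt")
        out = tr.apply(np.array([25.0]))
        assert out[0] == pytest.approx(np.arcsin(0.5))
        assert tr.rescale_used == 100.0

    def test_arcsine_above_100_errors(self):
        with pytest.raises(ValueError, match="100"):
            apply_transformation(np.array([150.0]), "arcsine_sqrt")

    def test_log_offset_for_zeros_recorded(self):
        tr = Transformation("log")
        out = tr.apply(np.array([0.0, 2.0, 4.0]))
        assert tr.offset_used == 1.0  # half the smallest positive value
        assert out[0] == pytest.approx(np.log(1.0))

    def test_negative_tukey_lambda_sign_preserving(self):
        tr = Transformation("tukey_ladder", lam=-1.0)
        out = tr.apply(np.array([2.0, 4.0]))
        np.testing.assert_allclose(out, [-0.5, -0.25])
        # monotone increasing despite the negative power
        assert out[1] > out[0]

    def test_sqrt_domain_error_names_values(self):
        with pytest.raises(ValueError, match="negative"):
            apply_transformation(np.array([-1.0]), "sqrt")

    def test_unknown_name(self):
        with pytest.raises(ValueError, match="unknown transformation"):
            Transformation("box_cox")


class TestFitLmem:
    def test_balanced_group_estimates_equal_case_mean_means(self):
        # brute-force oracle: in a balanced one-way design the fitted group
        # means equal the plain means of case means
        df = simulate_measurement_table(
            {"Young": 5, "Aged": 5, "CDS": 5}, n_pairs_per_case=3,
            case_sd=1.0, resid_sd=0.5,
            group_effects={"Aged": 1.0, "CDS": 2.0}, seed=2, paired=False,
        )
        fit = fit_lmem(df, ModelSpec(outcome="value", fixed="group"))
        case_means = df.groupby(["group", "case_id"])["value"].mean()
        expected = case_means.groupby("group").mean()
        names = list(fit.design_info.column_names)
        beta = np.asarray(fit.params)
        fitted = {"Aged": beta[names.index("Intercept")]}
        for g in ("CDS", "Young"):
            fitted[g] = fitted["Aged"] + beta[names.index(f"group[T.{g}]")]
        for g, mu in expected.items():
            assert fitted[g] == pytest.approx(mu, abs=1e-4)

    def test_missing_outcome_column(self):
        df = simulate_measurement_table({"A": 3, "B": 3}, seed=0)
        with pytest.raises(ValueError, match="nope"):
            fit_lmem(df, ModelSpec(outcome="nope", fixed="group"))

    def test_constant_outcome_degenerate(self):
        df = simulate_measurement_table({"A": 3, "B": 3}, seed=0)
        df["value"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_lmem(df, ModelSpec(outcome="value", fixed="group"))

    def test_nested_random_structure_reports_roi_variance(self):
        df = simulate_measurement_table(
            {"A": 6, "B": 6}, n_pairs_per_case=4, case_sd=1.0, roi_sd=1.0,
            resid_sd=0.5, seed=3,
        )
        fit = fit_lmem(
            df, ModelSpec(outcome="value", fixed="plaque_status",
                          random="case_roi")
        )
        assert "roi_in_case_var" in fit.variance_components
        assert fit.variance_components["roi_in_case_var"] > 0.1

    def test_zero_case_variance_estimated_near_zero(self):
        df = simulate_measurement_table(
            {"A": 8, "B": 8}, n_pairs_per_case=4, case_sd=0.0, resid_sd=1.0,
            seed=4, paired=False,
        )
        fit = fit_lmem(df, ModelSpec(outcome="value", fixed="group"))
        assert fit.variance_components["case_intercept_var"] < 0.1

    def test_aic_prefers_simpler_fixed_structure_under_null(self):
        # no age effect simulated: the age covariate should not improve AIC
        # by more than the tie threshold in most datasets
        wins = 0
        for seed in range(8):
            df = simulate_measurement_table(
                {"Young": 6, "Aged": 6, "CDS": 6}, n_pairs_per_case=3,
                case_sd=1.0, resid_sd=1.0, seed=100 + seed, paired=False,
            )
            rng = np.random.default_rng(seed)
            age_by_case = {
                c: rng.uniform(2, 20) for c in df["case_id"].unique()
            }
            df["age_years"] = df["case_id"].map(age_by_case)
            simple = fit_lmem(df, ModelSpec(outcome="value", fixed="group"))
            withage = fit_lmem(
                df, ModelSpec(outcome="value", fixed="group + age_years")
            )
            if simple.aic < withage.aic + 2.0:
                wins += 1
        assert wins >= 6

    def test_parameter_recovery_within_two_se(self):
        hits, total = 0, 25
        for seed in range(total):
            true_effect = 1.5
            df = simulate_measurement_table(
                {"A": 12, "B": 12}, n_pairs_per_case=4, case_sd=0.8,
                resid_sd=1.0, group_effects={"B": true_effect},
                seed=500 + seed, paired=False,
            )
            fit = fit_lmem(df, ModelSpec(outcome="value", fixed="group"))
            names = list(fit.design_info.column_names)
            i = names.index("group[T.B]")
            est = float(np.asarray(fit.params)[i])
            se = float(np.sqrt(fit.cov_fe[i, i]))
            if abs(est - true_effect) <= 2 * se:
                hits += 1
        assert hits / total >= 0.9


@pytest.fixture(scope="module")
def interaction_fit():
    df = simulate_measurement_table(
        {"Young": 5, "Aged": 5, "CDS": 5}, n_pairs_per_case=3,
        case_sd=1.0, resid_sd=1.0, plaque_effect=1.0, seed=6,
    )
    return fit_lmem(
        df, ModelSpec(outcome="value", fixed="plaque_status * group",
                      random="case_roi")
    )


class TestPosthoc:
    def test_three_groups_three_contrasts(self, interaction_fit):
        contrasts = posthoc_contrasts(interaction_fit, "group_pairs")
        assert len(contrasts) == 3
        labels = {c.comparison for c in contrasts}
        assert len(labels) == 3

    def test_plaque_within_group_one_per_group(self, interaction_fit):
        contrasts = posthoc_contrasts(interaction_fit, "plaque_within_group")
        assert len(contrasts) == 3
        assert all("plaque - no_plaque" in c.comparison for c in contrasts)

    def test_adjusted_p_at_least_unadjusted(self, interaction_fit):
        for family in ("group_pairs", "plaque_within_group"):
            for c in posthoc_contrasts(interaction_fit, family):
                assert c.p_adjusted >= c.p_unadjusted - 1e-12
                assert 0.0 <= c.p_adjusted <= 1.0

    def test_family_of_one_equals_unadjusted(self):
        df = simulate_measurement_table(
            {"A": 6}, n_pairs_per_case=3, case_sd=0.5, resid_sd=1.0,
            plaque_effect=0.8, seed=7,
        )
        fit = fit_lmem(
            df, ModelSpec(outcome="value", fixed="plaque_status",
                          random="case_roi")
        )
        (c,) = posthoc_contrasts(fit, "plaque_within_group")
        assert c.p_adjusted == pytest.approx(c.p_unadjusted, rel=1e-4)

    def test_df_method_recorded(self, interaction_fit):
        for c in posthoc_contrasts(interaction_fit, "group_pairs"):
            assert c.df_method == "between_within"
            assert c.transformation == "identity"

    def test_missing_term_errors(self):
        df = simulate_measurement_table({"A": 4, "B": 4}, seed=8,
                                        paired=False)
        fit = fit_lmem(df, ModelSpec(outcome="value", fixed="group"))
        with pytest.raises(ValueError, match="plaque"):
            posthoc_contrasts(fit, "plaque_within_group")


class TestFixedEffectTest:
    def test_term_absent_errors(self):
        df = simulate_measurement_table({"A": 4, "B": 4}, seed=9,
                                        paired=False)
        fit = fit_lmem(df, ModelSpec(outcome="value", fixed="group"))
        with pytest.raises(ValueError, match="not in the model"):
            fixed_effect_test(fit, "plaque_status")

    def test_strong_effect_detected(self):
        df = simulate_measurement_table(
            {"A": 8, "B": 8}, n_pairs_per_case=3, case_sd=0.5, resid_sd=0.5,
            group_effects={"B": 3.0}, seed=10, paired=False,
        )
        fit = fit_lmem(df, ModelSpec(outcome="value", fixed="group"))
        assert fixed_effect_test(fit, "group")["p"] < 1e-4


class TestSelectTransformation:
    def test_gaussian_prefers_identity(self):
        chosen = []
        for seed in range(5):
            df = simulate_measurement_table(
                {"A": 6, "B": 6}, n_pairs_per_case=3, case_sd=0.5,
                resid_sd=1.0, seed=200 + seed, paired=False,
            )
            fit, trail = select_transformation(
                df, ModelSpec(outcome="value", fixed="group")
            )
            chosen.append(fit.spec.transformation.label)
            assert trail[0]["transformation"] == "identity"
        assert chosen.count("identity") >= 4

    def test_lognormal_prefers_log_like(self):
        chosen = []
        for seed in range(5):
            df = simulate_measurement_table(
                {"A": 6, "B": 6}, n_pairs_per_case=3, case_sd=0.5,
                resid_sd=1.0, seed=300 + seed, paired=False,
            )
            df["value"] = np.exp(df["value"])
            fit, _ = select_transformation(
                df, ModelSpec(outcome="value", fixed="group")
            )
            chosen.append(fit.spec.transformation)
        log_like = sum(
            1 for t in chosen
            if t.name == "log"
            or (t.name == "tukey_ladder" and abs(t.lam) <= 0.25)
        )
        assert log_like >= 3

    def test_constant_outcome_errors(self):
        df = simulate_measurement_table({"A": 3, "B": 3}, seed=11)
        df["value"] = 5.0
        with pytest.raises((ValueError, RuntimeError)):
            select_transformation(
                df, ModelSpec(outcome="value", fixed="group")
            )

    def test_trail_records_all_candidates_when_identity_fails(self):
        df = simulate_measurement_table(
            {"A": 6, "B": 6}, n_pairs_per_case=3, case_sd=0.5, resid_sd=1.0,
            seed=12, paired=False,
        )
        df["value"] = np.exp(df["value"] * 1.5)
        _, trail = select_transformation(
            df, ModelSpec(outcome="value", fixed="group")
        )
        labels = [t["transformation"] for t in trail]
        assert "log" in labels and "sqrt" in labels
        assert any(l.startswith("tukey_ladder") for l in labels)


class TestCorrelations:
    def test_perfectly_monotone_rho_one(self):
        df = pd.DataFrame(
            {
                "group": ["CDS"] * 6,
                "case_id": [f"c{i}" for i in range(6)],
                "x": np.arange(6.0),
                "y": np.arange(6.0) ** 2,
            }
        )
        (res,) = case_level_correlations(df, [("x", "y")])
        assert res.rho == pytest.approx(1.0)

    def test_fewer_than_three_cases_skipped(self):
        df = pd.DataFrame(
            {
                "group": ["Aged"] * 2,
                "case_id": ["a", "b"],
                "x": [1.0, 2.0],
                "y": [2.0, 1.0],
            }
        )
        (res,) = case_level_correlations(df, [("x", "y")])
        assert res.rho is None
        assert "skipped" in res.note

    def test_averaging_is_per_case(self):
        # two stacks per case; correlation must use case means, not stacks
        df = pd.DataFrame(
            {
                "group": ["CDS"] * 8,
                "case_id": ["c1"] * 2 + ["c2"] * 2 + ["c3"] * 2 + ["c4"] * 2,
                "x": [1, 3, 2, 6, 3, 9, 4, 12],
                "y": [2.0, 4, 3, 7, 4, 10, 5, 13],
            }
        )
        (res,) = case_level_correlations(df, [("x", "y")])
        assert res.n_cases == 4
        assert res.rho == pytest.approx(1.0)

    def test_designed_recovery_cds_only(self):
        rng = np.random.default_rng(13)
        rows = []
        for g, coupled in (("Aged", False), ("CDS", True)):
            for i in range(8):
                ab = rng.uniform(1, 5)
                ingestion = 0.5 * ab + rng.normal(0, 0.1) if coupled else \
                    rng.uniform(0, 3)
                rows.append({"group": g, "case_id": f"{g}{i}", "x": ab,
                             "y": ingestion})
        df = pd.DataFrame(rows)
        results = {r.group: r for r in case_level_correlations(df,
                                                               [("x", "y")])}
        assert results["CDS"].p < 0.05
        assert results["CDS"].rho > 0.8
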