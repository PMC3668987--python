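import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from capri import (
    EstimationError,
    Profile,
    ResponseSet,
    ValidationError,
    attribute_importance,
    build_coding_matrix,
    consistency_check,
    fit_individual,
    fit_pooled,
    holdout_validation,
    population_from_table6,
    predict_rating,
    simulate_ratings,
)
from capri.design import DesignPlan
from capri.estimate import UtilityModel


def table6_model(pnd_attrs):
    spec = population_from_table6()
    return UtilityModel(pnd_attrs, spec.constant, dict(spec.mean_partworths))


class TestCodingMatrix:
    def test_two_level_attribute_gives_plus_minus_one(self, pnd_attrs):
        from capri import Attribute, AttributeSet
        from capri.coding import profiles_to_matrix

        attrs = AttributeSet((Attribute("x", "X", ("a", "b")),))
        cm = profiles_to_matrix([Profile({"x": 1}), Profile({"x": 2})], attrs)
        assert cm.matrix[:, 1].tolist() == [1.0, -1.0]

    def test_pnd_plan_has_thirteen_columns(self, pnd_plan):
        cm = build_coding_matrix(pnd_plan)
        assert cm.n_parameters == 13
        non_ref = [m for m in cm.column_map if m is not None]
        # every non-reference level appears exactly once
        assert len(non_ref) == len(set(non_ref)) == 12
        for a in pnd_plan.attrs:
            cols = [m for m in non_ref if m[0] == a.name]
            assert [lvl for _, lvl in cols] == list(range(1, a.n_levels))


class TestPooledFit:
    def test_exact_recovery_from_noiseless_simulation(self, pnd_plan, noiseless_responses):
        m = fit_pooled(noiseless_responses, pnd_plan)
        spec = population_from_table6()
        assert m.constant == pytest.approx(spec.constant, abs=1e-8)
        for name, vals in spec.mean_partworths.items():
            for i, v in enumerate(vals):
                assert m.partworths[name][i] == pytest.approx(v, abs=1e-8)

    def test_constant_response_gives_zero_partworths(self, pnd_plan):
        ids = pnd_plan.estimation_runs()[1]
        df = pd.DataFrame(
            [("R1", rid, 5) for rid in ids], columns=["respondent_id", "run_id", "rating"]
        )
        m = fit_pooled(ResponseSet(df), pnd_plan)
        assert m.constant == pytest.approx(5.0)
        for vals in m.partworths.values():
            assert np.allclose(vals, 0.0, atol=1e-10)

    def test_duplicating_respondents_leaves_estimates_unchanged(
        self, pnd_plan, table6_population
    ):
        rs = simulate_ratings(table6_population.replace(n_respondents=20), pnd_plan)
        dup = rs.data.copy()
        dup["respondent_id"] = dup["respondent_id"] + "_copy"
        doubled = ResponseSet(pd.concat([rs.data, dup], ignore_index=True))
        m1, m2 = fit_pooled(rs, pnd_plan), fit_pooled(doubled, pnd_plan)
        assert m1.constant == pytest.approx(m2.constant, abs=1e-10)
        for name in m1.partworths:
            assert np.allclose(m1.partworths[name], m2.partworths[name], atol=1e-10)

    def test_zero_sum_within_every_attribute(self, pnd_plan, table6_population):
        rs = simulate_ratings(table6_population.replace(n_respondents=15, seed=3), pnd_plan)
        m = fit_pooled(rs, pnd_plan)
        for vals in m.partworths.values():
            assert abs(sum(vals)) < 1e-9

    def test_matches_statsmodels_sum_coding_oracle(self, pnd_plan, table6_population):
        """Independent route: statsmodels formula API with Sum contrasts on
        level labels must give the same constant, part-worths and SEs."""
        rs = simulate_ratings(table6_population.replace(n_respondents=25, seed=5), pnd_plan)
        m = fit_pooled(rs, pnd_plan)
        est_ids = set(pnd_plan.estimation_runs()[1])
        rows = []
        for _, r in rs.data[rs.data["run_id"].isin(est_ids)].iterrows():
            p = pnd_plan.run(r["run_id"])
            row = {f"x_{name}": lvl for name, lvl in p.levels.items()}
            row["rating"] = r["rating"]
            rows.append(row)
        df = pd.DataFrame(rows)
        terms = " + ".join(f"C(x_{a.name}, Sum)" for a in pnd_plan.attrs)
        res = smf.ols(f"rating ~ {terms}", data=df).fit()
        assert m.constant == pytest.approx(res.params["Intercept"], abs=1e-8)
        assert m.constant_se == pytest.approx(res.bse["Intercept"], abs=1e-8)
        for a in pnd_plan.attrs:
            for j in range(1, a.n_levels):
                key = f"C(x_{a.name}, Sum)[S.{j}]"
                assert m.partworths[a.name][j - 1] == pytest.approx(
                    res.params[key], abs=1e-8
                )
                assert m.std_errors[a.name][j - 1] == pytest.approx(res.bse[key], abs=1e-8)

    def test_unknown_run_and_missing_coverage_rejected(self, pnd_plan):
        df = pd.DataFrame(
            [("R1", "E01", 4), ("R1", "ZZ", 4)],
            columns=["respondent_id", "run_id", "rating"],
        )
        with pytest.raises(ValidationError):
            fit_pooled(ResponseSet(df), pnd_plan)
        partial = pd.DataFrame(
            [("R1", "E01", 4)], columns=["respondent_id", "run_id", "rating"]
        )
        with pytest.raises(EstimationError):
            fit_pooled(ResponseSet(partial), pnd_plan)


class TestIndividualFit:
    def test_average_of_individual_fits_equals_pooled(self, pnd_plan, table6_population):
        rs = simulate_ratings(table6_population.replace(n_respondents=12, seed=9), pnd_plan)
        pooled = fit_pooled(rs, pnd_plan)
        models, averaged = fit_individual(rs, pnd_plan)
        assert len(models) == 12
        assert averaged.constant == pytest.approx(pooled.constant, abs=1e-10)
        for name in pooled.partworths:
            assert np.allclose(
                averaged.partworths[name], pooled.partworths[name], atol=1e-10
            )

    def test_single_respondent_average_is_that_respondent(self, pnd_plan, table6_population):
        rs = simulate_ratings(table6_population.replace(n_respondents=1), pnd_plan)
        models, averaged = fit_individual(rs, pnd_plan)
        assert len(models) == 1
        assert averaged.partworths == models[0][1].partworths

    def test_incomplete_respondent_excluded_with_warning(
        self, pnd_plan, table6_population, caplog
    ):
        rs = simulate_ratings(table6_population.replace(n_respondents=3), pnd_plan)
        drop = rs.data[
            ~((rs.data["respondent_id"] == "R0001") & (rs.data["run_id"] == "E05"))
        ]
        with caplog.at_level("WARNING"):
            models, _ = fit_individual(ResponseSet(drop), pnd_plan)
        assert len(models) == 2
        assert any("R0001" in rec.message for rec in caplog.records)


class TestImportance:
    def test_expertise_has_smallest_range(self, pnd_attrs):
        imp = attribute_importance(table6_model(pnd_attrs)).rows
        row = imp[imp["attribute"] == "expertise"].iloc[0]
        assert row["range"] == pytest.approx(0.036)
        assert row["rank"] == len(imp)
        assert imp["importance"].sum() == pytest.approx(1.0)
        assert sorted(imp["rank"]) == list(range(1, len(imp) + 1))

    def test_single_active_attribute_takes_full_importance(self, pnd_attrs):
        pw = {a.name: (0.0,) * a.n_levels for a in pnd_attrs}
        pw["cost"] = (0.5, 0.0, -0.5)
        imp = attribute_importance(UtilityModel(pnd_attrs, 0.0, pw)).rows
        row = imp[imp["attribute"] == "cost"].iloc[0]
        assert row["importance"] == pytest.approx(1.0)
        assert row["rank"] == 1


class TestPrediction:
    def test_zero_model_predicts_midpoint(self, pnd_attrs, innovation_a):
        pw = {a.name: (0.0,) * a.n_levels for a in pnd_attrs}
        m = UtilityModel(pnd_attrs, 0.0, pw)
        assert predict_rating(m, innovation_a, scale_midpoint=4.0) == pytest.approx(4.0)

    def test_worked_example_rounds_to_094(self, pnd_attrs, innovation_a):
        m = table6_model(pnd_attrs)
        assert round(predict_rating(m, innovation_a, scale_midpoint=0.0), 2) == 0.94

    def test_one_level_change_shifts_by_partworth_difference(self, pnd_attrs, innovation_a):
        m = table6_model(pnd_attrs)
        moved = Profile({**innovation_a.levels, "evidence": 1})
        diff = predict_rating(m, innovation_a) - predict_rating(m, moved)
        assert diff == pytest.approx(0.405 - (-0.243))


class TestHoldout:
    def test_noiseless_prediction_is_perfect(self, pnd_plan, noiseless_responses):
        m = fit_pooled(noiseless_responses, pnd_plan)
        rep = holdout_validation(m, noiseless_responses, pnd_plan)
        assert rep.pearson_r == pytest.approx(1.0, abs=1e-12)
        assert rep.r_squared == pytest.approx(rep.pearson_r**2, abs=1e-12)
        assert len(rep.table) == 5

    def test_noisy_survey_scale_validation_is_strong(self, pnd_plan, table6_population):
        rs = simulate_ratings(table6_population, pnd_plan)  # N=139, noise 0.5
        m = fit_pooled(rs, pnd_plan)
        rep = holdout_validation(m, rs, pnd_plan, scale_midpoint=0.0)
        assert rep.r_squared > 0.5

    def test_too_few_holdouts_rejected(self, pnd_attrs, noiseless_responses):
        from capri import generate_plan

        plan = generate_plan(pnd_attrs, "auto", 0)  # no consistency runs
        est_only = noiseless_responses.for_runs(plan.run_ids)
        m = fit_pooled(est_only, plan)
        with pytest.raises(ValidationError):
            holdout_validation(m, est_only, plan)

    def test_constant_predictions_rejected(self, pnd_plan, pnd_attrs, noiseless_responses):
        pw = {a.name: (0.0,) * a.n_levels for a in pnd_attrs}
        flat = UtilityModel(pnd_attrs, 4.0, pw)
        with pytest.raises(EstimationError):
            holdout_validation(flat, noiseless_responses, pnd_plan)


class TestConsistency:
    def test_rational_population_passes_all_pairs(self, pnd_attrs):
        """With orderable attributes restricted to the monotone ones, every
        dominance pair must pass under the published utilities."""
        from capri import add_validation_scenarios, generate_plan

        orderings = {"cost": (3, 2, 1), "evidence": (1, 2, 3, 4), "needs": (1, 2)}
        plan = add_validation_scenarios(
            generate_plan(pnd_attrs, "auto", 0), 5, seed=0, orderings=orderings
        )
        m = table6_model(pnd_attrs)
        report = consistency_check(plan, model=m)
        assert len(report) == 5
        assert report["passed"].all()

    def test_inverted_preferences_fail(self, pnd_attrs):
        from capri import add_validation_scenarios, generate_plan

        orderings = {"cost": (3, 2, 1), "evidence": (1, 2, 3, 4), "needs": (1, 2)}
        plan = add_validation_scenarios(
            generate_plan(pnd_attrs, "auto", 0), 5, seed=0, orderings=orderings
        )
        spec = population_from_table6()
        negated = {k: tuple(-x for x in v) for k, v in spec.mean_partworths.items()}
        m = UtilityModel(pnd_attrs, spec.constant, negated)
        report = consistency_check(plan, model=m)
        assert not report["passed"].any()

    def test_requires_exactly_one_source(self, pnd_plan, noiseless_responses, pnd_attrs):
        with pytest.raises(ValidationError):
            consistency_check(pnd_plan)
        with pytest.raises(ValidationError):
            consistency_check(
                pnd_plan, rs=noiseless_responses, model=table6_model(pnd_attrs)
            )


class TestOracleEquivalence:
    def test_fractional_equals_full_factorial_on_noiseless_data(self, pnd_attrs, pnd_plan):
        """Both designs recover the generating utilities exactly, so the
        16-run fractional fit equals the 864-run full-factorial fit."""
        import itertools

        combos = itertools.product(*[range(1, a.n_levels + 1) for a in pnd_attrs])
        profiles = [
            Profile(dict(zip(pnd_attrs.names, c))) for c in combos
        ]
        full = DesignPlan(
            pnd_attrs,
            profiles,
            ["estimation"] * len(profiles),
            [f"F{i:03d}" for i in range(len(profiles))],
            0,
            "full factorial",
        )
        spec = population_from_table6(
            heterogeneity_sd=0.0,
            noise_sd=0.0,
            continuous_output=True,
            scale_midpoint=0.0,
            n_respondents=1,
        )
        m_frac = fit_pooled(simulate_ratings(spec, pnd_plan), pnd_plan)
        m_full = fit_pooled(simulate_ratings(spec, full), full)
        assert m_frac.constant == pytest.approx(m_full.constant, abs=1e-8)
        for name in m_frac.partworths:
            assert np.allclose(
                m_frac.partworths[name], m_full.partworths[name], atol=1e-8
            )
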