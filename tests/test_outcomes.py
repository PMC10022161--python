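"""Discounting, YLD/YLL accrual and cost accrual over traces."""

import dataclasses

import numpy as np
import pytest

from herniacea import (
    LifeTable,
    ModelParameters,
    PainDistribution,
    PainLevel,
    ValidationError,
    accrue_costs,
    accrue_yld,
    accrue_yll,
    closed_form_daly_per_person,
    discount_factor,
    run_cohort,
    summarize,
)

from conftest import flat_life_table

ALL_NONE = PainDistribution({"none": 1.0, "mild": 0.0, "moderate": 0.0, "severe": 0.0})


class TestDiscountFactor:
    @pytest.mark.parametrize(
        "cycle,rate,half,expected",
        [
            (0, 0.03, False, 1.0),
            (0, 0.03, True, 1.0),  # cycle 0 is never shifted
            (1, 0.03, False, 0.970874),
            (1, 0.03, True, 0.985329),
            (5, 0.0, True, 1.0),
        ],
    )
    def test_values(self, cycle, rate, half, expected):
        assert discount_factor(cycle, rate, half) == pytest.approx(expected, abs=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            discount_factor(1, -0.01, False)
        with pytest.raises(ValidationError):
            discount_factor(-1, 0.03, False)


def _one_state_params(pain: str, **overrides) -> ModelParameters:
    """Everyone untreated at one pain severity, no deaths, no discounting."""
    dist = {lv: 0.0 for lv in ("none", "mild", "moderate", "severe")}
    dist[pain] = 1.0
    defaults = dict(
        cohort_size=100.0,
        time_horizon=1,
        complication_risk=0.0,
        discount_rate=0.0,
        half_cycle_correction=False,
        pain_untreated=PainDistribution(dist),
        pain_recurrent=PainDistribution(dist),
    )
    defaults.update(overrides)
    return ModelParameters(**defaults)


class TestYLD:
    def test_pain_free_cohort_accrues_nothing(self):
        p = _one_state_params("none")
        trace = run_cohort(p, flat_life_table(q=0.0), False)
        assert accrue_yld(trace, p).sum() == 0.0

    def test_severe_pain_person_years(self):
        # 100 persons x 1 year x DW 0.324 = 32.4 YLD
        p = _one_state_params("severe")
        trace = run_cohort(p, flat_life_table(q=0.0), False)
        assert accrue_yld(trace, p).sum() == pytest.approx(32.4, abs=1e-9)

    def test_linearity_in_disability_weights(self, life_table):
        p = ModelParameters()
        doubled = dataclasses.replace(
            p,
            dw_map=tuple(
                PainLevel(lv.label, lv.ipq_scores, 2 * lv.disability_weight)
                for lv in p.dw_map
            ),
        )
        trace = run_cohort(p, life_table, False)
        assert accrue_yld(trace, doubled).sum() == pytest.approx(
            2 * accrue_yld(trace, p).sum(), rel=1e-12
        )

    def test_invariant_to_relabeling_equal_weights(self, life_table):
        # swapping mass between levels with identical DW leaves YLD unchanged
        w = {"none": 0.0, "mild": 0.1, "moderate": 0.1, "severe": 0.324}
        dw_map = tuple(
            PainLevel(lv.label, lv.ipq_scores, w[lv.label])
            for lv in ModelParameters().dw_map
        )
        a = ModelParameters(
            dw_map=dw_map,
            pain_untreated=PainDistribution(
                {"none": 0.2, "mild": 0.5, "moderate": 0.1, "severe": 0.2}
            ),
        )
        b = dataclasses.replace(
            a,
            pain_untreated=PainDistribution(
                {"none": 0.2, "mild": 0.1, "moderate": 0.5, "severe": 0.2}
            ),
        )
        ta = run_cohort(a, life_table, False)
        tb = run_cohort(b, life_table, False)
        assert accrue_yld(ta, a).sum() == pytest.approx(
            accrue_yld(tb, b).sum(), rel=1e-12
        )

    def test_half_cycle_averages_boundary_occupancy(self):
        # full pain-relieving repair with q = 0: cycle-1 person-time is the
        # average of the all-severe start and the all-pain-free end
        p = _one_state_params(
            "severe",
            time_horizon=2,
            repair_rate=1.0,
            risk_recurrent=0.0,
            risk_contralateral=0.0,
            half_cycle_correction=True,
            pain_repaired=ALL_NONE,
        )
        trace = run_cohort(p, flat_life_table(q=0.0), True, "md")
        yld = accrue_yld(trace, p)
        assert yld[1] == pytest.approx(0.5 * 100 * 0.324, abs=1e-9)
        assert yld[2] == pytest.approx(0.0, abs=1e-9)


class TestYLL:
    def test_zero_premature_risk_means_zero_yll(self, life_table):
        p = ModelParameters(complication_risk=0.0)
        trace = run_cohort(p, life_table, False)
        assert accrue_yll(trace, life_table).sum() == 0.0

    def test_one_attributable_death_counts_remaining_life_expectancy(self):
        # deterministic attributable death in cycle 1: risk 1, q 0
        p = ModelParameters(
            cohort_size=1.0,
            time_horizon=1,
            complication_risk=1.0,
            complication_mortality=1.0,
            discount_rate=0.0,
        )
        lt = flat_life_table(q=0.0, ex=20.0)
        trace = run_cohort(p, lt, False)
        assert trace.attributable_deaths[1] == pytest.approx(1.0)
        yll = accrue_yll(trace, lt, discount_rate=0.0)
        assert yll.sum() == pytest.approx(20.0, abs=1e-9)

    def test_background_deaths_carry_no_yll(self):
        p = ModelParameters(cohort_size=100.0, time_horizon=5, complication_risk=0.0)
        lt = flat_life_table(q=0.3, ex=10.0)
        trace = run_cohort(p, lt, False)
        assert trace.background_deaths.sum() > 50.0
        assert accrue_yll(trace, lt).sum() == 0.0

    def test_untreated_toy_yll_matches_survivor_sum(self, toy_params, toy_life_table):
        # closed-form for the untreated arm: survivors at cycle start t,
        # s_t = ((1-q)(1-r))^t, die attributably w.p. (1-q) r during t -> t+1
        q, r = 0.1, 0.05
        ex = 10.0
        trace = run_cohort(toy_params, toy_life_table, False)
        expected = sum(
            ((1 - q) * (1 - r)) ** t * (1 - q) * r * ex for t in range(3)
        )
        got = accrue_yll(trace, toy_life_table, discount_rate=0.0).sum()
        assert got == pytest.approx(expected, abs=1e-12)


class TestCosts:
    def test_untreated_arm_costs_nothing(self, base_params, life_table):
        trace = run_cohort(base_params, life_table, False)
        assert accrue_costs(trace, base_params, "md").sum() == 0.0

    @pytest.mark.parametrize(
        "provider,expected", [("md", 123_400.0), ("surgeon", 132_710.0)]
    )
    def test_thousand_repairs_at_published_unit_cost(self, provider, expected):
        p = ModelParameters(
            cohort_size=1000.0,
            time_horizon=1,
            repair_rate=1.0,
            complication_risk=0.0,
            risk_recurrent=0.0,
            risk_contralateral=0.0,
            discount_rate=0.0,
        )
        trace = run_cohort(p, flat_life_table(q=0.0), True, provider)
        assert trace.repairs[0] == pytest.approx(1000.0)
        assert accrue_costs(trace, p, provider).sum() == pytest.approx(
            expected, abs=1e-6
        )

    def test_provider_required_on_treated_arm(self, base_params, life_table):
        trace = run_cohort(base_params, life_table, True, "md")
        with pytest.raises(ValidationError):
            accrue_costs(trace, base_params, "none")


class TestSummarize:
    def test_daly_is_yld_plus_yll(self, base_params, life_table):
        for treated, provider in ((False, "none"), (True, "md")):
            trace = run_cohort(base_params, life_table, treated, provider)
            s = summarize(trace, base_params, life_table)
            assert s.total_daly == pytest.approx(
                s.total_yld + s.total_yll, abs=1e-9
            )
            assert s.total_cost >= 0 and s.total_yld >= 0 and s.total_yll >= 0

    def test_discounting_shrinks_totals(self, life_table):
        p = ModelParameters()
        p0 = dataclasses.replace(p, discount_rate=0.0)
        t = run_cohort(p, life_table, True, "md")
        s = summarize(t, p, life_table)
        s0 = summarize(run_cohort(p0, life_table, True, "md"), p0, life_table)
        assert s.total_cost < s0.total_cost
        assert s.total_daly < s0.total_daly
        # raw columns in the per-cycle frame dominate the discounted ones
        assert (s.series["daly"] >= s.series["daly_disc"] - 1e-12).all()

    def test_no_burden_when_dws_and_premature_risk_vanish(self, life_table):
        zero_dw = tuple(
            PainLevel(lv.label, lv.ipq_scores, 0.0) for lv in ModelParameters().dw_map
        )
        p = ModelParameters(complication_risk=0.0, dw_map=zero_dw)
        for treated, provider in ((False, "none"), (True, "md")):
            trace = run_cohort(p, life_table, treated, provider)
            s = summarize(trace, p, life_table)
            assert s.total_daly == 0.0

    def test_no_age_or_time_weighting(self):
        # a person-year of severe pain scores the same DW at any age and cycle
        lt = flat_life_table(q=0.0, lo=30, hi=80)
        early = _one_state_params("severe", starting_age=35)
        late = _one_state_params("severe", starting_age=70)
        y_early = accrue_yld(run_cohort(early, lt, False), early)
        y_late = accrue_yld(run_cohort(late, lt, False), late)
        assert y_early.sum() == pytest.approx(y_late.sum(), rel=1e-12)


class TestClosedForm:
    def test_single_shot_formula(self):
        lt = flat_life_table(q=0.0, ex=25.0)
        p = _one_state_params("severe")
        out = closed_form_daly_per_person(p, lt)
        assert out["yld"] == pytest.approx(0.324 * 25.0)
        assert out["yll"] == pytest.approx(0.0)
        assert out["daly"] == out["yld"] + out["yll"]

    def test_overstates_cycle_accrual_within_horizon(self, base_params, life_table):
        # full-life-expectancy burden exceeds the 10-year discounted accrual
        out = closed_form_daly_per_person(base_params, life_table)
        trace = run_cohort(base_params, life_table, False)
        s = summarize(trace, base_params, life_table)
        assert out["daly"] > s.total_daly / base_params.cohort_size
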