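"""Cohort propagation: stochasticity, conservation, and an exhaustive
path-enumeration oracle on a small two-pain-level model."""

import dataclasses
from collections import defaultdict

import numpy as np
import pytest
from hypothesis import given, strategies as st

from herniacea import (
    ModelParameters,
    PainDistribution,
    ValidationError,
    run_cohort,
    transition_probabilities,
)
from herniacea.markov import compartments

from conftest import flat_life_table


def make_pain(none, mild, moderate, severe):
    return PainDistribution(
        {"none": none, "mild": mild, "moderate": moderate, "severe": severe}
    )


class TestTransitionProbabilities:
    def test_rows_sum_to_one(self, base_params, life_table):
        for treated in (False, True):
            P = transition_probabilities(base_params, life_table, 55, treated)
            for src, row in P.items():
                assert sum(row.values()) == pytest.approx(1.0, abs=1e-12), src

    def test_untreated_arm_never_repairs(self, base_params, life_table):
        P = transition_probabilities(base_params, life_table, 50, treated_arm=False)
        for src, row in P.items():
            if src.startswith("repaired"):
                continue
            assert not any(dst.startswith("repaired") for dst in row), (src, row)

    def test_full_repair_rate_moves_all_survivors(self, base_params, life_table):
        P = transition_probabilities(base_params, life_table, 50, treated_arm=True)
        row = P["new_hernia:severe"]
        to_repaired = sum(v for k, v in row.items() if k.startswith("repaired"))
        assert to_repaired == pytest.approx(1.0 - row["death"], abs=1e-12)

    def test_age_outside_life_table(self, base_params, life_table):
        with pytest.raises(ValidationError):
            transition_probabilities(base_params, life_table, 300, True)

    @given(
        q=st.floats(0.0, 0.5),
        rho=st.floats(0.0, 1.0),
        rr=st.floats(0.0, 0.4),
        c=st.floats(0.0, 0.4),
    )
    def test_rows_stochastic_for_random_inputs(self, q, rho, rr, c):
        params = ModelParameters(
            repair_rate=rho, risk_recurrent=rr, risk_contralateral=c
        )
        lt = flat_life_table(q=q)
        P = transition_probabilities(params, lt, 50, treated_arm=True)
        for src, row in P.items():
            assert sum(row.values()) == pytest.approx(1.0, abs=1e-9), src


class TestRunCohort:
    def test_horizon_zero_is_initial_state_only(self, life_table):
        p = dataclasses.replace(ModelParameters(), time_horizon=0)
        trace = run_cohort(p, life_table, treated_arm=False)
        assert trace.occupancy.shape[0] == 1
        assert trace.occupancy[0].sum() == pytest.approx(p.cohort_size)

    def test_all_start_in_new_hernia(self, base_params, life_table):
        trace = run_cohort(base_params, life_table, treated_arm=False)
        labels = compartments()
        start = dict(zip(labels, trace.occupancy[0]))
        new_total = sum(v for k, v in start.items() if k.startswith("new_hernia"))
        assert new_total == pytest.approx(base_params.cohort_size)
        assert start["death"] == 0.0

    def test_no_flows_without_repair_or_death(self):
        p = ModelParameters(
            complication_risk=0.0, time_horizon=5, cohort_size=100.0
        )
        lt = flat_life_table(q=0.0)
        trace = run_cohort(p, lt, treated_arm=False)
        np.testing.assert_allclose(trace.occupancy[0], trace.occupancy[-1], atol=1e-12)

    def test_full_repair_no_losses_lands_everyone_in_repaired(self):
        # hand-computed chain: with q = 0, no premature risk and no
        # recurrence/contralateral return, cycle 1..T occupancy is the whole
        # cohort in 'repaired', split per the post-operative pain distribution
        p = ModelParameters(
            complication_risk=0.0,
            risk_recurrent=0.0,
            risk_contralateral=0.0,
            repair_rate=1.0,
            time_horizon=3,
            cohort_size=10.0,
        )
        lt = flat_life_table(q=0.0)
        trace = run_cohort(p, lt, treated_arm=True, provider="md")
        labels = compartments()
        rep = [i for i, l in enumerate(labels) if l.startswith("repaired")]
        for t in (1, 2, 3):
            assert trace.occupancy[t, rep].sum() == pytest.approx(10.0, abs=1e-12)
            expected = 10.0 * p.pain_repaired.as_array()
            np.testing.assert_allclose(trace.occupancy[t, rep], expected, atol=1e-12)
        assert trace.repairs[0] == pytest.approx(10.0)
        assert trace.repairs[1:].sum() == pytest.approx(0.0)

    def test_mass_conservation_every_cycle(self, base_params, life_table):
        for treated, provider in ((False, "none"), (True, "md")):
            trace = run_cohort(base_params, life_table, treated, provider)
            totals = trace.occupancy.sum(axis=1)
            np.testing.assert_allclose(
                totals, base_params.cohort_size, rtol=0, atol=1e-6
            )

    def test_death_absorbing_and_strictly_increasing(self, base_params, life_table):
        trace = run_cohort(base_params, life_table, treated_arm=True, provider="md")
        deaths = trace.death()
        assert np.all(np.diff(deaths) > 0)  # q > 0 at every model age

    def test_death_split_reconciles_with_occupancy(self, base_params, life_table):
        trace = run_cohort(base_params, life_table, treated_arm=False)
        inflow = np.diff(trace.death())
        split = (trace.attributable_deaths + trace.background_deaths)[1:]
        np.testing.assert_allclose(inflow, split, atol=1e-9)

    def test_untreated_arm_has_more_attributable_deaths(self, base_params, life_table):
        untreated = run_cohort(base_params, life_table, False)
        treated = run_cohort(base_params, life_table, True, "md")
        assert (
            untreated.attributable_deaths.sum()
            >= treated.attributable_deaths.sum() + 1.0
        )

    def test_provider_arm_consistency_enforced(self, base_params, life_table):
        with pytest.raises(ValidationError):
            run_cohort(base_params, life_table, treated_arm=True, provider="none")
        with pytest.raises(ValidationError):
            run_cohort(base_params, life_table, treated_arm=False, provider="md")

    def test_horizon_beyond_life_table_rejected(self, base_params):
        lt = flat_life_table(lo=45, hi=55)
        with pytest.raises(ValidationError):
            run_cohort(
                dataclasses.replace(base_params, time_horizon=10), lt, False
            )

    def test_trace_export_is_tidy(self, base_params, life_table):
        trace = run_cohort(base_params, life_table, False)
        frame = trace.to_frame()
        assert list(frame.columns) == ["cycle", "age", "compartment", "occupancy"]
        assert len(frame) == (base_params.time_horizon + 1) * len(compartments())


# ---------------------------------------------------------------------------
# Exhaustive path-enumeration oracle.  The transition rules below are written
# out by hand from the model description and share no code with the engine.

Q = 0.1  # background annual death probability in the toy model
R_PD = 0.05  # hernia-attributable premature-death risk
RHO = 0.6  # repair rate
RR = 0.2  # recurrence risk
RC = 0.1  # contralateral risk
PAIN_U = {"none": 0.5, "severe": 0.5}
PAIN_R = {"none": 0.8, "mild": 0.2}
PAIN_REC = {"none": 0.3, "severe": 0.7}


def _oracle_branches(comp, treated):
    """Hand-coded outgoing branches: (successor, probability, event)."""
    if comp == "death":
        return [("death", 1.0, None)]
    state, pain = comp.split(":")
    branches = []
    if state in ("new_hernia", "recurrent"):
        branches.append(("death", Q, "bg_death"))
        branches.append(("death", (1 - Q) * R_PD, "attr_death"))
        survive = (1 - Q) * (1 - R_PD)
        rho = RHO if treated else 0.0
        for p2, w in PAIN_R.items():
            branches.append((f"repaired:{p2}", survive * rho * w, "repair"))
        branches.append((comp, survive * (1 - rho), None))
    else:  # repaired
        branches.append(("death", Q, "bg_death"))
        survive = 1 - Q
        for p2, w in PAIN_U.items():
            branches.append((f"new_hernia:{p2}", survive * RC * w, None))
        for p2, w in PAIN_REC.items():
            branches.append((f"recurrent:{p2}", survive * RR * w, None))
        branches.append((comp, survive * (1 - RC - RR), None))
    return branches


def enumerate_paths(treated, n_cycles=3):
    """Walk every individual path through the toy model, weighted by probability."""
    occupancy = [defaultdict(float) for _ in range(n_cycles + 1)]
    attr_deaths = defaultdict(float)
    repairs = defaultdict(float)

    def walk(comp, cycle, prob):
        occupancy[cycle][comp] += prob
        if cycle == n_cycles:
            return
        for nxt, p, event in _oracle_branches(comp, treated):
            if p == 0.0:
                continue
            if event == "attr_death":
                attr_deaths[cycle + 1] += prob * p
            if event == "repair":
                repairs[cycle] += prob * p
            walk(nxt, cycle + 1, prob * p)

    for pain, w in PAIN_U.items():
        walk(f"new_hernia:{pain}", 0, w)
    return occupancy, attr_deaths, repairs


@pytest.mark.parametrize("treated,provider", [(False, "none"), (True, "md")])
def test_engine_matches_path_enumeration(toy_params, toy_life_table, treated, provider):
    trace = run_cohort(toy_params, toy_life_table, treated, provider)
    occupancy, attr_deaths, repairs = enumerate_paths(treated)
    labels = compartments()
    for t in range(4):
        got = dict(zip(labels, trace.occupancy[t]))
        for comp in labels:
            assert got[comp] == pytest.approx(occupancy[t][comp], abs=1e-9), (t, comp)
    for t in range(1, 4):
        assert trace.attributable_deaths[t] == pytest.approx(
            attr_deaths[t], abs=1e-9
        )
    for t in range(3):
        assert trace.repairs[t] == pytest.approx(repairs[t], abs=1e-9)
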