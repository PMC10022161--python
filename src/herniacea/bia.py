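"""Ten-year budget-impact simulation of national repair-service expansion.

Simulates 2020-2030 year by year: the untreated-hernia backlog grows by
incident cases and shrinks by repairs performed; repairs each year are the
largest volume that is simultaneously within workforce capacity, within the
annual budget cap (if any), and no larger than the backlog.  Expanding
capacity means training additional providers (at a per-trainee cost, only
during the initial ramp years and up to an annual intake cap) and
renovating facilities (one start-up cost per newly activated facility,
providers allocated to facilities in fixed-size blocks).  Health gains are
repairs x the per-patient incremental DALYs averted taken from the cohort
cost-effectiveness model, keeping the two halves of the analysis on one set
of assumptions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cea import run_cea
from .parameters import LifeTable, ModelParameters, ValidationError

__all__ = [
    "BIAScenario",
    "BIATrajectory",
    "run_bia",
    "bia_dsa",
    "elimination_schedule",
    "scenario_budget_cap",
    "scenario_elimination",
    "daly_averted_per_repair",
]


@dataclass(frozen=True)
class BIAScenario:
    """Constraints and unit costs of one service-expansion scenario."""

    label: str
    unit_cost: float  # USD per repair (provider-cadre procedure cost)
    start_year: int = 2020
    end_year: int = 2030
    initial_backlog: float = 1_000_000.0
    annual_incidence: float = 40_000.0
    starting_repair_rate: float = 0.0157  # fraction of prevalent cases repaired/year
    budget_cap: float | None = None  # USD per year; None = uncapped
    provider_productivity: float = 50.0  # repairs per provider per year
    providers_per_facility: int = 2
    training_cost: float = 2_000.0  # USD per trainee
    renovation_cost: float = 18_000.0  # USD per newly activated facility
    training_ramp: int = 5  # years during which new providers may be added
    annual_trainee_cap: int = 250  # max trainees per ramp year
    target_repairs: tuple[float, ...] | None = None  # optional per-year schedule

    def __post_init__(self) -> None:
        if self.end_year <= self.start_year:
            raise ValidationError("BIAScenario: end_year must exceed start_year")
        for name in (
            "unit_cost",
            "initial_backlog",
            "annual_incidence",
            "starting_repair_rate",
            "provider_productivity",
            "providers_per_facility",
            "training_cost",
            "renovation_cost",
            "training_ramp",
            "annual_trainee_cap",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"BIAScenario.{name}: must be >= 0")
        if self.budget_cap is not None and self.budget_cap < 0:
            raise ValidationError("BIAScenario.budget_cap: must be >= 0 or None")
        n_years = self.end_year - self.start_year + 1
        if self.target_repairs is not None and len(self.target_repairs) != n_years:
            raise ValidationError(
                f"BIAScenario.target_repairs: need {n_years} yearly values"
            )

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1

    @property
    def baseline_repairs(self) -> float:
        """Repairs per year the existing workforce already delivers."""
        return self.starting_repair_rate * self.initial_backlog

    @property
    def baseline_providers(self) -> int:
        return math.ceil(self.baseline_repairs / self.provider_productivity)


@dataclass(frozen=True)
class BIATrajectory:
    """Yearly series of one scenario run plus scenario-level totals."""

    scenario: BIAScenario
    years: pd.DataFrame
    infeasible_years: tuple[int, ...]

    @property
    def total_repairs(self) -> float:
        return float(self.years["repairs"].sum())

    @property
    def total_cost(self) -> float:
        return float(self.years["annual_cost_usd_2020"].sum())

    @property
    def total_dalys_averted(self) -> float:
        return float(self.years["dalys_averted"].sum())

    @property
    def final_backlog(self) -> float:
        return float(self.years["backlog"].iloc[-1])

    @property
    def providers_trained(self) -> int:
        return int(self.years["providers_trained_cumulative"].iloc[-1])


def daly_averted_per_repair(
    params: ModelParameters, life_table: LifeTable, provider: str = "md"
) -> float:
    """Per-patient incremental DALYs averted from the cohort model."""
    res = run_cea(params, life_table, provider)
    return res.incremental_dalys_averted / res.cohort_size


def _year_cost(
    scenario: BIAScenario,
    repairs: float,
    current_providers: int,
    current_facilities: int,
    trainee_cap: int,
) -> tuple[float, int, int]:
    """Cost of performing ``repairs`` this year and the hires it requires.

    Returns (annual cost, new trainees, new facilities).  Monotone
    non-decreasing in ``repairs``, which the budget search relies on.
    """
    needed = math.ceil(repairs / scenario.provider_productivity)
    new_trainees = min(max(0, needed - current_providers), trainee_cap)
    new_total_extra = (current_providers + new_trainees) - scenario.baseline_providers
    facilities_needed = math.ceil(new_total_extra / scenario.providers_per_facility)
    new_facilities = max(0, facilities_needed - current_facilities)
    cost = (
        repairs * scenario.unit_cost
        + new_trainees * scenario.training_cost
        + new_facilities * scenario.renovation_cost
    )
    return cost, new_trainees, new_facilities


def run_bia(
    scenario: BIAScenario,
    daly_per_repair: float,
) -> BIATrajectory:
    """Simulate the scenario year by year.

    Each year the backlog first grows by the annual incidence; repairs are
    then the largest whole-person volume satisfying (i) the optional target
    schedule (otherwise: repair as much of the backlog as possible),
    (ii) workforce capacity including this year's permissible trainee
    intake, and (iii) the budget cap.  The schedule is cumulative: volume a
    constrained year could not deliver stays in the plan and is caught up
    when capacity allows.  Years whose cap cannot fund a single repair are
    flagged infeasible and perform none.
    """
    if daly_per_repair < 0:
        raise ValidationError("daly_per_repair: must be >= 0")
    backlog = scenario.initial_backlog
    providers = scenario.baseline_providers
    facilities = 0  # newly activated facilities beyond the existing network
    trained_cum = 0
    rows = []
    infeasible = []
    cumulative_cost = 0.0
    plan_remaining = 0.0  # scheduled volume not yet delivered (carries forward)
    for k in range(scenario.n_years):
        year = scenario.start_year + k
        backlog += scenario.annual_incidence
        in_ramp = k < scenario.training_ramp
        trainee_cap = scenario.annual_trainee_cap if in_ramp else 0

        if scenario.target_repairs is not None:
            plan_remaining += scenario.target_repairs[k]
            desired = min(backlog, plan_remaining)
        else:
            desired = backlog
        capacity = (providers + trainee_cap) * scenario.provider_productivity
        upper = int(min(desired, capacity))

        def cost_of(r: float) -> float:
            return _year_cost(scenario, r, providers, facilities, trainee_cap)[0]

        if scenario.budget_cap is None or cost_of(upper) <= scenario.budget_cap:
            repairs = upper
        else:
            lo, hi = 0, upper  # invariant: cost_of(lo) <= cap < cost_of(hi)
            if cost_of(lo) > scenario.budget_cap:
                repairs = 0
            else:
                while hi - lo > 1:
                    mid = (lo + hi) // 2
                    if cost_of(mid) <= scenario.budget_cap:
                        lo = mid
                    else:
                        hi = mid
                repairs = lo
        if repairs == 0 and upper > 0 and scenario.budget_cap is not None:
            infeasible.append(year)

        cost, new_trainees, new_facilities = _year_cost(
            scenario, repairs, providers, facilities, trainee_cap
        )
        providers += new_trainees
        trained_cum += new_trainees
        facilities += new_facilities
        backlog -= repairs
        plan_remaining = max(0.0, plan_remaining - repairs)
        cumulative_cost += cost
        rows.append(
            {
                "year": year,
                "repairs": float(repairs),
                "backlog": backlog,
                "annual_cost_usd_2020": cost,
                "cumulative_cost_usd_2020": cumulative_cost,
                "dalys_averted": repairs * daly_per_repair,
                "providers_trained_cumulative": trained_cum,
                "facilities_renovated_cumulative": facilities,
            }
        )
    return BIATrajectory(
        scenario=scenario, years=pd.DataFrame(rows), infeasible_years=tuple(infeasible)
    )


def elimination_schedule(
    initial_backlog: float,
    annual_incidence: float,
    start_year: int = 2020,
    end_year: int = 2030,
    milestones: dict[int, float] | None = None,
) -> tuple[float, ...]:
    """Yearly repair targets that drive the backlog to zero by ``end_year``.

    ``milestones`` maps a year to the fraction of the initial backlog still
    untreated at that year's end (default: 30% remaining by 2025); the
    backlog declines linearly between milestones and reaches zero in the
    final year.  Returned repairs absorb the yearly incidence.
    """
    if milestones is None:
        milestones = {min(2025, end_year - 1): 0.30}
    points = sorted({**milestones, end_year: 0.0}.items())
    knots_x = [start_year - 1] + [y for y, _ in points]
    knots_y = [1.0] + [f for _, f in points]
    years = np.arange(start_year, end_year + 1)
    frac = np.interp(years, knots_x, knots_y)
    targets = []
    prev = initial_backlog
    for f in frac:
        level = f * initial_backlog
        targets.append(max(0.0, prev + annual_incidence - level))
        prev = level
    return tuple(targets)


def scenario_budget_cap(unit_cost: float, **overrides) -> BIAScenario:
    """Financially conservative expansion: USD 10 million annual cap.

    Providers each perform 50 repairs/year; up to 250 trainees per year over
    a 5-year ramp (1,250 total).
    """
    base = dict(
        label="scenario1_budget_cap",
        unit_cost=unit_cost,
        budget_cap=10_000_000.0,
        provider_productivity=50.0,
        training_ramp=5,
        annual_trainee_cap=250,
    )
    base.update(overrides)
    return BIAScenario(**base)


def scenario_elimination(unit_cost: float, **overrides) -> BIAScenario:
    """Aggressive expansion: eliminate the backlog by 2030, no budget cap.

    Providers each perform 200 repairs/year; up to 400 trainees per year
    over a 3-year ramp (1,200 total).  The yearly repair schedule targets
    roughly 70% of untreated hernias cleared by 2025 and full elimination
    by 2030.
    """
    base = dict(
        label="scenario2_elimination",
        unit_cost=unit_cost,
        budget_cap=None,
        provider_productivity=200.0,
        training_ramp=3,
        annual_trainee_cap=400,
    )
    base.update(overrides)
    sc = BIAScenario(**base)
    if sc.target_repairs is None:
        sc = replace(
            sc,
            target_repairs=elimination_schedule(
                sc.initial_backlog, sc.annual_incidence, sc.start_year, sc.end_year
            ),
        )
    return sc


_DEFAULT_VARIATIONS: tuple[tuple[str, str, float], ...] = (
    ("training_cost -20%", "training_cost", 0.8),
    ("training_cost +20%", "training_cost", 1.2),
    ("renovation_cost -20%", "renovation_cost", 0.8),
    ("renovation_cost +20%", "renovation_cost", 1.2),
)


def bia_dsa(
    scenario: BIAScenario,
    daly_per_repair: float,
    extra_providers_per_facility: int = 1,
    productivity_factor: float = 1.2,
) -> pd.DataFrame:
    """One-way sensitivity of the budget-impact model.

    Varies training and renovation costs by +/-20% and applies increments to
    providers-per-facility and provider productivity.  The outcome metric is
    the final-year backlog for budget-capped scenarios and the cumulative
    cost for uncapped (elimination) scenarios; rows report the change from
    the scenario's base run, sorted by absolute spread.
    """
    capped = scenario.budget_cap is not None
    metric = "final_backlog" if capped else "cumulative_cost"

    def outcome(sc: BIAScenario) -> float:
        traj = run_bia(sc, daly_per_repair)
        return traj.final_backlog if capped else traj.total_cost

    base_value = outcome(scenario)
    variations: list[tuple[str, BIAScenario]] = [
        (label, replace(scenario, **{name: getattr(scenario, name) * factor}))
        for label, name, factor in _DEFAULT_VARIATIONS
    ]
    variations.append(
        (
            f"providers_per_facility +{extra_providers_per_facility}",
            replace(
                scenario,
                providers_per_facility=scenario.providers_per_facility
                + extra_providers_per_facility,
            ),
        )
    )
    variations.append(
        (
            f"provider_productivity x{productivity_factor}",
            replace(
                scenario,
                provider_productivity=scenario.provider_productivity
                * productivity_factor,
            ),
        )
    )
    rows = [
        {
            "variation": label,
            "metric": metric,
            "value": outcome(sc),
            "base_value": base_value,
            "spread": outcome(sc) - base_value,
        }
        for label, sc in variations
    ]
    out = pd.DataFrame(rows)
    out = out.reindex(
        out["spread"].abs().sort_values(ascending=False, kind="stable").index
    )
    return out.reset_index(drop=True)
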