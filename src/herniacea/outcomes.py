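"""Discounted cost and DALY accrual over a cohort trace.

DALY = YLD + YLL.  Years lived with disability (YLD) accrue as
disability weight x person-time, cycle by cycle, over the model horizon;
years of life lost (YLL) accrue when a hernia-attributable death occurs, as
the remaining life expectancy at the age of death.  Background deaths carry
no YLL: background mortality is identical across arms and would cancel in
the incremental comparison while inflating both totals.  No age or time
weighting is applied.  A closed-form mode (disability weight x full
remaining life expectancy at presentation) is also provided for comparison
with the single-shot formulation of the burden formulas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markov import CohortTrace, STATES
from .parameters import LifeTable, ModelParameters, ValidationError

__all__ = [
    "discount_factor",
    "accrue_yld",
    "accrue_yll",
    "accrue_costs",
    "summarize",
    "closed_form_daly_per_person",
    "OutcomeSummary",
]


def discount_factor(cycle: int, rate: float, half_cycle: bool) -> float:
    """Present-value factor (1+rate)^(-t) for a reward booked in ``cycle``.

    With half-cycle correction, rewards in cycles >= 1 are treated as
    occurring mid-cycle (t = cycle - 0.5); cycle 0 is never shifted.
    """
    if rate < 0:
        raise ValidationError(f"discount_rate: {rate} is negative")
    if cycle < 0:
        raise ValidationError(f"cycle: {cycle} is negative")
    t = cycle - 0.5 if (half_cycle and cycle >= 1) else float(cycle)
    return float((1.0 + rate) ** (-t))


def _membership(trace: CohortTrace, half_cycle: bool) -> np.ndarray:
    """Living-compartment person-time for cycles 1..T, shape (T, 12).

    Person-time during cycle c (from model time c-1 to c) is the
    beginning-of-cycle occupancy, or the average of beginning and end
    occupancy under half-cycle correction.
    """
    living = trace.living()
    if half_cycle:
        return 0.5 * (living[:-1] + living[1:])
    return living[:-1]


def accrue_yld(
    trace: CohortTrace, params: ModelParameters, discounted: bool = True
) -> np.ndarray:
    """Per-cycle years lived with disability, indexed 0..T (entry 0 is 0)."""
    dw = np.tile(params.dw_array(), len(STATES))  # one weight per living compartment
    T = trace.n_cycles
    series = np.zeros(T + 1)
    if T == 0:
        return series
    m = _membership(trace, params.half_cycle_correction)
    raw = m @ dw
    for c in range(1, T + 1):
        f = (
            discount_factor(c, params.discount_rate, params.half_cycle_correction)
            if discounted
            else 1.0
        )
        series[c] = raw[c - 1] * f
    return series


def accrue_yll(
    trace: CohortTrace,
    life_table: LifeTable,
    discount_rate: float = 0.03,
    half_cycle: bool = True,
    discounted: bool = True,
) -> np.ndarray:
    """Per-cycle years of life lost to hernia-attributable deaths.

    Deaths during cycle c (ages ``starting_age + c - 1`` at last birthday)
    each contribute the remaining life expectancy at that age, discounted at
    the death cycle.
    """
    T = trace.n_cycles
    series = np.zeros(T + 1)
    for c in range(1, T + 1):
        deaths = trace.attributable_deaths[c]
        if deaths == 0.0:
            continue
        ex = life_table.ex_at(trace.ages[c - 1])
        f = discount_factor(c, discount_rate, half_cycle) if discounted else 1.0
        series[c] = deaths * ex * f
    return series


def accrue_costs(
    trace: CohortTrace,
    params: ModelParameters,
    provider: str,
    discounted: bool = True,
) -> np.ndarray:
    """Per-cycle procedure spending: repairs in cycle t x unit cost.

    Procedures are booked at the start of the cycle in which they are
    performed, so cycle-0 repairs are undiscounted.  The untreated arm
    accrues zero cost.
    """
    if not trace.treated_arm:
        return np.zeros(trace.n_cycles + 1)
    if provider not in ("md", "surgeon"):
        raise ValidationError(
            f"provider: treated-arm costing requires 'md' or 'surgeon', got {provider!r}"
        )
    unit = params.unit_cost(provider)
    T = trace.n_cycles
    series = np.zeros(T + 1)
    for t in range(T):
        f = (1.0 + params.discount_rate) ** (-t) if discounted else 1.0
        series[t] = trace.repairs[t] * unit * f
    return series


@dataclass(frozen=True)
class OutcomeSummary:
    """Discounted totals and per-cycle series for one model arm."""

    label: str
    provider: str
    cohort_size: float
    total_cost: float
    total_yld: float
    total_yll: float
    series: pd.DataFrame = field(repr=False)

    @property
    def total_daly(self) -> float:
        return self.total_yld + self.total_yll

    @property
    def cost_per_person(self) -> float:
        return self.total_cost / self.cohort_size

    @property
    def daly_per_person(self) -> float:
        return self.total_daly / self.cohort_size


def summarize(
    trace: CohortTrace,
    params: ModelParameters,
    life_table: LifeTable,
    label: str | None = None,
) -> OutcomeSummary:
    """Accrue all reward streams over ``trace`` into an :class:`OutcomeSummary`.

    The per-cycle frame carries each stream both raw and discounted.
    """
    provider = trace.provider
    kw = dict(
        discount_rate=params.discount_rate,
        half_cycle=params.half_cycle_correction,
    )
    yld = accrue_yld(trace, params)
    yld_raw = accrue_yld(trace, params, discounted=False)
    yll = accrue_yll(trace, life_table, discounted=True, **kw)
    yll_raw = accrue_yll(trace, life_table, discounted=False, **kw)
    if trace.treated_arm:
        cost = accrue_costs(trace, params, provider)
        cost_raw = accrue_costs(trace, params, provider, discounted=False)
    else:
        cost = np.zeros(trace.n_cycles + 1)
        cost_raw = np.zeros(trace.n_cycles + 1)

    series = pd.DataFrame(
        {
            "cycle": np.arange(trace.n_cycles + 1),
            "cost": cost_raw,
            "cost_disc": cost,
            "yld": yld_raw,
            "yld_disc": yld,
            "yll": yll_raw,
            "yll_disc": yll,
            "daly": yld_raw + yll_raw,
            "daly_disc": yld + yll,
        }
    )
    return OutcomeSummary(
        label=label or ("no_treatment" if not trace.treated_arm else f"repair_{provider}"),
        provider=provider,
        cohort_size=trace.cohort_size,
        total_cost=float(cost.sum()),
        total_yld=float(yld.sum()),
        total_yll=float(yll.sum()),
        series=series,
    )


def closed_form_daly_per_person(
    params: ModelParameters, life_table: LifeTable
) -> dict[str, float]:
    """Single-shot burden per untreated person at presentation.

    Literal reading of the burden formulas: YLD = disability weight x
    remaining life expectancy at the age of surgery; YLL = premature-death
    risk x the same life expectancy.  Provided for comparison with the
    cycle-accrued totals; it ignores the horizon, discounting and competing
    mortality, so it overstates burden relative to the cycle model.
    """
    ex = life_table.ex_at(params.starting_age)
    mean_dw = params.pain_untreated.mean_disability_weight(params.dw_map)
    yld = mean_dw * ex
    yll = params.risk_premature_death * ex
    return {"yld": yld, "yll": yll, "daly": yld + yll}
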