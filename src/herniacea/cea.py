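"""Pairwise incremental cost-effectiveness comparison.

Computes incremental cost, incremental DALYs averted, the ICER (USD per
DALY averted) and a dominance verdict for an intervention arm against a
comparator, plus a cost-effectiveness verdict against a willingness-to-pay
threshold band.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .outcomes import OutcomeSummary
from .parameters import ValidationError

__all__ = ["CEAResult", "compare", "against_threshold", "results_table", "run_cea"]

DOMINANCE_VERDICTS = ("none", "intervention_dominates", "comparator_dominates", "tie")


@dataclass(frozen=True)
class CEAResult:
    """One pairwise comparison (one row of a cost-effectiveness table)."""

    intervention: str
    comparator: str
    cohort_size: float
    cost_intervention: float
    cost_comparator: float
    daly_intervention: float
    daly_comparator: float
    incremental_cost: float
    incremental_dalys_averted: float
    icer: float | None
    dominance: str

    @property
    def cost_per_person_intervention(self) -> float:
        return self.cost_intervention / self.cohort_size

    @property
    def cost_per_person_comparator(self) -> float:
        return self.cost_comparator / self.cohort_size

    @property
    def dalys_averted_per_person(self) -> float:
        return self.incremental_dalys_averted / self.cohort_size

    def to_dict(self) -> dict:
        return {
            "intervention": self.intervention,
            "comparator": self.comparator,
            "cohort_size": self.cohort_size,
            "total_cost_usd_2020": self.cost_intervention,
            "total_daly": self.daly_intervention,
            "incremental_cost_usd_2020": self.incremental_cost,
            "incremental_dalys_averted": self.incremental_dalys_averted,
            "icer_usd_2020_per_daly": self.icer,
            "dominance": self.dominance,
        }


def compare(intervention: OutcomeSummary, comparator: OutcomeSummary) -> CEAResult:
    """Incremental analysis of ``intervention`` against ``comparator``.

    The ICER is reported only where it is informative: when the intervention
    buys health at extra cost (both increments positive) or saves money at a
    health loss (both negative).  Quadrant corners map to dominance
    verdicts; equal cost and effect is a tie.
    """
    if intervention.cohort_size != comparator.cohort_size:
        raise ValidationError(
            "compare: arms were run on different cohort sizes "
            f"({intervention.cohort_size} vs {comparator.cohort_size})"
        )
    d_cost = intervention.total_cost - comparator.total_cost
    averted = comparator.total_daly - intervention.total_daly

    icer: float | None = None
    if (d_cost > 0 and averted > 0) or (d_cost < 0 and averted < 0):
        icer = d_cost / averted

    if d_cost == 0 and averted == 0:
        dominance = "tie"
    elif d_cost <= 0 and averted >= 0:
        dominance = "intervention_dominates"
    elif d_cost >= 0 and averted <= 0:
        dominance = "comparator_dominates"
    else:
        dominance = "none"

    return CEAResult(
        intervention=intervention.label,
        comparator=comparator.label,
        cohort_size=intervention.cohort_size,
        cost_intervention=intervention.total_cost,
        cost_comparator=comparator.total_cost,
        daly_intervention=intervention.total_daly,
        daly_comparator=comparator.total_daly,
        incremental_cost=d_cost,
        incremental_dalys_averted=averted,
        icer=icer,
        dominance=dominance,
    )


def against_threshold(
    result: CEAResult, threshold_low: float, threshold_high: float
) -> str:
    """Verdict against a willingness-to-pay band (USD per DALY averted).

    ``cost_effective`` below the band (or when the intervention dominates),
    ``not_cost_effective`` above it, ``uncertain`` inside it or when no ICER
    is defined.
    """
    if threshold_low <= 0 or threshold_high <= 0 or threshold_low > threshold_high:
        raise ValidationError(
            f"thresholds: need 0 < low <= high, got ({threshold_low}, {threshold_high})"
        )
    if result.dominance == "intervention_dominates":
        return "cost_effective"
    if result.dominance == "comparator_dominates":
        return "not_cost_effective"
    if result.icer is None:
        return "uncertain"
    if result.icer < threshold_low:
        return "cost_effective"
    if result.icer > threshold_high:
        return "not_cost_effective"
    return "uncertain"


def results_table(results: list[CEAResult]) -> pd.DataFrame:
    """Stack pairwise results into a cost-effectiveness table."""
    return pd.DataFrame([r.to_dict() for r in results])


def run_cea(params, life_table, provider: str) -> CEAResult:
    """Full pipeline for one provider arm versus no treatment.

    Runs the cohort model for both arms, accrues discounted costs and
    DALYs, and returns the incremental comparison.
    """
    from .markov import run_cohort
    from .outcomes import summarize

    treated = summarize(
        run_cohort(params, life_table, treated_arm=True, provider=provider),
        params,
        life_table,
    )
    untreated = summarize(
        run_cohort(params, life_table, treated_arm=False), params, life_table
    )
    return compare(treated, untreated)
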