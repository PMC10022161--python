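"""Deterministic cohort propagation through the six-state hernia model.

States: new hernia, repaired hernia, recurrent hernia — each split into four
pain severities — plus an absorbing death state (13 compartments).  The
cohort is propagated as expected fractional occupancy (no sampling): every
cycle, death risks are applied first (background mortality for everyone,
plus the hernia-attributable premature-death risk for the unrepaired
states), then repair / recurrence / contralateral transitions move the
survivors.  Pain severity is assigned on entry to a state from that state's
pain distribution and retained until the state changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import (
    PAIN_LABELS,
    LifeTable,
    ModelParameters,
    ValidationError,
)

__all__ = [
    "STATES",
    "DEATH",
    "compartments",
    "transition_matrix",
    "transition_probabilities",
    "run_cohort",
    "CohortTrace",
]

STATES = ("new_hernia", "repaired", "recurrent")
DEATH = "death"

N_PAIN = len(PAIN_LABELS)
N_COMP = len(STATES) * N_PAIN + 1  # 13
_DEATH_IDX = N_COMP - 1


def compartments() -> list[str]:
    """Compartment labels in canonical order, death last."""
    return [f"{s}:{p}" for s in STATES for p in PAIN_LABELS] + [DEATH]


def _idx(state: str, pain: str | None = None) -> int:
    if state == DEATH:
        return _DEATH_IDX
    return STATES.index(state) * N_PAIN + PAIN_LABELS.index(pain)


def _state_slice(state: str) -> slice:
    i = STATES.index(state)
    return slice(i * N_PAIN, (i + 1) * N_PAIN)


def transition_matrix(
    params: ModelParameters, q: float, treated_arm: bool
) -> np.ndarray:
    """One-cycle transition matrix P (13x13, rows stochastic).

    ``q`` is the background annual death probability at the cohort's current
    age.  Death competes independently with the hernia-attributable risk in
    the unrepaired states: p_death = 1 - (1-q)(1-risk_premature).
    """
    r_pd = params.risk_premature_death
    rho = params.repair_rate if treated_arm else 0.0
    rho_rec = rho if params.repair_recurrent else 0.0
    c = params.risk_contralateral
    rr = params.risk_recurrent

    pain_rep = params.pain_repaired.as_array()
    pain_new = params.pain_untreated.as_array()
    pain_rec = params.pain_recurrent.as_array()

    P = np.zeros((N_COMP, N_COMP))
    d_unrep = 1.0 - (1.0 - q) * (1.0 - r_pd)
    d_rep = q

    for pi, pain in enumerate(PAIN_LABELS):
        # new hernia: die, get repaired (treated arm), or stay
        src = _idx("new_hernia", pain)
        s = 1.0 - d_unrep
        P[src, _DEATH_IDX] = d_unrep
        P[src, _state_slice("repaired")] += s * rho * pain_rep
        P[src, src] += s * (1.0 - rho)

        # recurrent hernia: die, get re-repaired (if enabled), or stay
        src = _idx("recurrent", pain)
        s = 1.0 - d_unrep
        P[src, _DEATH_IDX] = d_unrep
        P[src, _state_slice("repaired")] += s * rho_rec * pain_rep
        P[src, src] += s * (1.0 - rho_rec)

        # repaired: die (background only), contralateral new hernia,
        # recurrence, or stay
        src = _idx("repaired", pain)
        s = 1.0 - d_rep
        P[src, _DEATH_IDX] = d_rep
        P[src, _state_slice("new_hernia")] += s * c * pain_new
        P[src, _state_slice("recurrent")] += s * rr * pain_rec
        P[src, src] += s * (1.0 - c - rr)

    P[_DEATH_IDX, _DEATH_IDX] = 1.0
    return P


def transition_probabilities(
    params: ModelParameters,
    life_table: LifeTable,
    age: float,
    treated_arm: bool,
) -> dict[str, dict[str, float]]:
    """Nested-dict view of the one-cycle transition probabilities at ``age``."""
    q = life_table.q_at(age)  # raises if age is outside the table
    P = transition_matrix(params, q, treated_arm)
    labels = compartments()
    return {
        src: {dst: float(P[i, j]) for j, dst in enumerate(labels) if P[i, j] > 0.0}
        for i, src in enumerate(labels)
    }


@dataclass(frozen=True)
class CohortTrace:
    """Cycle-by-cycle record of one model arm.

    ``occupancy[t]`` is the compartment vector at the start of cycle ``t``
    (cycles 0..T).  ``repairs[t]`` counts operations performed during the
    transition from cycle ``t`` to ``t+1`` (last entry 0).
    ``attributable_deaths[t]`` / ``background_deaths[t]`` count deaths
    occurring during cycle ``t`` (entry 0 is 0).
    """

    occupancy: np.ndarray  # (T+1, 13)
    ages: np.ndarray  # (T+1,)
    repairs: np.ndarray  # (T+1,)
    attributable_deaths: np.ndarray  # (T+1,)
    background_deaths: np.ndarray  # (T+1,)
    cohort_size: float
    treated_arm: bool
    provider: str  # "md", "surgeon" or "none"

    @property
    def n_cycles(self) -> int:
        return len(self.occupancy) - 1

    def living(self) -> np.ndarray:
        """Occupancy of the living compartments, shape (T+1, 12)."""
        return self.occupancy[:, :_DEATH_IDX]

    def death(self) -> np.ndarray:
        return self.occupancy[:, _DEATH_IDX]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format export: cycle, age, compartment, occupancy."""
        labels = compartments()
        rows = []
        for t in range(len(self.occupancy)):
            for j, lab in enumerate(labels):
                rows.append((t, int(self.ages[t]), lab, self.occupancy[t, j]))
        return pd.DataFrame(rows, columns=["cycle", "age", "compartment", "occupancy"])


def run_cohort(
    params: ModelParameters,
    life_table: LifeTable,
    treated_arm: bool,
    provider: str = "none",
) -> CohortTrace:
    """Propagate the cohort for ``time_horizon`` one-year cycles.

    Everyone starts in the new-hernia state with pain severities distributed
    per ``pain_untreated``; ages advance one year per cycle from
    ``starting_age``.  Total persons (living + dead) are conserved exactly.
    """
    if treated_arm and provider not in ("md", "surgeon"):
        raise ValidationError(
            f"provider: treated arm requires 'md' or 'surgeon', got {provider!r}"
        )
    if not treated_arm and provider != "none":
        raise ValidationError("provider: must be 'none' for the untreated arm")

    T = params.time_horizon
    last_age = params.starting_age + T - 1
    if params.starting_age < life_table.min_age or last_age > life_table.max_age:
        raise ValidationError(
            f"time horizon needs ages {params.starting_age}..{last_age}, but the "
            f"life table covers {life_table.min_age}..{life_table.max_age}"
        )

    occupancy = np.zeros((T + 1, N_COMP))
    occupancy[0, _state_slice("new_hernia")] = (
        params.cohort_size * params.pain_untreated.as_array()
    )
    ages = params.starting_age + np.arange(T + 1)
    repairs = np.zeros(T + 1)
    attr_deaths = np.zeros(T + 1)
    bg_deaths = np.zeros(T + 1)

    rep_cols = _state_slice("repaired")
    r_pd = params.risk_premature_death
    for t in range(T):
        q = life_table.q_at(ages[t])
        P = transition_matrix(params, q, treated_arm)
        v = occupancy[t]
        occupancy[t + 1] = v @ P

        unrepaired = (
            v[_state_slice("new_hernia")].sum() + v[_state_slice("recurrent")].sum()
        )
        attr_deaths[t + 1] = unrepaired * (1.0 - q) * r_pd
        bg_deaths[t + 1] = v[:_DEATH_IDX].sum() * q
        # operations = flow into 'repaired' from the other living states
        inflow_sources = np.ones(N_COMP, dtype=bool)
        inflow_sources[rep_cols] = False
        repairs[t] = v[inflow_sources] @ P[inflow_sources, rep_cols].sum(axis=1)

    return CohortTrace(
        occupancy=occupancy,
        ages=ages,
        repairs=repairs,
        attributable_deaths=attr_deaths,
        background_deaths=bg_deaths,
        cohort_size=params.cohort_size,
        treated_arm=treated_arm,
        provider=provider,
    )
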