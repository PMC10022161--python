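"""Deterministic and probabilistic sensitivity analysis.

One-way deterministic analysis (DSA) re-runs the full pipeline with a
single input at its low/high bound (+/-20% for the published ranges) and
tabulates the ICER spread per input, tornado-sorted.  Structural choices —
starting age 50->60, discount rate 3%->3.5%, half-cycle correction on->off
— are re-run as labelled scenario rows.  Probabilistic analysis (PSA) draws
the five inputs with published normal distributions (truncated to their
valid domains by resampling), re-runs the pipeline per iteration, and feeds
cost-effectiveness acceptability curves (CEAC) via the net-monetary-benefit
rule: an iteration counts as cost-effective at willingness-to-pay lambda
when lambda x (DALYs averted) - (incremental cost) > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cea import run_cea
from .parameters import LifeTable, ModelParameters, ValidationError, replace_param

__all__ = [
    "DSARow",
    "StructuralScenario",
    "default_dsa_spec",
    "run_dsa",
    "PSADistribution",
    "default_psa_distributions",
    "draw_psa_parameters",
    "run_psa",
    "ceac",
]


@dataclass(frozen=True)
class DSARow:
    """One +/-range row of the one-way deterministic sensitivity spec."""

    name: str
    base: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValidationError(
                f"DSARow {self.name}: need low <= base <= high, got "
                f"({self.low}, {self.base}, {self.high})"
            )


@dataclass(frozen=True)
class StructuralScenario:
    """A labelled one-off structural toggle (not a +/-20% range)."""

    label: str
    name: str
    value: object


def default_dsa_spec(params: ModelParameters) -> list[DSARow]:
    """Published one-way ranges: +/-20% on each varied input."""

    def pm20(name: str, base: float) -> DSARow:
        return DSARow(name, base, 0.8 * base, 1.2 * base)

    return [
        pm20("cost_md", params.cost_md),
        pm20("cost_surgeon", params.cost_surgeon),
        pm20("dw_mild", params.disability_weight("mild")),
        pm20("dw_moderate", params.disability_weight("moderate")),
        pm20("dw_severe", params.disability_weight("severe")),
        pm20("risk_recurrent", params.risk_recurrent),
        pm20("risk_contralateral", params.risk_contralateral),
        pm20("risk_premature_death", params.risk_premature_death),
    ]


def default_structural_scenarios() -> list[StructuralScenario]:
    return [
        StructuralScenario("starting_age 50->60", "starting_age", 60),
        StructuralScenario("discount_rate 3%->3.5%", "discount_rate", 0.035),
        StructuralScenario("half_cycle_correction on->off", "half_cycle_correction", False),
    ]


def _icer_value(result) -> float:
    # dominant results plot at the quadrant boundary; spread stays meaningful
    return result.icer if result.icer is not None else float("nan")


def run_dsa(
    base: ModelParameters,
    life_table: LifeTable,
    provider: str,
    spec: list[DSARow] | None = None,
    structural: list[StructuralScenario] | None = None,
) -> pd.DataFrame:
    """One-way tornado table of ICERs for ``provider`` versus no treatment.

    Returns one row per varied input (columns ``icer_low`` / ``icer_high``,
    ``spread``) and one per structural scenario (``icer_low == icer_high``),
    sorted by absolute spread descending.  Inputs whose variation leaves the
    ICER unchanged get ``negligible=True`` so they can be dropped from the
    tornado figure.
    """
    if spec is None:
        spec = default_dsa_spec(base)
    if structural is None:
        structural = default_structural_scenarios()
    base_icer = run_cea(base, life_table, provider).icer
    rows = []
    for row in spec:
        icer_lo = _icer_value(
            run_cea(replace_param(base, row.name, row.low), life_table, provider)
        )
        icer_hi = _icer_value(
            run_cea(replace_param(base, row.name, row.high), life_table, provider)
        )
        rows.append(
            {
                "parameter": row.name,
                "kind": "range",
                "icer_low": icer_lo,
                "icer_high": icer_hi,
                "spread": icer_hi - icer_lo,
            }
        )
    for sc in structural:
        icer = _icer_value(
            run_cea(replace_param(base, sc.name, sc.value), life_table, provider)
        )
        rows.append(
            {
                "parameter": sc.label,
                "kind": "scenario",
                "icer_low": icer,
                "icer_high": icer,
                "spread": icer - base_icer,
            }
        )
    out = pd.DataFrame(rows)
    out["base_icer"] = base_icer
    # changes below one cent per DALY are presentation-invisible
    out["negligible"] = out["spread"].abs() < 0.01
    out = out.reindex(
        out["spread"].abs().sort_values(ascending=False, kind="stable").index
    )
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class PSADistribution:
    """A normal sampling distribution for one input, truncated to a domain."""

    name: str
    mean: float
    sd: float
    lower: float = 0.0
    upper: float = 1.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError(f"PSADistribution {self.name}: sd must be >= 0")
        if not self.lower <= self.mean <= self.upper:
            raise ValidationError(
                f"PSADistribution {self.name}: mean outside truncation bounds"
            )


def default_psa_distributions() -> list[PSADistribution]:
    """Published normal distributions for the five probabilistic inputs.

    Inputs with no published distribution (costs, premature-death risk,
    repair rate) are held at base case.
    """
    return [
        PSADistribution("dw_mild", 0.01140, 0.00400),
        PSADistribution("dw_moderate", 0.11400, 0.02000),
        PSADistribution("dw_severe", 0.32400, 0.05500),
        PSADistribution("risk_recurrent", 0.00376, 0.00013),
        PSADistribution("risk_contralateral", 0.00380, 0.00073),
    ]


_DW_NAMES = ("dw_mild", "dw_moderate", "dw_severe")


def _draw_one(rng: np.random.Generator, dist: PSADistribution) -> float:
    if dist.sd == 0.0:
        return dist.mean
    for _ in range(1000):
        x = rng.normal(dist.mean, dist.sd)
        if dist.lower <= x <= dist.upper:
            return float(x)
    raise ValidationError(
        f"PSADistribution {dist.name}: truncation bounds rejected 1000 draws"
    )


def draw_psa_parameters(
    dists: list[PSADistribution], n_iter: int, seed: int
) -> pd.DataFrame:
    """Draw ``n_iter`` joint parameter vectors, one independent substream each.

    Disability weights are additionally required to increase with severity
    (a model invariant); the rare draw violating the ordering is redrawn
    within its iteration's substream.
    """
    if n_iter < 1:
        raise ValidationError(f"n_iter: {n_iter} must be >= 1")
    substreams = np.random.SeedSequence(seed).spawn(n_iter)
    records = []
    for i, ss in enumerate(substreams):
        rng = np.random.default_rng(ss)
        while True:
            draw = {d.name: _draw_one(rng, d) for d in dists}
            dws = [draw[n] for n in _DW_NAMES if n in draw]
            if all(a < b for a, b in zip(dws, dws[1:])):
                break
        draw["iteration"] = i
        records.append(draw)
    return pd.DataFrame(records).set_index("iteration")


def run_psa(
    base: ModelParameters,
    life_table: LifeTable,
    provider: str,
    dists: list[PSADistribution] | None = None,
    n_iter: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo re-runs of the pipeline; one row per iteration.

    Columns: the drawn parameter values, ``incremental_cost`` and
    ``dalys_averted`` of ``provider`` versus no treatment.  Deterministic
    under a fixed seed.
    """
    if dists is None:
        dists = default_psa_distributions()
    draws = draw_psa_parameters(dists, n_iter, seed)
    inc_cost = np.empty(n_iter)
    averted = np.empty(n_iter)
    for i, (_, row) in enumerate(draws.iterrows()):
        p = base
        for name, value in row.items():
            p = replace_param(p, name, float(value))
        res = run_cea(p, life_table, provider)
        inc_cost[i] = res.incremental_cost
        averted[i] = res.incremental_dalys_averted
    out = draws.copy()
    out["incremental_cost"] = inc_cost
    out["dalys_averted"] = averted
    return out.reset_index()


def ceac(samples: pd.DataFrame, wtp_grid: np.ndarray | list[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve from PSA samples.

    For each willingness-to-pay value, the fraction of iterations with
    positive net monetary benefit.  Monotone non-decreasing whenever all
    iterations avert a non-negative number of DALYs.
    """
    if len(samples) == 0:
        raise ValidationError("ceac: empty PSA sample set")
    wtp = np.asarray(wtp_grid, dtype=float)
    if np.any(wtp < 0):
        raise ValidationError("ceac: willingness-to-pay values must be >= 0")
    d_cost = samples["incremental_cost"].to_numpy()
    d_eff = samples["dalys_averted"].to_numpy()
    prob = [(lam * d_eff - d_cost > 0).mean() for lam in wtp]
    return pd.DataFrame({"wtp_usd_2020_per_daly": wtp, "probability_cost_effective": prob})
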