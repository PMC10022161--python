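"""Model inputs for the Ghana inguinal-hernia repair evaluation.

This module is the single source of truth for every quantity the Markov
cohort model, the sensitivity analyses and the budget-impact simulator
consume: per-procedure costs, transition risks, disability weights, the
discount rate, the cohort specification, pain-level distributions and the
background life table.  All monetary values are 2020 US dollars; all risks
are annual probabilities.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ValidationError",
    "PainLevel",
    "PainDistribution",
    "CostComponents",
    "LifeTable",
    "ModelParameters",
    "PAIN_LABELS",
    "GBD2017_DW_MAP",
    "VOLTA_2020_COSTS",
    "DEFAULT_PAIN_UNTREATED",
    "DEFAULT_PAIN_REPAIRED",
    "DEFAULT_PAIN_RECURRENT",
    "derive_premature_death_risk",
    "total_procedure_cost",
    "load_parameters",
    "save_parameters",
    "replace_param",
    "base_case_life_table",
]


class ValidationError(ValueError):
    """An input violates a model invariant; the message names the field."""


#: Canonical ordering of pain severities, least to most severe.
PAIN_LABELS: tuple[str, ...] = ("none", "mild", "moderate", "severe")

PROVIDERS = ("md", "surgeon")


@dataclass(frozen=True)
class PainLevel:
    """A pain severity band: its IPQ scores and GBD disability weight.

    The Inguinal Pain Questionnaire (IPQ) grades pain on a 7-point scale;
    scores are collapsed into four severity bands, each carrying one
    disability weight (DW) from the Global Burden of Disease 2017 study.
    """

    label: str
    ipq_scores: frozenset[int]
    disability_weight: float

    def __post_init__(self) -> None:
        if self.label not in PAIN_LABELS:
            raise ValidationError(f"PainLevel.label: unknown label {self.label!r}")
        if not self.ipq_scores or not all(1 <= s <= 7 for s in self.ipq_scores):
            raise ValidationError("PainLevel.ipq_scores: scores must lie in 1..7")
        if not 0.0 <= self.disability_weight <= 1.0:
            raise ValidationError(
                f"PainLevel.disability_weight: {self.disability_weight} outside [0, 1]"
            )


#: IPQ score -> disability weight mapping (GBD 2017 chronic-pain weights).
GBD2017_DW_MAP: tuple[PainLevel, ...] = (
    PainLevel("none", frozenset({1}), 0.0),
    PainLevel("mild", frozenset({2, 3}), 0.011),
    PainLevel("moderate", frozenset({4, 5}), 0.114),
    PainLevel("severe", frozenset({6, 7}), 0.324),
)


def _validate_dw_map(dw_map: Iterable[PainLevel]) -> tuple[PainLevel, ...]:
    levels = tuple(dw_map)
    labels = [lv.label for lv in levels]
    if labels != list(PAIN_LABELS):
        raise ValidationError(
            f"dw_map: expected levels {PAIN_LABELS} in order, got {labels}"
        )
    scores = sorted(s for lv in levels for s in lv.ipq_scores)
    if scores != list(range(1, 8)):
        raise ValidationError("dw_map: IPQ scores 1..7 must partition across levels")
    weights = [lv.disability_weight for lv in levels]
    if weights[0] != 0.0:
        raise ValidationError("dw_map: 'none' must carry disability weight 0")
    if not all(a <= b for a, b in zip(weights, weights[1:])):
        raise ValidationError("dw_map: disability weights must not decrease with severity")
    return levels


@dataclass(frozen=True)
class PainDistribution:
    """Categorical distribution over the four pain severities.

    Each living health state of the model carries one such distribution:
    a person entering the state is split across severities in these
    proportions and keeps that severity until leaving the state.
    """

    probabilities: Mapping[str, float]

    def __post_init__(self) -> None:
        probs = dict(self.probabilities)
        if set(probs) != set(PAIN_LABELS):
            raise ValidationError(
                f"PainDistribution: expected keys {set(PAIN_LABELS)}, got {set(probs)}"
            )
        if any(p < 0 for p in probs.values()):
            raise ValidationError("PainDistribution: probabilities must be >= 0")
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"PainDistribution: probabilities sum to {total}, expected 1"
            )
        object.__setattr__(self, "probabilities", probs)

    def as_array(self) -> np.ndarray:
        return np.array([self.probabilities[l] for l in PAIN_LABELS], dtype=float)

    def mean_disability_weight(self, dw_map: Iterable[PainLevel] = GBD2017_DW_MAP) -> float:
        return float(
            sum(self.probabilities[lv.label] * lv.disability_weight for lv in dw_map)
        )


# Shipped default pain distributions.  The cohort-study pain prevalences are
# not published, so these are SYNTHETIC stand-ins produced by
# ``herniacea.synthetic.calibrate_to_paper`` against the published aggregate
# DALY totals and frozen here; override them in the run configuration when
# real data are available.
DEFAULT_PAIN_UNTREATED = PainDistribution(
    {"none": 0.33748, "mild": 0.145672, "moderate": 0.200062, "severe": 0.316786}
)
DEFAULT_PAIN_REPAIRED = PainDistribution(
    {"none": 0.49314, "mild": 0.50175, "moderate": 0.00511, "severe": 0.0}
)
DEFAULT_PAIN_RECURRENT = PainDistribution(
    {"none": 0.33748, "mild": 0.145672, "moderate": 0.200062, "severe": 0.316786}
)


@dataclass(frozen=True)
class CostComponents:
    """Per-operation resource costs (2020 USD) for open mesh repair.

    Components follow the micro-costing of a Ghanaian regional hospital:
    consumables, staff time priced from payroll salaries, overheads and
    capital items apportioned per operation.
    """

    medicines: float
    materials: float
    mesh: float
    staff_md: float
    staff_surgeon: float
    staff_nurse: float
    overhead: float
    capital_or: float
    capital_ward: float
    capital_equipment: float

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValidationError(f"CostComponents.{f.name}: {v} is negative")


#: Published per-operation resource prices (2020 USD), Volta Regional Hospital.
VOLTA_2020_COSTS = CostComponents(
    medicines=17.06,
    materials=9.18,
    mesh=13.20,
    staff_md=14.54,
    staff_surgeon=23.85,
    staff_nurse=6.26,
    overhead=48.60,
    capital_or=2.23,
    capital_ward=6.67,
    capital_equipment=5.64,
)


def derive_premature_death_risk(
    complication_risk: float, complication_mortality: float
) -> float:
    """Annual risk of hernia-attributable death without surgery.

    The product of the annual probability of a complication (incarceration
    or strangulation) and the case-fatality probability of a complicated
    hernia.

    Parameters
    ----------
    complication_risk
        Probability per patient-year of incarceration/strangulation.
    complication_mortality
        Probability of death given a complication.
    """
    for name, v in (
        ("complication_risk", complication_risk),
        ("complication_mortality", complication_mortality),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name}: {v} outside [0, 1]")
    return complication_risk * complication_mortality


def total_procedure_cost(components: CostComponents, provider: str) -> float:
    """Total cost of one mesh repair for the given provider cadre.

    Sums consumables, overhead, capital items, the nurse, and the staff cost
    of exactly one operating provider — a medical doctor (``"md"``) or a
    specialist surgeon (``"surgeon"``), never both.
    """
    if provider not in PROVIDERS:
        raise ValidationError(f"provider: {provider!r} not one of {PROVIDERS}")
    shared = (
        components.medicines
        + components.materials
        + components.mesh
        + components.staff_nurse
        + components.overhead
        + components.capital_or
        + components.capital_ward
        + components.capital_equipment
    )
    staff = components.staff_md if provider == "md" else components.staff_surgeon
    return shared + staff


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed annual mortality probability and remaining life expectancy.

    ``q[i]`` is the probability of dying between exact ages ``age[i]`` and
    ``age[i] + 1``; ``ex[i]`` is remaining life expectancy at ``age[i]``.
    """

    age: np.ndarray
    q: np.ndarray
    ex: np.ndarray

    def __post_init__(self) -> None:
        age = np.asarray(self.age, dtype=int)
        q = np.asarray(self.q, dtype=float)
        ex = np.asarray(self.ex, dtype=float)
        if not (len(age) == len(q) == len(ex)) or len(age) == 0:
            raise ValidationError("LifeTable: columns must be equal-length, nonempty")
        if not np.array_equal(np.diff(age), np.ones(len(age) - 1, dtype=int)):
            raise ValidationError("LifeTable.age: ages must be contiguous integers")
        if np.any(q < 0) or np.any(q > 1):
            raise ValidationError("LifeTable.q: probabilities outside [0, 1]")
        if np.any(ex < 0):
            raise ValidationError("LifeTable.ex: negative life expectancy")
        # beyond early childhood, remaining life expectancy declines with age
        adult = age >= 5
        if np.any(np.diff(ex[adult]) > 1e-9):
            raise ValidationError("LifeTable.ex: must be weakly decreasing past age 5")
        object.__setattr__(self, "age", age)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "ex", ex)

    @property
    def min_age(self) -> int:
        return int(self.age[0])

    @property
    def max_age(self) -> int:
        return int(self.age[-1])

    def _index(self, age: float) -> int:
        i = int(age) - self.min_age
        if not 0 <= i < len(self.age):
            raise ValidationError(
                f"age {age} outside life-table range "
                f"[{self.min_age}, {self.max_age}]"
            )
        return i

    def q_at(self, age: float) -> float:
        return float(self.q[self._index(age)])

    def ex_at(self, age: float) -> float:
        return float(self.ex[self._index(age)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.age, "q": self.q, "ex": self.ex})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LifeTable":
        missing = {"age", "q", "ex"} - set(frame.columns)
        if missing:
            raise ValidationError(f"LifeTable: missing columns {sorted(missing)}")
        return cls(
            age=frame["age"].to_numpy(),
            q=frame["q"].to_numpy(dtype=float),
            ex=frame["ex"].to_numpy(dtype=float),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        # round_trip parsing keeps probabilities bit-identical across save/load
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))


_PROB_FIELDS = (
    "repair_rate",
    "risk_recurrent",
    "risk_contralateral",
    "complication_risk",
    "complication_mortality",
    "risk_premature_death",
)


@dataclass(frozen=True)
class ModelParameters:
    """Complete base-case parameterisation of the cohort model.

    Defaults reproduce the published base case: a cohort of 707,121 adult
    men aged 50 followed for 10 one-year cycles, full repair coverage in the
    treated arm, 3% annual discounting with half-cycle correction, and
    per-procedure costs of USD 123.40 (medical doctor) / 132.71 (surgeon).
    """

    starting_age: int = 50
    time_horizon: int = 10
    cycle_length: float = 1.0
    cohort_size: float = 707_121.0
    repair_rate: float = 1.0
    risk_recurrent: float = 0.00376
    risk_contralateral: float = 0.00380
    complication_risk: float = 0.0056
    complication_mortality: float = 0.20
    risk_premature_death: float | None = None  # derived unless overridden
    discount_rate: float = 0.03
    half_cycle_correction: bool = True
    cost_md: float = 123.40
    cost_surgeon: float = 132.71
    repair_recurrent: bool = True
    dw_map: tuple[PainLevel, ...] = GBD2017_DW_MAP
    pain_untreated: PainDistribution = DEFAULT_PAIN_UNTREATED
    pain_repaired: PainDistribution = DEFAULT_PAIN_REPAIRED
    pain_recurrent: PainDistribution = DEFAULT_PAIN_RECURRENT

    def __post_init__(self) -> None:
        if self.risk_premature_death is None:
            object.__setattr__(
                self,
                "risk_premature_death",
                derive_premature_death_risk(
                    self.complication_risk, self.complication_mortality
                ),
            )
        for name in _PROB_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}: {v} outside [0, 1]")
        if self.risk_recurrent + self.risk_contralateral > 1.0:
            raise ValidationError(
                "risk_recurrent + risk_contralateral exceeds 1; repaired-state "
                "transitions would not be a probability distribution"
            )
        if self.discount_rate < 0:
            raise ValidationError(f"discount_rate: {self.discount_rate} is negative")
        if self.time_horizon < 0:
            raise ValidationError(f"time_horizon: {self.time_horizon} must be >= 0")
        if self.cycle_length != 1.0:
            raise ValidationError("cycle_length: only one-year cycles are supported")
        if self.cohort_size <= 0:
            raise ValidationError(f"cohort_size: {self.cohort_size} must be positive")
        if self.starting_age < 0:
            raise ValidationError(f"starting_age: {self.starting_age} is negative")
        if self.cost_md < 0 or self.cost_surgeon < 0:
            raise ValidationError("cost_md / cost_surgeon: negative procedure cost")
        object.__setattr__(self, "dw_map", _validate_dw_map(self.dw_map))

    # -- convenience accessors -------------------------------------------------

    def disability_weight(self, label: str) -> float:
        for lv in self.dw_map:
            if lv.label == label:
                return lv.disability_weight
        raise ValidationError(f"disability_weight: unknown pain level {label!r}")

    def dw_array(self) -> np.ndarray:
        return np.array([lv.disability_weight for lv in self.dw_map], dtype=float)

    def unit_cost(self, provider: str) -> float:
        if provider == "md":
            return self.cost_md
        if provider == "surgeon":
            return self.cost_surgeon
        raise ValidationError(f"provider: {provider!r} not one of {PROVIDERS}")

    # -- serialisation ---------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "starting_age": self.starting_age,
            "time_horizon": self.time_horizon,
            "cycle_length": self.cycle_length,
            "cohort_size": self.cohort_size,
            "repair_rate": self.repair_rate,
            "risk_recurrent": self.risk_recurrent,
            "risk_contralateral": self.risk_contralateral,
            "complication_risk": self.complication_risk,
            "complication_mortality": self.complication_mortality,
            "risk_premature_death": self.risk_premature_death,
            "discount_rate": self.discount_rate,
            "half_cycle_correction": self.half_cycle_correction,
            "cost_md": self.cost_md,
            "cost_surgeon": self.cost_surgeon,
            "repair_recurrent": self.repair_recurrent,
            "disability_weights": {
                lv.label: lv.disability_weight for lv in self.dw_map
            },
            "pain_untreated": dict(self.pain_untreated.probabilities),
            "pain_repaired": dict(self.pain_repaired.probabilities),
            "pain_recurrent": dict(self.pain_recurrent.probabilities),
        }
        return d


_SCALAR_KEYS = (
    "starting_age",
    "time_horizon",
    "cycle_length",
    "cohort_size",
    "repair_rate",
    "risk_recurrent",
    "risk_contralateral",
    "complication_risk",
    "complication_mortality",
    "risk_premature_death",
    "discount_rate",
    "half_cycle_correction",
    "cost_md",
    "cost_surgeon",
    "repair_recurrent",
)


def _dw_map_from_weights(weights: Mapping[str, float]) -> tuple[PainLevel, ...]:
    if set(weights) != set(PAIN_LABELS):
        raise ValidationError(
            f"disability_weights: expected keys {set(PAIN_LABELS)}, got {set(weights)}"
        )
    return tuple(
        PainLevel(lv.label, lv.ipq_scores, float(weights[lv.label]))
        for lv in GBD2017_DW_MAP
    )


def load_parameters(config: Mapping | str | Path | None = None) -> ModelParameters:
    """Build :class:`ModelParameters` from a config mapping or YAML/JSON file.

    An empty or missing config yields the published base case with the
    shipped (synthetic stand-in) pain distributions.  Any subset of keys may
    be overridden; every value is validated and errors name the offending
    field.  Pain distributions must be given in full (all four severities)
    — partially specified distributions are rejected.
    """
    if config is None:
        config = {}
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        config = yaml.safe_load(text) or {}
    if not isinstance(config, Mapping):
        raise ValidationError("config: expected a mapping at the top level")
    cfg = dict(config)
    cfg.pop("life_table", None)  # path consumed by callers, not here
    cfg.pop("scenarios", None)  # budget-impact blocks consumed by bia module

    kwargs: dict = {}
    for key in _SCALAR_KEYS:
        if key in cfg:
            kwargs[key] = cfg.pop(key)
    if "disability_weights" in cfg:
        kwargs["dw_map"] = _dw_map_from_weights(cfg.pop("disability_weights"))
    for key in ("pain_untreated", "pain_repaired", "pain_recurrent"):
        if key in cfg:
            spec = cfg.pop(key)
            if not isinstance(spec, Mapping):
                raise ValidationError(f"{key}: expected a mapping of level -> probability")
            kwargs[key] = PainDistribution(dict(spec))
    if cfg:
        raise ValidationError(f"config: unknown keys {sorted(cfg)}")
    return ModelParameters(**kwargs)


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    """Write parameters to YAML (or JSON if the suffix is ``.json``)."""
    path = Path(path)
    d = params.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=True))


_DW_PARAM = {"dw_mild": "mild", "dw_moderate": "moderate", "dw_severe": "severe"}


def replace_param(params: ModelParameters, name: str, value) -> ModelParameters:
    """Return a copy of ``params`` with one named input replaced.

    Accepts every scalar field of :class:`ModelParameters` plus the
    pseudo-names ``dw_mild`` / ``dw_moderate`` / ``dw_severe`` addressing a
    single disability weight; used by the one-way sensitivity analysis.
    """
    if name in _DW_PARAM:
        label = _DW_PARAM[name]
        weights = {lv.label: lv.disability_weight for lv in params.dw_map}
        weights[label] = float(value)
        return dataclasses.replace(params, dw_map=_dw_map_from_weights(weights))
    if name not in {f.name for f in dataclasses.fields(params)}:
        raise ValidationError(f"replace_param: unknown parameter {name!r}")
    return dataclasses.replace(params, **{name: value})


def base_case_life_table() -> LifeTable:
    """Load the shipped synthetic Ghana-2016-like male life table."""
    path = Path(__file__).parent / "data" / "ghana2016_male_synthetic_lifetable.csv"
    return LifeTable.from_csv(path)
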