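"""Model parameters: the single source of truth every analysis stage reads.

All epidemiological, test-performance, cost and time parameters for the four
surveillance strategies live in :class:`ModelParams`.  Parameters are
addressed elsewhere (deterministic and probabilistic sensitivity analysis,
calibration) by dotted *parameter paths* such as ``"test.sensitivity"`` or
``"epi.cum_recurrence_prob_5y.twelve_monthly"``.

Unit costs are in 2020 Australian dollars after multiplication by
``cpi_factor`` (a single consumer-price-index adjustment applied at load
time); raw costs sourced from the MBS/AR-DRG schedules can be kept in the
config at their price-year value with the matching factor.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, Field, field_validator, model_validator

STRATEGY_NAMES = (
    "three_four_monthly",
    "six_monthly",
    "twelve_monthly",
    "no_imaging",
)

MetricName = Literal["correct_diagnosis", "error_avoided"]


class StrategySpec(BaseModel):
    """A surveillance schedule: imaging visits (or clinical reviews) per year."""

    name: str
    visits_per_year: int = Field(ge=0)
    horizon_years: float = Field(default=5.0, gt=0)
    #: clinical reviews per year, used in place of imaging visits when
    #: visits_per_year == 0 (the no-imaging arm is still followed in clinic)
    reviews_per_year: int = Field(default=2, ge=0)

    @property
    def events_per_year(self) -> int:
        return self.visits_per_year if self.visits_per_year > 0 else self.reviews_per_year

    @property
    def imaging(self) -> bool:
        return self.visits_per_year > 0


class TestPerformance(BaseModel):
    sensitivity: float = Field(ge=0.0, le=1.0)
    specificity: float = Field(ge=0.0, le=1.0)


class EpidemiologyParams(BaseModel):
    """Distant-recurrence risk and non-imaging detection parameters.

    ``cum_recurrence_prob_5y`` is the per-strategy-group probability of a
    first distant recurrence within the horizon; a constant hazard is
    derived from it.  ``clinical_detection_prob`` is the per-review
    probability that an established recurrence presents symptomatically and
    is detected without imaging; clinical review raises no false positives
    unless ``clinical_fp_rate`` is configured.
    """

    cum_recurrence_prob_5y: dict[str, float]
    clinical_detection_prob: float = Field(ge=0.0, le=1.0)
    clinical_fp_rate: float = Field(default=0.0, ge=0.0, le=1.0)

    @field_validator("cum_recurrence_prob_5y")
    @classmethod
    def _probs_in_range(cls, v: dict[str, float]) -> dict[str, float]:
        for name, p in v.items():
            if not (0.0 <= p < 1.0):
                raise ValueError(
                    f"cum_recurrence_prob_5y[{name}]={p} must be in [0, 1)"
                )
        return v


class CostInputs(BaseModel):
    """Unit costs (AUD) and the discount rate.

    imaging_unit_cost is the whole-body PET/CT fee (PET/low-dose-CT item
    plus the adjunctive localisation CT item).  confirmatory_workup_cost is
    the composite work-up triggered by a positive or equivocal finding
    (FNAB, repeat whole-body PET/CT, other tests).
    """

    imaging_unit_cost: float = Field(ge=0)
    confirmatory_workup_cost: float = Field(ge=0)
    clinic_visit_cost: float = Field(ge=0)
    treatment_cost_stage_iv: float = Field(ge=0)
    cpi_factor: float = Field(default=1.0, gt=0)
    discount_rate: float = Field(default=0.05, ge=0)

    def adjusted(self, raw: float) -> float:
        return raw * self.cpi_factor


class ModelParams(BaseModel):
    strategies: list[StrategySpec]
    test: TestPerformance
    epi: EpidemiologyParams
    costs: CostInputs
    outcome_metric: MetricName = "correct_diagnosis"
    metric_mode: Literal["proportion", "difference"] = "proportion"
    discount_effects: bool = False
    wtp: float = Field(default=50_000.0, ge=0)

    @model_validator(mode="after")
    def _check_strategies(self) -> "ModelParams":
        names = [s.name for s in self.strategies]
        if len(names) != 4:
            raise ValueError("exactly four strategies are required")
        if len(set(names)) != 4:
            raise ValueError("strategy names must be distinct")
        missing = [n for n in names if n not in self.epi.cum_recurrence_prob_5y]
        if missing:
            raise ValueError(f"no recurrence probability for strategies {missing}")
        return self

    def strategy(self, name: str) -> StrategySpec:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(name)

    # -- config I/O ---------------------------------------------------------
    @classmethod
    def from_json(cls, path: str | Path) -> "ModelParams":
        return cls.model_validate_json(Path(path).read_text())

    def to_json(self, path: str | Path | None = None, indent: int = 2) -> str:
        text = json.dumps(self.model_dump(), indent=indent)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def default(cls) -> "ModelParams":
        """The packaged base case (see docs/methods.md for the rationale)."""
        from importlib.resources import files

        return cls.model_validate_json(
            files("survcea.data").joinpath("example_config.json").read_text()
        )


# ---------------------------------------------------------------------------
# unit-cost table (MBS/AR-DRG schedule extract)

#: composite confirmatory work-up = FNAB + whole-body PET/CT + other tests
_IMAGING_ITEMS = ("pet_low_dose_ct", "adjunctive_ct")
_CONFIRMATORY_ITEMS = ("fnab", "pet_low_dose_ct", "adjunctive_ct", "other_tests")


def load_unit_costs(
    path: str | Path,
    cpi_factors: dict[int, float] | float = 1.0,
    discount_rate: float = 0.05,
) -> CostInputs:
    """Build :class:`CostInputs` from a unit-cost CSV.

    The table has columns ``item_label, mbs_or_drg_code, raw_cost,
    price_year``.  Each raw cost is brought to 2020 AUD by the CPI factor
    for its price year (``cpi_factors`` may be a single factor or a
    year -> factor mapping).  The whole-body PET/CT fee is the sum of the
    PET/low-dose-CT item and the adjunctive localisation CT item; the
    confirmatory work-up is the composite of FNAB, a whole-body PET/CT and
    other tests.
    """
    import csv

    rows: dict[str, tuple[float, int]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(row for row in fh if not row.startswith("#"))
        for rec in reader:
            rows[rec["item_label"]] = (
                float(rec["raw_cost"]),
                int(rec["price_year"]),
            )
    required = set(_CONFIRMATORY_ITEMS) | {"clinic_visit", "treatment_stage_iv"}
    missing = required - rows.keys()
    if missing:
        raise ValueError(f"unit-cost table is missing items: {sorted(missing)}")

    def adjusted(label: str) -> float:
        raw, year = rows[label]
        factor = (
            cpi_factors if isinstance(cpi_factors, (int, float))
            else cpi_factors[year]
        )
        return raw * factor

    return CostInputs(
        imaging_unit_cost=sum(adjusted(i) for i in _IMAGING_ITEMS),
        confirmatory_workup_cost=sum(adjusted(i) for i in _CONFIRMATORY_ITEMS),
        clinic_visit_cost=adjusted("clinic_visit"),
        treatment_cost_stage_iv=adjusted("treatment_stage_iv"),
        cpi_factor=1.0,  # already applied per row
        discount_rate=discount_rate,
    )


# ---------------------------------------------------------------------------
# dotted parameter paths

def get_param(params: ModelParams, path: str) -> float:
    """Resolve a dotted path (attributes and dict keys) to its value."""
    obj: object = params
    for part in path.split("."):
        if isinstance(obj, dict):
            if part not in obj:
                raise KeyError(f"cannot resolve {path!r}: no key {part!r}")
            obj = obj[part]
        elif isinstance(obj, list):
            obj = obj[int(part)]
        else:
            if not hasattr(obj, part):
                raise KeyError(f"cannot resolve {path!r}: no attribute {part!r}")
            obj = getattr(obj, part)
    return obj  # type: ignore[return-value]


def with_updates(params: ModelParams, updates: dict[str, float]) -> ModelParams:
    """A deep copy of ``params`` with each dotted path set to its new value.

    The original is never mutated; sensitivity analyses stay pure.
    """
    new = params.model_copy(deep=True)
    for path, value in updates.items():
        parts = path.split(".")
        obj: object = new
        for part in parts[:-1]:
            if isinstance(obj, dict):
                obj = obj[part]
            elif isinstance(obj, list):
                obj = obj[int(part)]
            else:
                if not hasattr(obj, part):
                    raise KeyError(f"cannot resolve {path!r}: no attribute {part!r}")
                obj = getattr(obj, part)
        leaf = parts[-1]
        if isinstance(obj, dict):
            if leaf not in obj:
                raise KeyError(f"cannot resolve {path!r}: no key {leaf!r}")
            obj[leaf] = value
        else:
            if not hasattr(obj, leaf):
                raise KeyError(f"cannot resolve {path!r}: no attribute {leaf!r}")
            setattr(obj, leaf, value)
    # re-run validation on the mutated copy
    return ModelParams.model_validate(new.model_dump())


def set_param(params: ModelParams, path: str, value: float) -> ModelParams:
    return with_updates(params, {path: value})
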