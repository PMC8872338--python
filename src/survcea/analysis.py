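"""Model/Results facade over the surveillance cost-effectiveness pipeline.

``SurveillanceCEA`` is constructed from :class:`~survcea.params.ModelParams`
(or a JSON config); ``fit()`` evaluates the decision model and returns a
``CEAResults`` carrying per-strategy outcomes, the incremental tables for
both outcome metrics, and a text ``summary()``.  Sensitivity analyses hang
off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import cea, uncertainty
from .model import StrategyOutcome, compute_outcomes
from .params import MetricName, ModelParams

COMPARATOR_DEFAULT = "no_imaging"


class SurveillanceCEA:
    """The four-strategy surveillance decision model."""

    def __init__(self, params: ModelParams, comparator: str = COMPARATOR_DEFAULT):
        if comparator not in {s.name for s in params.strategies}:
            raise ValueError(f"comparator {comparator!r} is not a strategy")
        self.params = params
        self.comparator = comparator

    @classmethod
    def from_config(cls, path: str | Path, comparator: str = COMPARATOR_DEFAULT):
        return cls(ModelParams.from_json(path), comparator=comparator)

    def fit(self) -> "CEAResults":
        outcomes = compute_outcomes(self.params)
        tables = {
            metric: cea.incremental_vs_comparator(
                outcomes,
                comparator=self.comparator,
                metric=metric,
                wtp=self.params.wtp,
            )
            for metric in ("correct_diagnosis", "error_avoided")
        }
        return CEAResults(
            model=self, params=self.params, outcomes=outcomes, tables=tables
        )


@dataclass
class CEAResults:
    model: SurveillanceCEA
    params: ModelParams
    outcomes: list[StrategyOutcome]
    tables: dict[str, cea.CEATable]

    def table(self, metric: MetricName) -> cea.CEATable:
        return self.tables[metric]

    def outcome(self, strategy: str) -> StrategyOutcome:
        for o in self.outcomes:
            if o.name == strategy:
                return o
        raise KeyError(strategy)

    def icer(self, target: str, metric: MetricName | None = None) -> float:
        metric = metric or self.params.outcome_metric
        return uncertainty.icer_vs_comparator(
            self.params, target, self.model.comparator, metric
        )

    def tornado(
        self,
        ranges: Sequence[uncertainty.ParamRange],
        target: str = "twelve_monthly",
        metric: MetricName | None = None,
    ) -> list[uncertainty.TornadoEntry]:
        entries = [
            uncertainty.one_way_dsa(
                self.params, r, self.model.comparator, target, metric
            )
            for r in ranges
        ]
        return uncertainty.tornado(entries)

    def psa(
        self,
        specs: Sequence[uncertainty.DistributionSpec],
        n: int = 10_000,
        seed: int = 0,
        wtp_grid: np.ndarray | None = None,
        metric: MetricName | None = None,
    ) -> uncertainty.PSAResult:
        return uncertainty.run_psa(
            self.params, specs, n=n, seed=seed, wtp_grid=wtp_grid, metric=metric
        )

    def summary(self) -> str:
        lines = [
            "Surveillance imaging cost-effectiveness analysis",
            f"  horizon: {self.params.strategies[0].horizon_years:g} years, "
            f"discount rate: {self.params.costs.discount_rate:.0%}, "
            f"WTP: AUD {self.params.wtp:,.0f}/outcome",
            f"  comparator: {self.model.comparator}",
            "",
            "Outcome: distant recurrence correctly diagnosed and treated",
            self.tables["correct_diagnosis"].to_display_frame().to_string(index=False),
            "",
            "Outcome: diagnostic error avoided",
            self.tables["error_avoided"].to_display_frame().to_string(index=False),
        ]
        return "\n".join(lines)
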