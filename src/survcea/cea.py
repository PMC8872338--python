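"""Incremental cost-effectiveness analysis.

Ordering, strict and extended dominance, ICERs against a designated
comparator and along the efficiency frontier, and net monetary benefit.

Two reporting modes are produced: the comparator-anchored table (the
layout of the published base-case tables, with every strategy's increments
taken against the no-imaging comparator) and the sequential frontier table
(standard practice, with ICERs between adjacent frontier strategies).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import StrategyOutcome
from .params import MetricName

#: strategies on the frontier and not the comparator carry a numeric ICER
STATUS_COMPARATOR = "comparator"
STATUS_DOMINATED = "dominated"
STATUS_EXT_DOMINATED = "extendedly_dominated"
STATUS_COST_SAVING = "cost_saving_equal_effect"

#: ICERs above this are rendered as "Over AUD 1 M" in human-facing tables
ICER_DISPLAY_CAP = 1_000_000.0


@dataclass
class IncrementalRow:
    """One row of a comparator-anchored CEA table."""

    strategy: str
    mean_cost: float
    effect: float
    incr_cost: float | None = None
    incr_effect: float | None = None
    icer: float | None = None
    status: str | None = None  # comparator / dominated / extendedly_dominated
    tie: bool = False


@dataclass
class CEATable:
    rows: list[IncrementalRow]
    wtp: float
    comparator: str
    metric: str = ""
    icer_display_cap: float = ICER_DISPLAY_CAP

    def row(self, strategy: str) -> IncrementalRow:
        for r in self.rows:
            if r.strategy == strategy:
                return r
        raise KeyError(strategy)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "strategy": r.strategy,
                    "mean_cost": r.mean_cost,
                    "incr_cost": r.incr_cost,
                    "effect": r.effect,
                    "incr_effect": r.incr_effect,
                    "icer": r.icer,
                    "status": r.status,
                }
                for r in self.rows
            ]
        )

    def to_display_frame(self) -> pd.DataFrame:
        """Human-facing rendering: whole AUD, 4-decimal effects, capped ICERs."""
        recs = []
        for r in self.rows:
            if r.status == STATUS_COMPARATOR:
                icer_txt = "-"
            elif r.status in (STATUS_DOMINATED, STATUS_EXT_DOMINATED):
                icer_txt = "Dominated"
                if r.icer is not None and r.icer > self.icer_display_cap:
                    icer_txt += " (Over AUD 1 M)"
            elif r.status == STATUS_COST_SAVING:
                icer_txt = "Cost saving (equal effect)"
            elif r.icer is not None and r.icer > self.icer_display_cap:
                icer_txt = "Over AUD 1 M"
            elif r.icer is not None:
                icer_txt = f"{r.icer:,.0f}"
            else:
                icer_txt = "-"
            recs.append(
                {
                    "Strategy": r.strategy,
                    "Mean Cost (AUD)": f"{r.mean_cost:,.0f}",
                    "Incremental Cost (AUD)": (
                        "-" if r.incr_cost is None else f"{r.incr_cost:,.0f}"
                    ),
                    "Effectiveness": f"{r.effect:.4f}",
                    "Incremental Effectiveness": (
                        "-" if r.incr_effect is None else f"{r.incr_effect:.4f}"
                    ),
                    "ICER (AUD/Outcome)": icer_txt,
                }
            )
        return pd.DataFrame(recs)

    def to_csv(self, path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w", newline="") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.to_dataframe().to_csv(fh, index=False)


Point = tuple[str, float, float]  # (strategy, cost, effect)


def _as_points(
    outcomes: Iterable, metric: MetricName | None = None
) -> list[Point]:
    """Normalize outcomes to (name, cost, effect) triples.

    Accepts StrategyOutcome lists (``metric`` selects the effect and cost
    fields), (name, cost, effect) tuples, or a mapping name -> (cost, effect).
    """
    if isinstance(outcomes, Mapping):
        return [(str(k), float(c), float(e)) for k, (c, e) in outcomes.items()]
    points: list[Point] = []
    for item in outcomes:
        if isinstance(item, StrategyOutcome):
            m: MetricName = metric or "correct_diagnosis"
            points.append((item.name, item.cost_for(m), item.effect_for(m)))
        else:
            name, cost, effect = item
            points.append((str(name), float(cost), float(effect)))
    return points


@dataclass
class FrontierResult:
    """Dominance classification and the cost-sorted efficiency frontier."""

    status: dict[str, str]  # frontier / dominated / extendedly_dominated
    frontier: list[str]  # cost-ascending
    sequential_icers: dict[str, float | None]  # None for the cheapest
    ties: list[tuple[str, str]] = field(default_factory=list)


def dominance_frontier(
    outcomes: Iterable, metric: MetricName | None = None
) -> FrontierResult:
    """Classify strategies by strict and extended dominance.

    A strategy is strictly dominated if some other has cost <= and effect
    >= with at least one strict inequality.  Extended dominance removes
    strategies iteratively until sequential ICERs along the cost-sorted
    frontier are strictly increasing.  Exact ties in both cost and effect
    are both retained and flagged.
    """
    points = _as_points(outcomes, metric)
    if len(points) < 2:
        raise ValueError("dominance analysis needs at least two strategies")
    status: dict[str, str] = {}
    ties: list[tuple[str, str]] = []
    for name_i, cost_i, eff_i in points:
        dominated = False
        for name_j, cost_j, eff_j in points:
            if name_j == name_i:
                continue
            if cost_j == cost_i and eff_j == eff_i:
                if (name_j, name_i) not in ties:
                    ties.append((name_i, name_j))
                continue
            if cost_j <= cost_i and eff_j >= eff_i:
                dominated = True
                break
        status[name_i] = STATUS_DOMINATED if dominated else "frontier"

    survivors = sorted(
        (p for p in points if status[p[0]] == "frontier"),
        key=lambda p: (p[1], p[2]),
    )
    # iterative extended-dominance removal: sequential ICERs must increase
    changed = True
    while changed and len(survivors) > 2:
        changed = False
        for i in range(1, len(survivors) - 1):
            lo, mid, hi = survivors[i - 1], survivors[i], survivors[i + 1]
            icer_in = _safe_ratio(mid[1] - lo[1], mid[2] - lo[2])
            icer_out = _safe_ratio(hi[1] - mid[1], hi[2] - mid[2])
            if icer_in is not None and icer_out is not None and icer_in >= icer_out:
                status[mid[0]] = STATUS_EXT_DOMINATED
                survivors.pop(i)
                changed = True
                break

    seq: dict[str, float | None] = {}
    for i, (name, cost, eff) in enumerate(survivors):
        if i == 0:
            seq[name] = None
        else:
            prev = survivors[i - 1]
            seq[name] = _safe_ratio(cost - prev[1], eff - prev[2])
    return FrontierResult(
        status=status,
        frontier=[p[0] for p in survivors],
        sequential_icers=seq,
        ties=ties,
    )


def _safe_ratio(dc: float, de: float) -> float | None:
    if de == 0:
        return math.inf if dc > 0 else None
    return dc / de


def incremental_vs_comparator(
    outcomes: Iterable,
    comparator: str,
    metric: MetricName | None = None,
    wtp: float = 50_000.0,
) -> CEATable:
    """Comparator-anchored incremental analysis with dominance labels.

    Increments are signed differences against the comparator; rows are
    sorted by mean cost ascending.  Strategies off the frontier carry a
    dominance status instead of an ICER; an increment with zero effect
    difference is never reported as a division result.
    """
    points = _as_points(outcomes, metric)
    names = [p[0] for p in points]
    if comparator not in names:
        raise ValueError(f"unknown comparator {comparator!r}; have {names}")
    if metric is not None and metric not in ("correct_diagnosis", "error_avoided"):
        raise ValueError(f"unknown metric {metric!r}")
    frontier = dominance_frontier(points)
    comp_cost, comp_eff = next((c, e) for n, c, e in points if n == comparator)
    rows = []
    for name, cost, eff in sorted(points, key=lambda p: (p[1], p[2])):
        row = IncrementalRow(strategy=name, mean_cost=cost, effect=eff)
        row.tie = any(name in t for t in frontier.ties)
        if name == comparator:
            row.status = STATUS_COMPARATOR
        else:
            row.incr_cost = cost - comp_cost
            row.incr_effect = eff - comp_eff
            if frontier.status[name] != "frontier":
                row.status = frontier.status[name]
                row.icer = None
            elif row.incr_effect == 0:
                row.status = (
                    STATUS_DOMINATED if row.incr_cost > 0 else STATUS_COST_SAVING
                )
            else:
                row.icer = row.incr_cost / row.incr_effect
        rows.append(row)
    return CEATable(
        rows=rows, wtp=wtp, comparator=comparator, metric=metric or ""
    )


def sequential_frontier_table(
    outcomes: Iterable, metric: MetricName | None = None, wtp: float = 50_000.0
) -> pd.DataFrame:
    """The standard frontier report: adjacent-strategy ICERs, cost-ascending."""
    points = _as_points(outcomes, metric)
    res = dominance_frontier(points)
    by_name = {n: (c, e) for n, c, e in points}
    recs = []
    for name, _, _ in sorted(points, key=lambda p: (p[1], p[2])):
        cost, eff = by_name[name]
        recs.append(
            {
                "strategy": name,
                "mean_cost": cost,
                "effect": eff,
                "status": res.status[name],
                "sequential_icer": res.sequential_icers.get(name),
            }
        )
    return pd.DataFrame(recs)


def nmb(cost: float, effect: float, wtp: float) -> float:
    """Net monetary benefit: wtp * effect − cost."""
    if wtp < 0:
        raise ValueError("wtp must be >= 0")
    return wtp * effect - cost
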