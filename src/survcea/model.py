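"""Build and evaluate the four-strategy melanoma surveillance decision tree.

Each strategy is a chain of scheduled observation events (PET/CT visits, or
clinical reviews in the no-imaging arm) over a 5-year horizon.  Distant
recurrence arises with a constant hazard derived from the group's 5-year
cumulative probability; a recurrence arising within an interval is assumed
present at the next scheduled visit.  At each visit the patient's true
status is tested, yielding TP/FP/TN/FN branches:

* TP (or clinical detection) is absorbing — the cohort is censored at the
  first diagnosed distant recurrence;
* FN patients carry their undetected recurrence forward and may be caught
  at a later visit or remain undetected at the horizon;
* FP and TN patients continue on schedule.

Cost attachment: every attended visit accrues the imaging fee (imaging
arms) plus a clinic fee; the confirmatory work-up is accrued on TP, FP and
FN imaging results (clinicians work up equivocal findings even when the
scan reads negative); stage-IV treatment is accrued whenever distant
disease is eventually diagnosed, but only under the correct-diagnosis
outcome — the diagnostic-error outcome costs exclude treatment.

Two effectiveness metrics are supported, each in two modes:

``proportion`` (default)
    correct_diagnosis: P(no recurrence) + P(recurrence eventually
    diagnosed within the horizon).
    error_avoided: P(no diagnostic error over the horizon), an error being
    any false-positive episode or any missed (false-negative) test of an
    established recurrence.
``difference``
    The expected tally differences E[TP] − E[FN] and E[TN] − E[FP],
    the literal difference definition; these live on a count scale, not a
    proportion scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

from .params import MetricName, ModelParams, StrategySpec
from .tree import (
    CHANCE,
    DECISION,
    TERMINAL,
    DecisionTree,
    Node,
    Payoff,
    evaluate_node,
)

METRICS: tuple[MetricName, ...] = ("correct_diagnosis", "error_avoided")

# internal patient states along a strategy chain
_H_CLEAN = "disease_free"          # no recurrence, no diagnostic error yet
_H_ERR = "disease_free_post_error"  # no recurrence, at least one FP occurred
_R = "recurrent_undetected"         # recurrence present, missed so far (FN)


class Counts(NamedTuple):
    tp: float
    fp: float
    tn: float
    fn: float


def hazard_from_cumulative(cum_prob: float, horizon: float) -> float:
    """Constant yearly hazard matching a cumulative event probability.

    Solves 1 − exp(−λ·horizon) = cum_prob for λ.
    """
    if not (0.0 <= cum_prob < 1.0):
        raise ValueError(f"cum_prob={cum_prob} must be in [0, 1)")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    return -math.log1p(-cum_prob) / horizon


def interval_recurrence_prob(hazard: float, interval: float) -> float:
    """Probability of the event within one interval under a constant hazard."""
    if hazard < 0:
        raise ValueError("hazard must be >= 0")
    if interval <= 0:
        raise ValueError("interval must be positive")
    return -math.expm1(-hazard * interval)


def confusion_branches(
    prevalence: float, sensitivity: float, specificity: float
) -> list[tuple[str, float]]:
    """The four diagnostic outcome probabilities for one test.

    Returns (label, probability) pairs for TP, FN, FP, TN; they sum to 1
    exactly by construction.
    """
    for name, v in (
        ("prevalence", prevalence),
        ("sensitivity", sensitivity),
        ("specificity", specificity),
    ):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}={v} must be in [0, 1]")
    return [
        ("TP", prevalence * sensitivity),
        ("FN", prevalence * (1.0 - sensitivity)),
        ("FP", (1.0 - prevalence) * (1.0 - specificity)),
        ("TN", (1.0 - prevalence) * specificity),
    ]


def build_strategy_tree(
    spec: StrategySpec,
    params: ModelParams,
    metric: MetricName | None = None,
    include_treatment_cost: bool | None = None,
) -> Node:
    """The chance-node subtree for one surveillance strategy.

    ``metric`` selects which proportion-scale effectiveness the terminal
    nodes carry; TP/FP/TN/FN tallies are annotated on branches regardless,
    so difference-mode effects can be derived from the same tree.
    ``include_treatment_cost`` defaults to True for the correct-diagnosis
    outcome and False for the error-avoided outcome.

    Continuation subtrees are shared between branches (the result is a
    rooted DAG), keeping the node count linear in the number of visits.
    """
    metric = metric or params.outcome_metric
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if include_treatment_cost is None:
        include_treatment_cost = metric == "correct_diagnosis"

    n_events = round(spec.events_per_year * spec.horizon_years)
    if n_events <= 0:
        raise ValueError(
            f"strategy {spec.name!r} schedules no imaging visits and no "
            "clinical reviews; nothing can be observed"
        )
    horizon = spec.horizon_years
    dt = horizon / n_events
    costs = params.costs
    if spec.imaging:
        det_prob = params.test.sensitivity
        fp_rate = 1.0 - params.test.specificity
        visit_cost = costs.adjusted(costs.imaging_unit_cost + costs.clinic_visit_cost)
        conf_on_fn = True  # equivocal imaging findings get worked up
        conf_on_fp = True
    else:
        det_prob = params.epi.clinical_detection_prob
        fp_rate = params.epi.clinical_fp_rate
        visit_cost = costs.adjusted(costs.clinic_visit_cost)
        conf_on_fn = False  # a clinical miss triggers no investigations
        conf_on_fp = True
    conf_cost = costs.adjusted(costs.confirmatory_workup_cost)
    treat_cost = costs.adjusted(costs.treatment_cost_stage_iv)

    lam = hazard_from_cumulative(
        params.epi.cum_recurrence_prob_5y[spec.name], horizon
    )
    q = interval_recurrence_prob(lam, dt)

    def terminal_effect(state: str, detected: bool) -> float:
        if metric == "correct_diagnosis":
            # non-recurrent patients are correctly resolved; recurrent ones
            # only if eventually diagnosed
            return 1.0 if (detected or state in (_H_CLEAN, _H_ERR)) else 0.0
        # error_avoided: no FP ever and no FN ever
        return 1.0 if state == _H_CLEAN else 0.0

    memo: dict[tuple[int, str], Node] = {}

    def detection_leaf(k: int, state: str) -> Node:
        t = k * dt
        cost = conf_cost + (treat_cost if include_treatment_cost else 0.0)
        return Node(
            TERMINAL,
            label=f"{spec.name}_v{k}_detected",
            payoff=Payoff(cost=cost, effect=terminal_effect(state, detected=True)),
            accrual_time=t,
            counts=(1.0, 0.0, 0.0, 0.0),
        )

    def continue_via(
        k: int, label: str, cost: float, counts: Counts, next_state: str
    ) -> Node:
        """A branch wrapper carrying its payoff, then the shared next node."""
        return Node(
            CHANCE,
            label=f"{spec.name}_v{k}_{label}",
            payoff=Payoff(cost=cost),
            accrual_time=k * dt,
            counts=tuple(counts),
            children=[(1.0, node_at(k + 1, next_state))],
        )

    def node_at(k: int, state: str) -> Node:
        key = (k, state)
        cached = memo.get(key)
        if cached is not None:
            return cached
        if k > n_events:
            node = Node(
                TERMINAL,
                label=f"{spec.name}_end_{state}",
                payoff=Payoff(effect=terminal_effect(state, detected=False)),
                accrual_time=horizon,
            )
            memo[key] = node
            return node
        t = k * dt
        branches: list[tuple[float, Node]] = []
        if state == _R:
            if det_prob > 0:
                branches.append((det_prob, detection_leaf(k, state)))
            if det_prob < 1:
                branches.append(
                    (
                        1.0 - det_prob,
                        continue_via(
                            k, "FN", conf_cost if conf_on_fn else 0.0,
                            Counts(0, 0, 0, 1), _R,
                        ),
                    )
                )
        else:
            p_tp = q * det_prob
            p_fn = q * (1.0 - det_prob)
            p_fp = (1.0 - q) * fp_rate
            p_tn = (1.0 - q) * (1.0 - fp_rate)
            if p_tp > 0:
                branches.append((p_tp, detection_leaf(k, state)))
            if p_fn > 0:
                branches.append(
                    (
                        p_fn,
                        continue_via(
                            k, "FN", conf_cost if conf_on_fn else 0.0,
                            Counts(0, 0, 0, 1), _R,
                        ),
                    )
                )
            if p_fp > 0:
                branches.append(
                    (
                        p_fp,
                        continue_via(
                            k, "FP", conf_cost if conf_on_fp else 0.0,
                            Counts(0, 1, 0, 0), _H_ERR,
                        ),
                    )
                )
            if p_tn > 0:
                branches.append(
                    (p_tn, continue_via(k, "TN", 0.0, Counts(0, 0, 1, 0), state))
                )
        node = Node(
            CHANCE,
            label=f"{spec.name}_visit{k}_{state}",
            payoff=Payoff(cost=visit_cost),
            accrual_time=t,
            children=branches,
        )
        memo[key] = node
        return node

    root = node_at(1, _H_CLEAN)
    root.label = spec.name
    return root


def build_decision_tree(
    params: ModelParams,
    metric: MetricName | None = None,
    include_treatment_cost: bool | None = None,
) -> DecisionTree:
    """The full four-strategy model: a decision node over strategy subtrees."""
    root = Node(
        DECISION,
        label="surveillance_strategy",
        children=[
            build_strategy_tree(s, params, metric, include_treatment_cost)
            for s in params.strategies
        ],
    )
    return DecisionTree(root=root, strategy_labels=[s.name for s in params.strategies])


@dataclass
class StrategyOutcome:
    """Per-strategy expected discounted cost and effectiveness.

    The expected cost differs by outcome metric because stage-IV treatment
    costs enter only the correct-diagnosis analysis.
    """

    name: str
    expected_cost: float                 # correct-diagnosis costing (incl. treatment)
    expected_cost_error_avoided: float   # diagnostic-error costing (excl. treatment)
    effect_correct_diagnosis: float
    effect_error_avoided: float
    expected_counts: Counts

    def cost_for(self, metric: MetricName) -> float:
        return (
            self.expected_cost
            if metric == "correct_diagnosis"
            else self.expected_cost_error_avoided
        )

    def effect_for(self, metric: MetricName) -> float:
        return (
            self.effect_correct_diagnosis
            if metric == "correct_diagnosis"
            else self.effect_error_avoided
        )


def _outcome_for_strategy(
    spec: StrategySpec, params: ModelParams, metrics: tuple[MetricName, ...]
) -> dict[MetricName, tuple[float, float, Counts]]:
    out: dict[MetricName, tuple[float, float, Counts]] = {}
    for metric in metrics:
        node = build_strategy_tree(spec, params, metric=metric)
        val = evaluate_node(
            node,
            discount_rate=params.costs.discount_rate,
            discount_effects=params.discount_effects,
        )
        counts = Counts(*val.counts)
        if params.metric_mode == "difference":
            effect = (
                counts.tp - counts.fn
                if metric == "correct_diagnosis"
                else counts.tn - counts.fp
            )
        else:
            effect = val.effect
        out[metric] = (val.cost, effect, counts)
    return out


def compute_outcomes(params: ModelParams) -> list[StrategyOutcome]:
    """Evaluate every strategy under both outcome metrics."""
    outcomes = []
    for spec in params.strategies:
        per_metric = _outcome_for_strategy(spec, params, METRICS)
        cost_cd, eff_cd, counts = per_metric["correct_diagnosis"]
        cost_ea, eff_ea, _ = per_metric["error_avoided"]
        outcomes.append(
            StrategyOutcome(
                name=spec.name,
                expected_cost=cost_cd,
                expected_cost_error_avoided=cost_ea,
                effect_correct_diagnosis=eff_cd,
                effect_error_avoided=eff_ea,
                expected_counts=counts,
            )
        )
    return outcomes


def compute_metric_points(
    params: ModelParams, metric: MetricName
) -> dict[str, tuple[float, float]]:
    """(expected cost, effect) per strategy for a single metric.

    Cheaper than :func:`compute_outcomes` when only one metric is needed
    (one tree build per strategy); used by the sensitivity analyses.
    """
    points: dict[str, tuple[float, float]] = {}
    for spec in params.strategies:
        per_metric = _outcome_for_strategy(spec, params, (metric,))
        cost, effect, _ = per_metric[metric]
        points[spec.name] = (cost, effect)
    return points
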