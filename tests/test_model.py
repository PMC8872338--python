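"""Surveillance model: hazards, confusion branches, tree construction, outcomes."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from survcea.model import (
    Counts,
    build_strategy_tree,
    compute_outcomes,
    confusion_branches,
    hazard_from_cumulative,
    interval_recurrence_prob,
)
from survcea.params import ModelParams
from survcea.tree import DECISION, DecisionTree, Node, enumerate_paths, evaluate_node
from survcea.params import with_updates


class TestHazard:
    def test_zero_probability_gives_zero_hazard(self):
        assert hazard_from_cumulative(0.0, 5.0) == 0.0

    def test_half_in_one_year_is_log_two(self):
        assert hazard_from_cumulative(0.5, 1.0) == pytest.approx(math.log(2), rel=1e-14)

    @given(p=st.floats(0.0, 0.99), horizon=st.floats(0.5, 20.0))
    @settings(max_examples=200, derandomize=True)
    def test_inverse_round_trip(self, p, horizon):
        lam = hazard_from_cumulative(p, horizon)
        assert -math.expm1(-lam * horizon) == pytest.approx(p, abs=1e-12)

    def test_certain_event_rejected(self):
        with pytest.raises(ValueError):
            hazard_from_cumulative(1.0, 5.0)

    def test_interval_prob_zero_hazard(self):
        assert interval_recurrence_prob(0.0, 0.25) == 0.0

    def test_interval_prob_inverts_cumulative(self):
        lam = hazard_from_cumulative(0.3, 5.0)
        assert interval_recurrence_prob(lam, 5.0) == pytest.approx(0.3, abs=1e-12)

    def test_composition_identity(self):
        lam = 0.17
        q_half = interval_recurrence_prob(lam, 0.5)
        composed = 1.0 - (1.0 - q_half) ** 2
        assert composed == pytest.approx(interval_recurrence_prob(lam, 1.0), abs=1e-14)


class TestConfusionBranches:
    def test_zero_prevalence(self):
        branches = dict(confusion_branches(0.0, 0.79, 0.9))
        assert branches["TP"] == 0 and branches["FN"] == 0
        assert branches["FP"] == pytest.approx(0.1)
        assert branches["TN"] == pytest.approx(0.9)

    def test_full_prevalence_base_case_sensitivity(self):
        branches = dict(confusion_branches(1.0, 0.79, 0.9))
        assert branches["TP"] == pytest.approx(0.79)
        assert branches["FN"] == pytest.approx(0.21)
        assert branches["FP"] == 0 and branches["TN"] == 0

    @given(
        prev=st.floats(0, 1), se=st.floats(0, 1), sp=st.floats(0, 1)
    )
    @settings(max_examples=200, derandomize=True)
    def test_probabilities_sum_to_one(self, prev, se, sp):
        total = sum(p for _, p in confusion_branches(prev, se, sp))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            confusion_branches(1.2, 0.5, 0.5)


def _one_visit_params(base: ModelParams, prevalence=0.1, se=0.79, sp=0.9) -> ModelParams:
    """Horizon-1, single-visit toy configuration for closed-form checks."""
    p = base.model_copy(deep=True)
    for s in p.strategies:
        s.horizon_years = 1.0
        if s.name == "twelve_monthly":
            s.visits_per_year = 1
        elif s.name == "no_imaging":
            s.visits_per_year = 0
            s.reviews_per_year = 1
    p.test.sensitivity = se
    p.test.specificity = sp
    p.epi.cum_recurrence_prob_5y = {s.name: prevalence for s in p.strategies}
    return ModelParams.model_validate(p.model_dump())


class TestBuildStrategyTree:
    def test_one_visit_leaf_probabilities(self, base_params):
        params = _one_visit_params(base_params)
        node = build_strategy_tree(params.strategy("twelve_monthly"), params)
        tree = DecisionTree(root=Node(DECISION, label="root", children=[node]))
        paths = enumerate_paths(tree)
        probs = sorted(round(p.probability, 12) for p in paths)
        assert probs == sorted([0.079, 0.021, 0.09, 0.81])

    def test_perfect_clinical_detection_resolves_everyone(self, base_params):
        params = base_params.model_copy(deep=True)
        params.epi.clinical_detection_prob = 1.0
        params = ModelParams.model_validate(params.model_dump())
        out = {o.name: o for o in compute_outcomes(params)}
        assert out["no_imaging"].effect_correct_diagnosis == pytest.approx(1.0)

    def test_perfect_test_no_errors(self, base_params):
        params = with_updates(
            base_params,
            {
                "test.sensitivity": 1.0,
                "test.specificity": 1.0,
                "epi.clinical_detection_prob": 1.0,
            },
        )
        for o in compute_outcomes(params):
            assert o.effect_correct_diagnosis == pytest.approx(1.0)
            assert o.effect_error_avoided == pytest.approx(1.0)
            assert o.expected_counts.fp == pytest.approx(0.0)
            assert o.expected_counts.fn == pytest.approx(0.0)

    def test_perfect_test_closed_form_cost(self, base_params):
        """Se=Sp=1: detection happens at the first post-recurrence visit, so
        the expected cost has a hand-assembled closed form."""
        params = with_updates(
            base_params, {"test.sensitivity": 1.0, "test.specificity": 1.0}
        )
        spec = params.strategy("twelve_monthly")
        r = params.costs.discount_rate
        lam = hazard_from_cumulative(
            params.epi.cum_recurrence_prob_5y["twelve_monthly"], spec.horizon_years
        )
        q = interval_recurrence_prob(lam, 1.0)
        visit_cost = params.costs.imaging_unit_cost + params.costs.clinic_visit_cost
        detect_cost = (
            params.costs.confirmatory_workup_cost + params.costs.treatment_cost_stage_iv
        )
        expected = 0.0
        for k in range(1, 6):
            attend = math.exp(-lam * (k - 1))  # alive-and-undetected before visit k
            disc = (1 + r) ** -k
            expected += attend * visit_cost * disc
            expected += attend * q * detect_cost * disc
        node = build_strategy_tree(spec, params, metric="correct_diagnosis")
        val = evaluate_node(node, discount_rate=r)
        assert val.cost == pytest.approx(expected, rel=1e-12)

    def test_zero_schedule_rejected(self, base_params):
        params = base_params.model_copy(deep=True)
        spec = params.strategy("no_imaging").model_copy(
            update={"visits_per_year": 0, "reviews_per_year": 0}
        )
        with pytest.raises(ValueError, match="nothing can be observed"):
            build_strategy_tree(spec, params)

    def test_tally_mass_matches_enumeration(self, base_params):
        """Probability-weighted TP/FP/TN/FN tallies agree with an
        independent path walk that sums counts along each path."""
        params = base_params
        spec = params.strategy("twelve_monthly")
        node = build_strategy_tree(spec, params)

        acc = Counts(0.0, 0.0, 0.0, 0.0)

        def walk(n, prob, counts):
            nonlocal acc
            if n.counts is not None:
                counts = tuple(c + i for c, i in zip(counts, n.counts))
            kids = n.children if n.kind != "chance" else n.children
            if not kids:
                acc = Counts(*(a + prob * c for a, c in zip(acc, counts)))
                return
            for p, child in kids:
                walk(child, prob * p, counts)

        walk(node, 1.0, (0.0, 0.0, 0.0, 0.0))
        val = evaluate_node(node)
        for got, want in zip(val.counts, acc):
            assert got == pytest.approx(want, abs=1e-12)


class TestOutcomeMonotonicity:
    @pytest.mark.parametrize("metric_attr,param,counts_attr", [
        ("effect_correct_diagnosis", "test.sensitivity", "fn"),
        ("effect_error_avoided", "test.specificity", "fp"),
    ])
    def test_better_test_never_hurts(self, base_params, metric_attr, param, counts_attr):
        values = [0.5, 0.7, 0.9, 0.99]
        effects, counts = [], []
        for v in values:
            out = {o.name: o for o in compute_outcomes(with_updates(base_params, {param: v}))}
            effects.append(getattr(out["twelve_monthly"], metric_attr))
            counts.append(getattr(out["twelve_monthly"].expected_counts, counts_attr))
        assert all(a <= b + 1e-12 for a, b in zip(effects, effects[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(counts, counts[1:]))

    def test_frequency_never_reduces_imaging_cost(self, base_params):
        """Undiscounted imaging spend is non-decreasing in visit frequency
        when recurrence risk is held equal across groups."""
        params = base_params.model_copy(deep=True)
        params.epi.cum_recurrence_prob_5y = {
            s.name: 0.4 for s in params.strategies
        }
        params.costs.imaging_unit_cost = 1.0
        params.costs.clinic_visit_cost = 0.0
        params.costs.confirmatory_workup_cost = 0.0
        params.costs.treatment_cost_stage_iv = 0.0
        params.costs.discount_rate = 0.0
        params = ModelParams.model_validate(params.model_dump())
        out = {o.name: o for o in compute_outcomes(params)}
        ordered = ["no_imaging", "twelve_monthly", "six_monthly", "three_four_monthly"]
        costs = [out[n].expected_cost for n in ordered]
        assert all(a <= b + 1e-12 for a, b in zip(costs, costs[1:]))

    def test_zero_costs_zero_rate_give_zero_cost(self, base_params):
        params = with_updates(
            base_params,
            {
                "costs.imaging_unit_cost": 0.0,
                "costs.clinic_visit_cost": 0.0,
                "costs.confirmatory_workup_cost": 0.0,
                "costs.treatment_cost_stage_iv": 0.0,
                "costs.discount_rate": 0.0,
            },
        )
        for o in compute_outcomes(params):
            assert o.expected_cost == 0.0
            assert o.expected_cost_error_avoided == 0.0

    def test_difference_mode_matches_count_tallies(self, base_params):
        params = base_params.model_copy(deep=True)
        params.metric_mode = "difference"
        diff = {o.name: o for o in compute_outcomes(params)}
        prop = {o.name: o for o in compute_outcomes(base_params)}
        for name, o in diff.items():
            c = prop[name].expected_counts
            assert o.effect_correct_diagnosis == pytest.approx(c.tp - c.fn)
            assert o.effect_error_avoided == pytest.approx(c.tn - c.fp)

    def test_treatment_cost_only_in_correct_diagnosis_costing(self, base_params):
        out = {o.name: o for o in compute_outcomes(base_params)}
        no_treat = with_updates(base_params, {"costs.treatment_cost_stage_iv": 0.0})
        out0 = {o.name: o for o in compute_outcomes(no_treat)}
        for name in out:
            # error-avoided costing never contains treatment costs
            assert out[name].expected_cost_error_avoided == pytest.approx(
                out0[name].expected_cost_error_avoided
            )
            # correct-diagnosis costing does (every arm detects someone)
            assert out[name].expected_cost > out0[name].expected_cost


class TestUnitCostTable:
    def test_composite_costs_from_schedule_items(self, tmp_path):
        from importlib.resources import files

        from survcea.params import load_unit_costs

        src = files("survcea.data").joinpath("example_unit_costs.csv").read_text()
        path = tmp_path / "costs.csv"
        path.write_text(src)
        costs = load_unit_costs(path, cpi_factors=1.0)
        # whole-body PET/CT = PET/low-dose-CT item + adjunctive CT item
        assert costs.imaging_unit_cost == pytest.approx(1128.75)
        # confirmatory composite = FNAB + whole-body PET/CT + other tests
        assert costs.confirmatory_workup_cost == pytest.approx(75.05 + 1128.75 + 300.0)
        assert costs.treatment_cost_stage_iv == pytest.approx(115072.0)

    def test_cpi_factor_applied_per_price_year(self, tmp_path):
        from survcea.params import load_unit_costs

        path = tmp_path / "costs.csv"
        path.write_text(
            "item_label,mbs_or_drg_code,raw_cost,price_year\n"
            "pet_low_dose_ct,61553,900,2018\n"
            "adjunctive_ct,61505,100,2018\n"
            "fnab,30094,70,2020\n"
            "other_tests,,300,2020\n"
            "clinic_visit,105,80,2018\n"
            "treatment_stage_iv,,100000,2020\n"
        )
        costs = load_unit_costs(path, cpi_factors={2018: 1.05, 2020: 1.0})
        assert costs.imaging_unit_cost == pytest.approx(1000 * 1.05)
        assert costs.clinic_visit_cost == pytest.approx(84.0)
        assert costs.treatment_cost_stage_iv == pytest.approx(100000.0)

    def test_missing_item_rejected(self, tmp_path):
        from survcea.params import load_unit_costs

        path = tmp_path / "costs.csv"
        path.write_text(
            "item_label,mbs_or_drg_code,raw_cost,price_year\n"
            "clinic_visit,105,80,2020\n"
        )
        with pytest.raises(ValueError, match="missing items"):
            load_unit_costs(path)
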