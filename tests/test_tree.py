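"""Decision-tree construction, QALM valuation and roll-back."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uticea import (
    STRATEGIES,
    build_decision_tree,
    enumerate_paths,
    expected_values,
    qalm_auc,
)
from uticea.tree import TerminalNode, ChanceNode


class TestQalmAuc:
    @pytest.mark.parametrize(
        "segments, expected",
        [
            ([(30, 1.0)], 1.0),
            ([(30, 0.0)], 0.0),
            ([(14, 0.68), (16, 0.83)], 0.76),
            ([(14, 0.68), (16, 0.76)], (14 * 0.68 + 16 * 0.76) / 30),
        ],
    )
    def test_area_under_curve(self, segments, expected):
        assert qalm_auc(segments, 30) == pytest.approx(expected, abs=1e-12)

    def test_rejects_incomplete_horizon(self):
        with pytest.raises(ValueError, match="deficit"):
            qalm_auc([(14, 0.68)], 30)

    def test_rejects_out_of_range_utility(self):
        with pytest.raises(ValueError, match="utility"):
            qalm_auc([(30, 1.2)], 30)

    @given(
        u1=st.floats(0, 1), u2=st.floats(0, 1),
        d1=st.integers(1, 29),
    )
    @settings(max_examples=50, deadline=None)
    def test_bounded_by_extreme_utilities(self, u1, u2, d1):
        q = qalm_auc([(d1, u1), (30 - d1, u2)], 30)
        assert min(u1, u2) - 1e-12 <= q <= max(u1, u2) + 1e-12


class TestBuildTree:
    def test_persistence_probability_matches_complement(self, params, structure):
        tree = build_decision_tree(params, structure)
        node = tree.strategies["pharmacist"]
        probs = {child.label if isinstance(child, TerminalNode) else "persist": p
                 for p, child in node.branches}
        assert probs["cured_initial"] == pytest.approx(0.886)
        assert probs["persist"] == pytest.approx(0.114)

    def test_certain_cure_prunes_persistence_subtree(self, params, structure):
        sure = params.replace(cure_rate={s: 1.0 for s in STRATEGIES})
        tree = build_decision_tree(sure, structure)
        for s in STRATEGIES:
            assert isinstance(tree.strategies[s], TerminalNode)

    def test_pharmacist_extend_terminal_cost(self, params, structure):
        """Second pharmacist visit plus a repeat antibiotic course."""
        tree = build_decision_tree(params, structure)
        terminals = {t.label: t for _, t in enumerate_paths(tree.strategies["pharmacist"])}
        assert terminals["persisted_extend"].cost == pytest.approx(
            23.00 + 14.47 + 23.00 + 14.47
        )
        assert terminals["persisted_switch"].cost == pytest.approx(
            23.00 + 14.47 + 23.00 + 18.47
        )

    def test_unknown_followup_provider_rejected(self, params, structure):
        from uticea import ConfigurationError

        bad = structure.replace(
            followup_provider={**structure.followup_provider, "family": "nurse"}
        )
        with pytest.raises(ConfigurationError, match="nurse"):
            build_decision_tree(params, bad)

    def test_branch_probabilities_validated(self):
        with pytest.raises(ValueError, match="sum"):
            ChanceNode("bad", ((0.5, TerminalNode("a", 0, ((30, 0.5),))),))


class TestExpectedValues:
    def test_certain_cure_cost_is_initial_contact_only(self, params, structure):
        sure = params.replace(cure_rate={s: 1.0 for s in STRATEGIES})
        out = {o.strategy: o for o in expected_values(build_decision_tree(sure, structure))}
        assert out["pharmacist"].expected_cost == pytest.approx(37.47)
        assert out["family"].expected_cost == pytest.approx(77.20 + 16.90)
        assert out["emergency"].expected_cost == pytest.approx(304.80 + 16.90)

    def test_reference_case_pharmacist_cost(self, params, structure):
        out = {o.strategy: o for o in expected_values(build_decision_tree(params, structure))}
        expected = 37.47 + 0.114 * (23.00 + 0.5 * 14.47 + 0.5 * 18.47)
        assert out["pharmacist"].expected_cost == pytest.approx(expected)
        assert out["pharmacist"].expected_cost == pytest.approx(41.96958)

    def test_rollback_equals_path_enumeration(self, params, structure):
        """Exhaustive oracle: weight every root-to-terminal path by its
        probability and compare to the recursive roll-back."""
        from uticea.tree import qalm_auc as q

        tree = build_decision_tree(params, structure)
        for outcome in expected_values(tree):
            paths = list(enumerate_paths(tree.strategies[outcome.strategy]))
            assert sum(p for p, _ in paths) == pytest.approx(1.0, abs=1e-12)
            cost = sum(p * t.cost for p, t in paths)
            qalm = sum(p * q(t.trajectory, tree.horizon_days) for p, t in paths)
            assert outcome.expected_cost == pytest.approx(cost, abs=1e-9)
            assert outcome.expected_qalm == pytest.approx(qalm, abs=1e-12)

    @given(
        cure=st.floats(0.01, 0.99),
        p_ext=st.floats(0.0, 1.0),
        u=st.floats(0.05, 0.95),
    )
    @settings(max_examples=50, deadline=None)
    def test_constant_utility_gives_qalm_equal_to_it(self, params, structure, cure, p_ext, u):
        p = params.replace(
            cure_rate={s: cure for s in STRATEGIES},
            utility={k: u for k in params.utility},
            p_extend_vs_switch=p_ext,
        )
        for o in expected_values(build_decision_tree(p, structure)):
            assert o.expected_qalm == pytest.approx(u, abs=1e-12)

    def test_cost_monotone_in_persistence_rate(self, params, structure):
        costs = []
        for cure in (0.95, 0.90, 0.85, 0.80):
            p = params.replace(cure_rate={s: cure for s in STRATEGIES})
            out = expected_values(build_decision_tree(p, structure))
            costs.append([o.expected_cost for o in out])
        arr = np.array(costs)
        assert (np.diff(arr, axis=0) > 0).all()

    def test_cost_bounded_by_terminal_extremes(self, params, structure):
        tree = build_decision_tree(params, structure)
        for o in expected_values(tree):
            terminal_costs = [t.cost for _, t in enumerate_paths(tree.strategies[o.strategy])]
            assert min(terminal_costs) <= o.expected_cost <= max(terminal_costs)
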