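"""Sequential dominance analysis and acceptability curves."""

import numpy as np
import pytest

from uticea import StrategyOutcome, ceac, icer, run_psa, sequential_cea
from uticea.frontier import DOMINATED, EXTENDED_DOMINATED, ON_FRONTIER


def nmb_enumeration_frontier(outcomes, extra_grid=None):
    """Independent oracle: a strategy is on the frontier iff some
    willingness-to-pay value makes it the unique NMB maximiser.

    Candidate WTP values are 0, midpoints between all distinct pairwise
    ICER slopes, and a value beyond the largest slope, optionally topped up
    with a dense grid.
    """
    costs = np.array([o.expected_cost for o in outcomes])
    effects = np.array([o.expected_qalm for o in outcomes])
    slopes = []
    for i in range(len(outcomes)):
        for j in range(len(outcomes)):
            de = effects[j] - effects[i]
            if de > 0:
                slopes.append((costs[j] - costs[i]) / de)
    slopes = sorted({s for s in slopes if s > 0})
    candidates = [0.0]
    for a, b in zip(slopes, slopes[1:]):
        candidates.append((a + b) / 2)
    if slopes:
        candidates += [slopes[0] / 2, slopes[-1] * 2 + 1]
    if extra_grid is not None:
        candidates += list(extra_grid)
    on = set()
    for w in candidates:
        nmb = w * effects - costs
        best = nmb.max()
        winners = np.flatnonzero(nmb == best)
        if len(winners) == 1:
            on.add(outcomes[winners[0]].strategy)
    return on


class TestSequentialCea:
    def test_reference_case_family_vs_pharmacist_icer(self):
        """ICER from the published mean costs and QALMs."""
        res = sequential_cea(
            [
                StrategyOutcome("pharmacist", 72.47, 0.75137),
                StrategyOutcome("family", 141.53, 0.75142),
                StrategyOutcome("emergency", 368.16, 0.75146),
            ]
        )
        assert res.icer_of("family") == pytest.approx(1_381_200, abs=1)
        # textbook rule: the ED step ICER (~5.67M) still increases along the
        # ladder, so ED stays on the frontier at the printed rounding
        assert res.status_of("emergency") == ON_FRONTIER
        assert res.icer_of("emergency") == pytest.approx(5_665_750, abs=1)

    def test_single_strategy(self):
        res = sequential_cea([StrategyOutcome("only", 10.0, 0.5)])
        assert res.frontier == ["only"]
        assert np.isnan(res.table["icer"]).all()

    def test_strict_dominance(self):
        res = sequential_cea(
            [StrategyOutcome("A", 10.0, 0.5), StrategyOutcome("B", 5.0, 0.6)]
        )
        assert res.status_of("A") == DOMINATED
        assert res.frontier == ["B"]

    def test_weak_dominance_on_effect_tie(self):
        res = sequential_cea(
            [StrategyOutcome("cheap", 5.0, 0.5), StrategyOutcome("dear", 9.0, 0.5)]
        )
        assert res.status_of("dear") == DOMINATED

    def test_extended_dominance_removed(self):
        # B's step ICER (100) exceeds C's subsequent step ICER (50):
        # a mixture of A and C outperforms B
        res = sequential_cea(
            [
                StrategyOutcome("A", 0.0, 0.0),
                StrategyOutcome("B", 10.0, 0.1),
                StrategyOutcome("C", 15.0, 0.2),
            ]
        )
        assert res.status_of("B") == EXTENDED_DOMINATED
        assert res.frontier == ["A", "C"]
        assert res.icer_of("C") == pytest.approx(15.0 / 0.2)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            sequential_cea(
                [StrategyOutcome("A", 1.0, 0.1), StrategyOutcome("A", 2.0, 0.2)]
            )

    def test_input_order_invariance(self):
        outs = [
            StrategyOutcome("A", 5.0, 0.3),
            StrategyOutcome("B", 7.0, 0.6),
            StrategyOutcome("C", 2.0, 0.4),
        ]
        base = sequential_cea(outs)
        flipped = sequential_cea(outs[::-1])
        assert base.frontier == flipped.frontier
        assert (base.table["strategy"] == flipped.table["strategy"]).all()

    def test_adding_dominated_strategy_keeps_icers(self):
        outs = [
            StrategyOutcome("A", 5.0, 0.3),
            StrategyOutcome("B", 9.0, 0.6),
        ]
        with_dominated = outs + [StrategyOutcome("junk", 20.0, 0.1)]
        a = sequential_cea(outs)
        b = sequential_cea(with_dominated)
        assert a.icer_of("B") == b.icer_of("B")
        assert b.status_of("junk") == DOMINATED

    def test_frontier_icers_strictly_increase(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = rng.integers(2, 7)
            outs = [
                StrategyOutcome(f"s{i}", rng.uniform(0, 100), rng.uniform(0, 1))
                for i in range(n)
            ]
            table = sequential_cea(outs).table
            icers = table.loc[table["status"] == ON_FRONTIER, "icer"].dropna().to_numpy()
            assert (np.diff(icers) > 0).all()

    def test_matches_nmb_enumeration_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            n = int(rng.integers(1, 7))
            outs = [
                StrategyOutcome(f"s{i}", rng.uniform(0, 100), rng.uniform(0, 1))
                for i in range(n)
            ]
            assert set(sequential_cea(outs).frontier) == nmb_enumeration_frontier(outs)


class TestCeac:
    def test_hand_worked_two_strategy_example(self):
        """Three hand-written iterations: at WTP = 1e6, B's NMB exceeds A's
        in two of three iterations."""
        from uticea.psa import PsaResult

        costs = np.array([[10.0, 50.0], [10.0, 50.0], [10.0, 50.0]])
        qalms = np.array(
            [[0.50, 0.50006], [0.50, 0.50008], [0.50, 0.50002]]
        )
        psa = PsaResult(("A", "B"), costs, qalms, seed=0, n_iter=3)
        table = ceac(psa, [1e6])
        # per-iteration NMB differences: B-A = 1e6*dq - 40 = 20, 40, -20
        assert table.probabilities[0] == pytest.approx([1 / 3, 2 / 3])

    def test_wtp_zero_awards_cheapest(self, params, structure):
        psa = run_psa(params, structure, n_iter=500, seed=2)
        table = ceac(psa, [0.0])
        winners = np.argmin(psa.costs, axis=1)
        expected = np.bincount(winners, minlength=3) / 500
        assert table.probabilities[0] == pytest.approx(expected, abs=1e-12)

    def test_probabilities_sum_to_one(self, params, structure):
        psa = run_psa(params, structure, n_iter=400, seed=6)
        table = ceac(psa, np.linspace(0, 3e6, 31))
        assert table.probabilities.sum(axis=1) == pytest.approx(
            np.ones(31), abs=1e-12
        )

    def test_zero_variance_psa_gives_degenerate_curve(self, params, structure):
        psa = run_psa(params, structure, n_iter=50, seed=1, rel_halfwidth=0.0)
        table = ceac(psa, [0.0])
        j = int(np.argmin(psa.costs[0]))
        assert table.probabilities[0, j] == 1.0

    def test_empty_grid_rejected(self, params, structure):
        psa = run_psa(params, structure, n_iter=10, seed=1)
        with pytest.raises(ValueError, match="non-empty"):
            ceac(psa, [])

    def test_icer_sign_conventions(self):
        assert icer(10.0, 0.0) == np.inf
        assert icer(10.0, 0.002) == pytest.approx(5000.0)
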