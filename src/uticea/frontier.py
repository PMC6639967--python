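"""Sequential cost-effectiveness analysis and acceptability curves.

``sequential_cea`` implements the textbook frontier algorithm: strategies
are ranked by ascending cost, strictly (and weakly) dominated strategies are
removed, step ICERs are computed between adjacent survivors, and any
strategy whose step ICER is not below the next step's ICER is removed as
extended-dominated, iterating until the ladder of ICERs strictly increases.

``ceac`` computes the cost-effectiveness acceptability curve from PSA
draws: at each willingness-to-pay value, the share of iterations in which
each strategy attains the maximum net monetary benefit (NMB = WTP x QALM -
cost).  Exact NMB ties are awarded to the cheaper strategy — deterministic,
and conservative toward the lower-cost option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .psa import PsaResult
from .tree import StrategyOutcome

__all__ = [
    "FrontierResult",
    "CeacTable",
    "icer",
    "sequential_cea",
    "ceac",
    "default_wtp_grid",
]

ON_FRONTIER = "on_frontier"
DOMINATED = "dominated"
EXTENDED_DOMINATED = "extended_dominated"


def icer(incremental_cost: float, incremental_effect: float) -> float:
    """Incremental cost-effectiveness ratio: Δcost / Δeffect ($/QALM)."""
    if incremental_effect == 0:
        return np.inf if incremental_cost > 0 else -np.inf
    return incremental_cost / incremental_effect


@dataclass(frozen=True)
class FrontierResult:
    """Cost-sorted strategies with dominance labels and the ICER ladder."""

    table: pd.DataFrame  # strategy, cost, effect, status, incr_cost, incr_effect, icer

    @property
    def frontier(self) -> list[str]:
        mask = self.table["status"] == ON_FRONTIER
        return list(self.table.loc[mask, "strategy"])

    def status_of(self, strategy: str) -> str:
        row = self.table[self.table["strategy"] == strategy]
        if row.empty:
            raise KeyError(strategy)
        return row["status"].iloc[0]

    def icer_of(self, strategy: str) -> float:
        """Step ICER attached to a frontier strategy (NaN for the cheapest)."""
        row = self.table[self.table["strategy"] == strategy]
        if row.empty:
            raise KeyError(strategy)
        return float(row["icer"].iloc[0])


def sequential_cea(outcomes: Sequence[StrategyOutcome]) -> FrontierResult:
    """Dominance / extended-dominance pruning with a sequential ICER ladder.

    Weak dominance is included: with equal effects, the costlier strategy is
    labelled dominated.  Surviving frontier strategies carry the ICER of the
    step from the previous (cheaper) frontier strategy; the cheapest carries
    none.
    """
    labels = [o.strategy for o in outcomes]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate strategy labels")
    if len(outcomes) == 0:
        raise ValueError("need at least one strategy")

    entries = sorted(outcomes, key=lambda o: (o.expected_cost, o.expected_qalm))
    status = {o.strategy: ON_FRONTIER for o in entries}

    # strict + weak dominance: more costly and no more effective
    for o in entries:
        for other in entries:
            if other is o or status[other.strategy] == DOMINATED:
                continue
            if (
                other.expected_cost <= o.expected_cost
                and other.expected_qalm >= o.expected_qalm
                and (
                    other.expected_cost < o.expected_cost
                    or other.expected_qalm > o.expected_qalm
                )
            ):
                status[o.strategy] = DOMINATED
                break

    # extended dominance: remove strategies until step ICERs strictly increase
    active = [o for o in entries if status[o.strategy] == ON_FRONTIER]
    while len(active) > 2:
        icers = [
            icer(
                active[i].expected_cost - active[i - 1].expected_cost,
                active[i].expected_qalm - active[i - 1].expected_qalm,
            )
            for i in range(1, len(active))
        ]
        removed = False
        for i in range(len(icers) - 1):
            if icers[i] >= icers[i + 1]:
                status[active[i + 1].strategy] = EXTENDED_DOMINATED
                active.pop(i + 1)
                removed = True
                break
        if not removed:
            break

    rows = []
    frontier_prev: StrategyOutcome | None = None
    for o in entries:
        row = {
            "strategy": o.strategy,
            "mean_cost": o.expected_cost,
            "mean_qalm": o.expected_qalm,
            "status": status[o.strategy],
            "incr_cost": np.nan,
            "incr_qalm": np.nan,
            "icer": np.nan,
        }
        if status[o.strategy] == ON_FRONTIER:
            if frontier_prev is not None:
                d_cost = o.expected_cost - frontier_prev.expected_cost
                d_qalm = o.expected_qalm - frontier_prev.expected_qalm
                row["incr_cost"] = d_cost
                row["incr_qalm"] = d_qalm
                row["icer"] = icer(d_cost, d_qalm)
            frontier_prev = o
        rows.append(row)
    return FrontierResult(table=pd.DataFrame(rows))


def default_wtp_grid(
    stop: float = 5_000_000.0, step: float = 10_000.0
) -> np.ndarray:
    """Willingness-to-pay grid spanning the model's ICER magnitudes."""
    return np.arange(0.0, stop + step, step)


@dataclass(frozen=True)
class CeacTable:
    """Acceptability probabilities per strategy over a WTP grid."""

    wtp: np.ndarray
    strategies: tuple[str, ...]
    probabilities: np.ndarray  # (n_wtp, n_strategy)

    def to_frame(self) -> pd.DataFrame:
        """Long format: (wtp, strategy, probability)."""
        n_wtp, k = self.probabilities.shape
        return pd.DataFrame(
            {
                "wtp": np.repeat(self.wtp, k),
                "strategy": list(self.strategies) * n_wtp,
                "probability": self.probabilities.ravel(),
            }
        )

    def plot(self, ax=None):
        """Plot the acceptability curves (one per strategy)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for j, s in enumerate(self.strategies):
            ax.plot(self.wtp, self.probabilities[:, j], label=s)
        ax.set_xlabel("Willingness to pay ($/QALM)")
        ax.set_ylabel("Probability cost-effective")
        ax.set_ylim(-0.02, 1.02)
        ax.legend()
        return ax


def ceac(psa: PsaResult, wtp_grid: Sequence[float]) -> CeacTable:
    """Cost-effectiveness acceptability curve from PSA draws.

    For each WTP value and iteration, the winning strategy maximises
    NMB = WTP x QALM - cost; exact ties go to the cheaper strategy.  The
    per-strategy probability is the fraction of iterations won.
    """
    wtp = np.asarray(wtp_grid, dtype=float)
    if wtp.size == 0:
        raise ValueError("willingness-to-pay grid must be non-empty")
    if np.any(wtp < 0):
        raise ValueError("willingness-to-pay values must be >= 0")
    n_iter, k = psa.costs.shape
    probs = np.empty((wtp.size, k))
    for i, w in enumerate(wtp):
        nmb = w * psa.qalms - psa.costs
        best = nmb.max(axis=1, keepdims=True)
        # among NMB-maximisers, pick the cheapest (deterministic tie-break)
        cost_if_best = np.where(nmb == best, psa.costs, np.inf)
        winner = np.argmin(cost_if_best, axis=1)
        probs[i] = np.bincount(winner, minlength=k) / n_iter
    return CeacTable(wtp=wtp, strategies=psa.strategies, probabilities=probs)
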