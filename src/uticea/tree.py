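"""Decision-tree construction, QALM valuation and expected-value roll-back.

The tree has one branch per management strategy.  Within each branch the
patient is either cured by the initial antibiotic course (probability =
cure rate) or her infection persists; a persistent patient either extends
the initial antibiotic or switches to a fluoroquinolone, incurring a
follow-up contact and a second course of medication.  Every root-to-terminal
path carries an accumulated cost and a piecewise-constant utility trajectory
spanning the full one-month horizon, valued in quality-adjusted life-months
(QALMs) by the area-under-the-curve rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

from .params import (
    STRATEGIES,
    ConfigurationError,
    ParameterSet,
    StructureConfig,
)

__all__ = [
    "TerminalNode",
    "ChanceNode",
    "DecisionTree",
    "StrategyOutcome",
    "qalm_auc",
    "build_decision_tree",
    "expected_values",
    "enumerate_paths",
]

_PROB_TOL = 1e-12


def qalm_auc(segments: Sequence[tuple[float, float]], horizon_days: int) -> float:
    """Quality-adjusted life-months of a piecewise-constant utility trajectory.

    ``segments`` is an ordered list of ``(duration_days, utility)`` pairs
    whose durations must sum exactly to ``horizon_days``.  The area under
    the utility curve, normalised by the horizon, gives QALMs accrued over
    one month:

        QALM = sum(duration_i * utility_i) / horizon_days

    >>> qalm_auc([(14, 0.68), (16, 0.83)], 30)
    0.76
    """
    total = 0.0
    days = 0.0
    for duration, utility in segments:
        if duration < 0:
            raise ValueError(f"segment duration must be non-negative, got {duration}")
        if not 0.0 <= utility <= 1.0:
            raise ValueError(f"utility must lie in [0, 1], got {utility}")
        total += duration * utility
        days += duration
    if days != horizon_days:
        raise ValueError(
            f"segment durations sum to {days} days, not the {horizon_days}-day "
            f"horizon (deficit {horizon_days - days})"
        )
    return total / horizon_days


@dataclass(frozen=True)
class TerminalNode:
    """A leaf: realised path cost and the full utility trajectory."""

    label: str
    cost: float
    trajectory: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "trajectory", tuple(tuple(s) for s in self.trajectory))


@dataclass(frozen=True)
class ChanceNode:
    """An uncertain event with probability-labelled outgoing branches."""

    label: str
    branches: tuple[tuple[float, "ChanceNode | TerminalNode"], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "branches", tuple(self.branches))
        total = sum(p for p, _ in self.branches)
        if abs(total - 1.0) > _PROB_TOL:
            raise ValueError(
                f"branch probabilities at {self.label!r} sum to {total}, not 1"
            )


@dataclass(frozen=True)
class DecisionTree:
    """Root decision node: one subtree per strategy, plus the time horizon."""

    strategies: dict[str, "ChanceNode | TerminalNode"] = field(default_factory=dict)
    horizon_days: int = 30

    def validate(self) -> None:
        """Check path durations and branch probabilities throughout."""
        for strategy, node in self.strategies.items():
            for prob, terminal in enumerate_paths(node):
                days = sum(d for d, _ in terminal.trajectory)
                if days != self.horizon_days:
                    raise ValueError(
                        f"{strategy}/{terminal.label}: trajectory spans {days} "
                        f"days, not the {self.horizon_days}-day horizon"
                    )


@dataclass(frozen=True)
class StrategyOutcome:
    """Expected cost (CAD) and expected QALMs of one strategy."""

    strategy: str
    expected_cost: float
    expected_qalm: float


def _persisted_trajectory(
    params: ParameterSet, structure: StructureConfig
) -> tuple[tuple[float, float], ...]:
    """Utility path of a persistent patient: baseline, persisted, then
    (optionally) cured-after-subsequent-treatment for the last days."""
    cured_days = structure.persisted_cured_days
    if cured_days > params.subsequent_window_days:
        raise ConfigurationError(
            f"persisted_cured_days ({cured_days}) exceeds the subsequent "
            f"window ({params.subsequent_window_days} days)"
        )
    u = params.utility
    segments = [(params.initial_window_days, u["baseline"])]
    persisted_days = params.subsequent_window_days - cured_days
    if persisted_days > 0:
        segments.append((persisted_days, u["persisted"]))
    if cured_days > 0:
        segments.append((cured_days, u["cured_subsequent"]))
    return tuple(segments)


def build_decision_tree(
    params: ParameterSet, structure: StructureConfig | None = None
) -> DecisionTree:
    """Assemble the three-strategy decision tree from point estimates.

    Each strategy branch contains a cure terminal (initial visit + initial
    medication; utility at baseline for the initial window, then at the
    cured level) and, when the persistence probability is positive, a chance
    node splitting persistent patients between extending the initial
    antibiotic and switching to a fluoroquinolone (follow-up visit +
    second medication course; utility per the structure's segmentation).
    Degenerate probabilities (cure rate 1, extend probability 0 or 1) prune
    the corresponding subtree.
    """
    if structure is None:
        structure = StructureConfig()
    strategies: dict[str, ChanceNode | TerminalNode] = {}
    for strategy in STRATEGIES:
        initial_visit_key = {
            "pharmacist": "pharmacist",
            "family": "family_initial",
            "emergency": "emergency",
        }[strategy]
        base_cost = (
            params.visit_cost[initial_visit_key] + params.initial_med_cost[strategy]
        )
        cure_traj = (
            (params.initial_window_days, params.utility["baseline"]),
            (params.subsequent_window_days, params.utility["cured_initial"]),
        )
        cure_node = TerminalNode("cured_initial", base_cost, cure_traj)

        p_cure = params.cure_rate[strategy]
        if p_cure >= 1.0:
            strategies[strategy] = cure_node
            continue

        followup_key = structure.followup_provider[strategy]
        if followup_key not in params.visit_cost:
            raise ConfigurationError(
                f"followup_provider[{strategy}] = {followup_key!r} has no "
                f"visit_cost entry"
            )
        followup_cost = base_cost + params.visit_cost[followup_key]
        extend_key = (
            "extend_pharmacist" if strategy == "pharmacist" else "extend_physician"
        )
        persisted_traj = _persisted_trajectory(params, structure)
        extend_node = TerminalNode(
            "persisted_extend",
            followup_cost + params.subsequent_med_cost[extend_key],
            persisted_traj,
        )
        switch_node = TerminalNode(
            "persisted_switch",
            followup_cost + params.subsequent_med_cost["switch_fluoroquinolone"],
            persisted_traj,
        )
        p_ext = params.p_extend_vs_switch
        if p_ext >= 1.0:
            persistence_node: ChanceNode | TerminalNode = extend_node
        elif p_ext <= 0.0:
            persistence_node = switch_node
        else:
            persistence_node = ChanceNode(
                "persistence_management",
                ((p_ext, extend_node), (1.0 - p_ext, switch_node)),
            )
        strategies[strategy] = ChanceNode(
            "initial_outcome",
            ((p_cure, cure_node), (1.0 - p_cure, persistence_node)),
        )
    tree = DecisionTree(strategies=strategies, horizon_days=params.horizon_days)
    tree.validate()
    return tree


def enumerate_paths(
    node: "ChanceNode | TerminalNode",
) -> Iterator[tuple[float, TerminalNode]]:
    """Yield every (path probability, terminal) pair below ``node``."""
    if isinstance(node, TerminalNode):
        yield 1.0, node
        return
    for prob, child in node.branches:
        for sub_prob, terminal in enumerate_paths(child):
            yield prob * sub_prob, terminal


def _roll_back(
    node: "ChanceNode | TerminalNode", horizon_days: int
) -> tuple[float, float]:
    if isinstance(node, TerminalNode):
        return node.cost, qalm_auc(node.trajectory, horizon_days)
    cost = 0.0
    qalm = 0.0
    for prob, child in node.branches:
        c, q = _roll_back(child, horizon_days)
        cost += prob * c
        qalm += prob * q
    return cost, qalm


def expected_values(tree: DecisionTree) -> list[StrategyOutcome]:
    """Probability-weighted roll-back of cost and QALMs per strategy."""
    outcomes = []
    for strategy, node in tree.strategies.items():
        cost, qalm = _roll_back(node, tree.horizon_days)
        outcomes.append(StrategyOutcome(strategy, cost, qalm))
    return outcomes
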