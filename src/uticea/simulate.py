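"""Patient-level microsimulation and synthetic parameter generation.

The decision tree's expectations have a simple patient-level counterpart:
each simulated woman is cured by the initial course with her arm's cure
probability; if not, she extends the initial antibiotic or switches to a
fluoroquinolone.  Her realised cost is the sum of unit costs along her path
and her QALM is the area under her utility trajectory.  Averaging many
simulated patients therefore converges to the roll-back expected values,
which makes the microsimulation an independent oracle for every analytic
stage.

Two separate seed-derived random streams are used: one for parameter
jitter (synthetic ParameterSets) and one for patient outcomes, so tests can
vary either in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ParameterSet, StructureConfig, default_parameter_set
from .tree import TerminalNode, build_decision_tree, enumerate_paths, qalm_auc

__all__ = [
    "MicrosimResult",
    "generate_parameter_set",
    "simulate_cohort",
    "microsimulate",
]

# independent sub-streams of a user seed
_JITTER_STREAM = 0
_OUTCOME_STREAM = 1


def _stream_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[stream])


def _jitter_group(
    rng: np.random.Generator, values: dict, jitter: float, is_prob: bool
) -> dict:
    out = {}
    for key, value in values.items():
        factor = 1.0 + rng.uniform(-jitter, jitter)
        v = value * factor
        if is_prob:
            v = float(np.clip(v, 1e-6, 1.0 - 1e-6))
        out[key] = v
    return out


def generate_parameter_set(seed: int, jitter: float = 0.0) -> ParameterSet:
    """A synthetic ParameterSet: reference values jittered multiplicatively.

    Every cost, probability and utility is scaled by an independent uniform
    factor in [1 - jitter, 1 + jitter]; probabilities and utilities are
    clipped to the open unit interval.  ``jitter = 0`` returns the reference
    point estimates verbatim; the same seed always returns the same set.
    """
    if jitter < 0:
        raise ValueError("jitter must be non-negative")
    base = default_parameter_set()
    if jitter == 0.0:
        return base
    rng = _stream_rng(seed, _JITTER_STREAM)
    return base.replace(
        cure_rate=_jitter_group(rng, dict(base.cure_rate), jitter, True),
        visit_cost=_jitter_group(rng, dict(base.visit_cost), jitter, False),
        initial_med_cost=_jitter_group(rng, dict(base.initial_med_cost), jitter, False),
        subsequent_med_cost=_jitter_group(
            rng, dict(base.subsequent_med_cost), jitter, False
        ),
        utility=_jitter_group(rng, dict(base.utility), jitter, True),
    )


@dataclass(frozen=True)
class MicrosimResult:
    """Cohort means with their Monte Carlo standard errors."""

    strategy: str
    mean_cost: float
    mean_qalm: float
    se_cost: float
    se_qalm: float
    n_patients: int


def _strategy_paths(
    strategy: str, params: ParameterSet, structure: StructureConfig | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[TerminalNode]]:
    """Path probabilities, costs and QALMs for one strategy's subtree."""
    tree = build_decision_tree(params, structure)
    if strategy not in tree.strategies:
        raise KeyError(f"unknown strategy {strategy!r}")
    probs, costs, qalms, terminals = [], [], [], []
    for prob, terminal in enumerate_paths(tree.strategies[strategy]):
        probs.append(prob)
        costs.append(terminal.cost)
        qalms.append(qalm_auc(terminal.trajectory, tree.horizon_days))
        terminals.append(terminal)
    return np.array(probs), np.array(costs), np.array(qalms), terminals


def simulate_cohort(
    strategy: str,
    params: ParameterSet | None = None,
    structure: StructureConfig | None = None,
    n_patients: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate individual patient trajectories through one strategy's arm.

    Returns one row per patient with her realised path, accumulated cost
    and QALM.  Patient outcomes are independent Bernoulli/categorical
    draws, matching the tree's independence assumptions.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if params is None:
        params = default_parameter_set()
    probs, costs, qalms, terminals = _strategy_paths(strategy, params, structure)
    rng = _stream_rng(seed, _OUTCOME_STREAM)
    path_idx = rng.choice(len(probs), size=n_patients, p=probs)
    labels = [t.label for t in terminals]
    cured = np.array([lbl == "cured_initial" for lbl in labels])
    branch = np.array(
        [
            {"cured_initial": "", "persisted_extend": "extend",
             "persisted_switch": "switch"}[lbl]
            for lbl in labels
        ]
    )
    return pd.DataFrame(
        {
            "strategy": strategy,
            "cured_initially": cured[path_idx],
            "persistence_branch": branch[path_idx],
            "cost": costs[path_idx],
            "qalm": qalms[path_idx],
        }
    )


def microsimulate(
    strategy: str,
    params: ParameterSet | None = None,
    structure: StructureConfig | None = None,
    n_patients: int = 100_000,
    seed: int = 0,
) -> MicrosimResult:
    """Cohort means of cost and QALM with standard errors.

    At large ``n_patients`` this converges to the roll-back expectation of
    the same strategy; the standard errors quantify the Monte Carlo noise
    for oracle comparisons.
    """
    cohort = simulate_cohort(strategy, params, structure, n_patients, seed)
    n = len(cohort)
    cost = cohort["cost"].to_numpy()
    qalm = cohort["qalm"].to_numpy()
    ddof = 1 if n > 1 else 0
    return MicrosimResult(
        strategy=strategy,
        mean_cost=float(cost.mean()),
        mean_qalm=float(qalm.mean()),
        se_cost=float(cost.std(ddof=ddof) / np.sqrt(n)),
        se_qalm=float(qalm.std(ddof=ddof) / np.sqrt(n)),
        n_patients=n,
    )
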