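"""Model/Results facade over the decision-analytic pipeline.

:class:`UtiCostEffectivenessModel` is constructed from a parameter set (or
a config file) and a perspective; ``fit()`` runs the probabilistic
sensitivity analysis and returns a :class:`UtiCostEffectivenessResults`
object carrying the draws, the per-strategy means with 95% percentile
intervals, the sequential cost-effectiveness frontier and the acceptability
curve, with a ``summary()`` table laid out like a published
cost-effectiveness table.

Example
-------
>>> from uticea import UtiCostEffectivenessModel
>>> model = UtiCostEffectivenessModel.from_config()
>>> res = model.fit(n_iter=2000, seed=7)
>>> res.summary().columns.tolist()[:3]
['strategy', 'mean_cost', 'cost_lo']
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import frontier as frontier_mod
from .params import (
    ParameterSet,
    SocietalConstants,
    StructureConfig,
    _societal_from_mapping,
    _structure_from_mapping,
    load_config,
    parameter_set_from_mapping,
)
from .psa import DEFAULT_REL_HALFWIDTH, DEFAULT_SEED, PsaResult, run_psa
from .societal import apply_societal_perspective
from .tree import StrategyOutcome, build_decision_tree, expected_values

__all__ = ["UtiCostEffectivenessModel", "UtiCostEffectivenessResults"]


class UtiCostEffectivenessModel:
    """Decision-analytic cost-utility model of uncomplicated-UTI management.

    Parameters
    ----------
    params
        Point estimates (defaults to the bundled reference case).
    structure
        Tree-structure options (follow-up provider, utility segmentation).
    perspective
        ``"health_system"`` (payer costs only, the reference case) or
        ``"societal"`` (adds productivity losses and out-of-pocket costs).
    societal_constants
        Inputs for the societal augmentation; ignored under the
        health-system perspective.
    """

    def __init__(
        self,
        params: ParameterSet | None = None,
        structure: StructureConfig | None = None,
        perspective: str = "health_system",
        societal_constants: SocietalConstants | None = None,
    ):
        if perspective not in ("health_system", "societal"):
            raise ValueError(
                f"perspective must be 'health_system' or 'societal', "
                f"got {perspective!r}"
            )
        self.reference_params = (
            params if params is not None else parameter_set_from_mapping(load_config())
        )
        self.structure = structure if structure is not None else StructureConfig()
        self.perspective = perspective
        self.societal_constants = (
            societal_constants if societal_constants is not None else SocietalConstants()
        )
        if perspective == "societal":
            self.params = apply_societal_perspective(
                self.reference_params, self.societal_constants, self.structure
            )
        else:
            self.params = self.reference_params

    @classmethod
    def from_config(
        cls, path: str | Path | None = None, perspective: str = "health_system"
    ) -> "UtiCostEffectivenessModel":
        """Build the model from a YAML/JSON parameter file (bundled default
        when ``path`` is None)."""
        cfg = load_config(path)
        return cls(
            params=parameter_set_from_mapping(cfg),
            structure=_structure_from_mapping(cfg),
            perspective=perspective,
            societal_constants=_societal_from_mapping(cfg),
        )

    def with_cure_rate(self, strategy: str, value: float) -> "UtiCostEffectivenessModel":
        """Scenario helper: same model with one arm's cure rate replaced."""
        return UtiCostEffectivenessModel(
            params=self.reference_params.with_cure_rate(strategy, value),
            structure=self.structure,
            perspective=self.perspective,
            societal_constants=self.societal_constants,
        )

    def expected_values(self) -> pd.DataFrame:
        """Deterministic roll-back at the point estimates."""
        tree = build_decision_tree(self.params, self.structure)
        rows = expected_values(tree)
        return pd.DataFrame(
            {
                "strategy": [o.strategy for o in rows],
                "expected_cost": [o.expected_cost for o in rows],
                "expected_qalm": [o.expected_qalm for o in rows],
            }
        )

    def fit(
        self,
        n_iter: int = 10_000,
        seed: int = DEFAULT_SEED,
        rel_halfwidth: float = DEFAULT_REL_HALFWIDTH,
        shared_physician_cure_draw: bool = False,
    ) -> "UtiCostEffectivenessResults":
        """Run the probabilistic sensitivity analysis."""
        psa = run_psa(
            self.params,
            self.structure,
            n_iter=n_iter,
            seed=seed,
            rel_halfwidth=rel_halfwidth,
            shared_physician_cure_draw=shared_physician_cure_draw,
        )
        return UtiCostEffectivenessResults(self, psa)


class UtiCostEffectivenessResults:
    """PSA results: draws, summaries, frontier and acceptability curve."""

    def __init__(self, model: UtiCostEffectivenessModel, psa: PsaResult):
        self.model = model
        self.psa = psa

    @property
    def mean_outcomes(self) -> list[StrategyOutcome]:
        costs = self.psa.mean_costs()
        qalms = self.psa.mean_qalms()
        return [
            StrategyOutcome(s, float(c), float(q))
            for s, c, q in zip(self.psa.strategies, costs, qalms)
        ]

    def frontier(self) -> frontier_mod.FrontierResult:
        """Sequential dominance analysis on the PSA means."""
        return frontier_mod.sequential_cea(self.mean_outcomes)

    def per_iteration_frontier_share(self) -> pd.DataFrame:
        """Diagnostic: share of iterations each strategy is cheapest-on-
        frontier (undominated), rather than using the means."""
        n, k = self.psa.costs.shape
        counts = np.zeros(k)
        for i in range(n):
            outs = [
                StrategyOutcome(s, self.psa.costs[i, j], self.psa.qalms[i, j])
                for j, s in enumerate(self.psa.strategies)
            ]
            fr = frontier_mod.sequential_cea(outs)
            for s in fr.frontier:
                counts[self.psa.strategies.index(s)] += 1
        return pd.DataFrame(
            {"strategy": self.psa.strategies, "frontier_share": counts / n}
        )

    def ceac(self, wtp_grid=None) -> frontier_mod.CeacTable:
        """Cost-effectiveness acceptability curve over a WTP grid."""
        if wtp_grid is None:
            wtp_grid = frontier_mod.default_wtp_grid()
        return frontier_mod.ceac(self.psa, wtp_grid)

    def summary(self) -> pd.DataFrame:
        """Cost-effectiveness table: means, 95% intervals, incrementals,
        ICERs and dominance status, sorted by ascending cost."""
        psa_summary = self.psa.summary()
        fr = self.frontier().table
        return fr.merge(
            psa_summary[
                ["strategy", "cost_lo", "cost_hi", "qalm_lo", "qalm_hi"]
            ],
            on="strategy",
        )[
            [
                "strategy",
                "mean_cost",
                "cost_lo",
                "cost_hi",
                "mean_qalm",
                "qalm_lo",
                "qalm_hi",
                "incr_cost",
                "incr_qalm",
                "icer",
                "status",
            ]
        ]
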