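"""Probabilistic sensitivity analysis.

Every uncertain input (cure rates, utilities, unit costs) is assigned a
distribution centred on its point estimate: beta for probabilities and
utilities, gamma for costs.  The published uncertainty statement — inputs
varied "simultaneously +/-25% of the point estimates" — is read as a 95%
interval half-width, i.e. sd = 0.25 * mean / 1.96.  Reading it instead as a
+/-25% uniform range or a 25% coefficient of variation would push the beta
fits for utilities near 0.83 outside their feasible variance bound, so the
interval reading is the one that admits the stated distribution families.

Each Monte Carlo iteration draws every parameter independently, rebuilds the
decision tree, rolls it back, and records per-strategy (cost, QALM) pairs.
Summaries are percentile-based 95% intervals around the iteration means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import STRATEGIES, ParameterSet, StructureConfig
from .tree import build_decision_tree, expected_values

__all__ = [
    "DistributionSpec",
    "PsaResult",
    "fit_beta",
    "fit_gamma",
    "run_psa",
    "DEFAULT_SEED",
    "DEFAULT_REL_HALFWIDTH",
]

#: Arbitrary documented default seed.
DEFAULT_SEED = 20180701
#: Published parameter variation: +/-25% as a 95% interval half-width.
DEFAULT_REL_HALFWIDTH = 0.25

_Z95 = 1.96


def _implied_sd(mean: float, rel_halfwidth: float) -> float:
    return rel_halfwidth * abs(mean) / _Z95


def fit_beta(mean: float, rel_halfwidth: float) -> tuple[float, float]:
    """Method-of-moments beta parameters for a probability or utility.

    The implied standard deviation is ``rel_halfwidth * mean / 1.96`` (the
    +/-25% band treated as a 95% interval).  Returns ``(alpha, beta)`` such
    that the beta distribution has exactly the requested mean and sd.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must lie in (0, 1), got {mean}")
    if rel_halfwidth < 0:
        raise ValueError("rel_halfwidth must be non-negative")
    var = _implied_sd(mean, rel_halfwidth) ** 2
    bound = mean * (1.0 - mean)
    if var >= bound:
        raise ValueError(
            f"implied variance {var:.6g} infeasible for a beta with mean "
            f"{mean}: must be below mean*(1-mean) = {bound:.6g}"
        )
    if var == 0.0:
        return np.inf, np.inf  # degenerate; callers sample the point mass
    nu = bound / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def fit_gamma(mean: float, rel_halfwidth: float) -> tuple[float, float]:
    """Gamma (shape, scale) for a cost parameter.

    shape = (1.96 / rel_halfwidth)^2 and scale = mean / shape, so the
    distribution mean equals the point estimate and the sd equals
    ``rel_halfwidth * mean / 1.96``.
    """
    if mean <= 0:
        raise ValueError(f"gamma mean must be positive, got {mean}")
    if rel_halfwidth < 0:
        raise ValueError("rel_halfwidth must be non-negative")
    if rel_halfwidth == 0.0:
        return np.inf, 0.0  # degenerate point mass
    shape = (_Z95 / rel_halfwidth) ** 2
    return shape, mean / shape


@dataclass(frozen=True)
class DistributionSpec:
    """An uncertain parameter: its family, point estimate and spread."""

    family: str  # "beta" or "gamma"
    mean: float
    rel_halfwidth: float = DEFAULT_REL_HALFWIDTH

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        # validate feasibility eagerly
        self.shape_params()

    def shape_params(self) -> tuple[float, float]:
        if self.family == "beta":
            return fit_beta(self.mean, self.rel_halfwidth)
        return fit_gamma(self.mean, self.rel_halfwidth)

    @property
    def sd(self) -> float:
        return _implied_sd(self.mean, self.rel_halfwidth)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.rel_halfwidth == 0.0:
            return np.full(size, self.mean)
        a, b = self.shape_params()
        if self.family == "beta":
            return rng.beta(a, b, size=size)
        return rng.gamma(a, scale=b, size=size)


def parameter_distributions(
    params: ParameterSet, rel_halfwidth: float = DEFAULT_REL_HALFWIDTH
) -> dict[str, DistributionSpec]:
    """One DistributionSpec per uncertain model input, keyed 'group.name'.

    Probabilities and utilities get beta distributions; costs get gamma.
    The structural extend-vs-switch split is not an estimated quantity and
    is held fixed.
    """
    specs: dict[str, DistributionSpec] = {}
    for s, v in params.cure_rate.items():
        specs[f"cure_rate.{s}"] = DistributionSpec("beta", v, rel_halfwidth)
    for k, v in params.utility.items():
        specs[f"utility.{k}"] = DistributionSpec("beta", v, rel_halfwidth)
    for k, v in params.visit_cost.items():
        specs[f"visit_cost.{k}"] = DistributionSpec("gamma", v, rel_halfwidth)
    for k, v in params.initial_med_cost.items():
        specs[f"initial_med_cost.{k}"] = DistributionSpec("gamma", v, rel_halfwidth)
    for k, v in params.subsequent_med_cost.items():
        specs[f"subsequent_med_cost.{k}"] = DistributionSpec("gamma", v, rel_halfwidth)
    return specs


@dataclass(frozen=True)
class PsaResult:
    """Per-iteration (cost, QALM) draws and their summaries.

    ``costs`` and ``qalms`` are ``(n_iter, n_strategy)`` arrays with columns
    in ``strategies`` order.
    """

    strategies: tuple[str, ...]
    costs: np.ndarray
    qalms: np.ndarray
    seed: int
    n_iter: int

    def mean_costs(self) -> np.ndarray:
        return self.costs.mean(axis=0)

    def mean_qalms(self) -> np.ndarray:
        return self.qalms.mean(axis=0)

    def percentiles(self, q: tuple[float, float] = (2.5, 97.5)) -> dict[str, np.ndarray]:
        return {
            "cost": np.percentile(self.costs, q, axis=0),
            "qalm": np.percentile(self.qalms, q, axis=0),
        }

    def summary(self) -> pd.DataFrame:
        """Means with 95% percentile intervals, one row per strategy."""
        pct = self.percentiles()
        return pd.DataFrame(
            {
                "strategy": self.strategies,
                "mean_cost": self.mean_costs(),
                "cost_lo": pct["cost"][0],
                "cost_hi": pct["cost"][1],
                "mean_qalm": self.mean_qalms(),
                "qalm_lo": pct["qalm"][0],
                "qalm_hi": pct["qalm"][1],
            }
        )

    def draws_frame(self) -> pd.DataFrame:
        """Long-format draws: (iteration, strategy, cost, qalm)."""
        n, k = self.costs.shape
        return pd.DataFrame(
            {
                "iteration": np.repeat(np.arange(n), k),
                "strategy": list(self.strategies) * n,
                "cost": self.costs.ravel(),
                "qalm": self.qalms.ravel(),
            }
        )


def _draw_parameter_set(
    params: ParameterSet,
    specs: dict[str, DistributionSpec],
    draws: dict[str, float],
) -> ParameterSet:
    """Materialise one iteration's ParameterSet from sampled values."""

    def group(prefix: str, keys) -> dict[str, float]:
        return {k: draws[f"{prefix}.{k}"] for k in keys}

    return params.replace(
        cure_rate=group("cure_rate", params.cure_rate),
        utility=group("utility", params.utility),
        visit_cost=group("visit_cost", params.visit_cost),
        initial_med_cost=group("initial_med_cost", params.initial_med_cost),
        subsequent_med_cost=group("subsequent_med_cost", params.subsequent_med_cost),
    )


def run_psa(
    params: ParameterSet,
    structure: StructureConfig | None = None,
    n_iter: int = 10_000,
    seed: int = DEFAULT_SEED,
    rel_halfwidth: float = DEFAULT_REL_HALFWIDTH,
    shared_physician_cure_draw: bool = False,
) -> PsaResult:
    """Monte Carlo propagation of parameter uncertainty through the tree.

    Per iteration, every uncertain parameter is drawn independently from its
    fitted distribution, the tree is rebuilt and rolled back, and the
    per-strategy expected (cost, QALM) pair is recorded.  The same seed
    always yields the same draws matrix.

    ``shared_physician_cure_draw`` makes the family and emergency arms share
    one cure-rate draw per iteration (they share a point estimate); by
    default each arm is sampled independently.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if structure is None:
        structure = StructureConfig()
    specs = parameter_distributions(params, rel_halfwidth)
    rng = np.random.default_rng(seed)
    # draw all iterations up front, parameter by parameter, so the draw
    # stream is independent of tree evaluation order
    samples = {name: spec.sample(rng, n_iter) for name, spec in specs.items()}
    if shared_physician_cure_draw:
        samples["cure_rate.emergency"] = samples["cure_rate.family"]

    costs = np.empty((n_iter, len(STRATEGIES)))
    qalms = np.empty((n_iter, len(STRATEGIES)))
    order = {s: i for i, s in enumerate(STRATEGIES)}
    for i in range(n_iter):
        draw = {name: float(arr[i]) for name, arr in samples.items()}
        drawn_params = _draw_parameter_set(params, specs, draw)
        tree = build_decision_tree(drawn_params, structure)
        for outcome in expected_values(tree):
            j = order[outcome.strategy]
            costs[i, j] = outcome.expected_cost
            qalms[i, j] = outcome.expected_qalm
    return PsaResult(
        strategies=STRATEGIES,
        costs=costs,
        qalms=qalms,
        seed=seed,
        n_iter=n_iter,
    )
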