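"""Budget impact of expanding pharmacist-initiated UTI management.

The eligible population (women expected to seek care for uncomplicated UTI
in a year) is projected forward at a constant growth rate with
nearest-integer rounding after each year.  Two expenditure scenarios are
compared over the horizon: the *current* scenario holds pharmacist uptake
at its present level, while the *new* scenario ramps uptake linearly to a
target by the final year.  The net budget impact is the new-scenario total
minus the current-scenario total, yearly and summed; negative values are
savings to the payer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .params import BiaConfig, ConfigurationError

__all__ = [
    "BudgetImpactResult",
    "project_population",
    "linear_uptake",
    "scenario_cost",
    "net_budget_impact",
    "BudgetImpactModel",
]


def _round_half_up(x: float) -> int:
    """Round to the nearest integer with exact halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def project_population(
    year1_count: int, growth_rate: float, n_years: int
) -> np.ndarray:
    """Yearly eligible-population counts under compound growth.

    Year 1 equals the input; each later year is the previous year times
    (1 + growth_rate), rounded to the nearest person.
    """
    if year1_count <= 0:
        raise ValueError("year1_count must be positive")
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    counts = [int(year1_count)]
    for _ in range(n_years - 1):
        counts.append(_round_half_up(counts[-1] * (1.0 + growth_rate)))
    return np.array(counts, dtype=np.int64)


def linear_uptake(
    current: float, target: float, n_years: int
) -> np.ndarray:
    """Pharmacist-uptake ramp: linear from the current rate (year 0
    baseline) to the target rate in the final year."""
    if not 0.0 <= current <= 1.0 or not 0.0 <= target <= 1.0:
        raise ValueError("uptake fractions must lie in [0, 1]")
    years = np.arange(1, n_years + 1)
    return current + (target - current) * years / n_years


def scenario_cost(
    population: float,
    uptake: float,
    per_patient_cost: Mapping[str, float],
    provider_mix: Mapping[str, float],
) -> float:
    """Total yearly expenditure for one scenario-year.

    The pharmacist share of patients costs the pharmacist per-patient
    amount; the remainder splits between family and emergency care per the
    provider mix:

        total = N * [u * c_pharm + (1 - u) * (m_fam * c_fam + m_ed * c_ed)]
    """
    if not 0.0 <= uptake <= 1.0:
        raise ValueError(f"uptake must lie in [0, 1], got {uptake}")
    mix_sum = sum(provider_mix.values())
    if abs(mix_sum - 1.0) > 1e-9:
        raise ConfigurationError(f"provider_mix must sum to 1, got {mix_sum}")
    physician_blend = sum(
        share * per_patient_cost[provider]
        for provider, share in provider_mix.items()
    )
    per_patient = (
        uptake * per_patient_cost["pharmacist"] + (1.0 - uptake) * physician_blend
    )
    return population * per_patient


@dataclass(frozen=True)
class BudgetImpactResult:
    """Yearly and total expenditure under both scenarios, plus net impact."""

    years: np.ndarray
    current_totals: np.ndarray
    new_totals: np.ndarray

    @property
    def net_impacts(self) -> np.ndarray:
        return self.new_totals - self.current_totals

    @property
    def total_current(self) -> float:
        return float(self.current_totals.sum())

    @property
    def total_new(self) -> float:
        return float(self.new_totals.sum())

    @property
    def total_net(self) -> float:
        return float(self.net_impacts.sum())

    def to_frame(self) -> pd.DataFrame:
        """One row per year plus a totals row; negative net = savings."""
        df = pd.DataFrame(
            {
                "year": self.years,
                "current_total": self.current_totals,
                "new_total": self.new_totals,
                "net_impact": self.net_impacts,
            }
        )
        totals = pd.DataFrame(
            {
                "year": ["total"],
                "current_total": [self.total_current],
                "new_total": [self.total_new],
                "net_impact": [self.total_net],
            }
        )
        return pd.concat([df, totals], ignore_index=True)


def net_budget_impact(
    current_totals: Sequence[float], new_totals: Sequence[float]
) -> BudgetImpactResult:
    """Net impact of the new scenario versus the current, year by year.

    Accepts precomputed yearly totals (e.g. published projections) or the
    output of :class:`BudgetImpactModel`.
    """
    current = np.asarray(current_totals, dtype=float)
    new = np.asarray(new_totals, dtype=float)
    if current.shape != new.shape:
        raise ValueError(
            f"scenario year coverage differs: {current.shape} vs {new.shape}"
        )
    years = np.arange(1, current.size + 1)
    return BudgetImpactResult(years=years, current_totals=current, new_totals=new)


class BudgetImpactModel:
    """Five-year budget projection from a :class:`BiaConfig`.

    Example
    -------
    >>> from uticea.params import BiaConfig
    >>> result = BudgetImpactModel(BiaConfig()).run()
    >>> result.total_net < 0  # expanding pharmacist care saves money
    True
    """

    def __init__(self, config: BiaConfig | None = None):
        self.config = config if config is not None else BiaConfig()

    def population(self) -> np.ndarray:
        c = self.config
        return project_population(c.year1_population, c.growth_rate, c.n_years)

    def uptake_schedule(self) -> tuple[np.ndarray, np.ndarray]:
        """(current, new) yearly uptake fractions."""
        c = self.config
        current = np.full(c.n_years, c.current_uptake)
        new = linear_uptake(c.current_uptake, c.target_uptake, c.n_years)
        return current, new

    def run(self) -> BudgetImpactResult:
        c = self.config
        pop = self.population()
        cur_uptake, new_uptake = self.uptake_schedule()
        current = np.array(
            [
                _round_half_up(scenario_cost(p, u, c.per_patient_cost, c.provider_mix))
                for p, u in zip(pop, cur_uptake)
            ],
            dtype=float,
        )
        new = np.array(
            [
                _round_half_up(scenario_cost(p, u, c.per_patient_cost, c.provider_mix))
                for p, u in zip(pop, new_uptake)
            ],
            dtype=float,
        )
        return net_budget_impact(current, new)

    def summary(self) -> pd.DataFrame:
        df = self.run().to_frame()
        pop = self.population()
        cur_uptake, new_uptake = self.uptake_schedule()
        df.insert(1, "population", list(pop) + [pop.sum()])
        df.insert(2, "uptake_new", list(np.round(new_uptake, 6)) + [np.nan])
        return df
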