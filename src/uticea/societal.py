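"""Societal-perspective costing: productivity losses and out-of-pocket costs.

The reference case counts only payer-borne costs.  The societal scenario
adds, per health-professional contact, the value of work time lost (hours
away times the average hourly wage) and the patient's travel cost (hourly
parking for the visit's duration, or a round-trip transit fare).  Pharmacy
visits are assumed to need no time off work, so the pharmacist arm accrues
only the transit fare.  QALMs are unaffected; only costs change.
"""

from __future__ import annotations

from .params import (
    STRATEGIES,
    ConfigurationError,
    ParameterSet,
    SocietalConstants,
    StructureConfig,
)

__all__ = [
    "productivity_loss",
    "out_of_pocket",
    "visit_addon",
    "apply_societal_perspective",
]


def productivity_loss(hours: float, wage: float) -> float:
    """Value of work time lost: hours away from work times the hourly wage."""
    if hours < 0:
        raise ValueError(f"hours must be non-negative, got {hours}")
    if wage < 0:
        raise ValueError(f"wage must be non-negative, got {wage}")
    return hours * wage


def out_of_pocket(
    mode: str, hours: float = 0.0, constants: SocietalConstants | None = None
) -> float:
    """Patient travel cost: hourly parking or a round-trip transit fare."""
    if constants is None:
        constants = SocietalConstants()
    if mode == "parking":
        if hours < 0:
            raise ValueError(f"hours must be non-negative, got {hours}")
        return constants.parking_rate_per_hour * hours
    if mode == "transit":
        return 2.0 * constants.transit_fare_one_way
    raise ConfigurationError(f"unknown transport mode {mode!r}; use 'parking' or 'transit'")


def _contact_hours(strategy: str, constants: SocietalConstants) -> float:
    """Hours spent on the initial contact (drives the parking charge)."""
    if strategy == "family":
        return constants.hours_family_visit
    if strategy == "emergency":
        return constants.hours_ed_visit
    return 0.0


def visit_addon(strategy: str, constants: SocietalConstants) -> float:
    """Societal add-on for one contact in the given arm: lost work + travel."""
    if strategy not in STRATEGIES:
        raise ConfigurationError(f"unknown strategy {strategy!r}")
    lost = productivity_loss(
        constants.work_loss_hours[strategy], constants.hourly_wage
    )
    travel = out_of_pocket(
        constants.transport_mode[strategy],
        hours=_contact_hours(strategy, constants),
        constants=constants,
    )
    return lost + travel


def _followup_strategy(strategy: str, structure: StructureConfig) -> str:
    """The arm whose add-on schedule applies to the follow-up contact.

    A follow-up billed at the family fee accrues the family arm's time and
    travel costs even when it occurs in the emergency arm's pathway.
    """
    provider = structure.followup_provider[strategy]
    if provider in ("family_initial", "family_followup"):
        return "family"
    if provider == "emergency":
        return "emergency"
    return "pharmacist"


def apply_societal_perspective(
    params: ParameterSet,
    constants: SocietalConstants | None = None,
    structure: StructureConfig | None = None,
) -> ParameterSet:
    """Return a new ParameterSet with per-visit costs widened to the
    societal perspective.

    Each arm's initial visit cost is incremented by that arm's add-on.  When
    ``constants.followup_addons`` is true (the default), the follow-up visit
    fee is likewise incremented by the add-on of the arm delivering the
    follow-up contact.  The input ParameterSet is unmodified.
    """
    if constants is None:
        constants = SocietalConstants()
    if structure is None:
        structure = StructureConfig()
    visit_cost = dict(params.visit_cost)
    initial_key = {
        "pharmacist": "pharmacist",
        "family": "family_initial",
        "emergency": "emergency",
    }
    for strategy in STRATEGIES:
        visit_cost[initial_key[strategy]] += visit_addon(strategy, constants)
    if constants.followup_addons:
        # the follow-up fee key may be shared across arms (both physician
        # arms default to the family follow-up fee), so increment it once
        followup_keys = {
            structure.followup_provider[s]: _followup_strategy(s, structure)
            for s in STRATEGIES
        }
        for key, addon_arm in followup_keys.items():
            if key in initial_key.values():
                continue  # already augmented above
            visit_cost[key] += visit_addon(addon_arm, constants)
    return params.replace(visit_cost=visit_cost)
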