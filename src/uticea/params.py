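"""Model inputs: point estimates, tree-structure options, and config I/O.

The model compares three strategies for initiating antibiotic treatment of
uncomplicated urinary tract infection in otherwise healthy, non-pregnant
women: assessment by a community pharmacist, by a family physician, or by an
emergency physician.  A :class:`ParameterSet` holds every unit cost (2018
Canadian dollars), transition probability and health-state utility the
decision tree consumes; :class:`StructureConfig` holds the choices that
shape the tree itself (who delivers the follow-up contact, how the utility
trajectory of a persistent patient is segmented).

All three objects are immutable; scenario analyses derive modified copies
with :func:`dataclasses.replace`-style helpers rather than mutating state.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "STRATEGIES",
    "ConfigurationError",
    "ParameterSet",
    "StructureConfig",
    "SocietalConstants",
    "BiaConfig",
    "default_parameter_set",
    "default_structure",
    "default_societal_constants",
    "default_bia_config",
    "load_config",
    "parameter_set_from_mapping",
]

#: Canonical strategy order: ascending expected cost in the reference case.
STRATEGIES = ("pharmacist", "family", "emergency")


class ConfigurationError(ValueError):
    """Raised when a configuration value is missing, unknown or out of range."""


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigurationError(f"{name} must lie in [0, 1], got {value!r}")


def _check_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ConfigurationError(f"{name} must be non-negative, got {value!r}")


@dataclass(frozen=True)
class ParameterSet:
    """Point estimates feeding the decision tree.

    Costs are in 2018 CAD; utilities are preference weights on the usual
    0 (death) to 1 (full health) scale; the horizon is one month, split into
    a 14-day initial-treatment window and a 16-day subsequent window.

    Attributes
    ----------
    cure_rate
        Probability of symptom resolution after initial treatment, keyed by
        strategy (``pharmacist``, ``family``, ``emergency``).  The
        complement is the persistence rate.
    visit_cost
        Fee per health-professional contact, keyed by provider:
        ``pharmacist``, ``family_initial``, ``family_followup``,
        ``emergency``.
    initial_med_cost
        Cost of the initially prescribed antibiotic course, keyed by
        strategy (aggregated over the prescribing mix of each arm).
    subsequent_med_cost
        Cost of second-round treatment: ``extend_pharmacist`` /
        ``extend_physician`` (same antibiotic continued) and
        ``switch_fluoroquinolone``.
    utility
        Health-state utilities: ``baseline`` (symptomatic), ``cured_initial``,
        ``persisted``, ``cured_subsequent``.
    p_extend_vs_switch
        Probability that a persistent patient extends the initial antibiotic
        rather than switching to a fluoroquinolone.  Not an observed
        quantity; defaults to an uninformative 0.5 split.
    """

    cure_rate: Mapping[str, float]
    visit_cost: Mapping[str, float]
    initial_med_cost: Mapping[str, float]
    subsequent_med_cost: Mapping[str, float]
    utility: Mapping[str, float]
    p_extend_vs_switch: float = 0.5
    horizon_days: int = 30
    initial_window_days: int = 14
    subsequent_window_days: int = 16

    def __post_init__(self) -> None:
        for s in STRATEGIES:
            if s not in self.cure_rate:
                raise ConfigurationError(f"cure_rate missing strategy {s!r}")
            _check_prob(f"cure_rate[{s}]", self.cure_rate[s])
            if s not in self.initial_med_cost:
                raise ConfigurationError(f"initial_med_cost missing strategy {s!r}")
        for key in ("pharmacist", "family_initial", "family_followup", "emergency"):
            if key not in self.visit_cost:
                raise ConfigurationError(f"visit_cost missing provider {key!r}")
        for key in ("extend_pharmacist", "extend_physician", "switch_fluoroquinolone"):
            if key not in self.subsequent_med_cost:
                raise ConfigurationError(f"subsequent_med_cost missing {key!r}")
        for key in ("baseline", "cured_initial", "persisted", "cured_subsequent"):
            if key not in self.utility:
                raise ConfigurationError(f"utility missing state {key!r}")
            _check_prob(f"utility[{key}]", self.utility[key])
        for name, group in (
            ("visit_cost", self.visit_cost),
            ("initial_med_cost", self.initial_med_cost),
            ("subsequent_med_cost", self.subsequent_med_cost),
        ):
            for key, value in group.items():
                _check_nonneg(f"{name}[{key}]", value)
        _check_prob("p_extend_vs_switch", self.p_extend_vs_switch)
        if self.initial_window_days + self.subsequent_window_days != self.horizon_days:
            raise ConfigurationError(
                "initial_window_days + subsequent_window_days must equal "
                f"horizon_days ({self.initial_window_days} + "
                f"{self.subsequent_window_days} != {self.horizon_days})"
            )
        # freeze the mapping fields so the dataclass is genuinely immutable
        for f in ("cure_rate", "visit_cost", "initial_med_cost",
                  "subsequent_med_cost", "utility"):
            object.__setattr__(self, f, dict(getattr(self, f)))

    @property
    def persistence_rate(self) -> dict[str, float]:
        """1 - cure rate, per strategy."""
        return {s: 1.0 - p for s, p in self.cure_rate.items()}

    def replace(self, **changes) -> "ParameterSet":
        """Return a copy with top-level fields replaced."""
        return dataclasses.replace(self, **changes)

    def with_cure_rate(self, strategy: str, value: float) -> "ParameterSet":
        if strategy not in self.cure_rate:
            raise ConfigurationError(f"unknown strategy {strategy!r}")
        rates = dict(self.cure_rate)
        rates[strategy] = value
        return self.replace(cure_rate=rates)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class StructureConfig:
    """Choices that shape the decision tree rather than parameterize it.

    ``followup_provider`` maps each strategy to the ``visit_cost`` key billed
    for the persistent patient's second contact.  By default the pharmacist
    arm returns to the pharmacist, while both physician arms use the family
    follow-up fee (a repeat emergency visit is neither printed as a follow-up
    fee nor clinically typical for persistent uncomplicated UTI).

    ``persisted_cured_days`` places the tail of a persistent patient's
    utility trajectory: the last so-many days of the subsequent window are
    valued at the cured-after-subsequent-treatment utility instead of the
    persisted utility.  The default of 0 ends the horizon at assumed
    resolution, so the cured-subsequent utility carries zero weight.
    """

    followup_provider: Mapping[str, str] = field(
        default_factory=lambda: {
            "pharmacist": "pharmacist",
            "family": "family_followup",
            "emergency": "family_followup",
        }
    )
    persisted_cured_days: int = 0

    def __post_init__(self) -> None:
        for s in STRATEGIES:
            if s not in self.followup_provider:
                raise ConfigurationError(f"followup_provider missing strategy {s!r}")
        if self.persisted_cured_days < 0:
            raise ConfigurationError("persisted_cured_days must be >= 0")
        object.__setattr__(self, "followup_provider", dict(self.followup_provider))

    def replace(self, **changes) -> "StructureConfig":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class SocietalConstants:
    """Inputs for the societal-perspective cost augmentation.

    Productivity loss is hours away from work times the average hourly wage;
    out-of-pocket cost is either hourly parking for the duration of the
    contact or a round-trip transit fare.  ``work_loss_hours`` of 0 encodes
    that pharmacist visits need no time off work.
    """

    hourly_wage: float = 22.97
    hours_family_visit: float = 4.0
    hours_ed_visit: float = 8.0
    parking_rate_per_hour: float = 1.75
    transit_fare_one_way: float = 2.75
    #: transport mode per strategy: "parking" or "transit"
    transport_mode: Mapping[str, str] = field(
        default_factory=lambda: {
            "pharmacist": "transit",
            "family": "transit",
            "emergency": "parking",
        }
    )
    #: hours of lost work per strategy's initial contact
    work_loss_hours: Mapping[str, float] = field(
        default_factory=lambda: {
            "pharmacist": 0.0,
            "family": 4.0,
            "emergency": 8.0,
        }
    )
    #: whether the persistence-branch follow-up contact repeats the add-on
    followup_addons: bool = True

    def __post_init__(self) -> None:
        for name in ("hourly_wage", "hours_family_visit", "hours_ed_visit",
                     "parking_rate_per_hour", "transit_fare_one_way"):
            _check_nonneg(name, getattr(self, name))
        for s in STRATEGIES:
            if s not in self.transport_mode:
                raise ConfigurationError(f"transport_mode missing strategy {s!r}")
            if self.transport_mode[s] not in ("parking", "transit"):
                raise ConfigurationError(
                    f"transport_mode[{s}] must be 'parking' or 'transit', "
                    f"got {self.transport_mode[s]!r}"
                )
            _check_nonneg(f"work_loss_hours[{s}]", self.work_loss_hours.get(s, 0.0))
        object.__setattr__(self, "transport_mode", dict(self.transport_mode))
        object.__setattr__(self, "work_loss_hours", dict(self.work_loss_hours))

    def replace(self, **changes) -> "SocietalConstants":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class BiaConfig:
    """Budget-impact settings: eligible population, uptake ramp, unit costs.

    The eligible population is Canadian women aged 25+ expected to seek care
    for uncomplicated UTI in a year (12% annual incidence applied to the
    base population, growing 1% per year).  The current scenario holds
    pharmacist uptake at ``current_uptake``; the new scenario ramps linearly
    to ``target_uptake`` by year ``n_years``.  ``provider_mix`` splits the
    non-pharmacist share between family and emergency care; the default
    emergency share is calibrated so the year-1 current-scenario per-patient
    cost matches the published reference projection and is logged as such.
    """

    year1_population: int = 1_614_384
    growth_rate: float = 0.01
    n_years: int = 5
    current_uptake: float = 0.01
    target_uptake: float = 0.25
    provider_mix: Mapping[str, float] = field(
        default_factory=lambda: {"family": 0.959596, "emergency": 0.040404}
    )
    per_patient_cost: Mapping[str, float] = field(
        default_factory=lambda: {
            "pharmacist": 72.47,
            "family": 141.53,
            "emergency": 368.16,
        }
    )

    def __post_init__(self) -> None:
        if self.year1_population <= 0:
            raise ConfigurationError("year1_population must be positive")
        if self.n_years < 1:
            raise ConfigurationError("n_years must be >= 1")
        _check_prob("current_uptake", self.current_uptake)
        _check_prob("target_uptake", self.target_uptake)
        mix_sum = sum(self.provider_mix.values())
        if abs(mix_sum - 1.0) > 1e-9:
            raise ConfigurationError(
                f"provider_mix must sum to 1, got {mix_sum!r}"
            )
        for s in STRATEGIES:
            if s not in self.per_patient_cost:
                raise ConfigurationError(f"per_patient_cost missing strategy {s!r}")
        object.__setattr__(self, "provider_mix", dict(self.provider_mix))
        object.__setattr__(self, "per_patient_cost", dict(self.per_patient_cost))

    def replace(self, **changes) -> "BiaConfig":
        return dataclasses.replace(self, **changes)


# ---------------------------------------------------------------------------
# config I/O


def _default_config_text() -> str:
    return resources.files("uticea").joinpath("data/default_params.yaml").read_text()


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML/JSON parameter file (the bundled default when ``path`` is None)."""
    if path is None:
        raw = yaml.safe_load(_default_config_text())
    else:
        p = Path(path)
        if not p.exists():
            raise ConfigurationError(f"parameter file not found: {p}")
        raw = yaml.safe_load(p.read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError("parameter file must contain a mapping at top level")
    return raw


def parameter_set_from_mapping(cfg: Mapping) -> ParameterSet:
    """Build a :class:`ParameterSet` from a loaded config mapping."""
    kwargs = {}
    for key in ("cure_rate", "visit_cost", "initial_med_cost",
                "subsequent_med_cost", "utility"):
        if key not in cfg:
            raise ConfigurationError(f"config missing required section {key!r}")
        kwargs[key] = cfg[key]
    for key in ("p_extend_vs_switch", "horizon_days", "initial_window_days",
                "subsequent_window_days"):
        if key in cfg:
            kwargs[key] = cfg[key]
    return ParameterSet(**kwargs)


def _structure_from_mapping(cfg: Mapping) -> StructureConfig:
    sub = cfg.get("structure", {})
    kwargs = {}
    if "followup_provider" in sub:
        kwargs["followup_provider"] = sub["followup_provider"]
    if "persisted_cured_days" in sub:
        kwargs["persisted_cured_days"] = sub["persisted_cured_days"]
    return StructureConfig(**kwargs)


def _societal_from_mapping(cfg: Mapping) -> SocietalConstants:
    sub = cfg.get("societal", {})
    allowed = {f.name for f in dataclasses.fields(SocietalConstants)}
    unknown = set(sub) - allowed
    if unknown:
        raise ConfigurationError(f"unknown societal keys: {sorted(unknown)}")
    return SocietalConstants(**sub)


def _bia_from_mapping(cfg: Mapping) -> BiaConfig:
    sub = cfg.get("bia", {})
    allowed = {f.name for f in dataclasses.fields(BiaConfig)}
    unknown = set(sub) - allowed
    if unknown:
        raise ConfigurationError(f"unknown bia keys: {sorted(unknown)}")
    return BiaConfig(**sub)


def default_parameter_set() -> ParameterSet:
    """The bundled reference-case point estimates."""
    return parameter_set_from_mapping(load_config())


def default_structure() -> StructureConfig:
    return _structure_from_mapping(load_config())


def default_societal_constants() -> SocietalConstants:
    return _societal_from_mapping(load_config())


def default_bia_config() -> BiaConfig:
    return _bia_from_mapping(load_config())
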