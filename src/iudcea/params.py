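"""Parameter containers for the IUD-provision decision model.

All monetary values are 2023 BRL; all probabilities are per monthly cycle;
utilities are on the usual 0-1 dead/full-health scale.

Each container is a plain dataclass with an explicit ``validate`` method
returning a list of human-readable violations (empty when valid), so that a
configuration file can be checked in one pass and every problem reported with
its field path.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field


class ValidationError(ValueError):
    """Raised when one or more parameter invariants are violated.

    ``errors`` holds every violation found, each naming the offending field.
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


def _check_prob(value: float, name: str, errors: list[str]) -> None:
    if not (0.0 <= value <= 1.0):
        errors.append(f"{name}={value!r} must be a probability in [0, 1]")


@dataclass(frozen=True)
class ScenarioSpec:
    """One provision strategy: who is trained and how fast uptake happens.

    p_provision is the monthly probability that an eligible non-user
    receives an IUD; cohort_size the number of eligible users followed;
    n_professionals the number of nurses whose training is costed.
    """

    name: str
    p_provision: float
    cohort_size: int
    n_professionals: int = 1

    def validate(self) -> list[str]:
        errors: list[str] = []
        if not self.name:
            errors.append("scenario name must be non-empty")
        _check_prob(self.p_provision, f"scenarios.{self.name}.p_provision", errors)
        if self.cohort_size < 1:
            errors.append(
                f"scenarios.{self.name}.cohort_size={self.cohort_size} must be >= 1"
            )
        if self.n_professionals < 0:
            errors.append(
                f"scenarios.{self.name}.n_professionals={self.n_professionals}"
                " must be >= 0"
            )
        return errors


@dataclass(frozen=True)
class TransitionParams:
    """Monthly transition probabilities between the four health states.

    p_provision is normally injected per scenario at run time; the field
    exists here so a single object fully determines one transition matrix.
    retain_iud_after_loss controls whether a woman whose pregnancy ends
    while using an IUD returns to the with-IUD or without-IUD state.
    """

    p_preg_no_iud: float
    p_preg_iud: float
    p_loss: float = 0.0
    p_provision: float = 0.0
    retain_iud_after_loss: bool = False

    def validate(self) -> list[str]:
        errors: list[str] = []
        for name in ("p_preg_no_iud", "p_preg_iud", "p_loss", "p_provision"):
            _check_prob(getattr(self, name), f"transitions.{name}", errors)
        if self.p_preg_iud > self.p_preg_no_iud:
            errors.append(
                "transitions.p_preg_iud must not exceed transitions.p_preg_no_iud"
                f" ({self.p_preg_iud!r} > {self.p_preg_no_iud!r})"
            )
        return errors


@dataclass(frozen=True)
class UtilitySet:
    """Per-state preference weights.

    The pregnant-with-IUD state is valued as u_iud_no_preg plus the
    (negative) disutility of an unintended pregnancy on the method;
    u_preg_no_iud is a free parameter because no published weight exists
    for that state in this population.
    """

    u_iud_no_preg: float = 1.0
    u_no_iud_no_preg: float = 0.8
    disutility_preg_iud: float = -0.1
    u_preg_no_iud: float = 0.7

    @property
    def u_preg_iud(self) -> float:
        return self.u_iud_no_preg + self.disutility_preg_iud

    def state_utilities(self) -> tuple[float, float, float, float]:
        """Utilities ordered as (NOT_PREG_NO_IUD, NOT_PREG_IUD, PREG_NO_IUD, PREG_IUD)."""
        return (
            self.u_no_iud_no_preg,
            self.u_iud_no_preg,
            self.u_preg_no_iud,
            self.u_preg_iud,
        )

    def validate(self) -> list[str]:
        errors: list[str] = []
        if self.disutility_preg_iud > 0:
            errors.append(
                f"utilities.disutility_preg_iud={self.disutility_preg_iud!r}"
                " must be <= 0"
            )
        labels = ("u_no_iud_no_preg", "u_iud_no_preg", "u_preg_no_iud", "u_preg_iud")
        for label, value in zip(labels, self.state_utilities()):
            if not (0.0 <= value <= 1.0):
                errors.append(f"utilities.{label}={value!r} must lie in [0, 1]")
        return errors


@dataclass(frozen=True)
class CostSet:
    """Unit costs (2023 BRL) from the SUS payer perspective."""

    c_training_per_professional: float = 1820.38
    c_insertion: float = 91.02
    c_consultation_no_iud: float = 10.00
    c_unintended_pregnancy: float = 3000.00

    def validate(self) -> list[str]:
        errors: list[str] = []
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if value < 0:
                errors.append(f"costs.{f.name}={value!r} must be >= 0")
        return errors


@dataclass(frozen=True)
class ModelConfig:
    """Horizon, cycle length, discounting and willingness-to-pay settings."""

    n_cycles: int = 3
    cycle_length: float = 1.0 / 12.0
    discount_rate: float = 0.0
    half_cycle_correction: bool = False
    wtp_primary: float = 40_000.0
    wtp_max: float = 120_000.0

    def validate(self) -> list[str]:
        errors: list[str] = []
        if self.n_cycles < 1:
            errors.append(f"config.n_cycles={self.n_cycles} must be >= 1")
        if self.cycle_length <= 0:
            errors.append(f"config.cycle_length={self.cycle_length!r} must be > 0")
        if self.discount_rate < 0:
            errors.append(f"config.discount_rate={self.discount_rate!r} must be >= 0")
        if self.wtp_primary < 0:
            errors.append(f"config.wtp_primary={self.wtp_primary!r} must be >= 0")
        if self.wtp_primary > self.wtp_max:
            errors.append(
                f"config.wtp_primary={self.wtp_primary!r} must not exceed"
                f" config.wtp_max={self.wtp_max!r}"
            )
        return errors


@dataclass(frozen=True)
class ParameterSet:
    """Every input needed for one full analysis.

    ``assumed`` lists dotted field paths whose values are assumptions rather
    than published figures; they travel with the object so serialized
    configurations keep the flag.
    """

    scenarios: tuple[ScenarioSpec, ...]
    transitions: TransitionParams
    utilities: UtilitySet = field(default_factory=UtilitySet)
    costs: CostSet = field(default_factory=CostSet)
    config: ModelConfig = field(default_factory=ModelConfig)
    assumed: tuple[str, ...] = ()

    def validate(self) -> list[str]:
        errors: list[str] = []
        if not self.scenarios:
            errors.append("scenarios must contain at least one entry")
        names = [s.name for s in self.scenarios]
        if len(set(names)) != len(names):
            errors.append(f"scenario names must be unique, got {names}")
        for s in self.scenarios:
            errors.extend(s.validate())
        errors.extend(self.transitions.validate())
        errors.extend(self.utilities.validate())
        errors.extend(self.costs.validate())
        errors.extend(self.config.validate())
        return errors

    def require_valid(self) -> "ParameterSet":
        errors = self.validate()
        if errors:
            raise ValidationError(errors)
        return self

    def scenario(self, name: str) -> ScenarioSpec:
        for s in self.scenarios:
            if s.name == name:
                return s
        raise KeyError(f"no scenario named {name!r}")


_GROUPS = ("transitions", "utilities", "costs", "config")


def get_param(ps: ParameterSet, path: str) -> float:
    """Read a parameter by dotted path.

    Paths are ``<group>.<field>`` for group in transitions/utilities/costs/
    config, or ``scenarios.<name>.<field>`` for per-scenario values.
    """
    parts = path.split(".")
    if parts[0] == "scenarios":
        if len(parts) != 3:
            raise KeyError(f"scenario path must be scenarios.<name>.<field>: {path!r}")
        return getattr(ps.scenario(parts[1]), parts[2])
    if len(parts) != 2 or parts[0] not in _GROUPS:
        raise KeyError(f"unknown parameter path {path!r}")
    group = getattr(ps, parts[0])
    if not hasattr(group, parts[1]):
        raise KeyError(f"unknown parameter path {path!r}")
    return getattr(group, parts[1])


def set_param(ps: ParameterSet, path: str, value) -> ParameterSet:
    """Return a copy of ``ps`` with the parameter at ``path`` replaced."""
    parts = path.split(".")
    if parts[0] == "scenarios":
        if len(parts) != 3:
            raise KeyError(f"scenario path must be scenarios.<name>.<field>: {path!r}")
        target = ps.scenario(parts[1])  # raises KeyError for unknown name
        if not hasattr(target, parts[2]):
            raise KeyError(f"unknown parameter path {path!r}")
        new_scenarios = tuple(
            dataclasses.replace(s, **{parts[2]: value}) if s.name == parts[1] else s
            for s in ps.scenarios
        )
        return dataclasses.replace(ps, scenarios=new_scenarios)
    get_param(ps, path)  # raises KeyError for unknown paths
    group = getattr(ps, parts[0])
    return dataclasses.replace(
        ps, **{parts[0]: dataclasses.replace(group, **{parts[1]: value})}
    )


def apply_values(ps: ParameterSet, values: dict[str, float]) -> ParameterSet:
    """Apply several path->value overrides at once (single pass, one copy each)."""
    out = ps
    for path, value in values.items():
        out = set_param(out, path, value)
    return out


def deep_copy(ps: ParameterSet) -> ParameterSet:
    return copy.deepcopy(ps)
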