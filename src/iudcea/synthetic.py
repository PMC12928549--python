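"""Base-case parameter fixture and a generator of random valid inputs.

``paper_fixture`` assembles the study's published base case: four provision
scenarios for Pernambuco's public health network (the observed 0.24% monthly
provision probability plus hypothetical expansions to 2%, 3.2% and 4%, with
the published eligible-user counts), the published utilities and unit costs,
a three-month monthly-cycle horizon with no discounting, and the Brazilian
willingness-to-pay thresholds. Quantities the study did not publish —
monthly pregnancy probabilities, the utility of an unintended pregnancy
without an IUD, consultation and pregnancy unit costs, professionals trained
per scenario — are filled with clearly flagged assumptions (see ``assumed``
on the returned object and the methods note for rationale).

``generate_params`` produces random-but-valid parameter sets, distribution
specifications and one-way ranges centred near the fixture, standing in for
the study's unpublished supplementary parameter table so that every pipeline
stage can be exercised without external data.
"""

from __future__ import annotations

import logging

import numpy as np

from .params import (
    CostSet,
    ModelConfig,
    ParameterSet,
    ScenarioSpec,
    TransitionParams,
    UtilitySet,
    apply_values,
    get_param,
    set_param,
)
from .sensitivity import DistributionSpec, ParamRange

__all__ = [
    "paper_fixture",
    "default_ranges",
    "default_distributions",
    "generate_params",
]

logger = logging.getLogger(__name__)


def annual_to_monthly(p_annual: float) -> float:
    """Convert an annual event probability to a monthly one: 1-(1-p)^(1/12)."""
    return 1.0 - (1.0 - p_annual) ** (1.0 / 12.0)


# Assumed clinical inputs (not published in the source study):
# typical-use pregnancy rate with no contraceptive method, 85%/year, and
# copper-IUD typical-use failure rate, 0.8%/year, both converted to monthly.
P_PREG_NO_METHOD_MONTHLY = annual_to_monthly(0.85)
P_PREG_IUD_MONTHLY = annual_to_monthly(0.008)

ASSUMED_PATHS = (
    "transitions.p_preg_no_iud",
    "transitions.p_preg_iud",
    "transitions.p_loss",
    "utilities.u_preg_no_iud",
    "costs.c_consultation_no_iud",
    "costs.c_unintended_pregnancy",
    "scenarios.Pernambuco.n_professionals",
    "scenarios.Scenario 1.n_professionals",
    "scenarios.Scenario 2.n_professionals",
    "scenarios.Scenario 3.n_professionals",
)


def paper_fixture() -> ParameterSet:
    """The frozen base-case parameter set (deterministic)."""
    scenarios = (
        ScenarioSpec("Pernambuco", p_provision=0.0024, cohort_size=600, n_professionals=1),
        ScenarioSpec("Scenario 1", p_provision=0.02, cohort_size=734, n_professionals=1),
        ScenarioSpec("Scenario 2", p_provision=0.032, cohort_size=1226, n_professionals=1),
        ScenarioSpec("Scenario 3", p_provision=0.04, cohort_size=1532, n_professionals=1),
    )
    return ParameterSet(
        scenarios=scenarios,
        transitions=TransitionParams(
            p_preg_no_iud=P_PREG_NO_METHOD_MONTHLY,
            p_preg_iud=P_PREG_IUD_MONTHLY,
            p_loss=0.0,
            retain_iud_after_loss=False,
        ),
        utilities=UtilitySet(
            u_iud_no_preg=1.0,
            u_no_iud_no_preg=0.8,
            disutility_preg_iud=-0.1,
            u_preg_no_iud=0.7,
        ),
        costs=CostSet(
            c_training_per_professional=1820.38,
            c_insertion=91.02,
            c_consultation_no_iud=10.00,
            c_unintended_pregnancy=3000.00,
        ),
        config=ModelConfig(
            n_cycles=3,
            cycle_length=1.0 / 12.0,
            discount_rate=0.0,
            half_cycle_correction=False,
            wtp_primary=40_000.0,
            wtp_max=120_000.0,
        ),
        assumed=ASSUMED_PATHS,
    ).require_valid()


# Parameters varied in sensitivity analyses: costs and utilities for the
# one-way ranges, plus the pregnancy probabilities for the probabilistic
# analysis (sd values are assumptions; the study states only that means and
# standard deviations were used).
_COST_PATHS = (
    "costs.c_training_per_professional",
    "costs.c_insertion",
    "costs.c_consultation_no_iud",
    "costs.c_unintended_pregnancy",
)
_UTILITY_PATHS = (
    "utilities.u_iud_no_preg",
    "utilities.u_no_iud_no_preg",
    "utilities.u_preg_no_iud",
    "utilities.disutility_preg_iud",
)
_PROB_PATHS = ("transitions.p_preg_no_iud", "transitions.p_preg_iud")


def default_ranges(ps: ParameterSet, rel: float = 0.2) -> list[ParamRange]:
    """Plus/minus ``rel`` one-way ranges on costs and utilities, clipped to domain."""
    ranges = []
    for path in _COST_PATHS + _UTILITY_PATHS:
        base = get_param(ps, path)
        lo, hi = sorted((base * (1 - rel), base * (1 + rel)))
        if path.split(".")[-1].startswith("u_"):
            hi = min(hi, 1.0)
        ranges.append(ParamRange(param_path=path, low=lo, base=base, high=hi))
    return ranges


def default_distributions(ps: ParameterSet, rel_sd: float = 0.1) -> list[DistributionSpec]:
    """Beta (probabilities/utilities) and gamma (costs) specs at ``rel_sd`` x mean."""
    dists = []
    for path in _COST_PATHS:
        mean = get_param(ps, path)
        dists.append(DistributionSpec(path, "gamma", mean=mean, sd=rel_sd * mean))
    for path in _UTILITY_PATHS + _PROB_PATHS:
        mean = get_param(ps, path)
        sd = _feasible_beta_sd(path, abs(mean), rel_sd * abs(mean))
        if mean in (0.0, 1.0):
            dists.append(DistributionSpec(path, "fixed", mean=mean))
        else:
            dists.append(DistributionSpec(path, "beta", mean=mean, sd=sd))
    return dists


def _feasible_beta_sd(path: str, mean: float, sd: float) -> float:
    """Shrink sd until the beta method of moments is feasible; log if shrunk."""
    if mean <= 0.0 or mean >= 1.0:
        return 0.0
    bound = np.sqrt(mean * (1.0 - mean))
    if sd >= bound:
        shrunk = 0.5 * bound
        logger.warning(
            "sd=%g infeasible for beta mean %g at %s; shrunk to %g",
            sd, mean, path, shrunk,
        )
        return shrunk
    return sd


def generate_params(
    seed: int, spread: float = 0.1
) -> tuple[ParameterSet, list[DistributionSpec], list[ParamRange]]:
    """Random valid parameter set + matching distribution specs and ranges.

    Means are drawn within a relative ``spread`` of the fixture values (and
    clipped to their domains); standard deviations are ``spread`` x mean with
    beta feasibility enforced; one-way ranges are mean +/- 2 sd clipped to
    the domain. Deterministic given the seed.
    """
    if not (0.0 < spread <= 0.5):
        raise ValueError(f"spread must lie in (0, 0.5], got {spread!r}")
    rng = np.random.default_rng(seed)
    base = paper_fixture()

    prob_paths = [f"scenarios.{s.name}.p_provision" for s in base.scenarios]
    prob_paths += list(_PROB_PATHS) + ["transitions.p_loss"]
    util_paths = ["utilities.u_iud_no_preg", "utilities.u_no_iud_no_preg",
                  "utilities.u_preg_no_iud"]

    values: dict[str, float] = {}
    dists: list[DistributionSpec] = []
    ranges: list[ParamRange] = []

    def jitter(v: float) -> float:
        return v * (1.0 + rng.uniform(-spread, spread))

    eps = 1e-6
    for path in prob_paths + util_paths:
        v = get_param(base, path)
        if v in (0.0, 1.0):  # boundary values stay fixed (beta infeasible there)
            mean, sd = v, 0.0
            family = "fixed"
        else:
            mean = float(np.clip(jitter(v), eps, 1.0 - eps))
            sd = _feasible_beta_sd(path, mean, spread * mean)
            family = "beta"
        values[path] = mean
        dists.append(DistributionSpec(path, family, mean=mean, sd=sd))
        ranges.append(
            ParamRange(path, low=max(0.0, mean - 2 * sd), base=mean,
                       high=min(1.0, mean + 2 * sd))
        )

    # disutility: beta on the magnitude, negated
    v = abs(get_param(base, "utilities.disutility_preg_iud"))
    mean = float(np.clip(jitter(v), eps, 1.0 - eps))
    sd = _feasible_beta_sd("utilities.disutility_preg_iud", mean, spread * mean)
    values["utilities.disutility_preg_iud"] = -mean
    dists.append(DistributionSpec("utilities.disutility_preg_iud", "beta",
                                  mean=-mean, sd=sd))
    ranges.append(
        ParamRange("utilities.disutility_preg_iud",
                   low=max(-1.0, -mean - 2 * sd), base=-mean,
                   high=min(0.0, -mean + 2 * sd))
    )

    for path in _COST_PATHS:
        mean = max(eps, jitter(get_param(base, path)))
        sd = spread * mean
        values[path] = mean
        dists.append(DistributionSpec(path, "gamma", mean=mean, sd=sd))
        ranges.append(ParamRange(path, low=max(0.0, mean - 2 * sd), base=mean,
                                 high=mean + 2 * sd))

    # keep the method-failure rate below the no-method pregnancy rate
    if values["transitions.p_preg_iud"] > values["transitions.p_preg_no_iud"]:
        values["transitions.p_preg_iud"] = values["transitions.p_preg_no_iud"]
        dists = [
            DistributionSpec(d.param_path, d.family,
                             mean=values["transitions.p_preg_iud"], sd=d.sd)
            if d.param_path == "transitions.p_preg_iud" else d
            for d in dists
        ]

    ps = apply_values(base, values).require_valid()
    return ps, dists, ranges
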