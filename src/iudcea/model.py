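"""Four-state monthly Markov cohort engine.

The cohort is distributed over four mutually exclusive health states:

* ``NOT_PREG_NO_IUD`` — not pregnant, no IUD (the starting state);
* ``NOT_PREG_IUD`` — not pregnant, using an IUD;
* ``PREG_NO_IUD`` — unintended pregnancy without an IUD;
* ``PREG_IUD`` — unintended pregnancy despite an IUD (method failure).

Within one cycle, uptake is evaluated before pregnancy risk: a woman offered
an IUD this month is only exposed to the (much lower) IUD failure rate from
the next month on, because insertion presupposes a non-pregnant consultation.
Pregnancy loss returns the cohort fraction to a non-pregnant state, with or
without the device depending on ``retain_iud_after_loss``.

Rewards follow the usual cohort-model conventions: utilities and recurring
costs accrue on the state occupied at the start of each cycle (an optional
half-cycle correction averages start and end occupancy instead), while
one-time costs (insertion, pregnancy) are charged on the transition flow
into the new state. Discounting is a per-cycle geometric factor; the default
annual rate is 0 because the horizon is shorter than a year.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .params import (
    CostSet,
    ModelConfig,
    ParameterSet,
    ScenarioSpec,
    TransitionParams,
    UtilitySet,
    ValidationError,
)

__all__ = [
    "HealthState",
    "CohortTrace",
    "build_transition_matrix",
    "run_cohort",
    "run_scenario",
    "run_all",
    "percent_increase",
]


class HealthState(enum.IntEnum):
    """The four model states; integer values index the transition matrix."""

    NOT_PREG_NO_IUD = 0
    NOT_PREG_IUD = 1
    PREG_NO_IUD = 2
    PREG_IUD = 3


@dataclass(frozen=True)
class CohortTrace:
    """Outputs of one cohort run.

    occupancy has shape (n_cycles + 1, 4): row 0 is the initial distribution,
    row t the distribution after cycle t. cum_cost / cum_qaly are the running
    per-person discounted totals at the same indices. Totals scale the
    per-person quantities by cohort size and add the one-off training cost.
    """

    scenario: str
    occupancy: np.ndarray
    cum_cost: np.ndarray
    cum_qaly: np.ndarray
    cost_per_person: float
    qaly_per_person: float
    cost_total: float
    qaly_total: float


def build_transition_matrix(tp: TransitionParams) -> np.ndarray:
    """Build the 4x4 row-stochastic monthly transition matrix.

    Raises ValidationError if any probability is outside [0, 1].
    """
    errors = tp.validate()
    if errors:
        raise ValidationError(errors)

    m = np.zeros((4, 4))
    s = HealthState

    # Uptake first, then pregnancy risk on the remainder.
    m[s.NOT_PREG_NO_IUD, s.NOT_PREG_IUD] = tp.p_provision
    m[s.NOT_PREG_NO_IUD, s.PREG_NO_IUD] = (1.0 - tp.p_provision) * tp.p_preg_no_iud
    m[s.NOT_PREG_NO_IUD, s.NOT_PREG_NO_IUD] = (
        (1.0 - tp.p_provision) * (1.0 - tp.p_preg_no_iud)
    )

    m[s.NOT_PREG_IUD, s.PREG_IUD] = tp.p_preg_iud
    m[s.NOT_PREG_IUD, s.NOT_PREG_IUD] = 1.0 - tp.p_preg_iud

    m[s.PREG_NO_IUD, s.NOT_PREG_NO_IUD] = tp.p_loss
    m[s.PREG_NO_IUD, s.PREG_NO_IUD] = 1.0 - tp.p_loss

    post_loss = s.NOT_PREG_IUD if tp.retain_iud_after_loss else s.NOT_PREG_NO_IUD
    m[s.PREG_IUD, post_loss] = tp.p_loss
    m[s.PREG_IUD, s.PREG_IUD] = 1.0 - tp.p_loss

    return m


def _cycle_rewards(
    occ_start: np.ndarray,
    occ_end: np.ndarray,
    flows: np.ndarray,
    utilities: np.ndarray,
    c: CostSet,
    cfg: ModelConfig,
) -> tuple[float, float]:
    """Undiscounted (cost, qaly) accrued during one cycle, per person."""
    s = HealthState
    occ_basis = 0.5 * (occ_start + occ_end) if cfg.half_cycle_correction else occ_start
    qaly = float(occ_basis @ utilities) * cfg.cycle_length
    cost = c.c_consultation_no_iud * float(occ_basis[s.NOT_PREG_NO_IUD])
    cost += c.c_insertion * float(flows[s.NOT_PREG_NO_IUD, s.NOT_PREG_IUD])
    cost += c.c_unintended_pregnancy * float(
        flows[s.NOT_PREG_NO_IUD, s.PREG_NO_IUD] + flows[s.NOT_PREG_IUD, s.PREG_IUD]
    )
    return cost, qaly


def run_cohort(
    scenario: ScenarioSpec,
    tp: TransitionParams,
    u: UtilitySet,
    c: CostSet,
    cfg: ModelConfig,
    initial: np.ndarray | None = None,
) -> CohortTrace:
    """Run the cohort model for one scenario and accumulate cost and QALYs.

    The scenario's provision probability overrides the one carried by ``tp``.
    The cohort starts entirely in NOT_PREG_NO_IUD unless ``initial`` (a
    length-4 distribution summing to 1) is given.
    """
    import dataclasses as _dc

    for obj in (scenario, u, c, cfg):
        errors = obj.validate()
        if errors:
            raise ValidationError(errors)
    tp = _dc.replace(tp, p_provision=scenario.p_provision)
    m = build_transition_matrix(tp)
    row_sums = m.sum(axis=1)
    if not np.allclose(row_sums, 1.0, atol=1e-12):
        raise ValidationError(
            [f"internal: transition matrix rows sum to {row_sums}, expected 1"]
        )

    if initial is None:
        occ = np.zeros(4)
        occ[HealthState.NOT_PREG_NO_IUD] = 1.0
    else:
        occ = np.asarray(initial, dtype=float)
        if occ.shape != (4,) or abs(occ.sum() - 1.0) > 1e-9 or (occ < 0).any():
            raise ValidationError(
                ["initial occupancy must be a length-4 distribution summing to 1"]
            )

    utilities = np.array(u.state_utilities())
    n = cfg.n_cycles
    occupancy = np.empty((n + 1, 4))
    occupancy[0] = occ
    cum_cost = np.zeros(n + 1)
    cum_qaly = np.zeros(n + 1)

    for t in range(1, n + 1):
        occ_start = occupancy[t - 1]
        flows = occ_start[:, None] * m
        occ_end = flows.sum(axis=0)
        occupancy[t] = occ_end
        cost, qaly = _cycle_rewards(occ_start, occ_end, flows, utilities, c, cfg)
        disc = (1.0 + cfg.discount_rate) ** (-(t - 1) * cfg.cycle_length)
        cum_cost[t] = cum_cost[t - 1] + disc * cost
        cum_qaly[t] = cum_qaly[t - 1] + disc * qaly

    cost_pp = float(cum_cost[-1])
    qaly_pp = float(cum_qaly[-1])
    cost_total = (
        scenario.cohort_size * cost_pp
        + scenario.n_professionals * c.c_training_per_professional
    )
    return CohortTrace(
        scenario=scenario.name,
        occupancy=occupancy,
        cum_cost=cum_cost,
        cum_qaly=cum_qaly,
        cost_per_person=cost_pp,
        qaly_per_person=qaly_pp,
        cost_total=cost_total,
        qaly_total=scenario.cohort_size * qaly_pp,
    )


def run_scenario(ps: ParameterSet, name: str) -> CohortTrace:
    """Run one named scenario from a full parameter set."""
    return run_cohort(
        ps.scenario(name), ps.transitions, ps.utilities, ps.costs, ps.config
    )


def run_all(ps: ParameterSet) -> list[CohortTrace]:
    """Run every scenario in the parameter set, in declared order."""
    return [run_scenario(ps, s.name) for s in ps.scenarios]


def percent_increase(p0: float, p1: float) -> float:
    """Relative increase from baseline p0 to p1, in percent: (p1-p0)/p0*100."""
    if p0 == 0:
        raise ValueError("baseline probability p0 must be non-zero")
    return (p1 - p0) / p0 * 100.0
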