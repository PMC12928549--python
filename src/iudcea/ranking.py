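"""Ranking of strategies by cost-effectiveness.

Implements the standard health-technology-assessment decision rules:

* **strong dominance** — a strategy is dominated when some other strategy is
  no more costly and no less effective, with at least one strict inequality;
* **extended dominance** — among the survivors ordered by effectiveness, a
  strategy is excluded when its incremental cost-effectiveness ratio (ICER)
  exceeds that of the next more effective option, i.e. a mixture of its
  neighbours would deliver more health at lower cost;
* **ICER** — incremental cost divided by incremental effectiveness against
  the comparator;
* **net monetary benefit (NMB)** — effectiveness x willingness-to-pay - cost.

The table builder mirrors the layout used in published CEA rankings: rows
sorted by ascending cost, increments computed against the preceding
non-dominated row (so dominated rows are still compared with the last
efficient strategy above them), and signed ICERs reported even for dominated
rows, flagged as not interpretable.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ValidationError

__all__ = [
    "StrategyResult",
    "Dominance",
    "CEARow",
    "CEATable",
    "classify_dominance",
    "build_cea_table",
    "nmb",
    "wtp_grid",
]


@dataclass(frozen=True)
class StrategyResult:
    """Total cost (BRL) and effectiveness (QALY) of one strategy."""

    name: str
    cost: float
    effectiveness: float


class Dominance(str, enum.Enum):
    NOT_DOMINATED = "NOT_DOMINATED"
    DOMINATED = "DOMINATED"
    EXTENDEDLY_DOMINATED = "EXTENDEDLY_DOMINATED"


def nmb(strategy: StrategyResult, wtp: float) -> float:
    """Net monetary benefit at a willingness-to-pay threshold (BRL/QALY)."""
    if wtp < 0:
        raise ValueError(f"wtp must be >= 0, got {wtp!r}")
    return strategy.effectiveness * wtp - strategy.cost


def _strongly_dominated(s: StrategyResult, others: list[StrategyResult]) -> bool:
    for t in others:
        if t is s:
            continue
        if t.cost <= s.cost and t.effectiveness >= s.effectiveness:
            if t.cost < s.cost or t.effectiveness > s.effectiveness:
                return True
    return False


def classify_dominance(
    strategies: list[StrategyResult],
) -> dict[str, Dominance]:
    """Label each strategy as not dominated, dominated, or extendedly dominated.

    Strong dominance is checked pairwise against every other strategy;
    extended dominance is then applied iteratively along the remaining
    frontier ordered by effectiveness. Exact (cost, effectiveness) ties are
    both kept. Output is independent of input order.
    """
    if not strategies:
        raise ValidationError(["at least one strategy is required"])
    names = [s.name for s in strategies]
    if len(set(names)) != len(names):
        raise ValidationError([f"strategy names must be unique, got {names}"])

    labels: dict[str, Dominance] = {}
    survivors: list[StrategyResult] = []
    for s in strategies:
        if _strongly_dominated(s, strategies):
            labels[s.name] = Dominance.DOMINATED
        else:
            labels[s.name] = Dominance.NOT_DOMINATED
            survivors.append(s)

    # Iterative extended-dominance sweep over distinct frontier points in
    # ascending effectiveness. Exact (cost, eff) ties collapse to a single
    # point (both members share its fate); among the survivors of strong
    # dominance, effectiveness and cost then increase strictly together.
    groups: dict[tuple[float, float], list[str]] = {}
    for s in survivors:
        groups.setdefault((s.effectiveness, s.cost), []).append(s.name)
    frontier = sorted(groups)
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        for i in range(1, len(frontier) - 1):
            (e_lo, c_lo), (e_mid, c_mid), (e_hi, c_hi) = frontier[i - 1 : i + 2]
            icer_lo = (c_mid - c_lo) / (e_mid - e_lo)
            icer_hi = (c_hi - c_mid) / (e_hi - e_mid)
            if icer_lo > icer_hi:
                for name in groups[(e_mid, c_mid)]:
                    labels[name] = Dominance.EXTENDEDLY_DOMINATED
                frontier.pop(i)
                changed = True
                break
    return labels


@dataclass(frozen=True)
class CEARow:
    name: str
    dominance: Dominance
    cost: float
    effectiveness: float
    incremental_cost: float | None
    incremental_effectiveness: float | None
    icer: float | None
    icer_interpretable: bool
    nmb: float


@dataclass(frozen=True)
class CEATable:
    """Cost-ordered ranking with increments, ICERs and NMB at one threshold."""

    rows: tuple[CEARow, ...]
    wtp: float

    def row(self, name: str) -> CEARow:
        for r in self.rows:
            if r.name == name:
                return r
        raise KeyError(f"no strategy named {name!r}")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strategy": [r.name for r in self.rows],
                "dominance": [r.dominance.value for r in self.rows],
                "cost": [r.cost for r in self.rows],
                "incremental_cost": [r.incremental_cost for r in self.rows],
                "effectiveness": [r.effectiveness for r in self.rows],
                "incremental_effectiveness": [
                    r.incremental_effectiveness for r in self.rows
                ],
                "icer": [r.icer for r in self.rows],
                "nmb": [r.nmb for r in self.rows],
            }
        )


def build_cea_table(strategies: list[StrategyResult], wtp: float) -> CEATable:
    """Assemble the ranked cost-effectiveness table.

    Rows are sorted by ascending cost (ties by descending effectiveness,
    then name). Incremental columns compare each row with the nearest
    non-dominated row above it; the cheapest row has no comparator. A zero
    incremental effectiveness yields a signed infinite ICER, flagged as not
    interpretable rather than raising.
    """
    labels = classify_dominance(strategies)
    ordered = sorted(strategies, key=lambda s: (s.cost, -s.effectiveness, s.name))

    rows: list[CEARow] = []
    last_efficient: StrategyResult | None = None
    for s in ordered:
        if last_efficient is None:
            inc_c = inc_e = icer = None
            interpretable = False
        else:
            inc_c = s.cost - last_efficient.cost
            inc_e = s.effectiveness - last_efficient.effectiveness
            if inc_e == 0:
                icer = math.inf if inc_c > 0 else (-math.inf if inc_c < 0 else 0.0)
                interpretable = False
            else:
                icer = inc_c / inc_e
                interpretable = labels[s.name] is Dominance.NOT_DOMINATED
        rows.append(
            CEARow(
                name=s.name,
                dominance=labels[s.name],
                cost=s.cost,
                effectiveness=s.effectiveness,
                incremental_cost=inc_c,
                incremental_effectiveness=inc_e,
                icer=icer,
                icer_interpretable=interpretable,
                nmb=nmb(s, wtp),
            )
        )
        if labels[s.name] is Dominance.NOT_DOMINATED:
            last_efficient = s
    return CEATable(rows=tuple(rows), wtp=wtp)


def wtp_grid(
    wtp_max: float = 120_000.0,
    step: float = 2_000.0,
    wtp_primary: float | None = 40_000.0,
) -> np.ndarray:
    """Ascending willingness-to-pay grid [0, wtp_max] containing wtp_primary."""
    grid = np.arange(0.0, wtp_max + 0.5 * step, step)
    if wtp_primary is not None and wtp_primary not in grid:
        grid = np.sort(np.append(grid, wtp_primary))
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("willingness-to-pay grid must be non-empty and increasing")
    return grid
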