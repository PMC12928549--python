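"""Structured-configuration reading/writing and tabular export.

A configuration file (YAML; JSON is a subset) mirrors the parameter
containers: ``scenarios`` (list), ``transitions``, ``utilities``, ``costs``,
``config`` mappings, an optional ``assumed`` list of dotted field paths
flagged as assumptions, and optional ``distributions`` / ``ranges`` blocks
for the sensitivity analyses. All monetary values are 2023 BRL and all
probabilities are per monthly cycle.

Parsing aggregates every violation (structural and invariant) into a single
ConfigError naming each offending field, rather than failing on the first.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .model import CohortTrace, HealthState
from .params import (
    CostSet,
    ModelConfig,
    ParameterSet,
    ScenarioSpec,
    TransitionParams,
    UtilitySet,
)
from .ranking import CEATable
from .sensitivity import (
    CEACCurve,
    DistributionSpec,
    ICEScatter,
    ParamRange,
    PSADraws,
    TornadoRow,
)

__all__ = [
    "ConfigError",
    "load_config",
    "parse_config",
    "save_config",
    "config_to_dict",
    "write_trace_csv",
    "write_cea_csv",
    "write_tornado_csv",
    "write_ceac_csv",
    "write_ice_csv",
]


class ConfigError(ValueError):
    """All problems found in a configuration, each naming its field path."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("\n".join(self.errors))


_SECTION_TYPES = {
    "transitions": TransitionParams,
    "utilities": UtilitySet,
    "costs": CostSet,
    "config": ModelConfig,
}
_TOP_KEYS = {"scenarios", "assumed", "distributions", "ranges", *_SECTION_TYPES}


def _build_section(cls, raw: dict, section: str, errors: list[str]):
    known = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in raw.items():
        if key not in known:
            errors.append(f"{section}.{key}: unknown field")
            continue
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except TypeError as exc:
        errors.append(f"{section}: {exc}")
        return cls() if section != "transitions" else None


def parse_config(
    raw: dict,
) -> tuple[ParameterSet, list[DistributionSpec], list[ParamRange]]:
    """Build a validated ParameterSet (plus sensitivity blocks) from a mapping."""
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError(["configuration root must be a mapping"])
    for key in raw:
        if key not in _TOP_KEYS:
            errors.append(f"{key}: unknown top-level section")

    scenarios: list[ScenarioSpec] = []
    raw_scen = raw.get("scenarios")
    if not isinstance(raw_scen, list) or not raw_scen:
        errors.append("scenarios: a non-empty list is required")
    else:
        for i, entry in enumerate(raw_scen):
            built = _build_section(ScenarioSpec, entry or {}, f"scenarios[{i}]", errors)
            if isinstance(built, ScenarioSpec):
                scenarios.append(built)

    raw_tp = raw.get("transitions")
    if not isinstance(raw_tp, dict):
        errors.append("transitions: a mapping is required")
        tp = None
    else:
        tp = _build_section(TransitionParams, raw_tp, "transitions", errors)

    sections: dict[str, Any] = {}
    for name in ("utilities", "costs", "config"):
        sections[name] = _build_section(
            _SECTION_TYPES[name], raw.get(name) or {}, name, errors
        )

    dists = []
    for i, entry in enumerate(raw.get("distributions") or []):
        try:
            d = DistributionSpec(
                param_path=entry["param"],
                family=entry.get("family", "fixed"),
                mean=entry["mean"],
                sd=entry.get("sd", 0.0),
            )
            errors.extend(d.validate())
            dists.append(d)
        except (KeyError, TypeError) as exc:
            errors.append(f"distributions[{i}]: {exc!r}")
    ranges = []
    for i, entry in enumerate(raw.get("ranges") or []):
        try:
            r = ParamRange(
                param_path=entry["param"],
                low=entry["low"],
                base=entry["base"],
                high=entry["high"],
            )
            errors.extend(r.validate())
            ranges.append(r)
        except (KeyError, TypeError) as exc:
            errors.append(f"ranges[{i}]: {exc!r}")

    if errors or tp is None:
        raise ConfigError(errors or ["transitions: a mapping is required"])

    ps = ParameterSet(
        scenarios=tuple(scenarios),
        transitions=tp,
        utilities=sections["utilities"],
        costs=sections["costs"],
        config=sections["config"],
        assumed=tuple(raw.get("assumed") or ()),
    )
    errors = ps.validate()
    if errors:
        raise ConfigError(errors)
    return ps, dists, ranges


def load_config(
    path: str | Path,
) -> tuple[ParameterSet, list[DistributionSpec], list[ParamRange]]:
    """Read and validate a YAML/JSON configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return parse_config(raw)


def config_to_dict(
    ps: ParameterSet,
    dists: list[DistributionSpec] | None = None,
    ranges: list[ParamRange] | None = None,
) -> dict:
    out: dict[str, Any] = {
        "scenarios": [dataclasses.asdict(s) for s in ps.scenarios],
        "transitions": dataclasses.asdict(ps.transitions),
        "utilities": dataclasses.asdict(ps.utilities),
        "costs": dataclasses.asdict(ps.costs),
        "config": dataclasses.asdict(ps.config),
        "assumed": list(ps.assumed),
    }
    if dists:
        out["distributions"] = [
            {"param": d.param_path, "family": d.family, "mean": d.mean, "sd": d.sd}
            for d in dists
        ]
    if ranges:
        out["ranges"] = [
            {"param": r.param_path, "low": r.low, "base": r.base, "high": r.high}
            for r in ranges
        ]
    return out


def save_config(
    ps: ParameterSet,
    path: str | Path,
    dists: list[DistributionSpec] | None = None,
    ranges: list[ParamRange] | None = None,
) -> None:
    """Write a configuration file that round-trips through ``load_config``."""
    with open(path, "w") as fh:
        yaml.safe_dump(
            config_to_dict(ps, dists, ranges), fh, sort_keys=False, width=100
        )


# ---------------------------------------------------------------------------
# tabular export: data-only CSVs with fixed headers; money to 2 decimals,
# probabilities/utilities to 6

def _fmt_money(x) -> str:
    return "" if x is None else f"{x:.2f}"


def _fmt_small(x) -> str:
    return "" if x is None else f"{x:.6f}"


def write_trace_csv(trace: CohortTrace, path: str | Path) -> None:
    rows = []
    n_cycles = trace.occupancy.shape[0] - 1
    for t in range(n_cycles + 1):
        for s in HealthState:
            rows.append(
                {
                    "cycle": t,
                    "state": s.name,
                    "occupancy": _fmt_small(trace.occupancy[t, s]),
                    "cum_cost": _fmt_money(trace.cum_cost[t]),
                    "cum_qaly": _fmt_small(trace.cum_qaly[t]),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_cea_csv(table: CEATable, path: str | Path) -> None:
    df = table.to_dataframe()
    for col in ("cost", "incremental_cost", "icer", "nmb"):
        df[col] = df[col].map(lambda x: "" if pd.isna(x) else f"{x:.2f}")
    for col in ("effectiveness", "incremental_effectiveness"):
        df[col] = df[col].map(lambda x: "" if pd.isna(x) else f"{x:.6f}")
    df.to_csv(path, index=False)


def write_tornado_csv(rows: list[TornadoRow], path: str | Path) -> None:
    pd.DataFrame(
        {
            "param": [r.param_path for r in rows],
            "icer_low": [_fmt_money(r.icer_at_low) for r in rows],
            "icer_high": [_fmt_money(r.icer_at_high) for r in rows],
            "spread": [_fmt_money(r.spread) for r in rows],
        }
    ).to_csv(path, index=False)


def write_ceac_csv(curve: CEACCurve, path: str | Path) -> None:
    df = curve.to_dataframe()
    df["wtp"] = df["wtp"].map(_fmt_money)
    for name in curve.strategies:
        df[name] = df[name].map(_fmt_small)
    df.to_csv(path, index=False)


def write_ice_csv(scatter: ICEScatter, path: str | Path) -> None:
    df = scatter.to_dataframe()
    df["delta_e"] = df["delta_e"].map(_fmt_small)
    df["delta_c"] = df["delta_c"].map(_fmt_money)
    df.to_csv(path, index=False)


def write_psa_csv(draws: PSADraws, path: str | Path) -> None:
    df = draws.to_dataframe()
    for name in draws.strategies:
        df[f"cost_{name}"] = df[f"cost_{name}"].map(_fmt_money)
        df[f"effectiveness_{name}"] = df[f"effectiveness_{name}"].map(_fmt_small)
    df.to_csv(path, index=False)


def write_manifest(path: str | Path, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
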