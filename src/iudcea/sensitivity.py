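"""Deterministic and probabilistic sensitivity analysis.

One-way (tornado) analysis pushes each parameter to its low and high bound
while holding everything else at base, reruns the model for a comparator
pair, and reports the swing in the ICER.

Probabilistic analysis samples every uncertain parameter from a distribution
matched to its mean and standard deviation (beta for probabilities and
utilities, gamma for costs, following standard PSA practice), reruns all
scenarios per iteration, and summarises the joint cost/effectiveness
uncertainty as a cost-effectiveness acceptability curve (CEAC) and an
incremental cost-effectiveness scatter with a 95% confidence ellipse.

All sampling is driven by a single numpy Generator (PCG64) seeded once, so a
run is fully reproducible from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .params import (
    ParameterSet,
    ValidationError,
    apply_values,
    get_param,
    set_param,
)
from .model import run_all, run_scenario
from .ranking import StrategyResult

__all__ = [
    "ParamRange",
    "DistributionSpec",
    "TornadoRow",
    "PSADraws",
    "CEACCurve",
    "ICEScatter",
    "tornado",
    "moment_match",
    "sample_dist",
    "run_psa",
    "ceac",
    "ice_scatter",
]


@dataclass(frozen=True)
class ParamRange:
    """Low/base/high values for one parameter in the tornado analysis."""

    param_path: str
    low: float
    base: float
    high: float

    def validate(self) -> list[str]:
        if not (self.low <= self.base <= self.high):
            return [
                f"range for {self.param_path}: low <= base <= high required,"
                f" got ({self.low!r}, {self.base!r}, {self.high!r})"
            ]
        return []


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution for one parameter, given as mean and sd.

    family is one of beta/gamma/normal/fixed. A beta on a negative mean is
    interpreted as a beta on the magnitude, negated after sampling — the
    convention used here for disutilities, keeping draws in [-1, 0].
    """

    param_path: str
    family: str
    mean: float
    sd: float = 0.0

    def validate(self) -> list[str]:
        errors: list[str] = []
        if self.family not in ("beta", "gamma", "normal", "fixed"):
            errors.append(
                f"{self.param_path}: unknown distribution family {self.family!r}"
            )
            return errors
        if self.sd < 0:
            errors.append(f"{self.param_path}: sd must be >= 0, got {self.sd!r}")
        if self.family == "beta" and not (0.0 < abs(self.mean) < 1.0) and self.sd > 0:
            errors.append(
                f"{self.param_path}: beta mean magnitude must lie in (0, 1),"
                f" got {self.mean!r}"
            )
        if self.family == "gamma" and self.mean <= 0 and self.sd > 0:
            errors.append(f"{self.param_path}: gamma mean must be > 0, got {self.mean!r}")
        return errors


@dataclass(frozen=True)
class TornadoRow:
    param_path: str
    icer_at_low: float
    icer_at_high: float

    @property
    def spread(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def _pair_icer(ps: ParameterSet, reference: str, target: str) -> float:
    ref = run_scenario(ps, reference)
    tgt = run_scenario(ps, target)
    d_eff = tgt.qaly_total - ref.qaly_total
    d_cost = tgt.cost_total - ref.cost_total
    if d_eff == 0:
        return math.inf if d_cost > 0 else (-math.inf if d_cost < 0 else 0.0)
    return d_cost / d_eff


def tornado(
    base: ParameterSet,
    ranges: list[ParamRange],
    reference: str,
    target: str,
) -> list[TornadoRow]:
    """One-way sensitivity of the target-vs-reference ICER to each parameter.

    Every candidate parameter set is validated before any model run, so a
    range that pushes a utility above 1 (say) fails fast with a field-named
    error rather than producing a nonsense ICER.
    """
    base.require_valid()
    candidates: list[tuple[ParamRange, ParameterSet, ParameterSet]] = []
    for r in ranges:
        errors = r.validate()
        if errors:
            raise ValidationError(errors)
        ps_low = set_param(base, r.param_path, r.low)
        ps_high = set_param(base, r.param_path, r.high)
        errors = ps_low.validate() + ps_high.validate()
        if errors:
            raise ValidationError(
                [f"range for {r.param_path} violates model invariants: {e}" for e in errors]
            )
        candidates.append((r, ps_low, ps_high))

    rows = [
        TornadoRow(
            param_path=r.param_path,
            icer_at_low=_pair_icer(ps_low, reference, target),
            icer_at_high=_pair_icer(ps_high, reference, target),
        )
        for r, ps_low, ps_high in candidates
    ]
    rows.sort(key=lambda row: -row.spread)
    return rows


def moment_match(dist: DistributionSpec) -> dict[str, float]:
    """Method-of-moments parameters for a distribution spec.

    beta: alpha/beta solving mean = a/(a+b), var = sd^2 (on the magnitude
    for negative means); gamma: shape = mean^2/sd^2, scale = sd^2/mean;
    normal: passthrough; fixed or sd == 0: degenerate at the mean.
    """
    errors = dist.validate()
    if errors:
        raise ValidationError(errors)
    if dist.family == "fixed" or dist.sd == 0:
        return {"family": "fixed", "value": dist.mean}
    if dist.family == "beta":
        m = abs(dist.mean)
        var = dist.sd**2
        if var >= m * (1.0 - m):
            raise ValidationError(
                [
                    f"{dist.param_path}: beta moments infeasible,"
                    f" sd^2={var!r} >= mean(1-mean)={m * (1 - m)!r}"
                ]
            )
        nu = m * (1.0 - m) / var - 1.0
        return {
            "family": "beta",
            "alpha": m * nu,
            "beta": (1.0 - m) * nu,
            "negate": dist.mean < 0,
        }
    if dist.family == "gamma":
        return {
            "family": "gamma",
            "shape": dist.mean**2 / dist.sd**2,
            "scale": dist.sd**2 / dist.mean,
        }
    return {"family": "normal", "mean": dist.mean, "sd": dist.sd}


def _domain(path: str, mean: float, family: str) -> tuple[float, float]:
    """Valid sampling interval for a parameter, by its path and sign."""
    leaf = path.rsplit(".", 1)[-1]
    if leaf.startswith("p_") or (leaf.startswith("u_") and mean >= 0):
        return (0.0, 1.0)
    if leaf.startswith("disutility") or mean < 0 and family == "beta":
        return (-1.0, 0.0)
    return (0.0, math.inf)


def sample_dist(
    dist: DistributionSpec, rng: np.random.Generator, size: int
) -> tuple[np.ndarray, int]:
    """Draw ``size`` values; out-of-domain draws are resampled (truncation).

    Returns (draws, number of resampled values). Beta and gamma draws cannot
    leave their natural support, so resampling only bites for normal
    specifications near a domain boundary.
    """
    params = moment_match(dist)
    lo, hi = _domain(dist.param_path, dist.mean, dist.family)

    if params["family"] == "fixed":
        return np.full(size, params["value"]), 0
    if params["family"] == "beta":
        draws = rng.beta(params["alpha"], params["beta"], size=size)
        if params["negate"]:
            draws = -draws
        return draws, 0
    if params["family"] == "gamma":
        return rng.gamma(params["shape"], params["scale"], size=size), 0

    draws = rng.normal(params["mean"], params["sd"], size=size)
    resampled = 0
    for _ in range(100):
        bad = (draws < lo) | (draws > hi)
        n_bad = int(bad.sum())
        if n_bad == 0:
            break
        resampled += n_bad
        draws[bad] = rng.normal(params["mean"], params["sd"], size=n_bad)
    else:
        draws = np.clip(draws, lo, hi)
    return draws, resampled


@dataclass(frozen=True)
class PSADraws:
    """Per-iteration (cost, effectiveness) for every strategy.

    costs and effects have shape (n_iter, n_strategies), columns ordered as
    ``strategies``. ``n_resampled`` counts draws rejected for leaving a
    parameter's valid domain; it is 0 whenever the distributions live wholly
    inside their domains. rng_algorithm documents the generator so runs can
    be reproduced across versions.
    """

    strategies: tuple[str, ...]
    costs: np.ndarray
    effects: np.ndarray
    seed: int
    n_iter: int
    n_resampled: int = 0
    rng_algorithm: str = "numpy.random.Generator(PCG64)"
    sampled: dict[str, np.ndarray] = field(default_factory=dict)

    def strategy_index(self, name: str) -> int:
        try:
            return self.strategies.index(name)
        except ValueError:
            raise KeyError(f"no strategy named {name!r}") from None

    def to_dataframe(self) -> pd.DataFrame:
        records = {"iteration": np.arange(self.n_iter)}
        for j, name in enumerate(self.strategies):
            records[f"cost_{name}"] = self.costs[:, j]
            records[f"effectiveness_{name}"] = self.effects[:, j]
        return pd.DataFrame(records)


def run_psa(
    base: ParameterSet,
    dists: list[DistributionSpec],
    n_iter: int = 10_000,
    seed: int = 0,
) -> PSADraws:
    """Monte Carlo probabilistic sensitivity analysis.

    Each iteration independently samples every parameter with a
    DistributionSpec, reruns all scenarios through the cohort model, and
    records total cost and total QALYs. Identical (seed, n_iter, dists)
    give byte-identical output.
    """
    base.require_valid()
    if n_iter < 1:
        raise ValueError(f"n_iter must be >= 1, got {n_iter}")
    for d in dists:
        get_param(base, d.param_path)  # unknown paths fail before sampling
    rng = np.random.default_rng(seed)

    sampled: dict[str, np.ndarray] = {}
    n_resampled = 0
    for d in dists:
        draws, bad = sample_dist(d, rng, n_iter)
        sampled[d.param_path] = draws
        n_resampled += bad

    names = tuple(s.name for s in base.scenarios)
    costs = np.empty((n_iter, len(names)))
    effects = np.empty((n_iter, len(names)))
    for i in range(n_iter):
        ps_i = apply_values(base, {p: v[i] for p, v in sampled.items()})
        for j, trace in enumerate(run_all(ps_i)):
            costs[i, j] = trace.cost_total
            effects[i, j] = trace.qaly_total

    return PSADraws(
        strategies=names,
        costs=costs,
        effects=effects,
        seed=seed,
        n_iter=n_iter,
        n_resampled=n_resampled,
        sampled=sampled,
    )


@dataclass(frozen=True)
class CEACCurve:
    """P(highest NMB) per strategy along a willingness-to-pay grid."""

    strategies: tuple[str, ...]
    wtp: np.ndarray
    probability: np.ndarray  # shape (len(wtp), n_strategies)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probability, columns=list(self.strategies))
        df.insert(0, "wtp", self.wtp)
        return df


def ceac(draws: PSADraws, grid: np.ndarray) -> CEACCurve:
    """Cost-effectiveness acceptability curve.

    At each threshold, each strategy's acceptability is the fraction of
    iterations in which its net monetary benefit is highest; exact ties
    split the iteration's weight equally, so columns always sum to 1.
    """
    grid = np.asarray(grid, dtype=float)
    if draws.n_iter == 0:
        raise ValidationError(["PSA draws are empty"])
    # nmb[w, i, j] = eff[i, j] * wtp[w] - cost[i, j]
    nmb = draws.effects[None, :, :] * grid[:, None, None] - draws.costs[None, :, :]
    best = nmb.max(axis=2, keepdims=True)
    winners = nmb == best
    weights = winners / winners.sum(axis=2, keepdims=True)
    return CEACCurve(
        strategies=draws.strategies, wtp=grid, probability=weights.mean(axis=1)
    )


@dataclass(frozen=True)
class ICEScatter:
    """Incremental cost-effectiveness cloud for one strategy pair.

    delta_e / delta_c are per-iteration (effect, cost) increments of target
    minus reference. The ellipse covers 95% of a bivariate normal with the
    cloud's sample mean and covariance (chi-square_2 0.95 quantile).
    """

    reference: str
    target: str
    delta_e: np.ndarray
    delta_c: np.ndarray
    center: np.ndarray
    covariance: np.ndarray
    semi_axes: np.ndarray
    angle_rad: float
    chi2_quantile: float

    def fraction_cost_effective(self, wtp: float) -> float:
        """Fraction of iterations where the target is worth its extra cost."""
        return float(np.mean(self.delta_c <= wtp * self.delta_e))

    def contains(self, delta_e: np.ndarray, delta_c: np.ndarray) -> np.ndarray:
        """Whether points fall inside the 95% ellipse (Mahalanobis test)."""
        pts = np.column_stack([delta_e, delta_c]) - self.center
        cov = self.covariance
        if np.linalg.matrix_rank(cov) < 2:
            return (pts == 0).all(axis=1)
        inv = np.linalg.inv(cov)
        d2 = np.einsum("ij,jk,ik->i", pts, inv, pts)
        return d2 <= self.chi2_quantile

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(self.delta_e.size),
                "delta_e": self.delta_e,
                "delta_c": self.delta_c,
            }
        )


def ice_scatter(draws: PSADraws, reference: str, target: str) -> ICEScatter:
    """Incremental cost-effectiveness scatter with a 95% confidence ellipse."""
    if reference == target:
        raise ValidationError(["reference and target strategies must differ"])
    i_ref = draws.strategy_index(reference)
    i_tgt = draws.strategy_index(target)
    delta_e = draws.effects[:, i_tgt] - draws.effects[:, i_ref]
    delta_c = draws.costs[:, i_tgt] - draws.costs[:, i_ref]

    center = np.array([delta_e.mean(), delta_c.mean()])
    if draws.n_iter > 1:
        cov = np.cov(np.vstack([delta_e, delta_c]))
    else:
        cov = np.zeros((2, 2))
    q95 = float(stats.chi2.ppf(0.95, df=2))
    eigvals, eigvecs = np.linalg.eigh(cov)
    eigvals = np.clip(eigvals, 0.0, None)
    semi_axes = np.sqrt(eigvals * q95)
    angle = float(np.arctan2(eigvecs[1, -1], eigvecs[0, -1]))
    return ICEScatter(
        reference=reference,
        target=target,
        delta_e=delta_e,
        delta_c=delta_c,
        center=center,
        covariance=cov,
        semi_axes=semi_axes,
        angle_rad=angle,
        chi2_quantile=q95,
    )
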