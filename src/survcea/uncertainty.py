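"""Deterministic and probabilistic sensitivity analysis.

One-way DSA recomputes the comparator-anchored ICER at the low and high
end of one parameter's range, all others held at base, and ranks
parameters by ICER swing (tornado ordering).  PSA draws every uncertain
parameter independently — beta distributions for probabilities and test
performance, gamma for costs, parameterized by (mean, standard error)
moment matching — rebuilds the model per draw, and summarizes the draws
as cost-effectiveness-plane points and a cost-effectiveness acceptability
curve (CEAC).

Random-number regime: one master seed; each parameter gets its own
deterministic substream keyed by a hash of its parameter path, so adding
or removing a parameter never perturbs the draws of the others.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .model import compute_metric_points
from .params import MetricName, ModelParams, get_param, with_updates

DistFamily = Literal["beta", "gamma"]


@dataclass
class ParamRange:
    """A low/base/high range for one-way sensitivity analysis."""

    param_path: str
    base: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low <= self.base <= self.high):
            raise ValueError(
                f"{self.param_path}: need low <= base <= high, got "
                f"({self.low}, {self.base}, {self.high})"
            )


def fit_beta(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments beta shape parameters (alpha, beta).

    Rejects infeasible variances: a beta variable with the given mean
    cannot have se**2 >= mean*(1-mean).
    """
    if not (0.0 < mean < 1.0):
        raise ValueError(f"mean={mean} must be in (0, 1)")
    if se <= 0:
        raise ValueError("se must be positive")
    if se * se >= mean * (1.0 - mean):
        raise ValueError(
            f"infeasible variance: se^2={se*se:.6g} >= mean*(1-mean)="
            f"{mean*(1-mean):.6g}"
        )
    nu = mean * (1.0 - mean) / (se * se) - 1.0
    return mean * nu, (1.0 - mean) * nu


def fit_gamma(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments gamma (shape, scale)."""
    if mean <= 0 or se <= 0:
        raise ValueError("mean and se must be positive")
    return mean * mean / (se * se), se * se / mean


@dataclass
class DistributionSpec:
    """A sampling distribution for one parameter, by moment matching."""

    param_path: str
    family: DistFamily
    mean: float
    se: float

    def shape_params(self) -> tuple[float, float]:
        if self.family == "beta":
            return fit_beta(self.mean, self.se)
        if self.family == "gamma":
            return fit_gamma(self.mean, self.se)
        raise ValueError(f"unknown family {self.family!r}")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        a, b = self.shape_params()
        if self.family == "beta":
            return rng.beta(a, b, size)
        return rng.gamma(shape=a, scale=b, size=size)

    def in_domain(self, x: float) -> bool:
        # open-interval check for probabilities: the model rejects a
        # cumulative probability of exactly 1 (infinite hazard)
        if self.family == "beta":
            return 0.0 <= x < 1.0
        return x >= 0.0 and math.isfinite(x)


@dataclass
class TornadoEntry:
    param_path: str
    icer_at_low: float
    icer_at_high: float
    icer_at_base: float | None = None

    @property
    def swing(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def icer_vs_comparator(
    params: ModelParams, target: str, comparator: str, metric: MetricName
) -> float:
    """The plain comparator-anchored ICER (signed; +/-inf on zero increment)."""
    points = compute_metric_points(params, metric)
    dc = points[target][0] - points[comparator][0]
    de = points[target][1] - points[comparator][1]
    if de == 0:
        return math.inf if dc > 0 else (-math.inf if dc < 0 else 0.0)
    return dc / de


def one_way_dsa(
    params: ModelParams,
    prange: ParamRange,
    comparator: str,
    target: str,
    metric: MetricName | None = None,
) -> TornadoEntry:
    """Recompute the target-vs-comparator ICER at each end of one range.

    Pure: ``params`` is never mutated; every evaluation uses a fresh copy
    with only the one parameter moved.
    """
    metric = metric or params.outcome_metric
    get_param(params, prange.param_path)  # unresolvable path -> KeyError here
    icers = {}
    for tag, value in (("low", prange.low), ("high", prange.high), ("base", prange.base)):
        p = with_updates(params, {prange.param_path: value})
        icers[tag] = icer_vs_comparator(p, target, comparator, metric)
    return TornadoEntry(
        param_path=prange.param_path,
        icer_at_low=icers["low"],
        icer_at_high=icers["high"],
        icer_at_base=icers["base"],
    )


def tornado(entries: Sequence[TornadoEntry]) -> list[TornadoEntry]:
    """Order entries by ICER swing, largest first; ties keep input order."""
    if not entries:
        raise ValueError("tornado needs at least one entry")
    return sorted(entries, key=lambda e: -e.swing)


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    ordered = tornado(entries)
    return pd.DataFrame(
        [
            {
                "param_path": e.param_path,
                "icer_at_low": e.icer_at_low,
                "icer_at_high": e.icer_at_high,
                "icer_at_base": e.icer_at_base,
                "swing": e.swing,
            }
            for e in ordered
        ]
    )


@dataclass
class PSAResult:
    """Monte-Carlo draws of (cost, effect) per strategy with CEAC."""

    n_draws: int
    seed: int
    strategies: list[str]
    metric: MetricName
    costs: np.ndarray    # (n_draws, n_strategies)
    effects: np.ndarray  # (n_draws, n_strategies)
    wtp_grid: np.ndarray
    ceac: np.ndarray     # (n_wtp, n_strategies), rows sum to 1
    n_resampled: int = 0
    sampled: dict[str, np.ndarray] = field(default_factory=dict)

    def mean_points(self) -> dict[str, tuple[float, float]]:
        return {
            s: (float(self.costs[:, i].mean()), float(self.effects[:, i].mean()))
            for i, s in enumerate(self.strategies)
        }

    def ceac_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.ceac, columns=self.strategies)
        df.insert(0, "wtp", self.wtp_grid)
        return df

    def draws_frame(self) -> pd.DataFrame:
        recs = []
        for i, s in enumerate(self.strategies):
            recs.append(
                pd.DataFrame(
                    {
                        "draw_id": np.arange(self.n_draws),
                        "strategy": s,
                        "cost": self.costs[:, i],
                        "effect": self.effects[:, i],
                    }
                )
            )
        return pd.concat(recs, ignore_index=True)

    def ce_plane(self, comparator: str) -> pd.DataFrame:
        """Incremental (cost, effect) of each strategy over the comparator."""
        j = self.strategies.index(comparator)
        recs = []
        for i, s in enumerate(self.strategies):
            if s == comparator:
                continue
            recs.append(
                pd.DataFrame(
                    {
                        "draw_id": np.arange(self.n_draws),
                        "strategy": s,
                        "incr_cost": self.costs[:, i] - self.costs[:, j],
                        "incr_effect": self.effects[:, i] - self.effects[:, j],
                    }
                )
            )
        return pd.concat(recs, ignore_index=True)

    def prob_cost_effective(self, target: str, comparator: str, wtp: float) -> float:
        """Fraction of draws where target beats comparator on NMB at wtp."""
        i = self.strategies.index(target)
        j = self.strategies.index(comparator)
        nmb_t = wtp * self.effects[:, i] - self.costs[:, i]
        nmb_c = wtp * self.effects[:, j] - self.costs[:, j]
        return float(np.mean(nmb_t > nmb_c))


def _substream(seed: int, param_path: str) -> np.random.Generator:
    # stable per-parameter substream: adding a parameter leaves others' draws intact
    key = zlib.crc32(param_path.encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, key]))


def sample_parameters(
    specs: Sequence[DistributionSpec], n: int, seed: int, max_resample: int = 1000
) -> tuple[dict[str, np.ndarray], int]:
    """Independent draws per parameter from per-path substreams.

    Out-of-domain draws are resampled (never clamped); the resample count
    is returned for logging.
    """
    samples: dict[str, np.ndarray] = {}
    n_resampled = 0
    for spec in specs:
        rng = _substream(seed, spec.param_path)
        x = spec.sample(rng, n)
        for _ in range(max_resample):
            bad = ~np.fromiter((spec.in_domain(v) for v in x), bool, count=n)
            if not bad.any():
                break
            n_resampled += int(bad.sum())
            x[bad] = spec.sample(rng, int(bad.sum()))
        else:
            raise RuntimeError(
                f"{spec.param_path}: could not draw in-domain values after "
                f"{max_resample} resampling rounds"
            )
        samples[spec.param_path] = x
    return samples, n_resampled


def default_wtp_grid() -> np.ndarray:
    return np.arange(0.0, 200_001.0, 1000.0)


def run_psa(
    params: ModelParams,
    specs: Sequence[DistributionSpec],
    n: int = 10_000,
    seed: int = 0,
    wtp_grid: np.ndarray | None = None,
    metric: MetricName | None = None,
) -> PSAResult:
    """Monte-Carlo propagation of parameter uncertainty.

    Per draw, every spec'd parameter is sampled independently, the model is
    rebuilt and evaluated, and (cost, effect) per strategy recorded.  The
    CEAC at each willingness-to-pay value is the fraction of draws in which
    the strategy maximizes net monetary benefit (ties resolved by strategy
    order, so at wtp=0 the CEAC is the probability of being cheapest).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    metric = metric or params.outcome_metric
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    for spec in specs:
        get_param(params, spec.param_path)  # fail fast on unresolvable paths
        spec.shape_params()  # and on infeasible moments
    samples, n_resampled = sample_parameters(specs, n, seed)
    strategies = [s.name for s in params.strategies]
    costs = np.empty((n, len(strategies)))
    effects = np.empty((n, len(strategies)))
    for i in range(n):
        p = with_updates(
            params, {path: float(x[i]) for path, x in samples.items()}
        )
        points = compute_metric_points(p, metric)
        for j, s in enumerate(strategies):
            costs[i, j], effects[i, j] = points[s]
    # CEAC: winner by NMB per draw per wtp; argmax breaks ties by label order
    nmb_cube = (
        wtp_grid[:, None, None] * effects[None, :, :] - costs[None, :, :]
    )  # (n_wtp, n_draws, n_strategies)
    winners = nmb_cube.argmax(axis=2)
    ceac = np.stack(
        [(winners == j).mean(axis=1) for j in range(len(strategies))], axis=1
    )
    return PSAResult(
        n_draws=n,
        seed=seed,
        strategies=strategies,
        metric=metric,
        costs=costs,
        effects=effects,
        wtp_grid=wtp_grid,
        ceac=ceac,
        n_resampled=n_resampled,
        sampled=samples,
    )
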