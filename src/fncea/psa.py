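"""Probabilistic sensitivity analysis and cost-effectiveness acceptability curves.

Parameter uncertainty is propagated by Monte Carlo: each iteration draws one
parameter set from the per-parameter distributions (Gamma for hospitalization
costs, Beta for utilities, risks, the complication split and case-fatality
rates, log-normal for relative risks; drug acquisition prices are fixed),
re-runs the cohort model for every strategy on that same draw, and records
cost, FN episodes and QALYs.  Acceptability curves report, per
willingness-to-pay value, the fraction of iterations in which each strategy
attains the maximal net monetary benefit.

The published Beta(61, 349) for the cycles-2-to-6 FN risk has mean 0.149 —
five times the 0.03 per-cycle point estimate — and is therefore interpreted
as the cumulative risk over the five later cycles; each draw q is converted
to the per-cycle scale as 1 - (1 - q)^(1/5), which reproduces the point
estimate at the distribution mean.  Set ``convert_cumulative=False`` to use
raw draws for sensitivity checking.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .economics import net_monetary_benefit
from .model_core import ParameterSet, StrategySpec, run_cohort

logger = logging.getLogger(__name__)

_MAX_REDRAWS_PER_ITERATION = 100


@dataclass(frozen=True)
class GammaDist:
    """Gamma distribution parameterized by shape and *rate* (mean = shape/rate)."""

    shape: float
    rate: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.rate <= 0:
            raise ValueError("gamma shape and rate must be positive")

    @property
    def mean(self) -> float:
        return self.shape / self.rate

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.gamma(self.shape, 1.0 / self.rate))


@dataclass(frozen=True)
class BetaDist:
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("beta parameters must be positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.beta(self.alpha, self.beta))


@dataclass(frozen=True)
class LogNormalDist:
    """Log-normal with location/scale on the log scale (median = exp(mu))."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("log-normal scale must be non-negative")

    @property
    def mean(self) -> float:
        return math.exp(self.mu + 0.5 * self.sigma**2)

    @property
    def median(self) -> float:
        return math.exp(self.mu)

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.lognormal(self.mu, self.sigma))


@dataclass(frozen=True)
class FixedValue:
    """Degenerate descriptor: the draw always equals the point value."""

    value: float

    @property
    def mean(self) -> float:
        return self.value

    def sample(self, rng: np.random.Generator) -> float:  # noqa: ARG002
        return self.value


Distribution = GammaDist | BetaDist | LogNormalDist | FixedValue


@dataclass(frozen=True)
class PSADistributionSet:
    """Per-parameter sampling descriptors.

    ``cumulative_risk_fields`` names parameters whose Beta draw represents a
    cumulative risk over the later chemotherapy cycles and must be converted
    to the per-cycle scale.
    """

    distributions: Mapping[str, Distribution]
    cumulative_risk_fields: frozenset = frozenset({"p_fn_cycle2to6"})

    def __post_init__(self) -> None:
        valid = {f.name for f in dataclasses.fields(ParameterSet)}
        for name in self.distributions:
            if name not in valid:
                raise ValueError(f"unknown model parameter {name!r} in PSA distributions")
        object.__setattr__(
            self, "cumulative_risk_fields", frozenset(self.cumulative_risk_fields)
        )


@dataclass(frozen=True)
class PsaResultSet:
    """Per-iteration, per-strategy PSA outcomes plus the sampled draws."""

    results: pd.DataFrame  # columns: iteration, strategy, cost, fn_episodes, qalys
    draws: pd.DataFrame  # one row per iteration, one column per sampled parameter
    seed: int
    n_iter: int
    n_redraws: int = 0

    def strategy_ids(self) -> list[str]:
        return list(self.results["strategy"].unique())


def cumulative_to_per_cycle(q: float, n_cycles: int) -> float:
    """Per-cycle risk p such that 1 - (1-p)^n equals the cumulative risk q."""
    return 1.0 - (1.0 - q) ** (1.0 / n_cycles)


def sample_parameters(
    psa: PSADistributionSet,
    rng: np.random.Generator,
    base: ParameterSet,
    *,
    convert_cumulative: bool = True,
) -> ParameterSet:
    """One joint parameter draw (independent across parameters).

    Parameters without a descriptor keep their base value.  Draws are taken
    in the declaration order of :class:`ParameterSet` fields so a given seed
    yields a reproducible sequence.  Out-of-range draws are clamped into the
    parameter's valid range with a logged warning (numerically rare; the
    stated distributions have the correct support).
    """
    n_later = base.n_cycles - 1
    sampled: dict[str, float] = {}
    for fld in dataclasses.fields(ParameterSet):
        dist = psa.distributions.get(fld.name)
        if dist is None:
            continue
        value = dist.sample(rng)
        if fld.name in psa.cumulative_risk_fields and convert_cumulative:
            value = cumulative_to_per_cycle(value, n_later)
        if fld.name.startswith(("p_", "cfr_", "utility_")) and not 0.0 <= value <= 1.0:
            clamped = min(max(value, 0.0), 1.0)
            logger.warning("clamped %s draw %.6g to %.6g", fld.name, value, clamped)
            value = clamped
        sampled[fld.name] = value
    return base.replace(**sampled)


def run_psa(
    strategies: Sequence[StrategySpec],
    psa: PSADistributionSet,
    base_params: ParameterSet,
    n_iter: int,
    seed: int,
    *,
    convert_cumulative: bool = True,
) -> PsaResultSet:
    """Monte Carlo propagation of parameter uncertainty.

    Within an iteration the same parameter draw is shared by all strategies
    (common random numbers across comparators).  Deterministic under a fixed
    seed.  An iteration whose draw still violates the parameter invariants
    after clamping is re-drawn; redraws are counted and logged.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    rng = np.random.default_rng(seed)
    rows: list[tuple] = []
    draw_rows: list[dict[str, float]] = []
    n_redraws = 0
    for it in range(n_iter):
        for _ in range(_MAX_REDRAWS_PER_ITERATION):
            try:
                params = sample_parameters(
                    psa, rng, base_params, convert_cumulative=convert_cumulative
                )
                break
            except ValueError as exc:
                n_redraws += 1
                logger.warning("iteration %d redrawn: %s", it, exc)
        else:
            raise RuntimeError(f"iteration {it}: too many invalid parameter draws")
        draw_rows.append(
            {name: getattr(params, name) for name in psa.distributions}
        )
        for strat in strategies:
            res = run_cohort(strat, params, collect_trace=False)
            rows.append((it, strat.id, res.expected_cost, res.expected_fn_episodes, res.expected_qalys))
    results = pd.DataFrame(
        rows, columns=["iteration", "strategy", "cost", "fn_episodes", "qalys"]
    )
    draws = pd.DataFrame(draw_rows)
    draws.insert(0, "iteration", np.arange(n_iter))
    return PsaResultSet(results=results, draws=draws, seed=seed, n_iter=n_iter, n_redraws=n_redraws)


def default_wtp_grid(outcome: str = "fn_episode_prevented") -> np.ndarray:
    """Willingness-to-pay grid: 0-50k USD in 1k steps per FN episode
    prevented, 0-200k USD in 5k steps per QALY."""
    if outcome == "fn_episode_prevented":
        return np.arange(0, 50_001, 1_000, dtype=float)
    if outcome == "qaly":
        return np.arange(0, 200_001, 5_000, dtype=float)
    raise ValueError(f"unknown outcome {outcome!r}")


def ceac(
    results: PsaResultSet,
    wtp_grid: Sequence[float] | None = None,
    outcome: str = "fn_episode_prevented",
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves.

    For each willingness-to-pay value, the probability (fraction of PSA
    iterations) that each strategy attains the maximal net monetary benefit;
    exact ties split the win equally.  Returns a DataFrame indexed by wtp
    with one column per strategy; rows sum to 1.
    """
    if wtp_grid is None:
        wtp_grid = default_wtp_grid(outcome)
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if len(wtp_grid) == 0:
        raise ValueError("wtp_grid must be non-empty")
    if (wtp_grid < 0).any():
        raise ValueError("willingness-to-pay values must be non-negative")
    if outcome == "fn_episode_prevented":
        effect_col = "fn_episodes"
        sign = -1.0  # fewer episodes is better; constant shift leaves argmax unchanged
    elif outcome == "qaly":
        effect_col = "qalys"
        sign = 1.0
    else:
        raise ValueError(f"unknown outcome {outcome!r}")

    wide_cost = results.results.pivot(index="iteration", columns="strategy", values="cost")
    wide_eff = results.results.pivot(index="iteration", columns="strategy", values=effect_col)
    order = [s for s in results.results["strategy"].unique()]
    cost = wide_cost[order].to_numpy()
    eff = sign * wide_eff[order].to_numpy()

    probs = np.empty((len(wtp_grid), len(order)))
    for k, wtp in enumerate(wtp_grid):
        nmb = net_monetary_benefit(cost, eff, wtp)
        best = nmb.max(axis=1, keepdims=True)
        winners = nmb >= best - 1e-9
        probs[k] = (winners / winners.sum(axis=1, keepdims=True)).mean(axis=0)
    return pd.DataFrame(probs, index=pd.Index(wtp_grid, name="wtp"), columns=order)


def plot_ceac(curves: pd.DataFrame, path: str, *, title: str | None = None) -> None:
    """Render acceptability curves to an image file (one line per strategy)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for col in curves.columns:
        ax.plot(curves.index, curves[col], label=col)
    ax.set_xlabel("Willingness to pay (2013 USD)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
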