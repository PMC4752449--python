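"""Incremental cost-effectiveness ranking, dominance and threshold pricing.

Strategies are compared on a cost/effect plane (effect oriented so that
larger is better: FN episodes prevented, or QALYs).  ``build_frontier``
classifies each strategy as on the efficiency frontier, strictly dominated
(another strategy costs no more and is at least as effective, one strictly),
or extended dominated (removed because its incremental cost-effectiveness
ratio exceeds that of the next more-effective option, i.e. a blend of its
neighbours is more efficient).  Pairwise ICERs are reported between
consecutive frontier members.

``threshold_price_search`` finds, by bisection, the highest acquisition
price of a drug at which a target strategy becomes the optimal choice
(maximal net monetary benefit on the QALY scale) at a given
willingness-to-pay threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .model_core import ParameterSet, StrategySpec, run_cohort

ON_FRONTIER = "on_frontier"
DOMINATED = "dominated"
EXTENDED_DOMINATED = "extended_dominated"


@dataclass(frozen=True)
class FrontierRow:
    strategy_id: str
    cost: float
    effect: float
    status: str
    comparator_id: str | None = None
    icer: float | None = None


@dataclass(frozen=True)
class FrontierTable:
    """Dominance-annotated strategies with pairwise frontier ICERs."""

    rows: tuple[FrontierRow, ...]

    def row(self, strategy_id: str) -> FrontierRow:
        for r in self.rows:
            if r.strategy_id == strategy_id:
                return r
        raise KeyError(strategy_id)

    def frontier_ids(self) -> list[str]:
        """Frontier members ordered by increasing cost."""
        return [
            r.strategy_id
            for r in sorted(self.rows, key=lambda r: (r.cost, -r.effect))
            if r.status == ON_FRONTIER
        ]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "strategy": r.strategy_id,
                    "cost": r.cost,
                    "effect": r.effect,
                    "status": r.status,
                    "comparator": r.comparator_id,
                    "icer": r.icer,
                }
                for r in sorted(self.rows, key=lambda r: (r.cost, -r.effect))
            ]
        )


def net_monetary_benefit(cost: float, effect: float, wtp: float) -> float:
    """Net monetary benefit: willingness-to-pay x effect - cost."""
    if wtp < 0:
        raise ValueError(f"willingness to pay must be non-negative, got {wtp}")
    return wtp * effect - cost


def build_frontier(results: Iterable[tuple[str, float, float]]) -> FrontierTable:
    """Classify strategies and compute frontier ICERs.

    Parameters
    ----------
    results:
        Iterable of ``(strategy_id, cost, effect)`` with effect oriented so
        that larger is better.
    """
    entries = [(str(i), float(c), float(e)) for i, c, e in results]
    ids = [i for i, _, _ in entries]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate strategy ids in frontier input")
    if len(entries) < 2:
        raise ValueError("frontier construction requires at least two strategies")

    def dominators(i: int) -> list[int]:
        _, ci, ei = entries[i]
        return [
            j
            for j, (_, cj, ej) in enumerate(entries)
            if j != i and cj <= ci and ej >= ei and (cj < ci or ej > ei)
        ]

    dominated_by: dict[int, int] = {}
    for i in range(len(entries)):
        doms = dominators(i)
        if doms:
            # attribute dominance to the most effective dominator
            # (ties: cheapest, then id), matching the usual table footnote
            dominated_by[i] = min(
                doms, key=lambda j: (-entries[j][2], entries[j][1], entries[j][0])
            )

    candidates = [i for i in range(len(entries)) if i not in dominated_by]
    # collapse exact (cost, effect) ties onto single frontier points
    points: dict[tuple[float, float], list[int]] = {}
    for i in candidates:
        points.setdefault((entries[i][1], entries[i][2]), []).append(i)
    frontier = sorted(points)  # increasing cost => strictly increasing effect

    extended: dict[int, None] = {}
    while True:
        icers = [
            (frontier[k][0] - frontier[k - 1][0]) / (frontier[k][1] - frontier[k - 1][1])
            for k in range(1, len(frontier))
        ]
        drop = next(
            (k for k in range(1, len(frontier) - 1) if icers[k - 1] > icers[k]), None
        )
        if drop is None:
            break
        for i in points[frontier[drop]]:
            extended[i] = None
        del frontier[drop]

    rows: list[FrontierRow] = []
    prev_point: dict[tuple[float, float], tuple[float, float] | None] = {}
    for k, pt in enumerate(frontier):
        prev_point[pt] = frontier[k - 1] if k > 0 else None
    for i, (sid, cost, effect) in enumerate(entries):
        if i in dominated_by:
            rows.append(
                FrontierRow(sid, cost, effect, DOMINATED, entries[dominated_by[i]][0], None)
            )
        elif i in extended:
            rows.append(FrontierRow(sid, cost, effect, EXTENDED_DOMINATED, None, None))
        else:
            prev = prev_point[(cost, effect)]
            if prev is None:
                rows.append(FrontierRow(sid, cost, effect, ON_FRONTIER, None, None))
            else:
                icer = (cost - prev[0]) / (effect - prev[1])
                comp = entries[points[prev][0]][0]
                rows.append(FrontierRow(sid, cost, effect, ON_FRONTIER, comp, icer))
    return FrontierTable(tuple(rows))


def frontier_from_cohorts(
    strategies: Sequence[StrategySpec],
    params: ParameterSet,
    outcome: str = "fn_episode_prevented",
) -> tuple[FrontierTable, pd.DataFrame]:
    """Run every strategy and build the frontier for the chosen outcome.

    For the episode outcome, effectiveness is expressed as FN episodes
    prevented relative to the strategy with the most episodes, so that
    larger is better; ICERs use unrounded increments.
    """
    results = [run_cohort(s, params, collect_trace=False) for s in strategies]
    table = pd.DataFrame(
        {
            "strategy": [r.strategy_id for r in results],
            "cost": [r.expected_cost for r in results],
            "fn_episodes": [r.expected_fn_episodes for r in results],
            "qalys": [r.expected_qalys for r in results],
            "survival": [r.survival_fraction for r in results],
        }
    )
    if outcome == "fn_episode_prevented":
        effect = table["fn_episodes"].max() - table["fn_episodes"]
    elif outcome == "qaly":
        effect = table["qalys"]
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    table["effect"] = effect
    frontier = build_frontier(zip(table["strategy"], table["cost"], table["effect"]))
    return frontier, table


def optimal_strategy_at_wtp(
    costs: Sequence[float], effects: Sequence[float], wtp: float
) -> int:
    """Index of the strategy with maximal net monetary benefit."""
    nmbs = [net_monetary_benefit(c, e, wtp) for c, e in zip(costs, effects)]
    return max(range(len(nmbs)), key=lambda i: (nmbs[i], -costs[i]))


def threshold_price_search(
    target_strategy: str,
    price_field: str,
    wtp: float,
    params: ParameterSet,
    strategies: Sequence[StrategySpec],
    *,
    price_lo: float = 0.0,
    price_hi: float | None = None,
    tol: float = 0.5,
) -> float | None:
    """Largest drug price at which the target strategy is the optimal choice.

    Re-runs all cohorts and rebuilds the QALY frontier at each candidate
    price; "optimal" means on the frontier and maximizing net monetary
    benefit at the stated willingness to pay.  Bisection to ``tol`` (USD)
    precision, searching downward from the current price.  Returns ``None``
    when no price in ``[price_lo, price_hi]`` satisfies the condition.
    """
    if wtp < 0:
        raise ValueError("willingness to pay must be non-negative")
    if price_field not in ("cost_nivestim_per_cycle", "cost_pegfilgrastim_per_cycle"):
        raise ValueError(f"price_field must be a drug cost, got {price_field!r}")
    if not any(s.id == target_strategy for s in strategies):
        raise ValueError(f"unknown target strategy {target_strategy!r}")
    if price_hi is None:
        price_hi = getattr(params, price_field)
    if price_hi < price_lo:
        raise ValueError("price_hi must be at least price_lo")

    def target_is_optimal(price: float) -> bool:
        trial = params.replace(**{price_field: price})
        frontier, table = frontier_from_cohorts(strategies, trial, outcome="qaly")
        if frontier.row(target_strategy).status != ON_FRONTIER:
            return False
        idx = optimal_strategy_at_wtp(table["cost"], table["effect"], wtp)
        return table["strategy"].iloc[idx] == target_strategy

    if target_is_optimal(price_hi):
        return float(price_hi)
    if not target_is_optimal(price_lo):
        return None
    lo, hi = price_lo, price_hi  # lo optimal, hi not
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if target_is_optimal(mid):
            lo = mid
        else:
            hi = mid
    return float(lo)
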