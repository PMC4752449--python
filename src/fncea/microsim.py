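"""Individual-level microsimulation mirroring the cohort model.

Each patient's 18 weeks are realized with Bernoulli draws under exactly the
cohort model's stochastic assumptions: FN onset at each cycle's week-2 entry
with the schedule- and history-dependent probability, a complication split,
and death at FN-episode exit with the stratum's case-fatality probability.
Costs and weekly QALYs accrue by the same rules as the cohort engine, so
sample means converge to the cohort expectations — the microsimulation is a
brute-force oracle for the deterministic model and a generator of
event-level synthetic data for downstream testing.

Each patient consumes a fixed-size block of uniforms (three per chemotherapy
cycle) from a single seeded stream, drawn row-major, so enlarging the cohort
never perturbs the trajectories of earlier patients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model_core import (
    WEEKS_PER_YEAR,
    ParameterSet,
    StrategySpec,
    fn_onset_probability,
    gcsf_given,
)

_DRAWS_PER_CYCLE = 3  # onset, complication split, case fatality

FN_EVENT_CODES = {0: None, 1: "uncomplicated", 2: "severe"}


@dataclass(frozen=True)
class CycleRecord:
    cycle: int
    gcsf_received: bool
    fn_event: str | None  # None | "uncomplicated" | "severe"
    died: bool


@dataclass(frozen=True)
class PatientHistory:
    patient_id: int
    cycles: tuple[CycleRecord, ...]
    cost: float
    qalys: float
    fn_episodes: int

    @property
    def died(self) -> bool:
        return any(c.died for c in self.cycles)


@dataclass(frozen=True)
class CohortSimResult:
    """Aggregate of n independent simulated patients."""

    strategy_id: str
    n: int
    seed: int
    means: dict
    standard_errors: dict
    event_log: pd.DataFrame | None = None


def _simulate_block(
    strategy: StrategySpec, params: ParameterSet, u: np.ndarray
) -> dict[str, np.ndarray]:
    """Vectorized trajectories for ``u`` of shape (n, n_cycles, 3) uniforms.

    Returns per-patient aggregates and per-cycle event arrays.  This is the
    single code path behind both :func:`simulate_patient` and
    :func:`simulate_cohort`.
    """
    n, n_cycles, _ = u.shape
    assert n_cycles == params.n_cycles
    dc = params.drug_cost(strategy.agent)
    u_week = np.array(params.state_utilities()) / WEEKS_PER_YEAR

    alive = np.ones(n, dtype=bool)
    history = np.zeros(n, dtype=bool)
    cost = np.zeros(n)
    qalys = np.zeros(n)
    episodes = np.zeros(n, dtype=np.int64)
    gcsf_log = np.zeros((n, n_cycles), dtype=bool)
    fn_log = np.zeros((n, n_cycles), dtype=np.int8)
    died_log = np.zeros((n, n_cycles), dtype=bool)
    cycle_cost = np.zeros((n, n_cycles))
    cycle_qalys = np.zeros((n, n_cycles))

    for c in range(1, n_cycles + 1):
        on = np.where(
            history,
            gcsf_given(strategy, c, True),
            gcsf_given(strategy, c, False),
        ) & alive
        p_no = fn_onset_probability(c, strategy.agent, True, False, params)
        p_off_no = fn_onset_probability(c, strategy.agent, False, False, params)
        p_hi = fn_onset_probability(c, strategy.agent, True, True, params)
        p_off_hi = fn_onset_probability(c, strategy.agent, False, True, params)
        p = np.where(history, np.where(on, p_hi, p_off_hi), np.where(on, p_no, p_off_no))

        fn = alive & (u[:, c - 1, 0] < p)
        severe = fn & (u[:, c - 1, 1] < params.p_severe_given_fn)
        uncomp = fn & ~severe
        dies = (severe & (u[:, c - 1, 2] < params.cfr_fn_severe)) | (
            uncomp & (u[:, c - 1, 2] < params.cfr_fn_uncomplicated)
        )

        c_cost = on * dc + severe * params.cost_hosp_fn_severe + uncomp * params.cost_hosp_fn_uncomplicated
        # weekly utilities: week 1 alive; week 2 in FN state if an episode
        # occurred; week 3 zero for patients who died at the episode's end
        alive_next = alive & ~dies
        w1 = alive * u_week[0]
        w2 = np.where(severe, u_week[1], np.where(uncomp, u_week[2], alive * u_week[0]))
        w3 = alive_next * u_week[0]
        c_qaly = w1 + w2 + w3

        cost += c_cost
        qalys += c_qaly
        episodes += fn
        gcsf_log[:, c - 1] = on
        fn_log[:, c - 1] = np.where(severe, 2, np.where(uncomp, 1, 0))
        died_log[:, c - 1] = dies
        cycle_cost[:, c - 1] = c_cost
        cycle_qalys[:, c - 1] = c_qaly
        history |= fn
        alive = alive_next

    return {
        "cost": cost,
        "qalys": qalys,
        "fn_episodes": episodes,
        "alive": alive,
        "gcsf": gcsf_log,
        "fn_event": fn_log,
        "died": died_log,
        "cycle_cost": cycle_cost,
        "cycle_qalys": cycle_qalys,
    }


def simulate_patient(
    strategy: StrategySpec,
    params: ParameterSet,
    rng: np.random.Generator,
    patient_id: int = 0,
) -> PatientHistory:
    """Realize a single patient trajectory from the given random stream."""
    u = rng.random((1, params.n_cycles, _DRAWS_PER_CYCLE))
    out = _simulate_block(strategy, params, u)
    records = tuple(
        CycleRecord(
            cycle=c + 1,
            gcsf_received=bool(out["gcsf"][0, c]),
            fn_event=FN_EVENT_CODES[int(out["fn_event"][0, c])],
            died=bool(out["died"][0, c]),
        )
        for c in range(params.n_cycles)
    )
    return PatientHistory(
        patient_id=patient_id,
        cycles=records,
        cost=float(out["cost"][0]),
        qalys=float(out["qalys"][0]),
        fn_episodes=int(out["fn_episodes"][0]),
    )


def simulate_cohort(
    n: int,
    strategy: StrategySpec,
    params: ParameterSet,
    seed: int,
    *,
    include_log: bool = True,
) -> CohortSimResult:
    """Aggregate n independent simulated patients.

    Deterministic under a fixed seed; the first m patients of a size-n run
    coincide with a size-m run under the same seed.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    u = rng.random((n, params.n_cycles, _DRAWS_PER_CYCLE))
    out = _simulate_block(strategy, params, u)

    means = {
        "cost": float(out["cost"].mean()),
        "fn_episodes": float(out["fn_episodes"].mean()),
        "qalys": float(out["qalys"].mean()),
        "survival": float(out["alive"].mean()),
    }
    ses = {
        "cost": float(out["cost"].std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        "fn_episodes": float(out["fn_episodes"].std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        "qalys": float(out["qalys"].std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        "survival": float(out["alive"].std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
    }
    log = None
    if include_log:
        n_cycles = params.n_cycles
        log = pd.DataFrame(
            {
                "patient": np.repeat(np.arange(n), n_cycles),
                "cycle": np.tile(np.arange(1, n_cycles + 1), n),
                "gcsf": out["gcsf"].ravel(),
                "fn_event": np.array(["none", "uncomplicated", "severe"])[
                    out["fn_event"].ravel()
                ],
                "died": out["died"].ravel(),
                "cycle_cost": out["cycle_cost"].ravel(),
                "cycle_qaly": out["cycle_qalys"].ravel(),
            }
        )
    return CohortSimResult(
        strategy_id=strategy.id,
        n=n,
        seed=seed,
        means=means,
        standard_errors=ses,
        event_log=log,
    )
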