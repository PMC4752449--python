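"""Weekly Markov cohort model of febrile neutropenia under G-CSF prophylaxis.

The model follows a homogeneous cohort of non-Hodgkin lymphoma patients
through six 3-week cycles of R-CHOP chemotherapy (an 18-week horizon, one
Markov cycle per week).  Five health states are tracked:

1. no FN and no history of FN,
2. FN with severe complications (one-week tunnel state),
3. FN without complications (one-week tunnel state),
4. no FN but a history of FN (carries the memory of past episodes),
5. dead of FN (absorbing).

FN onset happens once per chemotherapy cycle, on the transition from week 1
into week 2 of the cycle; the episode occupies week 2 and resolves (to the
history state) or ends in death at the end of that week.  The onset
probability is a baseline per-cycle risk multiplied by the relative risk of
the G-CSF agent when prophylaxis is given in that cycle and by the
FN-history relative risk for patients who have already had an episode; the
product is clamped to 1.

Costs (drug acquisition per cycle, hospitalization per FN episode) and
QALYs (annual utility weight / 52 per week of state occupancy, no
discounting over the short horizon) are accrued alongside the state
propagation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

WEEKS_PER_YEAR = 52.0

#: tolerance for the conservation-of-mass check on occupancy vectors
MASS_TOL = 1e-9


class HealthState(IntEnum):
    NO_FN_NO_HISTORY = 0
    FN_SEVERE = 1
    FN_NO_COMPLICATIONS = 2
    NO_FN_WITH_HISTORY = 3
    DEAD_OF_FN = 4


N_STATES = len(HealthState)

AGENTS = ("nivestim", "pegfilgrastim", "none")


@dataclass(frozen=True)
class StrategySpec:
    """A prophylaxis schedule.

    Parameters
    ----------
    id:
        Short machine-readable label, unique within an analysis.
    agent:
        ``"nivestim"`` (biosimilar filgrastim, one 7-day course per cycle),
        ``"pegfilgrastim"`` (one injection per cycle) or ``"none"``.
    pp_cycles:
        Chemotherapy cycles (subset of 1..6) in which G-CSF is given
        unconditionally (primary prophylaxis).
    sp_enabled:
        If true, G-CSF is also given in every cycle that starts after the
        patient's first FN episode (secondary prophylaxis).
    label:
        Optional human-readable name for reports.
    """

    id: str
    agent: str
    pp_cycles: frozenset = frozenset()
    sp_enabled: bool = False
    label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "pp_cycles", frozenset(int(c) for c in self.pp_cycles))
        if self.agent not in AGENTS:
            raise ValueError(f"unknown agent {self.agent!r}; expected one of {AGENTS}")
        if any(c < 1 or c > 6 for c in self.pp_cycles):
            raise ValueError(f"pp_cycles must be a subset of 1..6, got {sorted(self.pp_cycles)}")
        if self.agent == "none" and (self.pp_cycles or self.sp_enabled):
            raise ValueError("agent 'none' admits no prophylaxis cycles and no secondary prophylaxis")

    @property
    def display_name(self) -> str:
        return self.label or self.id


@dataclass(frozen=True)
class ParameterSet:
    """All point estimates of the model: costs (2013 USD), annual utility
    weights, per-cycle FN risks, relative risks and case-fatality rates.

    ``p_fn_cycle1`` / ``p_fn_cycle2to6`` are the per-cycle FN probabilities
    without prophylaxis and without FN history; ``rr_history`` multiplies the
    baseline for patients with a prior episode.
    """

    cost_pegfilgrastim_per_cycle: float
    cost_nivestim_per_cycle: float
    cost_hosp_fn_severe: float
    cost_hosp_fn_uncomplicated: float
    utility_no_fn: float
    utility_fn_uncomplicated: float
    utility_fn_severe: float
    rr_pegfilgrastim: float
    rr_nivestim: float
    rr_history: float
    p_fn_cycle1: float
    p_fn_cycle2to6: float
    p_severe_given_fn: float
    cfr_fn_severe: float
    cfr_fn_uncomplicated: float
    n_cycles: int = 6
    weeks_per_cycle: int = 3
    horizon_weeks: int = 18

    def __post_init__(self) -> None:
        for name in (
            "p_fn_cycle1",
            "p_fn_cycle2to6",
            "p_severe_given_fn",
            "cfr_fn_severe",
            "cfr_fn_uncomplicated",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "cost_pegfilgrastim_per_cycle",
            "cost_nivestim_per_cycle",
            "cost_hosp_fn_severe",
            "cost_hosp_fn_uncomplicated",
        ):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        for name in ("utility_no_fn", "utility_fn_uncomplicated", "utility_fn_severe"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("rr_pegfilgrastim", "rr_nivestim", "rr_history"):
            v = getattr(self, name)
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.n_cycles < 1 or self.weeks_per_cycle < 1:
            raise ValueError("n_cycles and weeks_per_cycle must be positive integers")
        if self.horizon_weeks != self.n_cycles * self.weeks_per_cycle:
            raise ValueError(
                f"horizon_weeks ({self.horizon_weeks}) must equal "
                f"n_cycles x weeks_per_cycle ({self.n_cycles * self.weeks_per_cycle})"
            )

    def replace(self, **changes) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    def drug_cost(self, agent: str) -> float:
        if agent == "nivestim":
            return self.cost_nivestim_per_cycle
        if agent == "pegfilgrastim":
            return self.cost_pegfilgrastim_per_cycle
        if agent == "none":
            return 0.0
        raise ValueError(f"unknown agent {agent!r}")

    def relative_risk(self, agent: str) -> float:
        if agent == "nivestim":
            return self.rr_nivestim
        if agent == "pegfilgrastim":
            return self.rr_pegfilgrastim
        if agent == "none":
            return 1.0
        raise ValueError(f"unknown agent {agent!r}")

    def state_utilities(self) -> tuple[float, float, float, float, float]:
        """Annual utility weight for each health state (history state shares
        the no-FN utility; the dead state has utility zero)."""
        return (
            self.utility_no_fn,
            self.utility_fn_severe,
            self.utility_fn_uncomplicated,
            self.utility_no_fn,
            0.0,
        )


@dataclass(frozen=True)
class CohortResult:
    """Expected per-patient outcomes of one strategy over the horizon."""

    strategy_id: str
    expected_cost: float
    cost_drug: float
    cost_hospitalization: float
    expected_fn_episodes: float
    expected_qalys: float
    survival_fraction: float
    trace: np.ndarray | None = None

    def trace_frame(self) -> pd.DataFrame:
        """Long-format weekly state occupancy (columns week, state, occupancy)."""
        if self.trace is None:
            raise ValueError("cohort was run without trace collection")
        weeks = np.repeat(np.arange(1, self.trace.shape[0] + 1), N_STATES)
        states = [s.name for s in HealthState] * self.trace.shape[0]
        return pd.DataFrame(
            {"week": weeks, "state": states, "occupancy": self.trace.ravel()}
        )


def fn_onset_probability(
    cycle_index: int,
    agent: str,
    on_gcsf: bool,
    has_history: bool,
    params: ParameterSet,
) -> float:
    """Per-cycle probability of an FN episode.

    Baseline risk for the cycle, multiplied by the agent's relative risk if
    G-CSF is given and by the FN-history relative risk if the patient has a
    prior episode; clamped to 1.
    """
    if not 1 <= int(cycle_index) <= params.n_cycles:
        raise ValueError(
            f"cycle_index must lie in 1..{params.n_cycles}, got {cycle_index}"
        )
    p = params.p_fn_cycle1 if cycle_index == 1 else params.p_fn_cycle2to6
    if on_gcsf:
        p *= params.relative_risk(agent)
    if has_history:
        p *= params.rr_history
    return min(p, 1.0)


def gcsf_given(strategy: StrategySpec, cycle_index: int, has_history: bool) -> bool:
    """Whether G-CSF is administered in a cycle.

    True when the cycle is a primary-prophylaxis cycle, or when secondary
    prophylaxis is enabled and an FN episode occurred in a strictly earlier
    cycle.
    """
    if strategy.agent == "none":
        return False
    return cycle_index in strategy.pp_cycles or (strategy.sp_enabled and has_history)


def week_phase(week_index: int, weeks_per_cycle: int = 3) -> tuple[int, int]:
    """(chemotherapy cycle, phase within cycle) of a model week, both 1-based."""
    return ((week_index - 1) // weeks_per_cycle + 1, (week_index - 1) % weeks_per_cycle + 1)


def _step(
    occ: list[float],
    week_index: int,
    strategy: StrategySpec,
    params: ParameterSet,
) -> tuple[list[float], float, float]:
    """One weekly transition on a plain-float occupancy vector.

    Returns the next vector plus the incident FN mass entering the severe and
    uncomplicated tunnel states (non-zero only on cycle phase 1).
    """
    s1, sev, unc, s4, dead = occ
    cycle, phase = week_phase(week_index, params.weeks_per_cycle)
    if phase == 1:
        # end of week 1 of the cycle: FN onset out of the two no-FN states
        p_no = fn_onset_probability(
            cycle, strategy.agent, gcsf_given(strategy, cycle, False), False, params
        )
        p_hi = fn_onset_probability(
            cycle, strategy.agent, gcsf_given(strategy, cycle, True), True, params
        )
        inc = s1 * p_no + s4 * p_hi
        inc_sev = inc * params.p_severe_given_fn
        inc_unc = inc - inc_sev
        return (
            [s1 * (1.0 - p_no), sev + inc_sev, unc + inc_unc, s4 * (1.0 - p_hi), dead],
            inc_sev,
            inc_unc,
        )
    if phase == 2:
        # end of week 2: the one-week FN tunnel empties to history or death
        deaths = sev * params.cfr_fn_severe + unc * params.cfr_fn_uncomplicated
        recovered = sev + unc - deaths
        return [s1, 0.0, 0.0, s4 + recovered, dead + deaths], 0.0, 0.0
    return [s1, sev, unc, s4, dead], 0.0, 0.0


def weekly_transition(
    occupancy,
    week_index: int,
    strategy: StrategySpec,
    params: ParameterSet,
) -> np.ndarray:
    """Propagate a five-state occupancy vector across one model week."""
    occ = np.asarray(occupancy, dtype=float)
    if occ.shape != (N_STATES,):
        raise ValueError(f"occupancy must have {N_STATES} entries, got shape {occ.shape}")
    if occ.min() < -MASS_TOL or abs(occ.sum() - 1.0) > MASS_TOL:
        raise ValueError(
            f"occupancy must be non-negative and sum to 1 (sum={occ.sum():.12g})"
        )
    if not 1 <= week_index <= params.horizon_weeks:
        raise ValueError(
            f"week_index must lie in 1..{params.horizon_weeks}, got {week_index}"
        )
    new, _, _ = _step(list(occ), week_index, strategy, params)
    return np.asarray(new, dtype=float)


def run_cohort(
    strategy: StrategySpec,
    params: ParameterSet,
    *,
    collect_trace: bool = True,
) -> CohortResult:
    """Run the cohort model for one strategy over the full horizon.

    The cohort starts with all mass in ``NO_FN_NO_HISTORY``.  Per week the
    occupancy-weighted utility / 52 is accrued; at each cycle start the drug
    cost is charged to the alive mass scheduled for G-CSF (the history
    stratum is read off the occupancy of the FN-history state); at each FN
    onset the stratum-specific hospitalization cost is charged to the
    incident mass.
    """
    occ = [1.0, 0.0, 0.0, 0.0, 0.0]
    utilities = params.state_utilities()
    dc = params.drug_cost(strategy.agent)
    qalys = 0.0
    drug_cost = 0.0
    hosp_cost = 0.0
    episodes = 0.0
    trace: list[tuple[float, ...]] | None = [] if collect_trace else None

    for week in range(1, params.horizon_weeks + 1):
        if trace is not None:
            trace.append(tuple(occ))
        qalys += sum(o * u for o, u in zip(occ, utilities)) / WEEKS_PER_YEAR
        cycle, phase = week_phase(week, params.weeks_per_cycle)
        if phase == 1 and dc > 0.0:
            if gcsf_given(strategy, cycle, False):
                drug_cost += dc * occ[HealthState.NO_FN_NO_HISTORY]
            if gcsf_given(strategy, cycle, True):
                drug_cost += dc * occ[HealthState.NO_FN_WITH_HISTORY]
        occ, inc_sev, inc_unc = _step(occ, week, strategy, params)
        episodes += inc_sev + inc_unc
        hosp_cost += (
            inc_sev * params.cost_hosp_fn_severe
            + inc_unc * params.cost_hosp_fn_uncomplicated
        )

    return CohortResult(
        strategy_id=strategy.id,
        expected_cost=drug_cost + hosp_cost,
        cost_drug=drug_cost,
        cost_hospitalization=hosp_cost,
        expected_fn_episodes=episodes,
        expected_qalys=qalys,
        survival_fraction=1.0 - occ[HealthState.DEAD_OF_FN],
        trace=np.asarray(trace) if trace is not None else None,
    )
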