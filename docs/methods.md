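# Methods

## Model structure and timing

The cohort model is a discrete-time Markov chain with a 1-week cycle over an
18-week horizon — six 3-week chemotherapy cycles, the duration of a standard
R-CHOP course.  Five states: (1) no FN, no history; (2) FN with severe
complications; (3) FN without complications; (4) no FN with a history of FN;
(5) dead of FN.  States 2 and 3 are tunnel states occupied for exactly one
week; state 5 is absorbing; death from causes other than FN is not modelled
over this short horizon.  The cohort starts entirely in state 1.

Within each 3-week chemotherapy cycle the weeks are phased as follows:

- **end of week 1** (cycle phase 1): FN onset.  Mass in states 1 and 4 moves
  into state 2 with probability `p x p_severe` and into state 3 with
  probability `p x (1 - p_severe)`, where `p` is the onset probability below.
- **end of week 2** (phase 2): tunnel exit.  FN mass dies with the
  state-specific case fatality, otherwise moves to state 4.  FN history is
  therefore permanent and an episode in cycle *c* is visible to the cycle
  *c + 1* schedule.
- **end of week 3** (phase 3): identity.

This phasing makes FN states occupied exactly in week 2 of each cycle and
guarantees that no mass sits in a tunnel state at a cycle boundary, so the
question of whether an in-episode patient receives that cycle's G-CSF never
arises.

## Onset probability and prophylaxis schedules

`p = p_base(cycle) x RR_agent^[on G-CSF] x RR_history^[history]`, clamped to
1.  The three relative risks are published separately; combining them
multiplicatively (with the clamp) is this package's convention for the joint
case.  A strategy is (agent, set of unconditional prophylaxis cycles,
secondary-prophylaxis flag); secondary prophylaxis administers G-CSF in every
cycle that begins after the first episode.  The seven packaged strategies
cover PP in all cycles, PP in cycles 1–2 with SP continuation, pure SP (each
for both agents), and no prophylaxis.

## Accrual conventions

- **QALYs**: occupancy-weighted annual utility / 52 per week of residence,
  no half-cycle correction and no discounting (the horizon is 18 weeks).
  State 4 shares the no-FN utility (0.80); the FN states use their own
  utilities (0.77 / 0.43); death contributes zero.  The ceiling is
  18 x 0.80 / 52 ≈ 0.2769 QALYs.
- **Drug cost**: charged once per chemotherapy cycle, at cycle start, to the
  alive mass meeting the schedule rule (the history stratum is identified
  with state-4 occupancy).  Pegfilgrastim is one injection per cycle
  (532 USD), nivestim one 7-day course (352 USD); administration cost is
  excluded (self-injection).
- **Hospitalization**: every FN episode is hospitalized; the full cost
  (22,135 USD severe / 9,588 USD uncomplicated, 2013 USD) is charged at
  onset.
- Chemotherapy itself continues for all six cycles regardless of FN and its
  cost, equal across strategies, is excluded.

All accumulation is in double precision; published-style display rounding
(whole dollars, 2-decimal episodes, 4-decimal QALYs) is applied only in CLI
output, never in stored CSVs or comparisons.

## Frontier, dominance and threshold search

Effectiveness for the episode outcome is expressed as FN episodes prevented
relative to the strategy with the most episodes; ICERs always use unrounded
increments (the frontier ICERs are ratios of differences of order 1e-2
episodes and are destroyed by table-level rounding).  Strict dominance
removes strategies that cost at least as much and deliver at most as much
(one strict); extended dominance iteratively removes frontier candidates
whose incremental ICER exceeds that of the next more-effective option.
Exact cost-and-effect ties stay on the frontier jointly with no ICER defined
between them; dominated rows are attributed to their most effective
dominator (ties: cheapest, then lexicographic id).

The threshold search bisects the target drug's per-cycle price to 0.5 USD
and returns the largest price at which the target strategy is on the QALY
frontier and maximizes net monetary benefit at the stated willingness to
pay; "most cost-effective" is operationalized as maximal NMB.  The
optimality region is monotone in the price because the target strategy uses
at least as many drug courses as any competitor that shares the priced
agent, so bisection is valid.  When even a zero price never makes the target
optimal the search reports "no threshold" (None) rather than raising.

## Probabilistic sensitivity analysis

Each of the 10,000 iterations draws one parameter set — Gamma (shape, rate)
for the two hospitalization costs, Beta for utilities, baseline risks, the
complication split and case fatalities, log-normal (log-scale mean, SD) for
the three relative risks; drug prices fixed — and re-runs all strategies on
that shared draw (common random numbers across comparators).  Parameters are
sampled independently; no correlation structure is published.  Draws are
taken in parameter declaration order from one seeded generator, so results
are bit-for-bit reproducible given (seed, iteration count, parameter file).

The published Beta(61, 349) for the cycles-2–6 risk has mean 0.149, five
times the 0.03 point estimate, and is interpreted here as the *cumulative*
risk over the five later cycles: each draw `q` is converted per cycle as
`p = 1 - (1 - q)^(1/5)`, which reproduces 0.03 at the distribution mean
(1 − (1 − 0.1488)^(1/5) ≈ 0.0317).  `convert_cumulative=False` uses raw
draws instead, for sensitivity checking.

CEACs assign each iteration's win to the strategy with maximal NMB (exact
ties split equally); curves therefore sum to 1 at every willingness-to-pay
point.  The default grid is 0–50,000 USD in 1,000-USD steps per episode
prevented and 0–200,000 USD in 5,000-USD steps per QALY.

## Microsimulation

The microsimulation realizes the identical generative process per patient:
one Bernoulli onset draw at each cycle's week-2 entry, one complication
split, one survival draw at episode exit, with costs and weekly QALYs
accrued by the same rules.  Each patient consumes a fixed block of
3 uniforms x 6 cycles from a single seeded PCG64 stream (row-major), so the
first *m* patients of a size-*n* run coincide with a size-*m* run — cohort
growth never perturbs earlier trajectories.  Sample means converge to the
cohort expectations at the usual n^(-1/2) rate; the test suite checks
agreement within 3 standard errors at 200,000 patients per strategy, and a
property-based variant adds a 6M/n allowance covering event types so rare
that a finite sample realizes none of them (the empirical SE is then zero
while the true mean is not degenerate; M bounds the per-patient impact).

What the generator emulates — and does not.  It reproduces the model's own
assumptions: a homogeneous cohort (no age, performance status or other
covariates), FN confined to one week per cycle, universal hospitalization,
permanent history, no non-FN mortality, no chemotherapy dose delay or
reduction.  Agreement between the two engines validates the implementation
against itself, not the model against real patients: it says nothing about
risk heterogeneity, outpatient FN management, or utilities beyond the three
published health-state weights.

## Problem sizes and numerics

Default analysis sizes: 10,000 PSA iterations; 200,000 patients per strategy
for oracle validation; threshold bisection to 0.5 USD.  Occupancy vectors
are validated to sum to 1 within 1e-9 on entry to the transition kernel and
conserve mass to ~1e-15 per step.  QALY and cost accumulators are plain
double sums over 18 terms, far below any precision concern.

## Known limitations

- The 18-week horizon truncates the survival benefit of avoided FN deaths;
  QALY differences between strategies are of order 1e-4 and the QALY-scale
  ICERs (millions of USD/QALY) are correspondingly sensitive to the accrual
  conventions above — they should be read as orders of magnitude.
- The published QALY totals are bracketed but not matched to the fourth
  decimal (this package computes ~0.2758–0.2763 vs ~0.2751–0.2756
  published); the increments between strategies, which drive every decision
  quantity, agree to within ~0.1%.
- Efficacy inputs treat the biosimilar's relative risk as exchangeable with
  filgrastim's; the model inherits that assumption from its inputs.
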