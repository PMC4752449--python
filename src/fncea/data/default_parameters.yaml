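# Default model inputs: costs in 2013 USD, annual utility weights, per-cycle
# FN risks, relative risks, case-fatality rates, and the sampling
# distributions used by the probabilistic sensitivity analysis.
parameters:
  cost_pegfilgrastim_per_cycle: 532      # one 6 mg injection per cycle
  cost_nivestim_per_cycle: 352           # one 7-day course of 300 ug injections
  cost_hosp_fn_severe: 22135             # hospitalization, FN with severe complications
  cost_hosp_fn_uncomplicated: 9588       # hospitalization, FN without complications
  utility_no_fn: 0.80                    # NHL on chemotherapy, no FN
  utility_fn_uncomplicated: 0.77
  utility_fn_severe: 0.43
  rr_pegfilgrastim: 0.55                 # FN relative risk vs no G-CSF
  rr_nivestim: 0.62
  rr_history: 2.29                       # FN relative risk with vs without FN history
  p_fn_cycle1: 0.17                      # per-cycle FN risk, no prophylaxis, no history
  p_fn_cycle2to6: 0.03
  p_severe_given_fn: 0.14                # severe-complication share of FN episodes
  cfr_fn_severe: 0.025                   # case fatality, severe FN
  cfr_fn_uncomplicated: 0.0063
  n_cycles: 6
  weeks_per_cycle: 3
  horizon_weeks: 18

# Drug prices are fixed (not sampled) in the PSA.  The beta for the
# cycles-2-to-6 risk is the cumulative risk over the five later cycles and is
# converted to the per-cycle scale at sampling time.
psa:
  cost_hosp_fn_severe: {dist: gamma, shape: 29.23, rate: 0.0013}
  cost_hosp_fn_uncomplicated: {dist: gamma, shape: 98.72, rate: 0.010}
  utility_no_fn: {dist: beta, alpha: 92.70, beta: 23.17}
  utility_fn_uncomplicated: {dist: beta, alpha: 61.33, beta: 18.42}
  utility_fn_severe: {dist: beta, alpha: 4.43, beta: 5.78}
  rr_pegfilgrastim: {dist: lognormal, mu: -0.60, sigma: 0.22}
  rr_nivestim: {dist: lognormal, mu: -0.48, sigma: 0.13}
  rr_history: {dist: lognormal, mu: 0.83, sigma: 0.40}
  p_fn_cycle1: {dist: beta, alpha: 84, beta: 410}
  p_fn_cycle2to6: {dist: beta, alpha: 61, beta: 349, cumulative: true}
  p_severe_given_fn: {dist: beta, alpha: 13, beta: 83}
  cfr_fn_severe: {dist: beta, alpha: 4, beta: 154}
  cfr_fn_uncomplicated: {dist: beta, alpha: 1, beta: 157}

strategies:
  - id: pp-nivestim-all
    agent: nivestim
    pp_cycles: [1, 2, 3, 4, 5, 6]
    sp_enabled: false
    label: PP with nivestim (all cycles)
  - id: pp-nivestim-c12
    agent: nivestim
    pp_cycles: [1, 2]
    sp_enabled: true
    label: PP with nivestim (cycles 1 & 2)
  - id: sp-nivestim
    agent: nivestim
    pp_cycles: []
    sp_enabled: true
    label: SP with nivestim
  - id: pp-pegfilgrastim-all
    agent: pegfilgrastim
    pp_cycles: [1, 2, 3, 4, 5, 6]
    sp_enabled: false
    label: PP with pegfilgrastim (all cycles)
  - id: pp-pegfilgrastim-c12
    agent: pegfilgrastim
    pp_cycles: [1, 2]
    sp_enabled: true
    label: PP with pegfilgrastim (cycles 1 & 2)
  - id: sp-pegfilgrastim
    agent: pegfilgrastim
    pp_cycles: []
    sp_enabled: true
    label: SP with pegfilgrastim
  - id: no-prophylaxis
    agent: none
    pp_cycles: []
    sp_enabled: false
    label: No prophylaxis
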