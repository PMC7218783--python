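# Annotated pipeline configuration for the ED resource-allocation study.
#
# All times are minutes; the working day is day_length minutes long and
# arrival_rate is the expected number of arrivals over that day.

# Current staffing — the decision vector X1..X5.
resources:
  chw: 1            # X1: community health workers
  receptionists: 2  # X2
  nurses: 3         # X3
  cardiologists: 1  # X4
  beds: 7           # X5

workload:
  arrival_rate: 145        # ~52,000 patients/year
  esi_mix: [0.05, 0.15, 0.30, 0.30, 0.20]   # triage levels 1..5
  cardiac_fraction: 0.40
  day_length: 1440

service:
  cpr_success_prob: 0.7
  distributions:           # family: exponential (mean) | uniform (lo, hi) | deterministic (value)
    registration:     {family: exponential, params: [13.0]}
    nurse_assessment: {family: exponential, params: [10.0]}
    ecg:              {family: exponential, params: [6.0]}
    cpr:              {family: exponential, params: [15.0]}
    gp_visit:         {family: exponential, params: [12.0]}
    cpu_stay:         {family: exponential, params: [90.0]}
    icu_handoff:      {family: exponential, params: [14.0]}

design:
  bounds:                  # [L_i, U_i] per factor; coded -1 maps to L, +1 to U
    chw: [1, 2]
    receptionists: [1, 3]
    nurses: [1, 6]
    cardiologists: [1, 3]
    beds: [5, 10]
  replications: 10         # simulated days per design point
  common_random_numbers: false

analysis:
  max_order: 3             # interactions up to three-way
  alpha: 0.05              # significance level for model reduction
  forced_terms: [X2, X3, X4]   # kept regardless of significance
  validation_replications: 10

optimization:
  unit_costs:              # C_i, relative cost units
    chw: 0.6
    receptionists: 0.5
    nurses: 0.8
    cardiologists: 0.7
    beds: 2.0
  budget: null             # null -> cost of the current staffing; or a number, or "inf"

seed: 12345
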