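# Default exposure scenario, kinetic parameters and reconstruction settings.
#
# The kinetic parameters are configurable stand-ins for a one-compartment
# linear toxicokinetic model (absorption during exposure windows, first-order
# elimination, fixed urinary yield).  They are expressed against air
# concentration in ug NCO/m3, so the urinary-yield parameter absorbs the
# NCO-mass convention.  Half-lives reflect the faster urinary elimination of
# aliphatic diamines (HDA/TDA) versus the slower MDA kinetics reported in
# controlled human studies; they are order-of-magnitude defaults, not fitted
# values, and every downstream result that matters is checked by recovery
# and oracle properties rather than by these numbers.
scenario:
  weeks: 12
  days_per_week: 5
  hours_per_day: 8.0
  rpe_assumed: false

kinetics:
  MDI:
    absorbed_fraction: 0.2
    ventilation_rate: 1.25      # m3/h, light work
    elimination_half_life: 24.0 # h
    urinary_excretion_fraction: 0.1
    urine_flow: 0.0625          # L/h  (~1.5 L/day)
    error_gsd: 1.5
  TDI:
    absorbed_fraction: 0.2
    ventilation_rate: 1.25
    elimination_half_life: 6.0
    urinary_excretion_fraction: 0.1
    urine_flow: 0.0625
    error_gsd: 1.5

# Log10-log10 regression between air HDI and urinary HDA (per g creatinine).
hdi_calibration:
  slope: 0.4396
  intercept: 0.4612
  air_range: [0.3, 97.7]    # ug HDI/m3
  urine_range: [1.36, 27.7] # ug HDA/g creatinine

reconstruction:
  background: 0.2        # ug/L non-occupational urinary diamine background
  n_mc: 10000            # Monte Carlo integration iterations
  mh_iterations: 500     # Metropolis-Hastings iterations per chain
  mh_burn_in: 200
  proposal_scale: 0.5    # sd of the lognormal random-walk proposal (log scale)
  prior:
    type: halfnormal
    scale: 100.0         # ug NCO/m3; weakly informative, positive support
  include_zeros_in_gm: false
  default_creatinine: 1.36  # g/L, used when a urine record lacks creatinine

dose_response:
  cap: 7.5  # % excess risk; evaluation never extrapolates above this
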