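# Exact-count roster scenario for the mother and child welfare centre
# (MCWC): 30 days x 3 shifts. FWV = family welfare visitor (paramedic
# cadre); ANA = assistant nursing attendant, recorded doctor-style. The
# support pool is split into two sub-pools (peon/guard and sweeper/aya)
# whose joint coverage the two-pool standard in mcwc_standards.yaml scores.
facility: MCWC
n_days: 30
seed: 20140202
entries:
  - department: obgyn_ward
    cadre: fwv
    mode: graded_headcount
    shifts:
      morning: {counts: {3: 27, 2: 2, 1: 1}}
      evening: {counts: {3: 5, 2: 15, 1: 10}}
      night: {counts: {3: 1, 2: 11, 1: 17, 0: 1}}
  - department: operating_theatre
    cadre: ana
    mode: doctor_style
    shifts:
      morning: {counts: {present_majority: 27, offsite_not_called: 3}}
      evening: {counts: {present_majority: 13, offsite_not_called: 17}}
      night: {counts: {present_majority: 17, offsite_not_called: 13}}
  - department: general
    cadre: peon_guard
    mode: support_pool
    shifts:
      morning: {counts: {1: 30}}
      evening: {counts: {1: 30}}
      night: {counts: {1: 30}}
  - department: general
    cadre: sweeper_aya
    mode: support_pool
    shifts:
      morning: {counts: {1: 30}}
      evening: {counts: {1: 22, 0: 8}}
      night: {counts: {1: 27, 0: 3}}
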