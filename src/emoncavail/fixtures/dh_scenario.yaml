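# Exact-count roster scenario for the district hospital (DH): 30 observation
# days x 3 shifts, with per-shift category counts fixed to the facility's
# recorded presence distributions. Regenerating and tabulating this roster
# reproduces the DH nurse, technologist, support and emergency-physician
# index rows end to end.
facility: DH
n_days: 30
seed: 20140201
entries:
  - department: obgyn_ward
    cadre: nurse
    mode: graded_headcount
    shifts:
      morning: {counts: {3: 29, 2: 1}}
      evening: {counts: {3: 8, 2: 21, 1: 1}}
      night: {counts: {3: 2, 2: 22, 1: 6}}
  - department: pediatric_ward
    cadre: nurse
    mode: graded_headcount
    shifts:
      morning: {counts: {3: 4, 2: 20, 1: 6}}
      evening: {counts: {2: 7, 1: 23}}
      night: {counts: {2: 12, 1: 18}}
  - department: operating_theatre
    cadre: nurse
    mode: graded_headcount_with_oncall
    shifts:
      morning: {counts: {2: 25, 1: 2, 0: 3}}
      evening: {counts: {oncall1: 4, 0: 26}}
      night: {counts: {0: 30}}
  - department: laboratory
    cadre: technologist
    mode: doctor_style
    shifts:
      morning: {counts: {present_majority: 27, offsite_responded: 2, offsite_not_called: 1}}
      evening: {counts: {offsite_responded: 25, offsite_not_called: 5}}
      night: {counts: {offsite_responded: 22, offsite_not_called: 8}}
  - department: emergency
    cadre: doctor
    mode: doctor_style
    shifts:
      morning: {counts: {present_majority: 30}}
      evening: {counts: {present_majority: 30}}
      night: {counts: {present_majority: 30}}
  - department: general
    cadre: support
    mode: support_pool
    shifts:
      morning: {counts: {2: 30}}
      evening: {counts: {2: 30}}
      night: {counts: {2: 24, 1: 6}}
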