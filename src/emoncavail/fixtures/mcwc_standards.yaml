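# Staffing standards for the MCWC: three FWVs in the morning and two in
# the off-peak shifts for the ob/gyn ward; full support coverage requires
# at least one provider from EACH of the peon/guard and sweeper/aya
# sub-pools (any single provider scores partial).
obgyn_ward:
  fwv: {morning: 3, evening: 2, night: 2}
general:
  support:
    morning: 2
    evening: 2
    night: 2
    rule: two_pool
    pool: [peon_guard, sweeper_aya]
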