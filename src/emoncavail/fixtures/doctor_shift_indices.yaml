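# Per-shift physician availability index values recorded for the two study
# facilities (per-discipline physician presence was scored with the
# doctor-style formula; only the resulting per-shift index values are
# retained here). Used as inputs to the day-average computation.
DH:
  obgyn_ward: {morning: 83.3, evening: 21.7, night: 16.7}
  pediatric_ward: {morning: 86.7, evening: 0.0, night: 0.0}
  emergency: {morning: 100.0, evening: 100.0, night: 100.0}
  anesthesia: {morning: 68.3, evening: 11.7, night: 1.7}
  pathology: {morning: 90.0, evening: 0.0, night: 0.0}
MCWC:
  obgyn_ward: {morning: 58.3, evening: 28.3, night: 8.3}
  anesthesia: {morning: 68.3, evening: 31.7, night: 8.3}
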