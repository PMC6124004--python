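# emoncavail

Availability indices for round-the-clock staffing of emergency obstetric
and newborn care (EmONC) facilities.

Public district-level facilities in settings like Bangladesh are expected
to keep maternity services running across three daily shifts — morning
(8 AM–2 PM), evening (2 PM–9 PM) and night (9 PM–8 AM) — but sanctioned
posts, hiring and actual presence diverge sharply, especially off-peak.
`emoncavail` turns shift-level observations of provider presence
(who was on site, how many, whether anyone answered an emergency call)
into a single availability index per provider cadre, department and
shift, for facility managers, health-system researchers and advocacy.

## The index

Each observed shift is scored and the index is the mean score over N
observed shifts, times 100, giving a percentage on [−100, 100]:

- **Doctor-style cadres** (consultants + medical officers pooled per
  discipline; anesthetists; medical technologists; nurse aides):

  index = (a + b/2 + c − d)/N × 100

  where per shift *a* = someone present >50% of the shift, *b* = present
  <50%, *c* = off-site but came when called, *d* = called and did not
  come. A shift with nobody on site and no call arising earns 0.

- **Nurses / FWVs** against a minimum of 3 (morning wards):
  (m₃ + 2m₂/3 + m₁/3 − m₀)/N × 100; against a minimum of 2 (evening and
  night wards): (m₂ + m₁/2 − m₀)/N × 100 — partial staffing earns the
  fraction of the minimum that was present.

- **Operating-theatre nurses** (minimum 2, all shifts):
  (m₂ + m₁/2 + m₂ₐ + m₁ₐ/2 − m₀)/N × 100, where the *a* categories credit
  nurses who arrived purely on emergency call.

- **Support staff** (pooled peon/ward boy/aya/sweeper/guard, minimum 2):
  (s₂ + s₁/2 − s₀)/N × 100.

The **day average** is the unweighted mean of the three per-shift
indices at full precision; rounding to one decimal happens only at
report time.

## Worked example

The package ships exact-count roster scenarios for a district hospital
(DH) and a mother and child welfare centre (MCWC): 30 observation days ×
3 shifts with fixed per-shift category counts. Generate the DH roster and
compute its index matrix:

```bash
emoncavail simulate \
  --scenario "$(python -c 'from emoncavail.io import fixture_path; print(fixture_path("dh_scenario.yaml"))')" \
  --out dh_roster.csv
emoncavail compute --input dh_roster.csv --out dh_report
```

which prints (also written to `dh_report/index_matrix.csv` and
`dh_report/summary.txt`, with the per-shift presence distributions in
`dh_report/presence_distribution.csv`):

```
facility        department        cadre  morning  evening  night  day_average
      DH         emergency       doctor    100.0    100.0  100.0        100.0
      DH           general      support    100.0    100.0   90.0         96.7
      DH        laboratory technologist     96.7     83.3   73.3         84.4
      DH        obgyn_ward        nurse     98.9     98.3   90.0         95.7
      DH operating_theatre        nurse     86.7      6.7    0.0         31.1
      DH    pediatric_ward        nurse     64.4     61.7   70.0         65.4
```

Reading: emergency doctors were fully available around the clock
(100.0), ob/gyn nurses were near-fully staffed in every shift, while the
operating theatre essentially lacked nurses outside the morning — the
6.7 in the evening comes entirely from nurses answering emergency
calls — dragging its day average to 31.1.

The MCWC scenario uses a two-pool support standard (at least one
peon/guard **and** one sweeper/aya for full coverage):

```bash
emoncavail compute --input mcwc_roster.csv \
  --standards "$(python -c 'from emoncavail.io import fixture_path; print(fixture_path("mcwc_standards.yaml"))')" \
  --out mcwc_report
```

## Library use

```python
from emoncavail import (default_standards, generate, load_scenario,
                        index_report)
from emoncavail.io import fixture_path

records = generate(load_scenario(fixture_path("dh_scenario.yaml")))
report = index_report(records, default_standards())
print(report.to_frame(decimals=1))
```

`emoncavail.synth` also supports sampled scenarios (categorical or
binomial per-shift presence models) for simulation studies of the index
itself.

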