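# Methods

## The measurement problem

A facility is ready to deliver emergency obstetric and newborn care only
if the right providers are actually present — or reachable — in every
shift, not just sanctioned on paper. The package quantifies this from a
prospective observation design: one record per (facility, department,
day, shift, cadre) over an observation window (30 days in the packaged
scenarios, collected in three 10-day phases that are pooled for
analysis), three shifts per day. Night-shift information gathered
retrospectively by interviewing the providers on duty is flagged via the
record's `provenance` field but treated identically in computation.

## Scoring model

Every index is the mean over observed shifts of a per-shift score, times
100. The score is +1 when the shift met its standard, a fraction when it
was partially met, and −1 when service demonstrably failed:

| cadre type | +1 | fractional credit | −1 | 0 (unscored) |
|---|---|---|---|---|
| doctor-style | someone on site >50% of the shift (a), or off-site and came when called (c) | on site <50% (b): ½ | called, nobody came (d) | off-site, no call arose |
| ward nurses/FWVs (min *m* ∈ {2, 3}) | headcount ≥ *m* | k of *m* present: k/*m* | none present | — |
| OT nurses (min 2) | ≥2 on site, or ≥2 arrived on call | 1 on site or 1 arrived on call: ½ | a call went unanswered | nobody on site, no call arose |
| support pool (min 2) | ≥2 (two-pool variant: ≥1 from each sub-pool) | exactly 1: ½ | none | — |

Assumptions baked into this model:

- **Shifts are weighted equally** despite unequal nominal durations
  (6 / 7 / 11 h). The day average is the plain mean of the three shift
  indices.
- **On-call response is as good as presence** at the same headcount;
  arrival delay is not discounted.
- **Categories are exclusive and top-coded.** The formulas' categories are
  a partition of the observed shifts: the top category is "at or above the
  minimum" and lower categories are exact counts. A headcount exactly at
  the minimum is always the top category (≥ semantics).
- **The neutral category.** A doctor-style or on-call cadre whose shift
  saw nobody on site *and no emergency call* cannot be scored as a failure
  to respond; such shifts stay in the denominator with score 0. This is
  what makes an index like 96.7 over 30 shifts (29 credited, 1 neutral)
  attainable. Consequently an index of 100 requires every shift in a top
  category, and indices can only go negative through observed failures.
- **Pooling before classification.** Consultants and medical officers of
  one discipline pool into a single shift classification (the best state
  achieved by anyone); government and project nurses pool into one
  headcount; the support pool merges peon/ward boy/aya/sweeper/guard. An
  optional two-pool support rule demands one provider from each of two
  sub-pools for full credit. A pooled-headcount rule (`pool_rule: sum`)
  can combine two headcount cadres (e.g. FWVs with nurse aides), but no
  packaged scenario exercises it as a reported quantity — see
  "Known discrepancies".

## Tunable parameters

- **Minimum staffing standards** (per department × cadre × shift):
  defaults are 3/2/2 nurses for ob/gyn and pediatric wards
  (morning/evening/night), 2/2/2 for OT nurses and the support pool, and
  1 provider per shift for every doctor-style discipline. Override via a
  YAML file (`--standards`).
- **Headcount sanity bound** (default 20): larger values raise a
  validation warning, not an error.
- **`--clamp-negative`** (default off): presentation-only clamp of
  negative indices to 0. Raw values are the faithful default since
  negative indices, while arithmetically possible, carry the meaning
  "failures outnumbered successes" and should usually be shown.
- **`--decimals`** (default 1): presentation rounding, half away from
  zero, applied only at report time.

## Missing data

Shifts without an observation are dropped and N reduced accordingly —
never imputed as absence. A gap in the day sequence is a warning, a
duplicated key or a payload inconsistent with the cadre's mode is a hard
error (CLI exit 2).

## Synthetic rosters

`emoncavail.synth` generates observation sets with known presence
probabilities. **Exact mode** fixes per-shift category counts and assigns
them to days deterministically, so a scenario transcribing a published
presence distribution reproduces its indices end to end — this is how the
packaged DH and MCWC scenarios (30 days × 3 shifts) work. **Sampled
mode** draws outcomes independently per day from a categorical vector or
a binomial headcount model (pool size × per-person attendance
probability); one integer seed drives all draws through per-entry
substreams of numpy's `default_rng`.

What the generator does *not* emulate: day-to-day correlation in
absenteeism, within-shift arrival/departure dynamics, caseload-dependent
staffing, and observer error. Passing tests therefore demonstrate the
arithmetic and plumbing of the index on rosters with the study's marginal
structure, not robustness of the index to those real-data features.

## Numerical conventions

- All index arithmetic is exact in floating point (small-integer ratios);
  rounding happens once, at presentation, half away from zero.
- Day averages use full-precision shift values. Where only 1-decimal
  per-shift values are available as inputs (the physician rows),
  `snap_to_shift_grid` first maps each printed value back to the
  attainable grid (multiples of ½/N × 100 over N = 30 shifts), since
  e.g. 58.3/28.3/8.3 stand for 58.33/28.33/8.33 and average to 31.7, not
  31.6.
- An index over zero observed shifts raises `UndefinedIndexError`; in a
  report the cell is left empty (NaN) without disturbing other cells, and
  the CLI exits 1.

## Design choices where the design was open

- Exclusive, top-coded categories were chosen over the literal "at
  least k" reading of the category definitions because only the exclusive
  reading makes the distribution tables and the index matrix mutually
  consistent (e.g. an off-peak ward index of 90.0 over 30 shifts requires
  m₂ = 24 "two or more" and m₁ = 6 "exactly one").
- The drop-and-renormalize rule for unobserved shifts is our choice;
  alternatives (scoring missing as absent) would conflate non-observation
  with failure.
- Presence-distribution tables use one category layout across all three
  shifts, top-coded at the cadre's *highest* shift minimum, so off-peak
  index categories stay derivable from the printed rows.

## Known discrepancies and limitations

- The DH ob/gyn nurse day average computed from full-precision shift
  values is 95.74 (prints 95.7); the reference report shows 95.8,
  consistent with averaging differently rounded cells. The package
  reports its own full-precision result.
- The MCWC ob/gyn row combining FWVs with nurse aides (96.7/95.6/83.3,
  day average 82.4) is not derivable from the per-cadre marginals by any
  combination rule we could identify (its printed day average is also
  below the mean of its own shift cells). The `sum` pool rule implements
  the natural pooled-headcount combination but does not reproduce that
  row, so it is excluded from the reproduced set.
- The index weights all providers of a cadre equally (no skill-mix
  weighting), ignores response delay, and says nothing about quality of
  care — it measures presence against a local standard, nothing more.
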