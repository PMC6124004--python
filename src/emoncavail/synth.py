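"""Synthetic roster generator.

Emulates the study design — a fixed number of observation days, three
shifts per day, one record per department x cadre x shift — with known
presence probabilities, so the whole pipeline can be exercised and
proportion-recovery properties asserted without facility data.

Two generation modes:

* ``exact`` — per-shift category counts are fixed integers assigned to
  days deterministically (stratified, not sampled), so a scenario built
  from a published presence distribution reproduces its indices exactly,
  end to end.
* ``sampled`` — outcomes are drawn independently per day from a category
  probability vector or a binomial headcount model; a single integer seed
  governs all draws through per-entry substreams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import (
    CadreMode,
    DoctorClassification,
    Shift,
    SHIFTS,
    ShiftObservation,
)

DEFAULT_SEED = 20140201

_ONCALL_PREFIX = "oncall"


@dataclass(frozen=True)
class ShiftSpec:
    """Outcome model for one entry x shift.

    Exactly one of ``counts`` (exact mode), ``probs`` (categorical
    sampling) or ``binomial`` (staff pool of ``pool`` providers attending
    independently with probability ``p``) is set. Category keys are
    classification names for doctor-style cadres, headcounts (as integers)
    for headcount cadres, and ``oncall<k>`` for k providers arriving purely
    on emergency call.
    """

    counts: Optional[Mapping[str, int]] = None
    probs: Optional[Mapping[str, float]] = None
    binomial: Optional[tuple[int, float]] = None  # (pool, p)

    def __post_init__(self):
        set_ = [x is not None for x in (self.counts, self.probs, self.binomial)]
        if sum(set_) != 1:
            raise ScenarioError(
                "each shift needs exactly one of counts/probs/binomial")
        if self.probs is not None:
            total = sum(self.probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ScenarioError(f"probability vector sums to {total}, not 1")
            if any(p < 0 for p in self.probs.values()):
                raise ScenarioError("negative category probability")
        if self.binomial is not None:
            pool, p = self.binomial
            if pool < 0 or not (0.0 <= p <= 1.0):
                raise ScenarioError("binomial needs pool >= 0 and p in [0, 1]")


@dataclass(frozen=True)
class ScenarioEntry:
    department: str
    cadre: str
    mode: CadreMode
    shifts: Mapping[Shift, ShiftSpec]


@dataclass(frozen=True)
class RosterScenario:
    facility: str
    n_days: int
    entries: Sequence[ScenarioEntry]
    rng_seed: int = DEFAULT_SEED

    def __post_init__(self):
        if self.n_days <= 0:
            raise ScenarioError("n_days must be positive")


class ScenarioError(ValueError):
    pass


# ---------------------------------------------------------------------------
# outcome encoding


def _observation(entry: ScenarioEntry, facility: str, day: int, shift: Shift,
                 key: str) -> ShiftObservation:
    base = dict(facility=facility, department=entry.department,
                day_index=day, shift=shift, cadre=entry.cadre,
                mode=entry.mode)
    if entry.mode is CadreMode.DOCTOR_STYLE:
        return ShiftObservation(
            classification=DoctorClassification(key), **base)
    if key.startswith(_ONCALL_PREFIX):
        return ShiftObservation(n_present=0,
                                n_oncall_responded=int(key[len(_ONCALL_PREFIX):]),
                                **base)
    return ShiftObservation(n_present=int(key), **base)


def outcome_key(obs: ShiftObservation) -> str:
    """Inverse of the scenario outcome encoding, for proportion recovery."""
    if obs.mode is CadreMode.DOCTOR_STYLE:
        return obs.classification.value
    if obs.n_oncall_responded and not obs.n_present:
        return f"{_ONCALL_PREFIX}{obs.n_oncall_responded}"
    return str(obs.n_present)


def _sorted_keys(keys) -> list[str]:
    # stable canonical order so exact-mode assignment is reproducible
    return sorted(str(k) for k in keys)


# ---------------------------------------------------------------------------
# generation


def generate(scenario: RosterScenario) -> list[ShiftObservation]:
    """Produce n_days x 3 shifts x entries observation records.

    Identical scenarios (including seed) yield identical records; exact
    counts must sum to n_days.
    """
    records: list[ShiftObservation] = []
    for ei, entry in enumerate(scenario.entries):
        for si, shift in enumerate(SHIFTS):
            spec = entry.shifts.get(shift)
            if spec is None:
                continue
            keys = _keys_for_days(spec, scenario, ei, si)
            for day, key in enumerate(keys, start=1):
                records.append(_observation(entry, scenario.facility,
                                            day, shift, key))
    records.sort(key=lambda r: (r.day_index, SHIFTS.index(r.shift),
                                r.department, r.cadre))
    return records


def _keys_for_days(spec: ShiftSpec, scenario: RosterScenario,
                   entry_idx: int, shift_idx: int) -> list[str]:
    n = scenario.n_days
    if spec.counts is not None:
        counts = {str(k): int(v) for k, v in spec.counts.items()}
        if sum(counts.values()) != n:
            raise ScenarioError(
                f"exact counts sum to {sum(counts.values())}, expected {n}")
        keys: list[str] = []
        for k in _sorted_keys(counts):
            keys.extend([k] * counts[k])
        return keys
    rng = np.random.default_rng([scenario.rng_seed, entry_idx, shift_idx])
    if spec.probs is not None:
        cats = _sorted_keys(spec.probs)
        p = np.array([spec.probs[_orig_key(spec.probs, c)] for c in cats])
        draws = rng.choice(len(cats), size=n, p=p / p.sum())
        return [cats[i] for i in draws]
    pool, p = spec.binomial
    return [str(int(k)) for k in rng.binomial(pool, p, size=n)]


def _orig_key(mapping: Mapping, skey: str):
    for k in mapping:
        if str(k) == skey:
            return k
    raise KeyError(skey)


# ---------------------------------------------------------------------------
# proportion recovery


def recover_proportions(records: Sequence[ShiftObservation],
                        scenario: RosterScenario) -> pd.DataFrame:
    """Empirical outcome proportions vs the scenario's target probabilities.

    For exact-count shifts the target is count/n_days; for binomial shifts
    it is the binomial pmf over headcounts. Columns: department, cadre,
    shift, outcome, expected, observed, abs_dev.
    """
    by_cell: dict[tuple, list[str]] = {}
    for r in records:
        by_cell.setdefault((r.department, r.cadre, r.shift), []).append(
            outcome_key(r))
    rows = []
    for entry in scenario.entries:
        for shift, spec in entry.shifts.items():
            observed = by_cell.get((entry.department, entry.cadre, shift), [])
            n = len(observed)
            expected = _expected_probs(spec, scenario.n_days)
            outcomes = set(expected) | set(observed)
            for key in _sorted_keys(outcomes):
                obs_p = observed.count(key) / n if n else float("nan")
                exp_p = expected.get(key, 0.0)
                rows.append({"department": entry.department,
                             "cadre": entry.cadre, "shift": shift.value,
                             "outcome": key, "expected": exp_p,
                             "observed": obs_p,
                             "abs_dev": abs(obs_p - exp_p)})
    return pd.DataFrame(rows)


def _expected_probs(spec: ShiftSpec, n_days: int) -> dict[str, float]:
    if spec.counts is not None:
        return {str(k): v / n_days for k, v in spec.counts.items()}
    if spec.probs is not None:
        return {str(k): float(v) for k, v in spec.probs.items()}
    pool, p = spec.binomial
    return {str(k): math.comb(pool, k) * p ** k * (1 - p) ** (pool - k)
            for k in range(pool + 1)}


# ---------------------------------------------------------------------------
# YAML (de)serialisation


def scenario_from_dict(data: Mapping[str, Any],
                       seed: Optional[int] = None) -> RosterScenario:
    try:
        entries = []
        for e in data["entries"]:
            shifts = {}
            for sname, sdata in e["shifts"].items():
                binom = sdata.get("binomial")
                shifts[Shift(sname)] = ShiftSpec(
                    counts=sdata.get("counts"),
                    probs=sdata.get("probs"),
                    binomial=(int(binom["pool"]), float(binom["p"]))
                    if binom else None,
                )
            entries.append(ScenarioEntry(
                department=e["department"], cadre=e["cadre"],
                mode=CadreMode(e["mode"]), shifts=shifts))
        return RosterScenario(
            facility=data["facility"], n_days=int(data["n_days"]),
            entries=entries,
            rng_seed=int(seed if seed is not None
                         else data.get("seed", DEFAULT_SEED)))
    except (KeyError, TypeError, ValueError) as err:
        if isinstance(err, ScenarioError):
            raise
        raise ScenarioError(f"malformed scenario: {err}") from err


def load_scenario(path, seed: Optional[int] = None) -> RosterScenario:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ScenarioError("scenario file is not a mapping")
    return scenario_from_dict(data, seed=seed)


__all__ = [
    "RosterScenario", "ScenarioEntry", "ShiftSpec", "ScenarioError",
    "generate", "recover_proportions", "outcome_key", "scenario_from_dict",
    "load_scenario", "DEFAULT_SEED",
]
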