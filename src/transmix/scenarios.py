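"""Scenario-ensemble sampling for the simulation study.

An ensemble draws many outbreak scenarios from configurable parameter
distributions, emulating small person-to-person outbreaks of
healthcare-acquired respiratory pathogens: a handful of groups (wards,
staff categories), total populations of a few hundred, a few introduced
cases, R0 in the 1-4 range, and a generation time of around 5 days. The
per-group true assortativity delta is uniform on [-1, 1] with a
configurable point mass at exactly 0 so that specificity (no-effect
scenarios) is measurable. Every sampled scenario carries its own
deterministic seed derived from (base_seed, scenario index, replicate
index), so any single run can be re-executed in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .simulator import ScenarioParams, discretised_gamma_pmf

__all__ = ["ScenarioEnsembleSpec", "sample_ensemble", "replicate_seed", "DEFAULT_RANGES"]

#: Default nosocomial-outbreak sampling ranges. All exposed, none hidden.
DEFAULT_RANGES: dict = {
    "n_groups": [2, 4],              # inclusive integer range
    "total_size": [50, 500],         # inclusive integer range, persons
    "r0": [1.0, 4.0],                # uniform, per group
    "delta": {"low": -1.0, "high": 1.0, "p_zero": 0.2},  # per group
    "total_imports": [1, 5],         # inclusive, allocated uniformly over groups
    "generation_time": {"mean": [5.0, 5.0], "sd": [2.0, 2.0]},  # days
    "incubation": {"mean": [4.0, 4.0], "sd": [2.0, 2.0]},       # days
    "min_group_size": 2,
    "horizon": 365,
}


def _merge_ranges(ranges: Optional[dict]) -> dict:
    merged = {k: (dict(v) if isinstance(v, dict) else list(v) if isinstance(v, list) else v)
              for k, v in DEFAULT_RANGES.items()}
    for key, val in (ranges or {}).items():
        if key not in merged:
            raise ValidationError(f"unknown ensemble range {key!r}; "
                                  f"known: {sorted(merged)}")
        if isinstance(merged[key], dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


@dataclass(frozen=True)
class ScenarioEnsembleSpec:
    """Ensemble design: how many scenarios/replicates and what to sample."""

    n_scenarios: int
    n_replicates: int
    base_seed: int = 0
    ranges: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_scenarios < 1 or self.n_replicates < 1:
            raise ValidationError("n_scenarios and n_replicates must be >= 1")
        object.__setattr__(self, "ranges", _merge_ranges(self.ranges))
        r = self.ranges
        for key in ("n_groups", "total_size", "total_imports"):
            lo, hi = r[key]
            if lo > hi or lo < 1:
                raise ValidationError(f"range {key}={r[key]} is infeasible")
        if r["n_groups"][0] < 2:
            raise ValidationError("n_groups must be at least 2 (assortativity "
                                  "is undefined for a single group)")
        if r["r0"][0] < 0:
            raise ValidationError(f"range r0={r['r0']} is infeasible (R0 >= 0)")
        d = r["delta"]
        if not (-1 <= d["low"] <= d["high"] <= 1) or not 0 <= d["p_zero"] <= 1:
            raise ValidationError(f"delta range {d} is infeasible")
        if r["min_group_size"] < 1:
            raise ValidationError("min_group_size must be >= 1")
        lo_groups = r["n_groups"][1] * r["min_group_size"]
        if r["total_size"][0] < lo_groups:
            raise ValidationError(
                f"total_size lower bound {r['total_size'][0]} cannot host "
                f"{r['n_groups'][1]} groups of at least {r['min_group_size']}"
            )

    @classmethod
    def from_dict(cls, cfg: dict) -> "ScenarioEnsembleSpec":
        known = {"n_scenarios", "n_replicates", "base_seed", "ranges"}
        unknown = set(cfg) - known
        if unknown:
            raise ValidationError(f"unknown ensemble spec keys {sorted(unknown)}")
        missing = {"n_scenarios", "n_replicates"} - set(cfg)
        if missing:
            raise ValidationError(f"ensemble spec missing keys {sorted(missing)}")
        return cls(**cfg)


def replicate_seed(base_seed: int, scenario_idx: int, replicate_idx: int) -> int:
    """Deterministic per-run integer seed (< 2**31)."""
    ss = np.random.SeedSequence((int(base_seed), int(scenario_idx), int(replicate_idx)))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _apportion(total: int, props: np.ndarray, minimum: int) -> np.ndarray:
    """Largest-remainder apportionment of `total` with a per-group floor."""
    G = props.size
    raw = props * (total - minimum * G)
    sizes = np.floor(raw).astype(int)
    rem = int(total - minimum * G - sizes.sum())
    order = np.argsort(-(raw - sizes))
    sizes[order[:rem]] += 1
    return sizes + minimum


def _sample_scenario(rng: np.random.Generator, r: dict) -> ScenarioParams:
    G = int(rng.integers(r["n_groups"][0], r["n_groups"][1] + 1))
    total = int(rng.integers(r["total_size"][0], r["total_size"][1] + 1))
    props = rng.dirichlet(np.ones(G))
    sizes = _apportion(total, props, r["min_group_size"])
    deltas = np.where(
        rng.random(G) < r["delta"]["p_zero"],
        0.0,
        rng.uniform(r["delta"]["low"], r["delta"]["high"], size=G),
    )
    r0s = rng.uniform(r["r0"][0], r["r0"][1], size=G)
    n_imports = int(rng.integers(r["total_imports"][0], r["total_imports"][1] + 1))
    imports = rng.multinomial(n_imports, np.ones(G) / G)
    imports = np.minimum(imports, sizes)  # tiny groups cannot host more imports
    if imports.sum() == 0:
        imports[int(np.argmax(sizes))] = 1
    gt = r["generation_time"]
    inc = r["incubation"]
    w = discretised_gamma_pmf(
        rng.uniform(*gt["mean"]), rng.uniform(*gt["sd"]), zero_lag=False
    )
    inc_pmf = discretised_gamma_pmf(
        rng.uniform(*inc["mean"]), rng.uniform(*inc["sd"]), zero_lag=True
    )
    return ScenarioParams(
        group_sizes=tuple(int(n) for n in sizes),
        deltas=tuple(float(d) for d in deltas),
        r0s=tuple(float(x) for x in r0s),
        initial_imports=tuple(int(m) for m in imports),
        generation_time_pmf=w,
        incubation_pmf=inc_pmf,
        horizon=int(r["horizon"]),
    )


def sample_ensemble(spec: ScenarioEnsembleSpec) -> list:
    """Draw the ensemble's scenarios, reproducibly from the base seed.

    Scenario i is sampled from a generator seeded by (base_seed, i), so
    the ensemble is stable under changes of n_scenarios prefix-wise and
    any scenario can be regenerated alone.
    """
    scenarios = []
    for i in range(spec.n_scenarios):
        rng = np.random.default_rng(np.random.SeedSequence((spec.base_seed, i)))
        scenarios.append(_sample_scenario(rng, spec.ranges))
    return scenarios


def ensemble_manifest(spec: ScenarioEnsembleSpec, scenarios: list) -> pd.DataFrame:
    """Tabular manifest: one row per scenario with parameters and seeds."""
    rows = []
    for i, sc in enumerate(scenarios):
        rows.append({
            "scenario": i,
            "n_groups": sc.n_groups,
            "group_sizes": "|".join(str(n) for n in sc.group_sizes),
            "deltas": "|".join(f"{d:.6g}" for d in sc.deltas),
            "r0s": "|".join(f"{r:.6g}" for r in sc.r0s),
            "imports": "|".join(str(m) for m in sc.initial_imports),
            "horizon": sc.horizon,
            "first_replicate_seed": replicate_seed(spec.base_seed, i, 0),
        })
    return pd.DataFrame(rows)
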