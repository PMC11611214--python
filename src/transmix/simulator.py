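"""Group-structured discrete-time branching-process outbreak simulator.

Infections spread in daily steps through G groups of fixed census size.
Each infected individual j of group a, infected on day s, exerts on day t
a force of infection (FOI) toward the whole of group b of

    lambda[b<-a,j](t) = w(t - s) * R0_a * pi[b<-a]

where w is the generation-time pmf on integer lags (no mass at lag 0: a
case cannot transmit on its infection day) and pi[b<-a] the mixing-matrix
column of the infector's group, derived from the group's assortativity
(gamma via delta) and the relative group sizes. Group b's members share
the summed FOI lambda_b(t); each susceptible is infected with probability
p_b(t) = 1 - exp(-lambda_b(t)/N_b) so the day's case count is
X_b(t+1) ~ Binomial(S_b(t), p_b(t)). New cases are allocated at random
among susceptibles, infected individuals are permanently immune, and each
new case's infector is drawn from the contributing infectors with
probability proportional to their individual FOI contribution toward b.
Symptom-onset dates are infection day plus an independent draw from the
incubation pmf; onsets drive only the downstream analysis windows, never
the dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import gamma as _gamma_dist

from .estimator import expected_mixing_matrix, gamma_from_delta
from .exceptions import ValidationError
from .groups import compute_group_fractions
from .tree import TransmissionTree
import pandas as pd

__all__ = [
    "ScenarioParams",
    "EpidemicState",
    "discretised_gamma_pmf",
    "individual_foi",
    "step",
    "attribute_infector",
    "simulate_outbreak",
]

DEFAULT_HORIZON = 365


def discretised_gamma_pmf(
    mean: float, sd: float, zero_lag: bool = True, tol: float = 1e-9
) -> np.ndarray:
    """Gamma distribution discretised onto integer days.

    Mass on day k is the gamma CDF increment over (k - 0.5, k + 0.5]
    (the day-0 cell integrates from 0), truncated where the tail drops
    below ``tol`` and renormalised. With ``zero_lag=False`` the day-0
    mass is removed before renormalising — the convention for generation
    times, where same-day transmission is excluded.
    """
    if mean <= 0 or sd <= 0:
        raise ValidationError(f"mean and sd must be > 0; got mean={mean}, sd={sd}")
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    kmax = max(3, int(math.ceil(mean + 12.0 * sd)))
    edges = np.concatenate([[0.0], np.arange(0.5, kmax + 1.5)])
    pmf = np.diff(_gamma_dist.cdf(edges, a=shape, scale=scale))
    keep = np.nonzero(pmf > tol)[0]
    pmf = pmf[: (keep[-1] + 1) if keep.size else 1]
    if not zero_lag:
        pmf[0] = 0.0
    total = pmf.sum()
    if total <= 0:
        raise ValidationError("discretisation left no probability mass")
    return pmf / total


@dataclass(frozen=True)
class ScenarioParams:
    """Complete input set for one simulated outbreak scenario.

    deltas hold the per-group true assortativity on the [-1, 1] scale
    (converted internally to gamma); generation_time_pmf is indexed by
    integer lag with pmf[0] == 0; incubation_pmf by integer delay from
    infection to onset.
    """

    group_sizes: tuple
    deltas: tuple
    r0s: tuple
    initial_imports: tuple
    generation_time_pmf: np.ndarray = field(repr=False)
    incubation_pmf: np.ndarray = field(repr=False)
    horizon: int = DEFAULT_HORIZON
    labels: Optional[tuple] = None

    def __post_init__(self):
        sizes = tuple(int(n) for n in self.group_sizes)
        G = len(sizes)
        deltas = tuple(float(d) for d in self.deltas)
        r0s = tuple(float(r) for r in self.r0s)
        imports = tuple(int(m) for m in self.initial_imports)
        labels = self.labels or tuple(f"g{i + 1}" for i in range(G))
        if not (len(deltas) == len(r0s) == len(imports) == len(labels) == G):
            raise ValidationError("per-group parameter lengths disagree")
        compute_group_fractions(sizes)  # >=2 groups, sizes >= 1
        if any(not -1.0 <= d <= 1.0 for d in deltas):
            raise ValidationError(f"deltas must be in [-1, 1]; got {deltas}")
        if any(r < 0 for r in r0s):
            raise ValidationError(f"R0 must be >= 0; got {r0s}")
        if any(m < 0 for m in imports):
            raise ValidationError(f"imports must be >= 0; got {imports}")
        if sum(imports) < 1:
            raise ValidationError("at least one group needs an initial import")
        if any(m > n for m, n in zip(imports, sizes)):
            raise ValidationError("imports cannot exceed the group's census size")
        if self.horizon < 1:
            raise ValidationError(f"horizon must be >= 1 day; got {self.horizon}")
        for name, pmf, zero_ok in (
            ("generation_time_pmf", self.generation_time_pmf, False),
            ("incubation_pmf", self.incubation_pmf, True),
        ):
            arr = np.asarray(pmf, dtype=float)
            if arr.ndim != 1 or arr.size < 1 or np.any(arr < 0):
                raise ValidationError(f"{name} must be a non-negative 1-d pmf")
            if abs(arr.sum() - 1.0) > 1e-6:
                raise ValidationError(f"{name} must sum to 1; got {arr.sum():.6f}")
            if not zero_ok and arr[0] != 0.0:
                raise ValidationError(f"{name} must have zero mass at lag 0")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "group_sizes", sizes)
        object.__setattr__(self, "deltas", deltas)
        object.__setattr__(self, "r0s", r0s)
        object.__setattr__(self, "initial_imports", imports)
        object.__setattr__(self, "labels", labels)

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)

    @property
    def fractions(self) -> np.ndarray:
        return compute_group_fractions(self.group_sizes)

    @property
    def gammas(self) -> tuple:
        return tuple(gamma_from_delta(d) for d in self.deltas)

    @property
    def mixing_matrix(self) -> np.ndarray:
        return expected_mixing_matrix(self.gammas, self.fractions)


def individual_foi(
    infection_day: int,
    r0: float,
    pi_col: np.ndarray,
    w: np.ndarray,
    t: int,
) -> np.ndarray:
    """Per-target-group FOI vector of one infector on day t.

    w(t - s) * R0 * pi[b<-a] over target groups b; zero outside w's
    support. Summed over all days and groups this returns exactly R0
    (both w and the mixing column are normalised).
    """
    lag = t - infection_day
    if lag < 0 or lag >= len(w):
        return np.zeros_like(np.asarray(pi_col, dtype=float))
    return float(w[lag]) * r0 * np.asarray(pi_col, dtype=float)


@dataclass
class EpidemicState:
    """Mutable per-day simulation state.

    Case arrays are ordered by infection day, so the infectious window
    [t - wmax, t - 1] is a contiguous slice tracked by ``active_start``.
    """

    day: int
    susceptible: np.ndarray          # S_b(t)
    case_group: list                 # group index per case
    case_infection_day: list         # s per case
    case_infector: list              # case index of infector, -1 = import
    active_start: int = 0            # first case possibly still infectious

    @property
    def n_cases(self) -> int:
        return len(self.case_group)


def _state_foi(state: EpidemicState, scenario: ScenarioParams, P: np.ndarray, t: int):
    """Active-case FOI weights and the per-group total FOI lambda_b(t)."""
    w = scenario.generation_time_pmf
    wmax = len(w) - 1
    s = np.asarray(state.case_infection_day[state.active_start:], dtype=np.int64)
    lags = t - s
    in_support = (lags >= 1) & (lags <= wmax)
    idx = np.nonzero(in_support)[0] + state.active_start
    if idx.size == 0:
        return idx, np.empty(0), np.zeros(scenario.n_groups)
    groups = np.asarray(state.case_group, dtype=np.int64)[idx]
    r0s = np.asarray(scenario.r0s)
    weights = w[lags[in_support]] * r0s[groups]   # w(t-s) * R0_a per infector
    lam = np.zeros(scenario.n_groups)
    # lambda_b = sum_a P[b, a] * (summed weight of group-a infectors)
    group_weight = np.bincount(groups, weights=weights, minlength=scenario.n_groups)
    lam = P @ group_weight
    return idx, weights, lam


def attribute_infector(
    target_group: int,
    active_idx: np.ndarray,
    active_weights: np.ndarray,
    active_groups: np.ndarray,
    P: np.ndarray,
    rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Draw infectors for new cases in one group.

    Each contributing infector j (group a) is chosen with probability
    proportional to its individual FOI toward the target group,
    w(t-s_j) * R0_a * pi[target<-a]; a degenerate single contributor is
    chosen with probability 1.
    """
    contrib = active_weights * P[target_group, active_groups]
    total = contrib.sum()
    if total <= 0:
        raise ValidationError(
            "internal inconsistency: new case with zero FOI toward its group"
        )
    return rng.choice(active_idx, size=size, p=contrib / total)


def step(
    state: EpidemicState,
    scenario: ScenarioParams,
    P: np.ndarray,
    rng: np.random.Generator,
) -> list:
    """Advance one day: draw new cases and attribute their infectors.

    Returns the list of (group_index, infector_case_index) for cases
    infected on day state.day + 1, after appending them to the state.
    Draw order is fixed: per-group binomials in group order, then
    infector attribution per group in case order.
    """
    t = state.day
    G = scenario.n_groups
    sizes = np.asarray(scenario.group_sizes)
    active_idx, active_weights, lam = _state_foi(state, scenario, P, t)
    # advance the active window: cases older than the w support never matter again
    wmax = len(scenario.generation_time_pmf) - 1
    while (
        state.active_start < state.n_cases
        and t - state.case_infection_day[state.active_start] >= wmax
    ):
        state.active_start += 1
    new = []
    if active_idx.size:
        p_inf = 1.0 - np.exp(-lam / sizes)
        n_new = np.array(
            [rng.binomial(state.susceptible[b], p_inf[b]) for b in range(G)]
        )
        active_groups = np.asarray(state.case_group, dtype=np.int64)[active_idx]
        for b in range(G):
            if n_new[b] == 0:
                continue
            infectors = attribute_infector(
                b, active_idx, active_weights, active_groups, P, rng, size=int(n_new[b])
            )
            for inf in infectors:
                new.append((b, int(inf)))
            state.susceptible[b] -= int(n_new[b])
    for b, inf in new:
        state.case_group.append(b)
        state.case_infection_day.append(t + 1)
        state.case_infector.append(inf)
    state.day = t + 1
    return new


def simulate_outbreak(
    scenario: ScenarioParams,
    seed=None,
    rng: Optional[np.random.Generator] = None,
) -> TransmissionTree:
    """Run one outbreak and return its annotated transmission tree.

    Imports are infected on day 0 and emit FOI like any case; the daily
    loop runs to the horizon but exits early once no infector can still
    transmit. Fully reproducible: the same scenario and seed give an
    identical tree.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    G = scenario.n_groups
    P = scenario.mixing_matrix
    state = EpidemicState(
        day=0,
        susceptible=np.asarray(scenario.group_sizes, dtype=np.int64).copy(),
        case_group=[],
        case_infection_day=[],
        case_infector=[],
    )
    for b in range(G):
        for _ in range(scenario.initial_imports[b]):
            state.case_group.append(b)
            state.case_infection_day.append(0)
            state.case_infector.append(-1)
        state.susceptible[b] -= scenario.initial_imports[b]
    wmax = len(scenario.generation_time_pmf) - 1
    last_infection = 0 if state.n_cases else -1
    while state.day < scenario.horizon:
        if last_infection < 0 or state.day - last_infection >= wmax:
            break  # nobody can transmit any more
        if not state.susceptible.any():
            break
        new = step(state, scenario, P, rng)
        if new:
            last_infection = state.day  # state.day already advanced to t+1
    n = state.n_cases
    inc = scenario.incubation_pmf
    delays = rng.choice(len(inc), size=n, p=inc) if n else np.empty(0, dtype=int)
    labels = scenario.labels
    infector = [
        "" if j < 0 else str(j) for j in state.case_infector
    ]
    df = pd.DataFrame({
        "case_id": [str(i) for i in range(n)],
        "group": [labels[g] for g in state.case_group],
        "onset_day": np.asarray(state.case_infection_day, dtype=np.int64) + delays,
        "infection_day": pd.array(state.case_infection_day, dtype="Int64"),
        "infector_id": pd.array(infector, dtype="string"),
    })
    return TransmissionTree(df, validate=False)
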