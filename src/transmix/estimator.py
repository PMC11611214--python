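"""Closed-form transmission-assortativity estimation.

The assortativity coefficient gamma_a of group a is the multiplicative
excess of the within-group person-to-person transmission rate over the
between-group rate (1 = homogeneous mixing, 0 = fully disassortative,
infinity = fully assortative). Under the one-parameter-per-group mixing
model, the expected proportion of secondary cases landing in group b when
the infector belongs to group a is

    pi[b<-a] = f_b / ((1 - f_a) + gamma_a f_a)          (b != a)
    pi[a<-a] = gamma_a f_a / ((1 - f_a) + gamma_a f_a)

so gamma_a is identified from the observed within-group proportion
pi = tau[a<-a] / tau[.<-a] via

    gamma_a = pi (1 - f_a) / (f_a (1 - pi))

and is reported on the rescaled delta = (gamma - 1)/(gamma + 1) in
[-1, 1] (delta = 1 when gamma is infinite). A Clopper-Pearson exact
binomial interval on pi is pushed through the (strictly increasing)
pi -> delta map to give an interval on delta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import beta as _beta

from .exceptions import UndefinedEstimateError, ValidationError

__all__ = [
    "TransmissionCounts",
    "AssortativityEstimate",
    "clopper_pearson_interval",
    "gamma_from_pi",
    "delta_from_gamma",
    "gamma_from_delta",
    "delta_from_pi",
    "estimate_delta",
    "expected_mixing_matrix",
]


@dataclass(frozen=True)
class TransmissionCounts:
    """Transmission-pair counts emitted by one group.

    tau_within is the number of infector->infectee pairs staying inside
    the group; tau_out_total counts every pair whose infector belongs to
    the group (imported cases never appear on the infectee side).
    """

    group: object
    tau_within: int
    tau_out_total: int

    def __post_init__(self):
        tw, tt = self.tau_within, self.tau_out_total
        if tw != int(tw) or tt != int(tt):
            raise ValidationError("transmission counts must be integers")
        if tw < 0 or tt < 0 or tw > tt:
            raise ValidationError(
                f"need 0 <= tau_within <= tau_out_total; got ({tw}, {tt})"
            )

    @property
    def pi_hat(self) -> float:
        if self.tau_out_total == 0:
            raise UndefinedEstimateError(
                f"group {self.group!r} emitted no transmissions"
            )
        return self.tau_within / self.tau_out_total


@dataclass(frozen=True)
class AssortativityEstimate:
    """Point estimate and CI of delta for one group.

    ``status`` is "ok" for a defined estimate and "no_emissions" when the
    group emitted nothing (all numeric fields NaN); callers aggregating
    over many outbreaks filter on it rather than catching exceptions.
    """

    group: object
    pi_hat: float
    gamma_hat: float
    delta_hat: float
    ci_low: float
    ci_high: float
    alpha: float
    n: int
    tau_within: int
    status: str = "ok"

    @property
    def defined(self) -> bool:
        return self.status == "ok"

    def contains(self, delta_true: float) -> bool:
        """Whether the CI covers a given true delta."""
        return bool(self.defined and self.ci_low <= delta_true <= self.ci_high)

    @property
    def significant(self) -> bool:
        """CI excludes 0: a detected (dis)assortative signal."""
        return bool(self.defined and (self.ci_low > 0.0 or self.ci_high < 0.0))


def clopper_pearson_interval(successes: int, trials: int, alpha: float):
    """Exact (Clopper-Pearson) two-sided binomial interval on a proportion.

    Beta-quantile form: low = Beta(alpha/2; x, n-x+1), high =
    Beta(1-alpha/2; x+1, n-x), with low = 0 when x = 0 and high = 1 when
    x = n. Coverage is >= 1 - alpha for every p (conservative).
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must be in (0, 1); got {alpha}")
    if trials == 0:
        raise UndefinedEstimateError("no trials: proportion undefined")
    if trials < 0 or successes < 0 or successes > trials:
        raise ValidationError(
            f"need 0 <= successes <= trials; got ({successes}, {trials})"
        )
    if successes == 0:
        low = 0.0
    else:
        low = float(_beta.ppf(alpha / 2.0, successes, trials - successes + 1))
    if successes == trials:
        high = 1.0
    else:
        high = float(_beta.ppf(1.0 - alpha / 2.0, successes + 1, trials - successes))
    return low, high


def gamma_from_pi(pi: float, f: float) -> float:
    """Assortativity coefficient from the within-group proportion.

    gamma = pi (1 - f) / (f (1 - pi)); pi = 1 maps to +inf, pi = 0 to 0.
    """
    if not 0.0 < f < 1.0:
        raise ValidationError(f"group fraction must be in (0, 1); got {f}")
    if not 0.0 <= pi <= 1.0:
        raise ValidationError(f"proportion must be in [0, 1]; got {pi}")
    if pi == 1.0:
        return math.inf
    return pi * (1.0 - f) / (f * (1.0 - pi))


def delta_from_gamma(gamma: float) -> float:
    """Rescale gamma in [0, inf] onto delta in [-1, 1].

    delta = 1 if gamma is infinite, else (gamma - 1) / (gamma + 1).
    """
    if math.isinf(gamma):
        return 1.0
    if gamma < 0:
        raise ValidationError(f"gamma must be >= 0 or infinite; got {gamma}")
    return (gamma - 1.0) / (gamma + 1.0)


def gamma_from_delta(delta: float) -> float:
    """Inverse rescaling: gamma = (1 + delta) / (1 - delta), delta=1 -> inf."""
    if not -1.0 <= delta <= 1.0:
        raise ValidationError(f"delta must be in [-1, 1]; got {delta}")
    if delta == 1.0:
        return math.inf
    return (1.0 + delta) / (1.0 - delta)


def delta_from_pi(pi: float, f: float) -> float:
    """Direct pi -> delta map: (pi - f) / (pi + f (1 - 2 pi)).

    Algebraically the composition delta_from_gamma(gamma_from_pi(pi, f));
    strictly increasing in pi at fixed f (derivative 2 f (1-f) /
    (pi + f - 2 pi f)^2 > 0), which is what licenses endpoint-transforming
    a CI on pi into a CI on delta.
    """
    if not 0.0 < f < 1.0:
        raise ValidationError(f"group fraction must be in (0, 1); got {f}")
    if not 0.0 <= pi <= 1.0:
        raise ValidationError(f"proportion must be in [0, 1]; got {pi}")
    return (pi - f) / (pi + f * (1.0 - 2.0 * pi))


def _undefined_estimate(group, alpha: float) -> AssortativityEstimate:
    nan = float("nan")
    return AssortativityEstimate(
        group=group, pi_hat=nan, gamma_hat=nan, delta_hat=nan,
        ci_low=nan, ci_high=nan, alpha=alpha, n=0, tau_within=0,
        status="no_emissions",
    )


def estimate_delta(
    counts: TransmissionCounts, f: float, alpha: float = 0.05
) -> AssortativityEstimate:
    """Estimate delta for one group from its transmission counts.

    The point estimate applies the pi -> delta map to pi_hat =
    tau_within / tau_out_total; the CI applies the same map to the
    Clopper-Pearson bounds on pi. A group with tau_out_total = 0 returns
    a "no_emissions" estimate rather than raising, so batch evaluation
    over many simulated outbreaks never aborts.
    """
    if not 0.0 < f < 1.0:
        raise ValidationError(f"group fraction must be in (0, 1); got {f}")
    if counts.tau_out_total == 0:
        if not 0.0 < alpha < 1.0:
            raise ValidationError(f"alpha must be in (0, 1); got {alpha}")
        return _undefined_estimate(counts.group, alpha)
    pi_hat = counts.pi_hat
    lo_pi, hi_pi = clopper_pearson_interval(counts.tau_within, counts.tau_out_total, alpha)
    return AssortativityEstimate(
        group=counts.group,
        pi_hat=pi_hat,
        gamma_hat=gamma_from_pi(pi_hat, f),
        delta_hat=delta_from_pi(pi_hat, f),
        ci_low=delta_from_pi(lo_pi, f),
        ci_high=delta_from_pi(hi_pi, f),
        alpha=alpha,
        n=counts.tau_out_total,
        tau_within=counts.tau_within,
    )


def expected_mixing_matrix(
    gammas: Sequence[float], fractions: Sequence[float]
) -> np.ndarray:
    """Column-stochastic mixing matrix implied by (gamma, f).

    Entry [b, a] is pi[b<-a], the expected proportion of the secondary
    cases of a group-a infector that land in group b. Column a has
    diagonal gamma_a f_a / D_a and off-diagonal f_b / D_a with
    D_a = (1 - f_a) + gamma_a f_a; an infinite gamma_a gives the unit
    column on a. Every column sums to 1 identically.
    """
    gam = np.asarray(gammas, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if gam.shape != f.shape or gam.ndim != 1:
        raise ValidationError(
            f"gammas and fractions must be 1-d and matching; got {gam.shape} vs {f.shape}"
        )
    if f.size < 2 or np.any(f <= 0) or np.any(f >= 1) or abs(f.sum() - 1.0) > 1e-9:
        raise ValidationError("fractions must be in (0,1) and sum to 1 over >=2 groups")
    if np.any(gam < 0):
        raise ValidationError("every gamma must be >= 0 or infinite")
    G = f.size
    P = np.empty((G, G))
    for a in range(G):
        if math.isinf(gam[a]):
            P[:, a] = 0.0
            P[a, a] = 1.0
            continue
        denom = (1.0 - f[a]) + gam[a] * f[a]
        P[:, a] = f / denom
        P[a, a] = gam[a] * f[a] / denom
    return P
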