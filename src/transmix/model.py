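"""Model/results interface for assortativity estimation.

`TransmissionAssortativity` bundles a transmission tree with the group
census; `fit()` returns `AssortativityResults` holding per-group delta
estimates with Clopper-Pearson-propagated confidence intervals and a
`summary()` table. `estimate_delta_over_trees` pools one group's estimate
across a set of plausible trees (e.g. posterior draws from an outbreak
reconstruction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .estimator import (
    AssortativityEstimate,
    TransmissionCounts,
    estimate_delta,
)
from .exceptions import UndefinedEstimateError, ValidationError
from .groups import GroupStructure
from .tree import TransmissionTree, count_transmissions

__all__ = [
    "TransmissionAssortativity",
    "AssortativityResults",
    "PooledEstimate",
    "estimate_delta_over_trees",
]

_RESULT_COLUMNS = [
    "group", "n_emitted", "tau_within", "pi_hat", "gamma_hat",
    "delta_hat", "ci_low", "ci_high", "alpha", "status",
]


class TransmissionAssortativity:
    """Group-transmission assortativity model for one transmission tree.

    Parameters
    ----------
    tree : TransmissionTree
        Who-infected-whom line list.
    groups : GroupStructure
        Census sizes of every group in the population (must cover every
        group appearing in the tree; groups with no cases are fine and
        simply yield undefined estimates).
    """

    def __init__(self, tree: TransmissionTree, groups: GroupStructure):
        unknown = set(tree.cases["group"]) - {str(l) for l in groups.labels}
        if unknown:
            raise ValidationError(
                f"line-list groups {sorted(unknown)} missing from the group table; "
                f"known groups: {list(groups.labels)}"
            )
        self.tree = tree
        self.groups = groups

    @classmethod
    def from_csv(cls, linelist_path, group_table_path) -> "TransmissionAssortativity":
        return cls(
            TransmissionTree.from_csv(linelist_path),
            GroupStructure.from_csv(group_table_path),
        )

    @classmethod
    def from_dataframe(
        cls, cases: pd.DataFrame, sizes: Mapping[object, int]
    ) -> "TransmissionAssortativity":
        return cls(TransmissionTree(cases), GroupStructure.from_mapping(sizes))

    def counts(self, group, window_end: Optional[int] = None) -> TransmissionCounts:
        """Windowed (tau_within, tau_total) for one group."""
        if str(group) not in set(self.tree.cases["group"]):
            # group exists in the census but has no cases: zero emissions
            self.groups.index_of(group if group in self.groups.labels else str(group))
            return TransmissionCounts(group=str(group), tau_within=0, tau_out_total=0)
        return count_transmissions(self.tree, group, window_end)

    def fit(
        self, alpha: float = 0.05, window_end: Optional[int] = None
    ) -> "AssortativityResults":
        """Estimate delta with CI for every group in the census."""
        estimates = []
        for label, f in zip(self.groups.labels, self.groups.fractions):
            est = estimate_delta(self.counts(label, window_end), float(f), alpha)
            estimates.append(est)
        return AssortativityResults(self, estimates, alpha=alpha, window_end=window_end)


class AssortativityResults:
    """Per-group delta estimates from a fitted assortativity model."""

    def __init__(
        self,
        model: TransmissionAssortativity,
        estimates: Sequence[AssortativityEstimate],
        alpha: float,
        window_end: Optional[int],
    ):
        self.model = model
        self.estimates = list(estimates)
        self.alpha = alpha
        self.window_end = window_end

    def __getitem__(self, group) -> AssortativityEstimate:
        for est in self.estimates:
            if str(est.group) == str(group):
                return est
        raise KeyError(group)

    @property
    def frame(self) -> pd.DataFrame:
        rows = [
            {
                "group": e.group,
                "n_emitted": e.n,
                "tau_within": e.tau_within,
                "pi_hat": e.pi_hat,
                "gamma_hat": e.gamma_hat,
                "delta_hat": e.delta_hat,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "alpha": e.alpha,
                "status": e.status,
            }
            for e in self.estimates
        ]
        return pd.DataFrame(rows, columns=_RESULT_COLUMNS)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def summary(self) -> str:
        """Human-readable estimation table."""
        df = self.frame
        lines = [
            "Transmission assortativity estimates "
            f"(alpha={self.alpha:g}, window_end="
            f"{'none' if self.window_end is None else self.window_end})",
            "-" * 72,
            f"{'group':>8} {'f':>7} {'tau_w/tau_tot':>14} {'delta':>8} "
            f"{'ci_low':>8} {'ci_high':>8}  status",
        ]
        for (_, r), f in zip(df.iterrows(), self.model.groups.fractions):
            if r["status"] == "ok":
                lines.append(
                    f"{r['group']:>8} {f:>7.3f} "
                    f"{str(r['tau_within']) + '/' + str(r['n_emitted']):>14} "
                    f"{r['delta_hat']:>8.3f} {r['ci_low']:>8.3f} {r['ci_high']:>8.3f}  ok"
                )
            else:
                lines.append(
                    f"{r['group']:>8} {f:>7.3f} {'0/0':>14} "
                    f"{'--':>8} {'--':>8} {'--':>8}  {r['status']}"
                )
        return "\n".join(lines)


@dataclass(frozen=True)
class PooledEstimate:
    """Estimate of one group's delta pooled across candidate trees."""

    group: object
    delta_hat: float
    spread_low: float
    spread_high: float
    alpha: float
    n_trees: int
    n_undefined: int
    per_tree: tuple

    @property
    def defined(self) -> bool:
        return self.n_trees - self.n_undefined > 0


def estimate_delta_over_trees(
    trees: Iterable[TransmissionTree],
    group,
    f: float,
    alpha: float = 0.05,
    window_end: Optional[int] = None,
    pool_counts: bool = False,
) -> PooledEstimate:
    """Pool one group's assortativity over several transmission trees.

    Intended for posterior tree sets from probabilistic outbreak
    reconstruction. Default pooling: mean of the per-tree delta point
    estimates, with the across-tree (alpha/2, 1-alpha/2) percentile
    interval as spread; trees where the group emitted nothing are skipped
    and counted. With ``pool_counts=True`` the tau counts are summed
    across trees before a single estimate (not the default: trees may
    disagree on who emits, so summed counts mix incompatible denominators).
    """
    trees = list(trees)
    if not trees:
        raise ValidationError("need at least one tree to pool over")
    deltas = []
    n_undefined = 0
    tot_within = tot_out = 0
    for tree in trees:
        if str(group) not in set(tree.cases["group"]):
            n_undefined += 1
            continue
        counts = count_transmissions(tree, group, window_end)
        if counts.tau_out_total == 0:
            n_undefined += 1
            continue
        tot_within += counts.tau_within
        tot_out += counts.tau_out_total
        deltas.append(estimate_delta(counts, f, alpha).delta_hat)
    if not deltas:
        raise UndefinedEstimateError(
            f"group {group!r} emitted no transmissions in any of the "
            f"{len(trees)} trees"
        )
    if pool_counts:
        pooled = estimate_delta(
            TransmissionCounts(str(group), tot_within, tot_out), f, alpha
        )
        point, lo, hi = pooled.delta_hat, pooled.ci_low, pooled.ci_high
    else:
        arr = np.asarray(deltas)
        point = float(arr.mean())
        lo, hi = (
            float(np.percentile(arr, 100.0 * alpha / 2.0)),
            float(np.percentile(arr, 100.0 * (1.0 - alpha / 2.0))),
        )
    return PooledEstimate(
        group=str(group), delta_hat=point, spread_low=lo, spread_high=hi,
        alpha=alpha, n_trees=len(trees), n_undefined=n_undefined,
        per_tree=tuple(deltas),
    )
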