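"""Group structure: census sizes and relative fractions.

The estimator compares observed within-group transmission against the
homogeneous-mixing expectation, which is set by each group's share
f_a = N_a / sum_g N_g of the total population. With a single group every
f would be 1 and assortativity is undefined, so at least two groups are
required.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = ["GroupStructure", "compute_group_fractions"]


def compute_group_fractions(sizes: Sequence[int] | np.ndarray) -> np.ndarray:
    """Relative group sizes f_a = N_a / sum(N).

    Parameters
    ----------
    sizes : sequence of int
        Census count per group, order preserved. At least two groups,
        every count >= 1 (so every fraction is strictly inside (0, 1)).

    Returns
    -------
    ndarray of float
        Fractions summing to 1, in input order.
    """
    arr = np.asarray(sizes)
    if arr.ndim != 1 or arr.size < 2:
        raise ValidationError(
            "group fractions need more than 1 group; "
            f"got {arr.size} (f must exclude the endpoints 0 and 1)"
        )
    if not np.issubdtype(arr.dtype, np.number) or np.any(arr != np.floor(arr)):
        raise ValidationError("group sizes must be integers")
    if np.any(arr < 1):
        raise ValidationError(f"every group size must be >= 1; got {arr.tolist()}")
    return arr / arr.sum()


@dataclass(frozen=True)
class GroupStructure:
    """Ordered group labels with census sizes and derived fractions."""

    labels: tuple
    sizes: np.ndarray = field(repr=False)
    fractions: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        labels = tuple(self.labels)
        sizes = np.asarray(self.sizes, dtype=np.int64)
        if len(labels) != sizes.size:
            raise ValidationError("labels and sizes must have the same length")
        if len(set(labels)) != len(labels):
            raise ValidationError("group labels must be unique")
        fractions = compute_group_fractions(sizes)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "sizes", sizes)
        object.__setattr__(self, "fractions", fractions)

    @classmethod
    def from_mapping(cls, sizes: Mapping[object, int]) -> "GroupStructure":
        return cls(tuple(sizes.keys()), np.fromiter(sizes.values(), dtype=np.int64))

    @classmethod
    def from_csv(cls, path) -> "GroupStructure":
        """Read a two-column ``group,size`` table."""
        df = pd.read_csv(path)
        missing = {"group", "size"} - set(df.columns)
        if missing:
            raise ValidationError(f"group table {path} is missing columns {sorted(missing)}")
        return cls(tuple(df["group"].astype(str)), df["size"].to_numpy())

    @property
    def n_groups(self) -> int:
        return len(self.labels)

    @property
    def total_size(self) -> int:
        return int(self.sizes.sum())

    def index_of(self, label) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValidationError(
                f"unknown group {label!r}; known groups: {list(self.labels)}"
            ) from None

    def fraction_of(self, label) -> float:
        return float(self.fractions[self.index_of(label)])

    def __iter__(self) -> Iterable:
        return iter(self.labels)
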