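"""Transmission trees (who-infected-whom line lists).

A tree is a case-level table: case id, group label, symptom-onset day,
optional infection day, and the infector's case id (empty for imported
cases, which start chains but are never anyone's infectee). Days are
integers, 0-based from outbreak start. This is the object the tau counts
of the assortativity estimator are read from.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .estimator import TransmissionCounts
from .exceptions import ValidationError

__all__ = ["TransmissionTree", "count_transmissions"]

_COLUMNS = ["case_id", "group", "onset_day", "infection_day", "infector_id"]


class TransmissionTree:
    """Line list of cases linked by infector ids.

    Parameters
    ----------
    cases : DataFrame
        Columns ``case_id, group, onset_day`` required;
        ``infection_day`` optional (nullable); ``infector_id`` empty/NA
        for imported cases. Ids and group labels are normalised to str.
    validate : bool
        Check structural invariants (unique ids, resolvable infectors,
        infector infected strictly before infectee, onset >= infection).
    """

    def __init__(self, cases: pd.DataFrame, validate: bool = True):
        df = cases.copy()
        missing = {"case_id", "group", "onset_day"} - set(df.columns)
        if missing:
            raise ValidationError(f"line list is missing columns {sorted(missing)}")
        df["case_id"] = df["case_id"].astype(str)
        df["group"] = df["group"].astype(str)
        df["onset_day"] = df["onset_day"].astype("int64")
        if "infection_day" not in df.columns:
            df["infection_day"] = pd.NA
        df["infection_day"] = df["infection_day"].astype("Int64")
        if "infector_id" not in df.columns:
            df["infector_id"] = pd.NA
        inf = df["infector_id"]
        inf = inf.mask(inf.astype(str).str.strip().eq(""), pd.NA)
        df["infector_id"] = inf.astype("string")
        df.loc[df["infector_id"].notna(), "infector_id"] = (
            df.loc[df["infector_id"].notna(), "infector_id"].astype(str)
        )
        self.cases = df[_COLUMNS].reset_index(drop=True)
        if validate:
            self._validate()

    def _validate(self):
        df = self.cases
        if df["case_id"].duplicated().any():
            dupes = df.loc[df["case_id"].duplicated(), "case_id"].tolist()
            raise ValidationError(f"duplicate case ids: {dupes[:5]}")
        known = set(df["case_id"])
        linked = df["infector_id"].dropna()
        unknown = set(linked) - known
        if unknown:
            raise ValidationError(f"infector ids not in line list: {sorted(unknown)[:5]}")
        if df["infection_day"].notna().all() and len(df):
            inf_day = df.set_index("case_id")["infection_day"]
            sub = df[df["infector_id"].notna()]
            src = inf_day.loc[sub["infector_id"]].to_numpy()
            if (src >= sub["infection_day"].to_numpy()).any():
                raise ValidationError(
                    "infector must be infected strictly before infectee"
                )
            if (df["onset_day"].to_numpy() < df["infection_day"].to_numpy()).any():
                raise ValidationError("onset_day must be >= infection_day")

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.cases)

    @property
    def groups_present(self) -> list:
        return sorted(self.cases["group"].unique())

    def onset_days(self, group: Optional[str] = None) -> pd.Series:
        df = self.cases
        if group is not None:
            df = df[df["group"] == str(group)]
        return df["onset_day"]

    def pairs(self) -> pd.DataFrame:
        """All infector->infectee pairs with groups and onset days.

        Columns: src_id, dst_id, src_group, dst_group, src_onset, dst_onset.
        Imported cases appear only on the src side.
        """
        df = self.cases
        idx = df.set_index("case_id")
        dst = df[df["infector_id"].notna()]
        src = idx.loc[dst["infector_id"]]
        return pd.DataFrame({
            "src_id": dst["infector_id"].to_numpy(),
            "dst_id": dst["case_id"].to_numpy(),
            "src_group": src["group"].to_numpy(),
            "dst_group": dst["group"].to_numpy(),
            "src_onset": src["onset_day"].to_numpy(),
            "dst_onset": dst["onset_day"].to_numpy(),
        })

    # -- IO --------------------------------------------------------------
    @classmethod
    def from_csv(cls, path, validate: bool = True) -> "TransmissionTree":
        df = pd.read_csv(
            path,
            dtype={"case_id": str, "group": str, "infector_id": "string"},
            keep_default_na=True,
        )
        if len(df) == 0 and df.columns.size == 0:
            raise ValidationError(f"{path}: empty file, expected a line-list header")
        return cls(df, validate=validate)

    def to_csv(self, path) -> None:
        self.cases.to_csv(path, index=False)


def count_transmissions(
    tree: TransmissionTree, group, window_end: Optional[int] = None
) -> TransmissionCounts:
    """Count transmissions emitted by one group, optionally time-windowed.

    A pair contributes only when BOTH the infector's and the infectee's
    symptom onsets fall on or before ``window_end`` (the emitting case
    must itself be observable within the analysis window); ``None`` means
    the whole outbreak. tau_within additionally requires the infectee to
    belong to the same group.
    """
    group = str(group)
    if group not in set(tree.cases["group"]):
        raise ValidationError(
            f"unknown group {group!r}; groups in tree: {tree.groups_present}"
        )
    pairs = tree.pairs()
    emitted = pairs[pairs["src_group"] == group]
    if window_end is not None:
        emitted = emitted[
            (emitted["src_onset"] <= window_end) & (emitted["dst_onset"] <= window_end)
        ]
    tau_total = int(len(emitted))
    tau_within = int((emitted["dst_group"] == group).sum())
    return TransmissionCounts(group=group, tau_within=tau_within, tau_out_total=tau_total)
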