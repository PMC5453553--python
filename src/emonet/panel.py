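"""Multi-subject emotion diary panels.

The central container is :class:`EmotionPanel`: a long-format table with one
row per (subject, beep) holding 7-point Likert item scores (raw data) or real
values (after preprocessing), plus the beep structure (day, beep-within-day,
global time index) and a group label per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The 14 emotion adjectives used throughout: 7 positive-affect items
#: followed by 7 negative-affect items.
PA_ITEMS = [
    "talkative",
    "enthusiastic",
    "confident",
    "cheerful",
    "energetic",
    "satisfied",
    "happy",
]
NA_ITEMS = [
    "tense",
    "anxious",
    "distracted",
    "restless",
    "irritated",
    "depressed",
    "guilty",
]
DEFAULT_ITEMS = PA_ITEMS + NA_ITEMS

#: Non-item columns of the long table, in canonical order.
META_COLS = ["subject_id", "group", "day", "beep", "time"]

MDD = "MDD"
CONTROL = "control"


@dataclass
class EmotionPanel:
    """Long-format multi-subject item x time panel.

    Parameters
    ----------
    data
        One row per (subject, time), columns ``subject_id, group, day, beep,
        time`` followed by one column per item.  ``time`` is the global beep
        index 1..T within each subject; missing item values are NaN.
    item_names
        Ordered item columns (length p).
    covariates
        Optional per-subject table indexed by ``subject_id`` (e.g. columns
        ``neuroticism``, ``bdi``, ``mean_na``) used by the density
        regressions.
    """

    data: pd.DataFrame
    item_names: list[str] = field(default_factory=lambda: list(DEFAULT_ITEMS))
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing_cols = [c for c in META_COLS + list(self.item_names) if c not in self.data.columns]
        if missing_cols:
            raise ValueError(f"panel data lacks columns: {missing_cols}")
        self.data = (
            self.data.sort_values(["subject_id", "time"], kind="mergesort").reset_index(drop=True)
        )
        groups_per_subject = self.data.groupby("subject_id", sort=False)["group"].nunique()
        if (groups_per_subject > 1).any():
            bad = groups_per_subject[groups_per_subject > 1].index.tolist()
            raise ValueError(f"subjects with more than one group label: {bad}")

    # ------------------------------------------------------------------ views
    @property
    def n_items(self) -> int:
        return len(self.item_names)

    @property
    def subjects(self) -> list:
        return list(self.data["subject_id"].unique())

    @property
    def group_of(self) -> pd.Series:
        """Group label per subject (index = subject_id)."""
        return self.data.groupby("subject_id", sort=False)["group"].first()

    def subjects_in(self, group: str) -> list:
        g = self.group_of
        return list(g.index[g == group])

    def wide(self, subject) -> np.ndarray:
        """(T, p) value array of one subject, NaN for missing."""
        sub = self.data[self.data["subject_id"] == subject]
        return sub[self.item_names].to_numpy(dtype=float)

    def wide_meta(self, subject) -> pd.DataFrame:
        sub = self.data[self.data["subject_id"] == subject]
        return sub[META_COLS].reset_index(drop=True)

    def to_arrays(self) -> tuple[list, np.ndarray, np.ndarray]:
        """Balanced (subjects, groups, X) view with X of shape (S, T, p).

        Requires every subject to share the same series length.
        """
        subjects = self.subjects
        lengths = self.data.groupby("subject_id", sort=False).size()
        if lengths.nunique() != 1:
            raise ValueError("panel is unbalanced; subjects have unequal T")
        T = int(lengths.iloc[0])
        X = self.data[self.item_names].to_numpy(dtype=float).reshape(len(subjects), T, self.n_items)
        groups = self.group_of.loc[subjects].to_numpy()
        return subjects, groups, X

    def with_values(self, X: np.ndarray) -> "EmotionPanel":
        """Return a copy with item values replaced by ``X`` of shape (S, T, p)."""
        df = self.data.copy()
        df[self.item_names] = X.reshape(-1, self.n_items)
        return EmotionPanel(df, list(self.item_names), self.covariates)

    def n_missing(self) -> int:
        return int(self.data[self.item_names].isna().to_numpy().sum())

    # ------------------------------------------------------------------- I/O
    def to_csv(self, path) -> None:
        """Write the long table (missing as empty fields)."""
        self.data[META_COLS + list(self.item_names)].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, covariates: pd.DataFrame | None = None) -> "EmotionPanel":
        df = pd.read_csv(path)
        items = [c for c in df.columns if c not in META_COLS]
        return cls(df, items, covariates)
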