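"""Addiction-like criterion scoring, attribution and classification.

Three behavioural scores are extracted per mouse from its event logs:

* **persistence** — mean non-reinforced active presses in the 10-min
  pellet-free period over the 3 FR5 sessions preceding the progressive-ratio
  test;
* **motivation** — breaking point of the progressive-ratio session (last
  completed response requirement);
* **compulsivity** — total footshocks taken in the 50-min punished session.

A mouse is positive for a criterion when its score is at or above the 75th
percentile of the control group's distribution of that score, and is
classified *addicted* when it meets 2 or 3 criteria.  Thresholds are always
computed on the control group alone, never on the pooled cohort.

:class:`CriteriaModel` / :class:`CriteriaResults` wrap the attribution step in
a fit/results pair: the model holds the score table and group labels, ``fit``
computes control thresholds, flags, criterion counts and labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import ProtocolDataset
from .schedules import (
    PR_SERIES,
    EventLog,
    breaking_point,
    count_active_presses,
    count_inactive_presses,
    count_pellet_free_active,
    count_reinforcers,
    count_shocks,
)

__all__ = [
    "CriterionScores",
    "MissingSessionError",
    "score_criteria",
    "score_dataset",
    "check_acquisition",
    "apply_exclusion",
    "percentile_threshold",
    "compute_thresholds",
    "attribute_and_classify",
    "CriteriaModel",
    "CriteriaResults",
]

CRITERIA = ("persistence", "motivation", "compulsivity")


@dataclass(frozen=True)
class CriterionScores:
    persistence: float
    motivation: int
    compulsivity: int

    def __post_init__(self) -> None:
        if self.persistence < 0 or self.motivation < 0 or self.compulsivity < 0:
            raise ValueError("criterion scores must be nonnegative")


class MissingSessionError(ValueError):
    """A required behavioural test is missing from the logs."""


def score_criteria(
    fr5_logs: Sequence[EventLog],
    pr_log: EventLog | None,
    shock_log: EventLog | None,
    series: Sequence[int] = PR_SERIES,
) -> CriterionScores:
    """Compute the three criterion scores for one mouse.

    ``fr5_logs`` must hold (at least) the 3 FR5 sessions preceding the PR
    test; the last three are used for persistence.
    """
    if len(fr5_logs) < 3:
        raise MissingSessionError(
            "persistence test requires 3 pre-PR FR5 sessions, "
            f"got {len(fr5_logs)}"
        )
    if pr_log is None:
        raise MissingSessionError("missing motivation test (progressive-ratio session)")
    if shock_log is None:
        raise MissingSessionError("missing compulsivity test (shock session)")
    pre_pr = fr5_logs[-3:]
    persistence = float(np.mean([count_pellet_free_active(lg) for lg in pre_pr]))
    motivation = breaking_point(pr_log, series)
    compulsivity = count_shocks(shock_log)
    return CriterionScores(persistence, motivation, compulsivity)


def score_dataset(dataset: ProtocolDataset) -> pd.DataFrame:
    """Score every mouse of a simulated cohort.

    Returns a DataFrame indexed by mouse id with the three criterion scores,
    the group label and the exclusion flag.
    """
    excluded = apply_exclusion(dataset)
    rows = {}
    for mouse_id in dataset.mouse_ids:
        fr5 = dataset.fr5_logs(mouse_id)
        pr = dataset.logs_of_kind(mouse_id, "pr")
        shock = dataset.logs_of_kind(mouse_id, "shock")
        scores = score_criteria(
            fr5, pr[0] if pr else None, shock[0] if shock else None
        )
        rows[mouse_id] = {
            "group": dataset.mice.loc[mouse_id, "group"],
            "persistence": scores.persistence,
            "motivation": scores.motivation,
            "compulsivity": scores.compulsivity,
            "excluded": mouse_id in excluded,
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("mouse_id")


def check_acquisition(
    reinforcers: Sequence[float] | Sequence[EventLog],
    active: Sequence[float] | None = None,
    inactive: Sequence[float] | None = None,
    *,
    stability: float = 0.20,
    min_active_fraction: float = 0.75,
    min_reinforcers: int = 5,
) -> bool:
    """Operant-responding acquisition check.

    True iff some 3 consecutive sessions simultaneously satisfy: (1) each
    session's reinforcer count deviates < ``stability`` (20 %) from the
    3-session mean; (2) at least 75 % of presses are on the active lever over
    those sessions; and (3) at least ``min_reinforcers`` reinforcers in every
    one of the three sessions.

    Accepts either per-session event logs or raw per-session arrays of
    reinforcer / active-press / inactive-press counts.
    """
    if len(reinforcers) and isinstance(reinforcers[0], EventLog):
        logs: Sequence[EventLog] = reinforcers  # type: ignore[assignment]
        reinforcers = [count_reinforcers(lg) for lg in logs]
        active = [count_active_presses(lg) for lg in logs]
        inactive = [count_inactive_presses(lg) for lg in logs]
    r = np.asarray(reinforcers, dtype=float)
    if r.size < 3:
        raise ValueError("acquisition check needs at least 3 sessions")
    a = np.asarray(active, dtype=float) if active is not None else None
    i = np.asarray(inactive, dtype=float) if inactive is not None else None
    for k in range(r.size - 2):
        window = r[k : k + 3]
        mean = window.mean()
        if window.min() < min_reinforcers:
            continue
        if mean <= 0 or np.any(np.abs(window - mean) / mean >= stability):
            continue
        if a is not None and i is not None:
            tot = a[k : k + 3].sum() + i[k : k + 3].sum()
            if tot > 0 and a[k : k + 3].sum() / tot < min_active_fraction:
                continue
        return True
    return False


def apply_exclusion(
    dataset: ProtocolDataset,
    *,
    min_responding_fraction: float = 0.25,
) -> set[str]:
    """Mice to exclude from criterion attribution.

    A mouse is excluded iff it earned at least one reinforcer in fewer than
    25 % of its FR5 sessions *and* never met the acquisition criteria
    (conjunction; "responded" is read as >= 1 reinforcer in a session).
    Returns the set of excluded mouse ids.
    """
    excluded: set[str] = set()
    for mouse_id in dataset.mouse_ids:
        fr5 = dataset.fr5_logs(mouse_id)
        if not fr5:
            continue
        responded = np.mean([count_reinforcers(lg) >= 1 for lg in fr5])
        if responded >= min_responding_fraction:
            continue
        if len(fr5) >= 3 and check_acquisition(fr5):
            continue
        excluded.add(mouse_id)
    return excluded


def percentile_threshold(values: Iterable[float], q: float = 75.0) -> float:
    """q-th percentile with the linear-interpolation (inclusive) convention."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot compute a percentile of an empty control group")
    return float(np.percentile(arr, q, method="linear"))


def compute_thresholds(
    control_scores: pd.DataFrame, q: float = 75.0
) -> pd.Series:
    """Per-criterion control 75th percentiles (control group only)."""
    if control_scores.empty:
        raise ValueError("control group is empty after exclusion")
    return pd.Series(
        {c: percentile_threshold(control_scores[c], q) for c in CRITERIA},
        name="threshold",
    )


def attribute_and_classify(
    scores: pd.DataFrame,
    thresholds: pd.Series,
    *,
    strict: bool = False,
) -> pd.DataFrame:
    """Flag each criterion against its threshold and classify mice.

    A criterion is met when score >= threshold ("equal or beyond"); with
    ``strict=True`` the comparison is strictly greater.  A mouse is addicted
    iff it meets at least 2 of the 3 criteria.
    """
    out = scores[list(CRITERIA)].copy()
    for c in CRITERIA:
        t = thresholds[c]
        out[f"{c}_flag"] = (out[c] > t) if strict else (out[c] >= t)
    flags = out[[f"{c}_flag" for c in CRITERIA]]
    out["n_criteria"] = flags.sum(axis=1).astype(int)
    out["label"] = np.where(out["n_criteria"] >= 2, "addicted", "non_addicted")
    return out


class CriteriaModel:
    """Percentile-threshold addiction classification of a scored cohort.

    Parameters
    ----------
    scores : DataFrame
        Per-mouse criterion scores (columns persistence, motivation,
        compulsivity), indexed by mouse id.
    groups : Series
        Group label per mouse, aligned with ``scores``.
    control : str
        Label of the control group whose 75th percentiles define the
        thresholds.
    excluded : Series of bool, optional
        Pre-computed exclusion flags; excluded mice take no part in threshold
        estimation and receive no label.
    strict : bool
        Use a strictly-greater comparison instead of >=.
    """

    def __init__(
        self,
        scores: pd.DataFrame,
        groups: pd.Series,
        control: str = "control",
        excluded: pd.Series | None = None,
        strict: bool = False,
        percentile: float = 75.0,
    ) -> None:
        missing = [c for c in CRITERIA if c not in scores.columns]
        if missing:
            raise ValueError(f"scores is missing criterion columns {missing}")
        self.scores = scores[list(CRITERIA)].copy()
        self.groups = groups.reindex(scores.index)
        if self.groups.isna().any():
            raise ValueError("groups must cover every scored mouse")
        if control not in set(self.groups):
            raise ValueError(f"control group {control!r} not present")
        self.control = control
        self.excluded = (
            excluded.reindex(scores.index).fillna(False).astype(bool)
            if excluded is not None
            else pd.Series(False, index=scores.index)
        )
        self.strict = strict
        self.percentile = percentile

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        group_col: str = "group",
        control: str = "control",
        excluded_col: str | None = "excluded",
        **kwargs,
    ) -> "CriteriaModel":
        excluded = (
            df[excluded_col]
            if excluded_col is not None and excluded_col in df.columns
            else None
        )
        return cls(df, df[group_col], control=control, excluded=excluded, **kwargs)

    @classmethod
    def from_dataset(cls, dataset: ProtocolDataset, control: str = "control",
                     **kwargs) -> "CriteriaModel":
        return cls.from_dataframe(score_dataset(dataset), control=control, **kwargs)

    def fit(self) -> "CriteriaResults":
        keep = ~self.excluded
        control_mask = keep & (self.groups == self.control)
        if not control_mask.any():
            raise ValueError("control group is empty after exclusion")
        thresholds = compute_thresholds(
            self.scores.loc[control_mask], self.percentile
        )
        table = attribute_and_classify(
            self.scores.loc[keep], thresholds, strict=self.strict
        )
        table.insert(0, "group", self.groups.loc[keep])
        return CriteriaResults(self, thresholds, table)


class CriteriaResults:
    """Fitted attribution: thresholds, per-mouse flags and labels."""

    def __init__(self, model: CriteriaModel, thresholds: pd.Series,
                 table: pd.DataFrame) -> None:
        self.model = model
        self.thresholds = thresholds
        self.table = table

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]

    @property
    def n_criteria(self) -> pd.Series:
        return self.table["n_criteria"]

    def addicted_fraction(self, group: str | None = None) -> float:
        t = self.table if group is None else self.table[self.table["group"] == group]
        if len(t) == 0:
            raise ValueError(f"no classified mice in group {group!r}")
        return float((t["label"] == "addicted").mean())

    def group_summary(self) -> pd.DataFrame:
        """Per-group counts and addicted percentage."""
        rows = []
        for g, t in self.table.groupby("group", sort=False):
            n_add = int((t["label"] == "addicted").sum())
            rows.append(
                {
                    "group": g,
                    "n": len(t),
                    "n_excluded": int(
                        (self.model.excluded & (self.model.groups == g)).sum()
                    ),
                    "n_addicted": n_add,
                    "addicted_pct": 100.0 * n_add / len(t),
                }
            )
        return pd.DataFrame(rows).set_index("group")

    def to_frame(self) -> pd.DataFrame:
        """Per-mouse report: scores, thresholds, flags, counts and label."""
        out = self.table.copy()
        for c in CRITERIA:
            out[f"{c}_threshold"] = self.thresholds[c]
        out["excluded"] = False
        dropped = self.model.scores.index.difference(out.index)
        if len(dropped):
            extra = self.model.scores.loc[dropped].copy()
            extra.insert(0, "group", self.model.groups.loc[dropped])
            extra["excluded"] = True
            out = pd.concat([out, extra])
        return out.loc[self.model.scores.index]

    def summary(self) -> str:
        lines = ["Addiction-like criterion attribution", "=" * 44]
        lines.append(f"control group: {self.model.control}  "
                     f"(comparison: score {'>' if self.model.strict else '>='} "
                     f"{self.model.percentile:g}th percentile)")
        lines.append("thresholds:")
        for c in CRITERIA:
            lines.append(f"  {c:<13s} {self.thresholds[c]:10.3f}")
        lines.append("")
        gs = self.group_summary()
        lines.append(f"{'group':<14s}{'n':>5s}{'excl':>6s}{'addicted':>10s}{'pct':>8s}")
        for g, row in gs.iterrows():
            lines.append(
                f"{g:<14s}{row['n']:>5.0f}{row['n_excluded']:>6.0f}"
                f"{row['n_addicted']:>10.0f}{row['addicted_pct']:>7.1f}%"
            )
        return "\n".join(lines)
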