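"""Weekly productivity labeling and participant grouping.

Daily self-reports on the 0-4 scale are averaged within each survey week
(weekdays and weekends alike); a weekly mean >= 2 marks a high-productivity
week, and a participant with at least 2 high weeks out of the 3 survey weeks
belongs to the high-productivity group.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "WeekLabel",
    "ParticipantGroup",
    "weekly_mean_scores",
    "label_week",
    "assign_participant_group",
    "label_table",
    "group_table",
]

DEFAULT_THRESHOLD = 2.0
HIGH, LOW = "high", "low"


@dataclass(frozen=True)
class WeekLabel:
    participant_id: str
    week: int
    mean_score: float
    n_days: int
    label: str


@dataclass(frozen=True)
class ParticipantGroup:
    participant_id: str
    n_high_weeks: int
    group: str


def weekly_mean_scores(records: pd.DataFrame, week: int) -> pd.DataFrame:
    """Per-participant mean daily score for one week.

    ``records`` has columns participant_id, day, week, score.  Participants
    with no records in the week are simply absent from the output (their
    omission is visible by comparing index sets).
    """
    sub = records[records["week"] == week]
    if sub.empty:
        return pd.DataFrame(columns=["participant_id", "week", "mean_score", "n_days"])
    agg = (
        sub.groupby("participant_id")["score"]
        .agg(mean_score="mean", n_days="size")
        .reset_index()
    )
    agg.insert(1, "week", week)
    return agg


def label_week(mean_score: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """high iff the weekly mean score is >= threshold (boundary inclusive)."""
    if not 0 <= mean_score <= 4:
        raise ValueError(f"mean_score must lie in [0, 4], got {mean_score}")
    return HIGH if mean_score >= threshold else LOW


def assign_participant_group(labels: dict[int, str]) -> str:
    """high group iff at least 2 of the survey weeks are labeled high.

    ``labels`` maps survey week -> 'high'/'low'; every surveyed week must be
    present (participants with incomplete labels are excluded upstream).
    """
    if not labels:
        raise ValueError("no week labels provided")
    bad = [v for v in labels.values() if v not in (HIGH, LOW)]
    if bad:
        raise ValueError(f"unknown labels: {bad}")
    n_high = sum(1 for v in labels.values() if v == HIGH)
    return HIGH if n_high >= 2 else LOW


def label_table(
    records: pd.DataFrame,
    survey_weeks=(1, 6, 15),
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Weekly mean + label for every participant x survey week with data."""
    frames = [weekly_mean_scores(records, w) for w in survey_weeks]
    table = pd.concat(frames, ignore_index=True)
    if table.empty:
        return table.assign(label=pd.Series(dtype=str))
    table["label"] = table["mean_score"].map(lambda m: label_week(m, threshold))
    return table


def group_table(labels: pd.DataFrame, survey_weeks=(1, 6, 15)) -> pd.DataFrame:
    """Participant-level groups from the week-label table.

    Participants lacking a label for any survey week are dropped (incomplete
    survey response); columns: participant_id, n_high_weeks, group.
    """
    rows = []
    needed = set(survey_weeks)
    for pid, sub in labels.groupby("participant_id"):
        have = dict(zip(sub["week"], sub["label"]))
        if not needed <= set(have):
            continue
        chosen = {w: have[w] for w in needed}
        n_high = sum(1 for v in chosen.values() if v == HIGH)
        rows.append(
            {
                "participant_id": pid,
                "n_high_weeks": n_high,
                "group": assign_participant_group(chosen),
            }
        )
    return pd.DataFrame(rows, columns=["participant_id", "n_high_weeks", "group"])
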