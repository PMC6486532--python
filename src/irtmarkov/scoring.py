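"""Total scores and the symptom-defined exacerbation engine.

The daily raw total is the sum of all item scores of a fully completed day
(maximum 51 for the standard catalogue: 9 items to 4 plus 5 items to 3) and
is rescaled to 0-100.  The instrument's proprietary Rasch-based scoring
table is not public, so the default transform is linear; a custom lookup
table can be plugged in and is honoured bit-exactly on its domain.

A symptom-defined exacerbation is a sustained rise of the scaled total over
a rolling baseline: at least 12 points on each of 2 consecutive diary days,
or at least 9 points on each of 3 consecutive diary days ("consecutive"
means calendar-adjacent days that both have data).  The baseline is reset
every 4 weeks: the first 28-day block uses the mean total of study week 1,
later blocks use the mean total over the last 7 days of the previous block,
unless fewer than 4 of those days have data, in which case the previous
baseline carries forward.  A zero baseline can never produce an event.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import ItemSpec
from .simulate import DiaryDataset

__all__ = [
    "DailyTotalScore",
    "ExacerbationEvent",
    "total_scores",
    "rolling_baselines",
    "detect_exacerbations",
    "detect_all",
    "cumulative_event_curve",
]

BLOCK_DAYS = 28
WEEK_DAYS = 7
MIN_RESET_DAYS = 4
TWO_DAY_RISE = 12.0
THREE_DAY_RISE = 9.0


@dataclass(frozen=True)
class DailyTotalScore:
    subject_id: int
    day: int
    raw_total: int
    scaled_total: float


@dataclass(frozen=True)
class ExacerbationEvent:
    """One detected event; ``onset_day`` is the day the qualifying run of
    threshold exceedances completes."""

    subject_id: int
    onset_day: int
    rule: str                 # "two_day_12" or "three_day_9"
    baseline_in_force: float


def _max_raw(items: Sequence[ItemSpec]) -> int:
    return int(sum(it.max_score for it in items))


def total_scores(
    dataset: DiaryDataset,
    transform: str = "linear_0_100",
    table: Mapping[int, float] | None = None,
) -> pd.DataFrame:
    """Per subject-day raw and 0-100 scaled totals.

    ``transform="linear_0_100"`` scales by 100/max_raw; ``"custom_table"``
    looks raw totals up in ``table`` (which must cover every raw total that
    occurs).
    """
    raw = (
        dataset.records.groupby(["subject_id", "day"], sort=True)["score"]
        .sum()
        .reset_index()
        .rename(columns={"score": "raw_total"})
    )
    if transform == "linear_0_100":
        raw["scaled_total"] = 100.0 * raw["raw_total"] / _max_raw(dataset.items)
    elif transform == "custom_table":
        if table is None:
            raise ValueError("custom_table transform needs a lookup table")
        missing = set(raw["raw_total"].unique()) - set(table)
        if missing:
            raise ValueError(f"lookup table missing raw totals {sorted(missing)}")
        raw["scaled_total"] = raw["raw_total"].map(table).astype(float)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    return raw


def rolling_baselines(scores: pd.DataFrame) -> pd.DataFrame:
    """4-weekly baselines for one subject's ``(day, scaled_total)`` series.

    Block ``b`` spans days ``28(b-1)+1 .. 28b``.  The block-1 baseline is the
    mean scaled total over the days of week 1 with data; the block-``b``
    baseline (b > 1) is the mean over the last 7 days of block ``b-1`` if at
    least 4 of them have data, otherwise the previous baseline carries
    forward.  Raises if the subject has no data in week 1.
    """
    days = scores["day"].to_numpy()
    vals = scores["scaled_total"].to_numpy(dtype=float)
    if len(days) == 0:
        raise ValueError("no scores for subject")
    order = np.argsort(days)
    days, vals = days[order], vals[order]
    wk1 = (days >= 1) & (days <= WEEK_DAYS)
    if not wk1.any():
        raise ValueError("no completed day in study week 1; subject excluded")
    n_blocks = int(np.ceil(days.max() / BLOCK_DAYS))
    baselines = np.empty(n_blocks)
    baselines[0] = vals[wk1].mean()
    for b in range(2, n_blocks + 1):
        end = BLOCK_DAYS * (b - 1)
        win = (days >= end - WEEK_DAYS + 1) & (days <= end)
        if win.sum() >= MIN_RESET_DAYS:
            baselines[b - 1] = vals[win].mean()
        else:
            baselines[b - 1] = baselines[b - 2]
    return pd.DataFrame({"block": np.arange(1, n_blocks + 1), "baseline": baselines})


def detect_exacerbations(
    scores: pd.DataFrame, baselines: pd.DataFrame
) -> list[ExacerbationEvent]:
    """Symptom-defined exacerbation events for one subject.

    ``scores`` has columns ``(subject_id?, day, scaled_total)``; detection
    continues after an event (events may recur on later, non-overlapping
    qualifying runs' completion days).
    """
    sid = int(scores["subject_id"].iloc[0]) if "subject_id" in scores else 0
    days = scores["day"].to_numpy()
    vals = scores["scaled_total"].to_numpy(dtype=float)
    order = np.argsort(days)
    days, vals = days[order], vals[order]
    base_by_block = dict(zip(baselines["block"], baselines["baseline"]))
    blocks = (days - 1) // BLOCK_DAYS + 1
    base = np.array([base_by_block.get(int(b), np.nan) for b in blocks])
    rise = vals - base
    # a day contributes to a run only with data, a positive baseline in force
    ok2 = (base > 0) & (rise >= TWO_DAY_RISE)
    ok3 = (base > 0) & (rise >= THREE_DAY_RISE)
    day_set = {}
    for i, d in enumerate(days):
        day_set[int(d)] = i
    events: list[ExacerbationEvent] = []
    for i, d in enumerate(days):
        d = int(d)
        j = day_set.get(d - 1)
        if j is not None and ok2[i] and ok2[j]:
            events.append(ExacerbationEvent(sid, d, "two_day_12", float(base[i])))
            continue
        k = day_set.get(d - 2)
        if j is not None and k is not None and ok3[i] and ok3[j] and ok3[k]:
            events.append(ExacerbationEvent(sid, d, "three_day_9", float(base[i])))
    return events


def detect_all(
    dataset: DiaryDataset | pd.DataFrame,
    transform: str = "linear_0_100",
    table: Mapping[int, float] | None = None,
) -> pd.DataFrame:
    """Events for every subject of a dataset (or a precomputed totals frame).

    Subjects with no completed day in week 1 are skipped.  Returns a frame
    with columns ``subject_id, onset_day, rule, baseline``.
    """
    if isinstance(dataset, DiaryDataset):
        totals = total_scores(dataset, transform=transform, table=table)
    else:
        totals = dataset
    rows = []
    for sid, grp in totals.groupby("subject_id"):
        try:
            bl = rolling_baselines(grp)
        except ValueError:
            continue
        for ev in detect_exacerbations(grp, bl):
            rows.append((sid, ev.onset_day, ev.rule, ev.baseline_in_force))
    return pd.DataFrame(rows, columns=["subject_id", "onset_day", "rule", "baseline"])


def cumulative_event_curve(
    events: pd.DataFrame, n_subjects: int, max_day: int
) -> pd.DataFrame:
    """Cumulative proportion of subjects with at least one event by each day.

    Only the first event per subject counts; the curve is a monotone
    non-decreasing step function on days ``1..max_day`` with values in
    [0, 1] (denominator: all ``n_subjects``).
    """
    if n_subjects < 1:
        raise ValueError("empty dataset")
    days = np.arange(1, max_day + 1)
    if len(events):
        firsts = events.groupby("subject_id")["onset_day"].min().to_numpy()
        counts = np.cumsum(np.bincount(firsts, minlength=max_day + 1)[1:])
        counts = counts[:max_day]
    else:
        counts = np.zeros(max_day, dtype=int)
    return pd.DataFrame({"day": days, "proportion": counts / n_subjects})
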