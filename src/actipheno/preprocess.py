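"""Minute-level counts -> standardized 24-point day curves.

The clustering unit is a per-day 24-value z-scored curve: minute counts are
summed into hourly counts, then each day is standardized to mean 0 / SD 1
(population denominator) so that only the temporal shape, not the amount, of
activity enters the pattern clustering.  Only participants contributing seven
complete days are retained; no imputation is performed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DegenerateDayError, MalformedInputError

MINUTES_PER_DAY = 1440
HOURS_PER_DAY = 24
DAYS_PER_WEEK = 7

HOUR_COLUMNS = [f"h{h:02d}" for h in range(HOURS_PER_DAY)]


def minutes_to_hours(minutes: np.ndarray) -> np.ndarray:
    """Sum 1440 minute counts into 24 hourly counts (total preserved)."""
    m = np.asarray(minutes)
    if m.shape != (MINUTES_PER_DAY,):
        raise MalformedInputError(f"expected {MINUTES_PER_DAY} minute values, got shape {m.shape}")
    if not np.all(np.isfinite(m.astype(float))):
        raise MalformedInputError("minute counts must be finite")
    return m.reshape(HOURS_PER_DAY, 60).sum(axis=1)


def standardize_day(hourly: np.ndarray) -> np.ndarray:
    """z-score the 24 hourly values with the population SD (denominator 24)."""
    h = np.asarray(hourly, dtype=float)
    if h.shape != (HOURS_PER_DAY,):
        raise MalformedInputError(f"expected {HOURS_PER_DAY} hourly values, got shape {h.shape}")
    sd = h.std()  # population denominator
    if sd == 0.0:
        raise DegenerateDayError("constant day has no z-score")
    return (h - h.mean()) / sd


def filter_complete_weeks(activity: pd.DataFrame) -> tuple[pd.DataFrame, list[str], int]:
    """Keep participants with exactly 7 distinct complete (1440-minute) days.

    Returns the retained long-format rows, the sorted retained participant
    ids, and the retained day count (always 7 x participants).
    """
    if activity.empty:
        return activity.copy(), [], 0
    ok = activity.dropna(subset=["count"])
    per_day = ok.groupby(["participant_id", "day_index"], sort=True)["minute_of_day"].nunique()
    complete_days = per_day[per_day == MINUTES_PER_DAY]
    days_per_participant = complete_days.groupby("participant_id").size()
    retained = sorted(days_per_participant[days_per_participant == DAYS_PER_WEEK].index)
    kept = ok[ok["participant_id"].isin(retained)].copy()
    return kept, list(retained), DAYS_PER_WEEK * len(retained)


def hourly_table(activity: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a long minute table into one row per participant-day with h00..h23."""
    df = activity.copy()
    df["hour"] = df["minute_of_day"] // 60
    wide = (
        df.groupby(["participant_id", "day_index", "hour"])["count"]
        .sum()
        .unstack("hour")
        .sort_index()
    )
    wide.columns = [f"h{int(h):02d}" for h in wide.columns]
    return wide.reset_index()


def standardize_cohort(hourly: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """z-score every day; degenerate days disqualify their whole participant.

    A zero-variance day cannot enter the shape clustering, so its owner is
    treated like an incomplete week and dropped.  Returns the standardized
    table (participant_id, day_index, h00..h23) and a filter report.
    """
    values = hourly[HOUR_COLUMNS].to_numpy(dtype=float)
    sds = values.std(axis=1)
    bad_participants = set(hourly.loc[sds == 0.0, "participant_id"])
    keep = ~hourly["participant_id"].isin(bad_participants)
    kept = hourly[keep].reset_index(drop=True)
    v = kept[HOUR_COLUMNS].to_numpy(dtype=float)
    z = (v - v.mean(axis=1, keepdims=True)) / v.std(axis=1, keepdims=True)
    out = kept[["participant_id", "day_index"]].copy()
    out[HOUR_COLUMNS] = z
    report = {
        "input_days": int(len(hourly)),
        "degenerate_days": int((sds == 0.0).sum()),
        "excluded_participants": sorted(bad_participants),
        "retained_days": int(len(out)),
    }
    return out, report


def preprocess(activity: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Full stage: completeness filter -> hourly aggregation -> standardization."""
    kept, retained_ids, n_days = filter_complete_weeks(activity)
    input_participants = int(activity["participant_id"].nunique()) if len(activity) else 0
    if not retained_ids:
        empty = pd.DataFrame(columns=["participant_id", "day_index", *HOUR_COLUMNS])
        return empty, {
            "input_participants": input_participants,
            "complete_week_participants": 0,
            "complete_days": 0,
            "standardized_days": 0,
            "degenerate_days": 0,
        }
    hourly = hourly_table(kept)
    std, std_report = standardize_cohort(hourly)
    # a degenerate day invalidates the participant's whole week
    report = {
        "input_participants": input_participants,
        "complete_week_participants": len(retained_ids),
        "complete_days": n_days,
        "degenerate_days": std_report["degenerate_days"],
        "retained_participants": len(retained_ids) - len(std_report["excluded_participants"]),
        "standardized_days": int(len(std)),
    }
    return std, report
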