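"""Phone-usage phenotypes from screen lock/unlock event logs.

A usage episode runs from an unlock to the following lock. Daily features:
total/daytime/nighttime usage minutes (day-night split at 07:00/23:00, the
same boundaries as the sleep features), total lock duration (the rest of
the 1440-minute day), and the number of unlock events.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import pandas as pd

from .errors import ValidationError
from .sleep import segment_day_night

Episode = Tuple[pd.Timestamp, pd.Timestamp]

MINUTES_PER_DAY = 1440.0


def validate_alternating(events: pd.DataFrame) -> pd.DataFrame:
    """Sort by time and check strict unlock/lock alternation."""
    ev = events.sort_values("timestamp").reset_index(drop=True)
    ts = ev["timestamp"]
    if ts.duplicated().any():
        raise ValidationError(
            f"duplicate screen-event timestamp at {ts[ts.duplicated()].iloc[0]}"
        )
    kinds = ev["kind"]
    bad = kinds[kinds.shift() == kinds]
    if len(bad):
        raise ValidationError(
            f"two consecutive {bad.iloc[0]!r} events at {ts[bad.index[0]]}"
        )
    unknown = set(kinds.unique()) - {"unlock", "lock"}
    if unknown:
        raise ValidationError(f"unknown event kinds: {sorted(unknown)}")
    return ev


def build_sessions(
    events: pd.DataFrame,
    day_start: Optional[pd.Timestamp] = None,
    day_end: Optional[pd.Timestamp] = None,
) -> List[Episode]:
    """Usage episodes (unlock -> lock pairs), disjoint and ordered.

    A stream that starts with a lock is treated as an episode already open
    at ``day_start``; one that ends with an unlock is closed at
    ``day_end`` (both default to the first/last event time, making the
    boundary episodes empty).
    """
    if len(events) == 0:
        return []
    ev = validate_alternating(events)
    ts = [pd.Timestamp(t) for t in ev["timestamp"]]
    kinds = ev["kind"].tolist()
    episodes: List[Episode] = []
    if kinds[0] == "lock":
        start = pd.Timestamp(day_start) if day_start is not None else ts[0]
        if ts[0] > start:
            episodes.append((start, ts[0]))
        ts, kinds = ts[1:], kinds[1:]
    for i in range(0, len(ts) - 1, 2):
        episodes.append((ts[i], ts[i + 1]))
    if kinds and kinds[-1] == "unlock":
        end = pd.Timestamp(day_end) if day_end is not None else ts[-1]
        if end > ts[-1]:
            episodes.append((ts[-1], end))
    return episodes


@dataclass
class PhoneFeatures:
    total_usage_min: float
    daytime_usage_min: float
    nighttime_usage_min: float
    lock_duration_min: float
    unlock_count: int


def compute_phone_features(events: pd.DataFrame, date) -> PhoneFeatures:
    """Daily phone-usage features from events clipped to ``date``.

    ``events`` must lie within [date 00:00, date 24:00); an episode open
    at either boundary is closed there, so usage + lock time always equals
    1440 minutes for a fully observed day.
    """
    d0 = pd.Timestamp(date).normalize()
    d1 = d0 + pd.Timedelta(days=1)
    if len(events):
        t = pd.to_datetime(events["timestamp"])
        if (t < d0).any() or (t >= d1).any():
            raise ValidationError("events must be clipped to the requested date")
    episodes = build_sessions(events, day_start=d0, day_end=d1)
    day = night = 0.0
    for s, e in episodes:
        dd, nn = segment_day_night(s, e)
        day += dd
        night += nn
    total = day + night
    unlocks = int((events["kind"] == "unlock").sum()) if len(events) else 0
    return PhoneFeatures(
        total_usage_min=total,
        daytime_usage_min=day,
        nighttime_usage_min=night,
        lock_duration_min=MINUTES_PER_DAY - total,
        unlock_count=unlocks,
    )
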