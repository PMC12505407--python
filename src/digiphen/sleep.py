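"""Sleep phenotypes: total, daytime, and nighttime sleep per calendar day.

Daytime is the half-open window [07:00, 23:00) and nighttime its
complement [23:00, 07:00), so every sleep minute is counted exactly once.
Sleep intervals spanning midnight are clipped to each calendar date before
summation. When no sleep records exist, a screen-gap heuristic can infer
sleep from phone lock/unlock logs.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Tuple

import pandas as pd

from .errors import ValidationError

DAY_START_H = 7  # 07:00 local
DAY_END_H = 23  # 23:00 local

Interval = Tuple[pd.Timestamp, pd.Timestamp]


def _as_interval(start, end, *, max_hours: float | None = 24.0) -> Interval:
    s, e = pd.Timestamp(start), pd.Timestamp(end)
    if e <= s:
        raise ValidationError(f"sleep interval must have end > start ({s} .. {e})")
    if max_hours is not None and e - s > pd.Timedelta(hours=max_hours):
        raise ValidationError(f"sleep interval longer than {max_hours} h")
    return s, e


def merge_intervals(intervals: Iterable[Tuple]) -> List[Interval]:
    """Union of possibly-overlapping intervals; idempotent.

    The 24-hour single-record bound is not enforced here: a union of
    overlapping records may legitimately exceed it.
    """
    ivs = sorted(_as_interval(s, e, max_hours=None) for s, e in intervals)
    merged: List[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


_NS_PER_MIN = 60_000_000_000
_NS_PER_DAY = 1440 * _NS_PER_MIN
_NS_DAY_START = DAY_START_H * 60 * _NS_PER_MIN
_NS_DAY_END = DAY_END_H * 60 * _NS_PER_MIN


def segment_day_night(start, end) -> Tuple[float, float]:
    """Minutes of an interval falling in [07:00, 23:00) vs the rest.

    The two parts always sum exactly to the interval duration.
    """
    s, e = _as_interval(start, end)
    sv, ev = s.value, e.value  # ns since epoch; naive local time
    day_ns = 0
    d = (sv // _NS_PER_DAY) * _NS_PER_DAY
    while d < ev:
        lo = max(sv, d + _NS_DAY_START)
        hi = min(ev, d + _NS_DAY_END)
        if hi > lo:
            day_ns += hi - lo
        d += _NS_PER_DAY
    day_min = day_ns / _NS_PER_MIN
    total = (ev - sv) / _NS_PER_MIN
    return day_min, total - day_min


def clip_to_date(intervals: Iterable[Tuple], date) -> List[Interval]:
    """Portions of intervals that fall on calendar ``date`` ([00:00, 24:00))."""
    d0 = pd.Timestamp(date).normalize()
    d1 = d0 + pd.Timedelta(days=1)
    out: List[Interval] = []
    for s, e in intervals:
        s, e = _as_interval(s, e, max_hours=None)
        lo, hi = max(s, d0), min(e, d1)
        if hi > lo:
            out.append((lo, hi))
    return out


@dataclass
class SleepFeatures:
    total_min: float
    daytime_min: float
    nighttime_min: float


def compute_sleep_features(intervals: Iterable[Tuple], date) -> SleepFeatures:
    """Daily sleep totals for one calendar date.

    Overlapping records are merged first; records are clipped to the date
    so a night spanning midnight is split across the two days it touches.
    """
    clipped = clip_to_date(merge_intervals(intervals), date)
    day = night = 0.0
    for s, e in clipped:
        d, n = segment_day_night(s, e)
        day += d
        night += n
    return SleepFeatures(total_min=day + night, daytime_min=day, nighttime_min=night)


def _gap_overlaps_night(s: pd.Timestamp, e: pd.Timestamp) -> bool:
    """Does [s, e) intersect any nightly [21:00, 11:00 next day) window?"""
    for d in pd.date_range(s.normalize() - pd.Timedelta(days=1), e.normalize(), freq="D"):
        w0 = d + pd.Timedelta(hours=21)
        w1 = d + pd.Timedelta(hours=35)  # 11:00 next day
        if min(e, w1) > max(s, w0):
            return True
    return False


def _gap_is_nap(s: pd.Timestamp, e: pd.Timestamp) -> bool:
    """Entirely inside the same day's [12:00, 18:00) window?"""
    d = s.normalize()
    return (
        e.normalize() == d
        and s >= d + pd.Timedelta(hours=12)
        and e <= d + pd.Timedelta(hours=18)
    )


def infer_sleep_from_screen(events: pd.DataFrame, min_gap_min: float = 60.0) -> List[Interval]:
    """Infer sleep intervals from screen lock/unlock gaps.

    Each screen-off gap of at least ``min_gap_min`` minutes that overlaps
    the nightly [21:00, 11:00) window becomes a candidate nighttime sleep
    interval; gaps of that length lying entirely within [12:00, 18:00)
    become naps. ``events`` needs columns ``timestamp`` and ``kind``
    (alternating ``unlock``/``lock``).
    """
    if len(events) == 0:
        return []
    ev = events.sort_values("timestamp").reset_index(drop=True)
    kinds = ev["kind"].tolist()
    for i in range(1, len(kinds)):
        if kinds[i] == kinds[i - 1]:
            raise ValidationError(
                f"non-alternating screen stream at {ev['timestamp'].iloc[i]}"
            )
    out: List[Interval] = []
    ts = [pd.Timestamp(t) for t in ev["timestamp"]]
    for i in range(len(ev) - 1):
        if kinds[i] != "lock":
            continue
        s, e = ts[i], ts[i + 1]
        if (e - s).total_seconds() / 60.0 < min_gap_min:
            continue
        if _gap_overlaps_night(s, e) or _gap_is_nap(s, e):
            out.append((s, e))
    return out
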