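"""EMA prompt scheduling, response capture, and adherence accounting.

Prompts are delivered in up to eight daily contexts — waking, before
school, lunchtime, after school, before/after private tutoring, before
bedtime, and a conditional slot that fires once phone usage after midnight
exceeds 30 minutes. Prompt times are drawn uniformly within each slot's
eligible window, and no prompt is ever placed inside a school, tutoring,
or sleep window (lunch breaks the school exclusion).

Adherence follows the deployment's two definitions: mood adherence is the
percentage of sent prompts that were answered; lifestyle adherence is the
percentage of the 48 daily half-hour cells actually recorded, averaged
over days.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import IntegrityError, ValidationError

#: Post-midnight usage (minutes) that triggers the conditional slot.
POST_MIDNIGHT_TRIGGER_MIN = 30.0

#: Lifestyle grid resolution: 48 half-hour cells per day.
LIFESTYLE_CELLS_PER_DAY = 48


class PromptSlot(str, Enum):
    WAKING = "waking"
    BEFORE_SCHOOL = "before_school"
    LUNCHTIME = "lunchtime"
    AFTER_SCHOOL = "after_school"
    BEFORE_TUTORING = "before_tutoring"
    AFTER_TUTORING = "after_tutoring"
    BEFORE_BEDTIME = "before_bedtime"
    POST_MIDNIGHT_USAGE = "post_midnight_usage"


Window = Tuple[pd.Timestamp, pd.Timestamp]


@dataclass
class DayContext:
    """Schedule context for one participant-day.

    Windows are half-open [start, end) pairs; ``None`` means the activity
    does not occur that day. ``bedtime`` is the (possibly next-day) onset
    of the coming night's sleep.
    """

    date: pd.Timestamp
    wake_time: pd.Timestamp
    school: Optional[Window] = None
    lunch: Optional[Window] = None
    tutoring: Optional[Window] = None
    sleep_windows: List[Window] = field(default_factory=list)
    bedtime: Optional[pd.Timestamp] = None


@dataclass
class Prompt:
    prompt_id: str
    slot: PromptSlot
    sent_at: pd.Timestamp


def _clip_window(w: Window, lo: pd.Timestamp, hi: pd.Timestamp) -> Optional[Window]:
    s, e = max(w[0], lo), min(w[1], hi)
    return (s, e) if e > s else None


def subtract_windows(base: Window, holes: Sequence[Window]) -> List[Window]:
    """Parts of ``base`` not covered by any of ``holes``."""
    segments = [base]
    for h0, h1 in sorted(holes):
        nxt: List[Window] = []
        for s, e in segments:
            if h1 <= s or h0 >= e:
                nxt.append((s, e))
                continue
            if h0 > s:
                nxt.append((s, h0))
            if h1 < e:
                nxt.append((h1, e))
        segments = nxt
    return segments


def _sample_in_windows(windows: Sequence[Window], rng: np.random.Generator) -> Optional[pd.Timestamp]:
    """Uniform draw over the union of disjoint windows (by total measure)."""
    lens = np.array([(e - s).total_seconds() for s, e in windows], dtype=float)
    total = lens.sum()
    if total <= 0:
        return None
    x = rng.uniform(0.0, total)
    for (s, _e), ln in zip(windows, lens):
        if x <= ln:
            return s + pd.Timedelta(seconds=float(x))
        x -= ln
    s, e = windows[-1]
    return e - pd.Timedelta(seconds=1)


def _merge_windows(windows: Sequence[Window]) -> List[Window]:
    ws = sorted(windows)
    merged: List[Window] = []
    for s, e in ws:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _post_midnight_trigger(
    episodes: Sequence[Window], day0: pd.Timestamp
) -> Optional[pd.Timestamp]:
    """Moment cumulative usage since 00:00 crosses the 30-minute trigger."""
    cutoff = day0 + pd.Timedelta(hours=7)  # "after midnight" = before the day starts
    cum = 0.0
    for s, e in sorted(episodes):
        s, e = max(s, day0), min(e, cutoff)
        if e <= s:
            continue
        dur = (e - s).total_seconds() / 60.0
        if cum + dur > POST_MIDNIGHT_TRIGGER_MIN:
            return s + pd.Timedelta(minutes=POST_MIDNIGHT_TRIGGER_MIN - cum)
        cum += dur
    return None


def slot_windows(ctx: DayContext) -> Dict[PromptSlot, Window]:
    """Default clock windows for the non-conditional slots."""
    d0 = ctx.date.normalize()
    d1 = d0 + pd.Timedelta(days=1)
    out: Dict[PromptSlot, Window] = {}
    w = ctx.wake_time
    out[PromptSlot.WAKING] = (w, w + pd.Timedelta(minutes=30))
    if ctx.school is not None:
        if ctx.school[0] > w + pd.Timedelta(minutes=30):
            out[PromptSlot.BEFORE_SCHOOL] = (w + pd.Timedelta(minutes=30), ctx.school[0])
        out[PromptSlot.AFTER_SCHOOL] = (ctx.school[1], ctx.school[1] + pd.Timedelta(hours=2))
    lunch = ctx.lunch or (d0 + pd.Timedelta(hours=12), d0 + pd.Timedelta(hours=13))
    out[PromptSlot.LUNCHTIME] = lunch
    if ctx.tutoring is not None:
        out[PromptSlot.BEFORE_TUTORING] = (ctx.tutoring[0] - pd.Timedelta(hours=1), ctx.tutoring[0])
        out[PromptSlot.AFTER_TUTORING] = (ctx.tutoring[1], ctx.tutoring[1] + pd.Timedelta(hours=1))
    if ctx.bedtime is not None:
        out[PromptSlot.BEFORE_BEDTIME] = (ctx.bedtime - pd.Timedelta(hours=1), ctx.bedtime)
    # clip everything to the calendar day
    clipped = {}
    for slot, win in out.items():
        cw = _clip_window(win, d0, d1)
        if cw is not None:
            clipped[slot] = cw
    return clipped


def exclusion_windows(ctx: DayContext) -> List[Window]:
    """Merged school (minus lunch), tutoring, and sleep windows."""
    d0 = ctx.date.normalize()
    d1 = d0 + pd.Timedelta(days=1)
    holes: List[Window] = []
    if ctx.school is not None:
        school_parts = (
            subtract_windows(ctx.school, [ctx.lunch]) if ctx.lunch else [ctx.school]
        )
        holes.extend(school_parts)
    if ctx.tutoring is not None:
        holes.append(ctx.tutoring)
    holes.extend(ctx.sleep_windows)
    holes = [h for h in (_clip_window(w, d0, d1) for w in holes) if h is not None]
    return _merge_windows(holes)


def schedule_prompts(
    ctx: DayContext,
    screen_episodes: Sequence[Window],
    rng: np.random.Generator,
    *,
    id_prefix: str = "",
) -> List[Prompt]:
    """Generate the day's prompts: at most one per slot, each drawn
    uniformly within the slot's eligible (exclusion-free) window; the
    post-midnight slot fires at the instant cumulative usage since 00:00
    crosses 30 minutes, provided that instant is eligible."""
    holes = exclusion_windows(ctx)
    prompts: List[Prompt] = []
    for slot, window in slot_windows(ctx).items():
        eligible = subtract_windows(window, holes)
        t = _sample_in_windows(eligible, rng)
        if t is not None:
            prompts.append(Prompt(f"{id_prefix}{slot.value}", slot, t))

    trig = _post_midnight_trigger(screen_episodes, ctx.date.normalize())
    if trig is not None and not any(s <= trig < e for s, e in holes):
        prompts.append(
            Prompt(
                f"{id_prefix}{PromptSlot.POST_MIDNIGHT_USAGE.value}",
                PromptSlot.POST_MIDNIGHT_USAGE,
                trig,
            )
        )
    prompts.sort(key=lambda p: p.sent_at)
    return prompts


@dataclass
class AdherenceSummary:
    mood_adherence_pct: float
    lifestyle_adherence_pct: float
    per_participant: pd.DataFrame  # participant_id, mood_pct, lifestyle_pct


def compute_adherence(
    ema: pd.DataFrame,
    lifestyle: pd.DataFrame,
    n_days: int,
) -> AdherenceSummary:
    """Adherence percentages from the prompt/response log and lifestyle grid.

    ``ema`` holds one row per *sent* prompt (columns ``participant_id``,
    ``prompt_id``, ``answered_at`` nullable); mood adherence is answered /
    sent x 100 over the deployment. ``lifestyle`` holds one row per
    *recorded* half-hour cell (columns ``participant_id``, ``date``,
    ``cell``); the denominator is 48 cells x ``n_days``.
    """
    if ema["prompt_id"].duplicated().any():
        raise IntegrityError("duplicate prompt_id in EMA log")
    if n_days < 1:
        raise ValidationError("n_days must be >= 1")

    sent = ema.groupby("participant_id").size()
    answered = ema.groupby("participant_id")["answered_at"].count()
    mood = (answered / sent * 100.0).rename("mood_pct")

    denominator = float(LIFESTYLE_CELLS_PER_DAY * n_days)
    pids = sorted(set(ema["participant_id"]) | set(lifestyle["participant_id"]))
    recorded = lifestyle.groupby("participant_id").size().reindex(pids, fill_value=0)
    life = (recorded / denominator * 100.0).rename("lifestyle_pct")

    per = pd.concat([mood, life], axis=1).reset_index(names="participant_id")
    return AdherenceSummary(
        mood_adherence_pct=float(per["mood_pct"].mean()),
        lifestyle_adherence_pct=float(per["lifestyle_pct"].mean()),
        per_participant=per,
    )
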