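"""Synthetic smartphone-deployment generator with known ground truth.

Emulates a two-group adolescent cohort observed for four weeks: each
participant follows a school-week routine over a set of anchor places
(home at night, school on weekdays, tutoring some evenings, an evening or
weekend walk), produces alternating screen unlock/lock episodes, sleeps
nightly with optional afternoon naps, answers EMA prompts, fills a 48-cell
lifestyle grid, and completes questionnaires at three waves.

A latent daily-distress state (AR(1) per construct, plus group offsets)
drives both the EMA ratings and — through configurable signed couplings —
a small set of behavioural knobs (nap length, post-midnight phone use,
daytime usage, unlock count, walk distance). Because the couplings are
known, downstream parameter recovery is measurable.

All randomness flows from ``SimConfig.seed`` via per-participant
substreams, so identical configs give byte-identical datasets.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import CONSTRUCTS, INSTRUMENTS, SimConfig
from .ema import DayContext, Prompt, schedule_prompts
from .errors import ConfigError

#: Ordinal cut-points mapping latent z (plus noise) to ratings 1..5.
RATING_CUTPOINTS = np.array([-1.5, -0.5, 0.5, 1.5])

#: Instrument item counts and per-item response ranges.
INSTRUMENT_ITEMS: Dict[str, Tuple[int, int, int]] = {
    "dass": (21, 0, 3),
    "self_efficacy": (22, 1, 5),
    "time_management": (30, 1, 5),
    "mauq": (21, 1, 7),
}

#: DASS-21 subscale allocation (0-based item indices).
DASS_SUBSCALES: Dict[str, Tuple[int, ...]] = {
    "depression": (2, 4, 9, 12, 15, 16, 20),
    "anxiety": (1, 3, 6, 8, 14, 18, 19),
    "stress": (0, 5, 7, 10, 11, 13, 17),
}

WAVES = ("baseline", "mid", "post")

_ADJ_NEG = ("sad", "tense", "down", "irritable")
_ADJ_POS = ("happy", "relaxed", "calm", "content")

# Daily schedule landmarks, minutes from midnight.
_SCHOOL_START, _SCHOOL_END = 510, 930  # 08:30-15:30
_LUNCH_START, _LUNCH_END = 720, 780  # 12:00-13:00
_TUTOR_START, _TUTOR_END = 1080, 1200  # 18:00-20:00
_TRANSIT_MIN = 20
_NAP_START = 980  # 16:20
_WALK_KMH = 4.5


@dataclass
class EmaResponse:
    prompt_id: str
    answered_at: pd.Timestamp
    depression: int
    anxiety: int
    stress: int
    adjectives: Tuple[str, ...]


@dataclass
class CohortDataset:
    """A full synthetic deployment as flat tables plus its config."""

    config: SimConfig
    participants: pd.DataFrame  # participant_id, group
    gps: pd.DataFrame  # participant_id, timestamp, lat, lon
    screen: pd.DataFrame  # participant_id, timestamp, kind
    sleep: pd.DataFrame  # participant_id, start, end
    ema: pd.DataFrame  # one row per sent prompt; answered_at/ratings nullable
    lifestyle: pd.DataFrame  # one row per recorded half-hour cell
    items: pd.DataFrame  # questionnaire item responses
    latent: pd.DataFrame  # ground-truth daily distress states


def rating_from_latent(z: float, noise_sd: float, rng: np.random.Generator) -> int:
    """Ordinal 1-5 rating: latent z plus Gaussian noise through fixed
    symmetric cut-points at -1.5, -0.5, 0.5, 1.5."""
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    x = z + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
    return int(np.searchsorted(RATING_CUTPOINTS, x) + 1)


def generate_ema_responses(
    latent: Dict[str, float],
    prompts: Sequence[Prompt],
    adherence_p: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> List[EmaResponse]:
    """Responses to a day's prompts given the day's latent distress.

    Each prompt is answered independently with probability ``adherence_p``;
    ratings discretize the latent state plus noise.
    """
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    if not 0.0 <= adherence_p <= 1.0:
        raise ConfigError("adherence_p must be in [0, 1]")
    out: List[EmaResponse] = []
    for p in prompts:
        if rng.random() >= adherence_p:
            continue
        ratings = {c: rating_from_latent(latent[c], noise_sd, rng) for c in CONSTRUCTS}
        pool = _ADJ_NEG if np.mean(list(latent.values())) > 0 else _ADJ_POS
        adjectives = tuple(rng.choice(pool, size=2, replace=False))
        out.append(
            EmaResponse(
                prompt_id=p.prompt_id,
                answered_at=p.sent_at + pd.Timedelta(minutes=float(rng.uniform(1, 10))),
                depression=ratings["depression"],
                anxiety=ratings["anxiety"],
                stress=ratings["stress"],
                adjectives=adjectives,
            )
        )
    return out


def _latent_states(cfg: SimConfig, group: str, rng: np.random.Generator) -> np.ndarray:
    """(n_constructs, n_days) AR(1) latent distress, stationary variance 1."""
    rho = cfg.ar1_rho
    z = np.empty((len(CONSTRUCTS), cfg.n_days))
    for i, c in enumerate(CONSTRUCTS):
        mu = cfg.baseline_distress.get(group, {}).get(c, 0.0)
        z[i, 0] = mu + rng.normal()
        for d in range(1, cfg.n_days):
            z[i, d] = mu + rho * (z[i, d - 1] - mu) + np.sqrt(1 - rho**2) * rng.normal()
    return z


def _coupling_shift(cfg: SimConfig, feature: str, z_day: np.ndarray) -> float:
    """Sum of construct couplings on ``feature`` for one day's latent state."""
    total = 0.0
    for i, c in enumerate(CONSTRUCTS):
        total += cfg.coupling.get(c, {}).get(feature, 0.0) * z_day[i]
    return total


def _day_positions(
    minutes: np.ndarray,
    dow: int,
    anchors: List[Tuple[float, float]],
    outing_km: float,
    outing_bearing: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """Lat/lon at each minute-of-day for the deterministic routine."""
    home = anchors[0]
    school = anchors[1] if len(anchors) > 1 else home
    tutor = anchors[2] if len(anchors) > 2 else home
    lat = np.full(minutes.shape, home[0])
    lon = np.full(minutes.shape, home[1])

    def _leg(t0: float, t1: float, a, b) -> None:
        m = (minutes >= t0) & (minutes < t1)
        if not m.any():
            return
        frac = (minutes[m] - t0) / (t1 - t0)
        lat[m] = a[0] + frac * (b[0] - a[0])
        lon[m] = a[1] + frac * (b[1] - a[1])

    def _stay(t0: float, t1: float, a) -> None:
        m = (minutes >= t0) & (minutes < t1)
        lat[m], lon[m] = a[0], a[1]

    is_weekday = dow < 5
    tutoring_day = is_weekday and dow in (0, 2, 4)
    if is_weekday:
        _leg(_SCHOOL_START - _TRANSIT_MIN, _SCHOOL_START, home, school)
        _stay(_SCHOOL_START, _SCHOOL_END, school)
        _leg(_SCHOOL_END, _SCHOOL_END + _TRANSIT_MIN, school, home)
        if tutoring_day:
            _leg(_TUTOR_START - _TRANSIT_MIN, _TUTOR_START, home, tutor)
            _stay(_TUTOR_START, _TUTOR_END, tutor)
            _leg(_TUTOR_END, _TUTOR_END + _TRANSIT_MIN, tutor, home)
        outing_t0 = 1250 if tutoring_day else 1170
    else:
        outing_t0 = 840  # weekend afternoon walk

    if outing_km > 0:
        theta = np.radians(outing_bearing)
        dest = (
            home[0] + outing_km * np.cos(theta) / 111.32,
            home[1] + outing_km * np.sin(theta) / (111.32 * np.cos(np.radians(home[0]))),
        )
        dur = outing_km / _WALK_KMH * 60.0
        _leg(outing_t0, outing_t0 + dur, home, dest)
        _leg(outing_t0 + dur, outing_t0 + 2 * dur, dest, home)
    return lat, lon


def _split_episodes(
    window_pieces: List[Tuple[float, float]],
    n_episodes: int,
    total_min: float,
    rng: np.random.Generator,
) -> List[Tuple[float, float]]:
    """Place ``n_episodes`` disjoint usage episodes totalling roughly
    ``total_min`` minutes across the given windows (minutes of day)."""
    lengths = np.array([b - a for a, b in window_pieces], dtype=float)
    if lengths.sum() <= 0 or n_episodes < 1:
        return []
    alloc = np.maximum(1, np.round(n_episodes * lengths / lengths.sum()).astype(int))
    while alloc.sum() > n_episodes and (alloc > 1).any():
        alloc[np.argmax(alloc)] -= 1
    weights = rng.uniform(0.5, 1.5, size=int(alloc.sum()))
    durations = weights / weights.sum() * total_min
    episodes: List[Tuple[float, float]] = []
    j = 0
    for (a, b), k in zip(window_pieces, alloc):
        slot_w = (b - a) / k
        for s in range(k):
            dur = min(durations[j], 0.8 * slot_w)
            lo = a + s * slot_w
            # episodes sit near slot centres: phones are picked up at a
            # fairly steady rhythm through waking hours
            start = lo + (slot_w - dur) * rng.uniform(0.35, 0.65)
            episodes.append((start, start + dur))
            j += 1
    return sorted(episodes)


def _generate_participant(
    pid: str, group: str, cfg: SimConfig, rng: np.random.Generator
) -> Dict[str, pd.DataFrame]:
    day0 = pd.Timestamp(cfg.start_date).normalize()
    n = cfg.n_days
    z = _latent_states(cfg, group, rng)
    anchors = [(a[0], a[1]) for a in cfg.anchor_places]
    sig_lat = cfg.gps_noise_m / 111_320.0
    sig_lon = cfg.gps_noise_m / (111_320.0 * np.cos(np.radians(anchors[0][0])))

    # Daily behavioural knobs driven by the latent state.
    night_usage = np.empty(n)
    nap_min = np.empty(n)
    day_usage = np.empty(n)
    n_epi = np.empty(n, dtype=int)
    outing_km = np.empty(n)
    for d in range(n):
        u = {f: _coupling_shift(cfg, f, z[:, d]) for f in (
            "nighttime_usage_min", "daytime_sleep_min", "daytime_usage_min",
            "unlock_count", "total_distance_km",
        )}
        night_usage[d] = np.clip(35 + 35 * u["nighttime_usage_min"] + rng.normal(0, 10), 0, 150)
        nap_min[d] = np.clip(35 + 45 * u["daytime_sleep_min"] + rng.normal(0, 12), 0, 100)
        day_usage[d] = np.clip(170 + 45 * u["daytime_usage_min"] + rng.normal(0, 25), 30, 480)
        n_epi[d] = int(np.clip(round(24 + 7 * u["unlock_count"] + rng.normal(0, 2.5)), 4, 60))
        outing_km[d] = np.clip(1.5 + 1.2 * u["total_distance_km"] + rng.normal(0, 0.4), 0.9, 6.0)

    # Sleep onsets/ends. onset[d] starts the sleep that ends on morning of
    # day d: either the previous evening (~23:20) or, after post-midnight
    # phone use, shortly after that usage ends.
    wake_jit = rng.normal(0, 12, size=n + 1)
    bed_jit = rng.normal(0, 12, size=n + 1)
    onset = []
    end = []
    for d in range(n + 1):
        usage = night_usage[d] if d < n else 0.0
        if usage > 5.0:
            onset.append(day0 + pd.Timedelta(days=d, minutes=8 + usage + 4))
        else:
            onset.append(day0 + pd.Timedelta(days=d - 1, minutes=1400 + bed_jit[d]))
        end.append(day0 + pd.Timedelta(days=d, minutes=425 + wake_jit[d]))

    sleep_rows: List[Tuple[str, pd.Timestamp, pd.Timestamp]] = []
    for d in range(n + 1):
        if d == n:
            # final evening's onset: clipping keeps only its pre-midnight part
            sleep_rows.append((pid, onset[d], day0 + pd.Timedelta(days=d, minutes=425)))
        else:
            sleep_rows.append((pid, onset[d], end[d]))
    for d in range(n):
        if nap_min[d] >= 8.0:
            s = day0 + pd.Timedelta(days=d, minutes=_NAP_START)
            sleep_rows.append((pid, s, s + pd.Timedelta(minutes=nap_min[d])))

    gps_t: List[np.ndarray] = []
    gps_lat: List[np.ndarray] = []
    gps_lon: List[np.ndarray] = []
    screen_rows: List[Tuple[str, pd.Timestamp, str]] = []
    ema_rows: List[dict] = []
    life_rows: List[Tuple[str, pd.Timestamp, int, str]] = []

    for d in range(n):
        date = day0 + pd.Timedelta(days=d)
        dow = int(date.dayofweek)
        wake = end[d]
        wake_min = (wake - date).total_seconds() / 60.0
        onset_next = onset[d + 1]
        onset_tonight = onset_next.normalize() == date  # bed before midnight

        # --- screen episodes (minutes of day) ---
        episodes: List[Tuple[float, float]] = []
        if night_usage[d] > 0.5:
            episodes.append((8.0, 8.0 + night_usage[d]))
        episodes.append((wake_min + 8, wake_min + 8 + rng.uniform(5, 15)))
        evening_cap = (
            (onset_next - date).total_seconds() / 60.0 - 30.0 if onset_tonight else 1380.0
        )
        if nap_min[d] >= 8.0 and evening_cap > _NAP_START + nap_min[d]:
            pieces = [
                (wake_min + 30.0, _NAP_START),
                (_NAP_START + nap_min[d], evening_cap),
            ]
        else:
            pieces = [(wake_min + 30.0, evening_cap)]
        pieces = [(a, b) for a, b in pieces if b - a > 30.0]
        episodes.extend(
            _split_episodes(pieces, int(n_epi[d]), max(day_usage[d] - 30.0, 10.0), rng)
        )
        # a final session before bed: either right before a pre-midnight
        # sleep onset, or a late-evening session on nights the phone will
        # be used again after midnight
        if onset_tonight:
            onset_min = (onset_next - date).total_seconds() / 60.0
            episodes.append((onset_min - 25.0, onset_min - 6.0))
        else:
            start = 1395.0 + rng.uniform(-5.0, 5.0)
            episodes.append((start, start + 20.0))
        episodes = sorted((a, b) for a, b in episodes if b > a)
        ep_windows = [
            (date + pd.Timedelta(minutes=a), date + pd.Timedelta(minutes=b))
            for a, b in episodes
        ]
        for s, e in ep_windows:
            screen_rows.append((pid, s, "unlock"))
            screen_rows.append((pid, e, "lock"))

        # --- GPS ---
        mins = np.arange(0.0, 1440.0, float(cfg.gps_sample_min))
        lat, lon = _day_positions(mins, dow, anchors, outing_km[d], rng.uniform(0, 360))
        lat = lat + rng.normal(0, sig_lat, size=lat.shape)
        lon = lon + rng.normal(0, sig_lon, size=lon.shape)
        gps_t.append(date.to_datetime64() + (mins * 60).astype("timedelta64[s]"))
        gps_lat.append(lat)
        gps_lon.append(lon)

        # --- lifestyle grid ---
        cell_starts = np.arange(48) * 30.0
        mids = date + pd.to_timedelta(cell_starts + 15.0, unit="m")
        day_sleeps = [(onset[d], end[d])]
        if nap_min[d] >= 8.0:
            s = date + pd.Timedelta(minutes=_NAP_START)
            day_sleeps.append((s, s + pd.Timedelta(minutes=nap_min[d])))
        day_sleeps.append((onset_next, date + pd.Timedelta(days=1)))
        for cell in range(48):
            m = mids[cell]
            mm = cell_starts[cell] + 15.0
            if any(s <= m < e for s, e in day_sleeps):
                act = "sleep"
            elif dow < 5 and _SCHOOL_START <= mm < _SCHOOL_END:
                act = "study"
            elif dow in (0, 2, 4) and _TUTOR_START <= mm < _TUTOR_END:
                act = "study"
            else:
                act = "leisure"
            if rng.random() < cfg.adherence_p:
                life_rows.append((pid, date, cell, act))

        # --- EMA ---
        ctx = DayContext(
            date=date,
            wake_time=wake,
            school=(
                (date + pd.Timedelta(minutes=_SCHOOL_START), date + pd.Timedelta(minutes=_SCHOOL_END))
                if dow < 5
                else None
            ),
            lunch=(date + pd.Timedelta(minutes=_LUNCH_START), date + pd.Timedelta(minutes=_LUNCH_END)),
            tutoring=(
                (date + pd.Timedelta(minutes=_TUTOR_START), date + pd.Timedelta(minutes=_TUTOR_END))
                if dow in (0, 2, 4)
                else None
            ),
            sleep_windows=[(onset[d], end[d]), (onset_next, date + pd.Timedelta(days=2))]
            + (
                [
                    (
                        date + pd.Timedelta(minutes=_NAP_START),
                        date + pd.Timedelta(minutes=_NAP_START + nap_min[d]),
                    )
                ]
                if nap_min[d] >= 8.0
                else []
            ),
            bedtime=onset_next,
        )
        prompts = schedule_prompts(ctx, ep_windows, rng, id_prefix=f"{pid}-d{d:02d}-")
        latent_day = {c: float(z[i, d]) for i, c in enumerate(CONSTRUCTS)}
        responses = {
            r.prompt_id: r
            for r in generate_ema_responses(
                latent_day, prompts, cfg.adherence_p, cfg.ema_noise_sd, rng
            )
        }
        for p in prompts:
            r = responses.get(p.prompt_id)
            ema_rows.append(
                {
                    "participant_id": pid,
                    "prompt_id": p.prompt_id,
                    "slot": p.slot.value,
                    "sent_at": p.sent_at,
                    "answered_at": r.answered_at if r else pd.NaT,
                    "depression": r.depression if r else np.nan,
                    "anxiety": r.anxiety if r else np.nan,
                    "stress": r.stress if r else np.nan,
                    "adjectives": ";".join(r.adjectives) if r else "",
                }
            )

    # --- questionnaires ---
    item_rows: List[dict] = []
    person_re = {inst: rng.normal(0, 1.5) for inst in INSTRUMENTS}
    for w, wave in enumerate(WAVES):
        for inst in INSTRUMENTS:
            base = cfg.baseline_scores[inst][group]
            shift = cfg.group_time_effects.get(inst, {}).get(group, [0, 0, 0])[w]
            target = base + shift + person_re[inst]
            if inst.startswith("dass_"):
                construct = inst.split("_", 1)[1]
                idxs = DASS_SUBSCALES[construct]
                lo, hi = 0, 3
                per_item = target / len(idxs)
                for i in idxs:
                    item_rows.append(
                        {
                            "participant_id": pid,
                            "group": group,
                            "wave": wave,
                            "instrument": "dass",
                            "item": i,
                            "response": int(np.clip(round(rng.normal(per_item, 0.7)), lo, hi)),
                        }
                    )
            else:
                n_items, lo, hi = INSTRUMENT_ITEMS[inst]
                per_item = target / n_items
                for i in range(n_items):
                    item_rows.append(
                        {
                            "participant_id": pid,
                            "group": group,
                            "wave": wave,
                            "instrument": inst,
                            "item": i,
                            "response": int(np.clip(round(rng.normal(per_item, 0.7)), lo, hi)),
                        }
                    )
    if group == "intervention":
        n_items, lo, hi = INSTRUMENT_ITEMS["mauq"]
        per_item = 6.3 + rng.normal(0, 0.25)
        for i in range(n_items):
            item_rows.append(
                {
                    "participant_id": pid,
                    "group": group,
                    "wave": "post",
                    "instrument": "mauq",
                    "item": i,
                    "response": int(np.clip(round(rng.normal(per_item, 0.6)), lo, hi)),
                }
            )

    latent_df = pd.DataFrame(
        {
            "participant_id": pid,
            "day_index": np.arange(n),
            "depression": z[0],
            "anxiety": z[1],
            "stress": z[2],
        }
    )
    return {
        "gps": pd.DataFrame(
            {
                "participant_id": pid,
                "timestamp": np.concatenate(gps_t),
                "lat": np.concatenate(gps_lat),
                "lon": np.concatenate(gps_lon),
            }
        ),
        "screen": pd.DataFrame(screen_rows, columns=["participant_id", "timestamp", "kind"]),
        "sleep": pd.DataFrame(sleep_rows, columns=["participant_id", "start", "end"]),
        "ema": pd.DataFrame(ema_rows),
        "lifestyle": pd.DataFrame(
            life_rows, columns=["participant_id", "date", "cell", "activity"]
        ),
        "items": pd.DataFrame(item_rows),
        "latent": latent_df,
    }


def generate_cohort(config: SimConfig) -> CohortDataset:
    """Generate the full synthetic deployment for a :class:`SimConfig`.

    Deterministic given the config (including its seed): participants get
    independent substreams spawned from the root seed.
    """
    pids = [f"C{i + 1:02d}" for i in range(config.n_control)] + [
        f"I{i + 1:02d}" for i in range(config.n_intervention)
    ]
    groups = ["control"] * config.n_control + ["intervention"] * config.n_intervention
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(len(pids))

    parts: Dict[str, List[pd.DataFrame]] = {
        k: [] for k in ("gps", "screen", "sleep", "ema", "lifestyle", "items", "latent")
    }
    for pid, group, ss in zip(pids, groups, streams):
        frames = _generate_participant(pid, group, config, np.random.default_rng(ss))
        for k, v in frames.items():
            parts[k].append(v)

    merged = {k: pd.concat(v, ignore_index=True) for k, v in parts.items()}
    return CohortDataset(
        config=config,
        participants=pd.DataFrame({"participant_id": pids, "group": groups}),
        **merged,
    )
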