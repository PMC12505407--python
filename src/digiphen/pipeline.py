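"""Daily aggregation and the full analysis pathway.

``extract_daily_records`` reduces raw streams to one row per
participant-day: the 13 passive features (5 location, 3 sleep, 5 phone)
plus the daily mean EMA rating per construct. Days with insufficient data
get missing values, never imputed ones.

``run_full_analysis`` reproduces the study's statistical pathway on a
cohort: IQR-filtered Pearson correlations over the 13 x 3 feature-by-
construct grid, baseline group comparisons, 2x3 mixed ANOVAs with Scheffe
post hoc and change-score Cohen's d, and adherence accounting.
"""
from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import location as loc
from . import phone as ph
from . import sleep as sl
from . import stats as st
from .config import CONSTRUCTS, INSTRUMENTS
from .ema import AdherenceSummary, compute_adherence
from .errors import InsufficientDataError
from .synthetic import CohortDataset

log = logging.getLogger(__name__)

#: The 13 passive features, in the presentation order of the study's
#: correlation tables: location, sleep, then phone log.
FEATURES: List[str] = [
    "total_distance_km",
    "total_travel_time_min",
    "location_variance",
    "location_entropy",
    "normalized_entropy",
    "total_sleep_min",
    "daytime_sleep_min",
    "nighttime_sleep_min",
    "total_usage_min",
    "lock_duration_min",
    "daytime_usage_min",
    "nighttime_usage_min",
    "unlock_count",
]

_LOCATION_COLS = FEATURES[:5]
_SLEEP_COLS = FEATURES[5:8]
_PHONE_COLS = FEATURES[8:13]


def _day_seed(root_seed: int, pid: str, day: int) -> int:
    return (zlib.crc32(f"{root_seed}:{pid}:{day}".encode()) & 0x7FFFFFFF)


def extract_daily_records(dataset: CohortDataset) -> pd.DataFrame:
    """One row per participant-day with passive features and EMA means."""
    cfg = dataset.config
    day0 = pd.Timestamp(cfg.start_date).normalize()
    dates = [day0 + pd.Timedelta(days=d) for d in range(cfg.n_days)]

    gps_g = dict(tuple(dataset.gps.groupby("participant_id")))
    screen_g = dict(tuple(dataset.screen.groupby("participant_id")))
    sleep_g = dict(tuple(dataset.sleep.groupby("participant_id")))
    ema = dataset.ema.copy()
    ema["date"] = pd.to_datetime(ema["sent_at"]).dt.normalize()
    ema_g = dict(tuple(ema.groupby("participant_id")))

    rows: List[dict] = []
    for _, prow in dataset.participants.iterrows():
        pid, group = prow["participant_id"], prow["group"]
        gps_p = gps_g.get(pid)
        gps_by_date = {}
        if gps_p is not None:
            gps_p = gps_p.sort_values("timestamp")
            gps_by_date = dict(
                tuple(gps_p.groupby(pd.to_datetime(gps_p["timestamp"]).dt.normalize()))
            )
        screen_p = screen_g.get(pid)
        screen_by_date = {}
        if screen_p is not None:
            screen_p = screen_p.sort_values("timestamp")
            screen_by_date = dict(
                tuple(screen_p.groupby(pd.to_datetime(screen_p["timestamp"]).dt.normalize()))
            )
        sleep_p = sleep_g.get(pid)
        sleep_ivs = (
            sl.merge_intervals(
                zip(pd.to_datetime(sleep_p["start"]), pd.to_datetime(sleep_p["end"]))
            )
            if sleep_p is not None
            else []
        )
        ema_p = ema_g.get(pid)
        ema_by_date = dict(tuple(ema_p.groupby("date"))) if ema_p is not None else {}

        for d, date in enumerate(dates):
            rec: dict = {
                "participant_id": pid,
                "group": group,
                "date": date,
                "day_index": d,
            }
            # location
            feats = None
            sel = gps_by_date.get(date)
            if sel is not None:
                try:
                    feats = loc.compute_location_features(
                        sel["timestamp"].to_numpy(),
                        sel["lat"].to_numpy(),
                        sel["lon"].to_numpy(),
                        seed=_day_seed(cfg.seed, pid, d),
                    )
                except InsufficientDataError:
                    feats = None
            if feats is None:
                rec.update({c: np.nan for c in _LOCATION_COLS})
            else:
                rec.update(
                    {
                        "total_distance_km": feats.total_distance_km,
                        "total_travel_time_min": feats.total_travel_time_min,
                        "location_variance": feats.location_variance,
                        "location_entropy": feats.location_entropy,
                        "normalized_entropy": feats.normalized_entropy,
                    }
                )
            # sleep
            sf = sl.compute_sleep_features(sleep_ivs, date)
            rec.update(
                {
                    "total_sleep_min": sf.total_min,
                    "daytime_sleep_min": sf.daytime_min,
                    "nighttime_sleep_min": sf.nighttime_min,
                }
            )
            # phone
            sel = screen_by_date.get(date)
            if sel is None:
                sel = pd.DataFrame(columns=["timestamp", "kind"])
            pf = ph.compute_phone_features(sel, date)
            rec.update(
                {
                    "total_usage_min": pf.total_usage_min,
                    "daytime_usage_min": pf.daytime_usage_min,
                    "nighttime_usage_min": pf.nighttime_usage_min,
                    "lock_duration_min": pf.lock_duration_min,
                    "unlock_count": pf.unlock_count,
                }
            )
            # EMA daily means
            day_resp = ema_by_date.get(date)
            if day_resp is not None:
                day_resp = day_resp[day_resp["answered_at"].notna()]
            else:
                day_resp = pd.DataFrame(columns=list(CONSTRUCTS))
            for c in CONSTRUCTS:
                vals = day_resp[c].dropna() if len(day_resp) else pd.Series(dtype=float)
                rec[f"ema_{c}"] = float(vals.mean()) if len(vals) else np.nan
            rows.append(rec)
    return pd.DataFrame(rows)


def correlation_grid(
    records: pd.DataFrame,
    *,
    within_person: bool = False,
    bh: bool = False,
) -> pd.DataFrame:
    """Pearson r over the 13 features x 3 constructs grid.

    Feature values are IQR-filtered (pooled across participant-days)
    before pairing with the daily mean EMA ratings; excluded and missing
    values are dropped, never imputed. ``within_person`` optionally
    centers both variables on participant means first; ``bh`` appends
    Benjamini-Hochberg adjusted p-values.
    """
    rows = []
    for feature in FEATURES:
        keep = st.iqr_mask(records[feature].to_numpy())
        for construct in CONSTRUCTS:
            sub = records.loc[keep, ["participant_id", feature, f"ema_{construct}"]].dropna()
            if len(sub) < 3:
                rows.append(
                    {"feature": feature, "construct": construct,
                     "r": np.nan, "p": np.nan, "n": len(sub)}
                )
                continue
            x = sub[feature].to_numpy(dtype=float)
            y = sub[f"ema_{construct}"].to_numpy(dtype=float)
            if within_person:
                grp = sub.groupby("participant_id")
                x = x - grp[feature].transform("mean").to_numpy()
                y = y - grp[f"ema_{construct}"].transform("mean").to_numpy()
            res = st.pearson_corr(x, y, feature=feature, construct=construct)
            rows.append(
                {"feature": feature, "construct": construct,
                 "r": res.r, "p": res.p, "n": res.n}
            )
    grid = pd.DataFrame(rows)
    if bh:
        grid["p_adj"] = st.bh_adjust(grid["p"].to_numpy())
    return grid


def baseline_tests(waves: pd.DataFrame) -> pd.DataFrame:
    """Between-group comparisons at baseline: pooled-variance t test and
    Mann-Whitney U for each instrument."""
    base = waves[waves["wave"] == "baseline"]
    rows = []
    for outcome in INSTRUMENTS:
        if outcome not in base.columns:
            continue
        a = base.loc[base["group"] == "control", outcome].dropna()
        b = base.loc[base["group"] == "intervention", outcome].dropna()
        if len(a) < 2 or len(b) < 2:
            continue
        t, df, p = st.independent_t(a, b)
        u, pu = st.mann_whitney_u(a, b)
        rows.append(
            {
                "outcome": outcome,
                "mean_control": a.mean(),
                "sd_control": a.std(ddof=1),
                "mean_intervention": b.mean(),
                "sd_intervention": b.std(ddof=1),
                "t": t,
                "df": df,
                "p_t": p,
                "U": u,
                "p_u": pu,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AnalysisReport:
    """Serializable bundle of the full analysis outputs."""

    correlations: pd.DataFrame
    baseline: pd.DataFrame
    anova: pd.DataFrame
    posthoc: pd.DataFrame
    effect_sizes: pd.DataFrame
    adherence: AdherenceSummary
    records: pd.DataFrame
    waves: pd.DataFrame
    manifest: Dict = field(default_factory=dict)

    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.correlations.to_csv(out / "correlations.csv", index=False)
        self.baseline.to_csv(out / "baseline.csv", index=False)
        self.anova.to_csv(out / "anova.csv", index=False)
        self.posthoc.to_csv(out / "posthoc.csv", index=False)
        self.effect_sizes.to_csv(out / "effect_sizes.csv", index=False)
        self.adherence.per_participant.to_csv(out / "adherence.csv", index=False)
        self.records.to_csv(out / "daily_records.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def run_full_analysis(
    dataset: CohortDataset,
    *,
    within_person: bool = False,
    bh: bool = False,
    records: Optional[pd.DataFrame] = None,
) -> AnalysisReport:
    """The full pathway on one cohort: extraction, the 13x3 correlation
    grid, baseline tests, per-instrument mixed ANOVAs, and adherence."""
    cfg = dataset.config
    if records is None:
        records = extract_daily_records(dataset)
    grid = correlation_grid(records, within_person=within_person, bh=bh)
    waves = st.score_waves(dataset.items)
    base = baseline_tests(waves)

    anova_rows, posthoc_rows, d_rows = [], [], []
    can_anova = waves["group"].nunique() == 2 and waves.groupby("group")["participant_id"].nunique().min() >= 2
    if can_anova:
        for outcome in INSTRUMENTS:
            if outcome not in waves.columns:
                continue
            res = st.mixed_anova_2x3(waves, outcome)
            tab = res.table.copy()
            tab.insert(0, "outcome", outcome)
            anova_rows.append(tab)
            if len(res.posthoc):
                phd = res.posthoc.copy()
                phd.insert(0, "outcome", outcome)
                posthoc_rows.append(phd)
            d_rows.append({"outcome": outcome, "cohen_d_change": res.effect_size_d})
    anova = pd.concat(anova_rows, ignore_index=True) if anova_rows else pd.DataFrame()
    posthoc = pd.concat(posthoc_rows, ignore_index=True) if posthoc_rows else pd.DataFrame()
    effect_sizes = pd.DataFrame(d_rows)

    adherence = compute_adherence(dataset.ema, dataset.lifestyle, cfg.n_days)

    cfg_json = cfg.model_dump_json()
    manifest = {
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": json.loads(cfg_json),
        "n_participants": int(len(dataset.participants)),
        "n_daily_records": int(len(records)),
        "within_person": within_person,
        "bh_correction": bh,
        "iqr_excluded_per_feature": {
            f: int((~st.iqr_mask(records[f].to_numpy())).sum() - records[f].isna().sum())
            for f in FEATURES
        },
        "mood_adherence_pct": adherence.mood_adherence_pct,
        "lifestyle_adherence_pct": adherence.lifestyle_adherence_pct,
    }
    return AnalysisReport(
        correlations=grid,
        baseline=base,
        anova=anova,
        posthoc=posthoc,
        effect_sizes=effect_sizes,
        adherence=adherence,
        records=records,
        waves=waves,
        manifest=manifest,
    )
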