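"""Dataset serialization: the pipeline's CSV schemas plus a JSON sidecar.

Schemas (all UTF-8, header required, RFC-4180 quoting):

- ``gps.csv``: participant_id, timestamp, lat, lon
- ``screen_events.csv``: participant_id, timestamp, kind
- ``sleep.csv``: participant_id, start, end
- ``ema.csv``: participant_id, prompt_id, slot, sent_at, answered_at,
  depression, anxiety, stress, adjectives (semicolon-joined)
- ``lifestyle.csv``: participant_id, date, cell, activity
- ``questionnaire_items.csv``: participant_id, group, wave, instrument,
  item, response
- ``participants.csv``: participant_id, group
- ``ground_truth.json``: the full SimConfig (couplings included) plus the
  latent daily-distress states in ``latent.csv``
"""
from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .config import SimConfig
from .synthetic import CohortDataset

_TS = "%Y-%m-%dT%H:%M:%S"

_FILES = {
    "gps": "gps.csv",
    "screen": "screen_events.csv",
    "sleep": "sleep.csv",
    "ema": "ema.csv",
    "lifestyle": "lifestyle.csv",
    "items": "questionnaire_items.csv",
    "participants": "participants.csv",
    "latent": "latent.csv",
}


def save_dataset(dataset: CohortDataset, outdir) -> Path:
    """Write the full dataset to ``outdir``; returns the directory path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    gps = dataset.gps.copy()
    gps["timestamp"] = pd.to_datetime(gps["timestamp"]).dt.strftime(_TS)
    gps.to_csv(out / _FILES["gps"], index=False, float_format="%.7f")

    screen = dataset.screen.copy()
    screen["timestamp"] = pd.to_datetime(screen["timestamp"]).dt.strftime(_TS)
    screen.to_csv(out / _FILES["screen"], index=False)

    sleep = dataset.sleep.copy()
    for col in ("start", "end"):
        sleep[col] = pd.to_datetime(sleep[col]).dt.strftime(_TS)
    sleep.to_csv(out / _FILES["sleep"], index=False)

    ema = dataset.ema.copy()
    for col in ("sent_at", "answered_at"):
        ema[col] = pd.to_datetime(ema[col]).dt.strftime(_TS)
    ema.to_csv(out / _FILES["ema"], index=False, float_format="%.0f")

    lifestyle = dataset.lifestyle.copy()
    lifestyle["date"] = pd.to_datetime(lifestyle["date"]).dt.strftime("%Y-%m-%d")
    lifestyle.to_csv(out / _FILES["lifestyle"], index=False)

    dataset.items.to_csv(out / _FILES["items"], index=False)
    dataset.participants.to_csv(out / _FILES["participants"], index=False)
    dataset.latent.to_csv(out / _FILES["latent"], index=False, float_format="%.8f")

    with open(out / "ground_truth.json", "w") as fh:
        json.dump(
            {"sim_config": json.loads(dataset.config.model_dump_json())},
            fh,
            indent=2,
        )
    return out


def load_dataset(indir) -> CohortDataset:
    """Read a dataset directory written by :func:`save_dataset`."""
    d = Path(indir)
    with open(d / "ground_truth.json") as fh:
        cfg = SimConfig(**json.load(fh)["sim_config"])

    gps = pd.read_csv(d / _FILES["gps"], parse_dates=["timestamp"])
    screen = pd.read_csv(d / _FILES["screen"], parse_dates=["timestamp"])
    sleep = pd.read_csv(d / _FILES["sleep"], parse_dates=["start", "end"])
    ema = pd.read_csv(
        d / _FILES["ema"], parse_dates=["sent_at", "answered_at"],
        dtype={"adjectives": str}, keep_default_na=True,
    )
    ema["adjectives"] = ema["adjectives"].fillna("")
    lifestyle = pd.read_csv(d / _FILES["lifestyle"], parse_dates=["date"])
    items = pd.read_csv(d / _FILES["items"])
    participants = pd.read_csv(d / _FILES["participants"])
    latent = pd.read_csv(d / _FILES["latent"])
    return CohortDataset(
        config=cfg,
        participants=participants,
        gps=gps,
        screen=screen,
        sleep=sleep,
        ema=ema,
        lifestyle=lifestyle,
        items=items,
        latent=latent,
    )
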