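"""Generative configuration for synthetic study cohorts.

``SimConfig`` is the full specification of a simulated deployment: cohort
sizes, study length, the daily-routine anchor places, the signed couplings
between the latent daily-distress process and the passive features it is
allowed to steer, group-by-wave shifts on the questionnaire instruments,
and the noise/adherence parameters. Everything downstream (stream
generation, EMA responses, questionnaire items) is a deterministic
function of a ``SimConfig`` and its root seed.
"""
from __future__ import annotations

from typing import Dict, List, Tuple

from pydantic import BaseModel, Field, field_validator, model_validator

#: Emotional constructs rated 1-5 at each EMA prompt.
CONSTRUCTS: Tuple[str, ...] = ("depression", "anxiety", "stress")

#: Passive features the generator can steer independently of the others.
#: Location variance/entropy emerge from the movement kinematics and are
#: not steerable without also moving travel distance, so they are not
#: accepted as coupling targets.
COUPLABLE_FEATURES = frozenset(
    {
        "daytime_sleep_min",
        "nighttime_usage_min",
        "daytime_usage_min",
        "unlock_count",
        "total_distance_km",
    }
)

#: Scored instruments collected at the three questionnaire waves.
INSTRUMENTS: Tuple[str, ...] = (
    "dass_depression",
    "dass_anxiety",
    "dass_stress",
    "self_efficacy",
    "time_management",
)

GROUPS: Tuple[str, ...] = ("control", "intervention")

# Weak couplings whose signs mirror the study's observed associations:
# distress goes with more daytime sleep (except stress), less late-night
# phone use, fewer unlocks, shorter travel.
_DEFAULT_COUPLING: Dict[str, Dict[str, float]] = {
    "depression": {
        "daytime_sleep_min": 0.05,
        "nighttime_usage_min": -0.07,
        "unlock_count": -0.07,
        "total_distance_km": -0.04,
        "daytime_usage_min": -0.03,
    },
    "anxiety": {
        "daytime_sleep_min": 0.07,
        "nighttime_usage_min": -0.06,
        "unlock_count": -0.06,
    },
    "stress": {
        "daytime_sleep_min": -0.06,
        "nighttime_usage_min": -0.05,
        "unlock_count": -0.08,
    },
}

# Score-scale mean shifts per wave (baseline, mid, post). The intervention
# group improves on depression/stress/self-efficacy/time management; both
# groups drift down on anxiety (time effect without interaction).
_DEFAULT_GROUP_TIME_EFFECTS: Dict[str, Dict[str, List[float]]] = {
    "dass_depression": {"control": [0.0, -0.2, -0.4], "intervention": [0.0, -0.8, -1.6]},
    "dass_anxiety": {"control": [0.0, -1.0, -2.0], "intervention": [0.0, -1.0, -2.0]},
    "dass_stress": {"control": [0.0, 0.0, -0.1], "intervention": [0.0, -0.7, -1.4]},
    "self_efficacy": {"control": [0.0, 0.3, 0.7], "intervention": [0.0, 1.5, 3.0]},
    "time_management": {"control": [0.0, 0.5, 1.0], "intervention": [0.0, 1.6, 3.2]},
}

# Baseline mean instrument scores per group (control, intervention). The
# cohort emulated here entered the study with elevated depression and
# stress in the intervention arm.
_DEFAULT_BASELINE_SCORES: Dict[str, Dict[str, float]] = {
    "dass_depression": {"control": 10.2, "intervention": 18.1},
    "dass_anxiety": {"control": 10.5, "intervention": 11.5},
    "dass_stress": {"control": 12.0, "intervention": 19.8},
    "self_efficacy": {"control": 70.0, "intervention": 68.0},
    "time_management": {"control": 88.0, "intervention": 86.0},
}

# Latent distress z-scale offsets per group, mirroring the baseline
# imbalance above on the daily EMA side.
_DEFAULT_BASELINE_DISTRESS: Dict[str, Dict[str, float]] = {
    "control": {"depression": 0.0, "anxiety": 0.0, "stress": 0.0},
    "intervention": {"depression": 0.5, "anxiety": 0.1, "stress": 0.5},
}

# Urban anchor places (lat, lon, label): home, school ~1.2 km away,
# tutoring academy ~0.9 km away in the other direction.
_DEFAULT_ANCHORS: List[Tuple[float, float, str]] = [
    (37.5500, 127.0000, "home"),
    (37.5610, 127.0080, "school"),
    (37.5445, 126.9930, "tutoring"),
]


class SimConfig(BaseModel):
    """Full generative specification of a synthetic deployment."""

    n_intervention: int = Field(default=17, ge=0)
    n_control: int = Field(default=19, ge=0)
    n_days: int = Field(default=28, ge=1)
    seed: int = 0
    start_date: str = "2025-03-03"  # a Monday; weekday schedule keys off it

    anchor_places: List[Tuple[float, float, str]] = Field(
        default_factory=lambda: [tuple(a) for a in _DEFAULT_ANCHORS]
    )

    #: construct -> feature -> signed coefficient on the latent z scale.
    coupling: Dict[str, Dict[str, float]] = Field(
        default_factory=lambda: {c: dict(f) for c, f in _DEFAULT_COUPLING.items()}
    )

    #: instrument -> group -> per-wave mean shifts (baseline, mid, post).
    group_time_effects: Dict[str, Dict[str, List[float]]] = Field(
        default_factory=lambda: {
            i: {g: list(v) for g, v in d.items()}
            for i, d in _DEFAULT_GROUP_TIME_EFFECTS.items()
        }
    )

    baseline_scores: Dict[str, Dict[str, float]] = Field(
        default_factory=lambda: {
            i: dict(d) for i, d in _DEFAULT_BASELINE_SCORES.items()
        }
    )

    baseline_distress: Dict[str, Dict[str, float]] = Field(
        default_factory=lambda: {
            g: dict(d) for g, d in _DEFAULT_BASELINE_DISTRESS.items()
        }
    )

    adherence_p: float = Field(default=0.9, ge=0.0, le=1.0)
    gps_noise_m: float = Field(default=20.0, ge=0.0)
    ema_noise_sd: float = Field(default=1.0, ge=0.0)
    gps_sample_min: int = Field(default=10, ge=2)
    ar1_rho: float = Field(default=0.5, ge=0.0, lt=1.0)

    @field_validator("anchor_places")
    @classmethod
    def _anchors_nonempty(cls, v):
        if not v:
            raise ValueError("anchor_places must be non-empty")
        for lat, lon, _label in v:
            if not (-90.0 <= lat <= 90.0) or not (-180.0 < lon <= 180.0):
                raise ValueError(f"anchor out of range: ({lat}, {lon})")
        return v

    @field_validator("coupling")
    @classmethod
    def _coupling_known(cls, v):
        for construct, feats in v.items():
            if construct not in CONSTRUCTS:
                raise ValueError(f"unknown construct {construct!r}")
            unknown = set(feats) - COUPLABLE_FEATURES
            if unknown:
                raise ValueError(
                    f"coupling targets not steerable by the generator: {sorted(unknown)}"
                )
        return v

    @field_validator("group_time_effects")
    @classmethod
    def _effects_shape(cls, v):
        for instrument, groups in v.items():
            if instrument not in INSTRUMENTS:
                raise ValueError(f"unknown instrument {instrument!r}")
            for group, shifts in groups.items():
                if group not in GROUPS:
                    raise ValueError(f"unknown group {group!r}")
                if len(shifts) != 3:
                    raise ValueError("group_time_effects need 3 per-wave shifts")
        return v

    @model_validator(mode="after")
    def _cohort_nonempty(self):
        if self.n_intervention + self.n_control < 1:
            raise ValueError("cohort must contain at least one participant")
        return self

    def coupling_on(self, feature: str) -> Dict[str, float]:
        """Signed coefficients of each construct on ``feature``."""
        return {
            c: feats[feature]
            for c, feats in self.coupling.items()
            if feature in feats
        }
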