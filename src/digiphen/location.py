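"""Location phenotypes from daily GPS streams.

A day's GPS trace is reduced to five features: total distance travelled,
total travel time, location variance, location entropy, and normalized
location entropy. Points are first classified as stationary or moving by
thresholding the instantaneous speed (time derivative of position) at
1 km/h; stationary points are clustered with K-means into significant
places, and the dwell-time shares of those places define the entropy
features.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .errors import InsufficientDataError, ValidationError

EARTH_RADIUS_KM = 6371.0
SPEED_THRESHOLD_KMH = 1.0
#: Floor inside the log so a motionless day has a finite location variance.
VARIANCE_EPS = 1e-10


def _check_coords(lat, lon) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if not (np.all(np.isfinite(lat)) and np.all(np.isfinite(lon))):
        raise ValidationError("non-finite coordinate")
    if np.any(lat < -90.0) or np.any(lat > 90.0):
        raise ValidationError("latitude outside [-90, 90]")
    if np.any(lon <= -180.0) or np.any(lon > 180.0):
        raise ValidationError("longitude outside (-180, 180]")


def haversine_km(lat1, lon1, lat2, lon2, *, validate: bool = True):
    """Great-circle distance in km (Earth radius 6371.0 km); vectorized."""
    if validate:
        _check_coords(lat1, lon1)
        _check_coords(lat2, lon2)
    p1, l1, p2, l2 = (np.radians(np.asarray(a, dtype=float)) for a in (lat1, lon1, lat2, lon2))
    dphi = p2 - p1
    dlmb = l2 - l1
    h = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
    h = np.clip(h, 0.0, 1.0)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


def _times_to_seconds(times) -> np.ndarray:
    t = np.asarray(times)
    if np.issubdtype(t.dtype, np.datetime64):
        return t.astype("datetime64[ns]").astype("int64") / 1e9
    return t.astype(float)


def estimate_speeds(times, lats, lons) -> np.ndarray:
    """Per-interval speeds in km/h from consecutive fixes.

    ``speed[i]`` covers the interval from point ``i`` to point ``i+1``;
    the result has length ``n - 1``.
    """
    ts = _times_to_seconds(times)
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    if ts.size < 2:
        return np.empty(0)
    dt = np.diff(ts)
    if np.any(dt <= 0):
        raise ValidationError("timestamps must be strictly increasing")
    dist = haversine_km(lats[:-1], lons[:-1], lats[1:], lons[1:])
    return dist / (dt / 3600.0)


def classify_segments(speeds, threshold_kmh: float = SPEED_THRESHOLD_KMH) -> np.ndarray:
    """Boolean array, True where an interval is *moving*.

    An interval is stationary iff its speed is strictly below the
    threshold; a speed exactly at the threshold counts as moving.
    """
    s = np.asarray(speeds, dtype=float)
    if np.any(~np.isfinite(s)) or np.any(s < 0):
        raise ValidationError("speeds must be finite and non-negative")
    return s >= threshold_kmh


@dataclass
class PlaceClusterSet:
    """Significant places found among a day's stationary points."""

    k: int
    centroids: np.ndarray  # (k, 2) lat/lon
    labels: np.ndarray  # cluster index per stationary point
    dwell_fraction: np.ndarray  # time share per cluster, sums to 1

    @property
    def is_empty(self) -> bool:
        return self.k == 0


def _empty_clusters() -> PlaceClusterSet:
    return PlaceClusterSet(0, np.empty((0, 2)), np.empty(0, dtype=int), np.empty(0))


def cluster_places(
    lats,
    lons,
    dwell_s=None,
    *,
    max_k: int = 10,
    merge_radius_m: float = 500.0,
    seed: int = 0,
) -> PlaceClusterSet:
    """Cluster stationary points into significant places.

    K-means is run for k = 1, 2, ... and the chosen k is the smallest for
    which every point lies within ``merge_radius_m`` of its centroid
    (capped at ``max_k``). Clustering is done in raw lat/lon degrees —
    adequate at neighbourhood scale — while the coverage check uses
    great-circle metres. Dwell fractions are the time shares attributed to
    each cluster.
    """
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    if lats.size == 0:
        return _empty_clusters()
    _check_coords(lats, lons)
    if dwell_s is None:
        dwell_s = np.ones_like(lats)
    dwell_s = np.asarray(dwell_s, dtype=float)
    if np.any(dwell_s < 0):
        raise ValidationError("dwell times must be non-negative")

    pts = np.column_stack([lats, lons])
    n = pts.shape[0]
    cap = min(max_k, n)
    labels = np.zeros(n, dtype=int)
    centroids = pts.mean(axis=0, keepdims=True)
    for k in range(1, cap + 1):
        if k == 1:
            centroids = pts.mean(axis=0, keepdims=True)
            labels = np.zeros(n, dtype=int)
        else:
            n_init = 10 if n <= 10 else 1
            km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(pts)
            centroids = km.cluster_centers_
            labels = km.labels_.astype(int)
        dmax_km = haversine_km(
            lats, lons, centroids[labels, 0], centroids[labels, 1], validate=False
        ).max()
        if dmax_km * 1000.0 < merge_radius_m:
            break

    k = centroids.shape[0]
    total = dwell_s.sum()
    if total > 0:
        frac = np.bincount(labels, weights=dwell_s, minlength=k) / total
    else:
        frac = np.bincount(labels, minlength=k).astype(float) / n
    return PlaceClusterSet(k, centroids, labels, frac)


def dwell_entropy(dwell_fraction: Sequence[float]) -> float:
    """Shannon entropy (nats) of the dwell-fraction distribution."""
    p = np.asarray(dwell_fraction, dtype=float)
    p = p[p > 0]
    if p.size == 0:
        return 0.0
    return float(-(p * np.log(p)).sum())


@dataclass
class LocationFeatures:
    total_distance_km: float
    total_travel_time_min: float
    location_variance: float  # ln(var(lat) + var(lon) + eps)
    location_entropy: float  # nats, over significant-place dwell shares
    normalized_entropy: float  # entropy / ln k, 0 when k <= 1


def compute_location_features(
    times, lats, lons, *, seed: int = 0, threshold_kmh: float = SPEED_THRESHOLD_KMH
) -> LocationFeatures:
    """All five location features for one day's GPS stream.

    Raises :class:`InsufficientDataError` for fewer than two fixes;
    callers record the day as missing (never imputed).
    """
    ts = _times_to_seconds(times)
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    if ts.size < 2:
        raise InsufficientDataError("need at least 2 GPS points for a day")
    _check_coords(lats, lons)

    speeds = estimate_speeds(ts, lats, lons)
    moving = classify_segments(speeds, threshold_kmh)
    dt_min = np.diff(ts) / 60.0
    dist = haversine_km(lats[:-1], lons[:-1], lats[1:], lons[1:], validate=False)

    total_distance = float(dist[moving].sum())
    total_travel_time = float(dt_min[moving].sum())
    location_variance = float(np.log(lats.var() + lons.var() + VARIANCE_EPS))

    # Stationary intervals: dwell time of each is attributed to the
    # cluster of its leading point.
    stat = ~moving
    s_lat, s_lon = lats[:-1][stat], lons[:-1][stat]
    s_dwell = (dt_min[stat] * 60.0)
    clusters = cluster_places(s_lat, s_lon, s_dwell, seed=seed)
    entropy = dwell_entropy(clusters.dwell_fraction)
    norm = entropy / np.log(clusters.k) if clusters.k > 1 else 0.0

    return LocationFeatures(
        total_distance_km=total_distance,
        total_travel_time_min=total_travel_time,
        location_variance=location_variance,
        location_entropy=entropy,
        normalized_entropy=float(norm),
    )
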