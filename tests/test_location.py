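"""Location phenotypes: distances, speeds, place clustering, entropy."""
import itertools

import numpy as np
import pytest

from digiphen.errors import InsufficientDataError, ValidationError
from digiphen.location import (
    classify_segments,
    cluster_places,
    compute_location_features,
    dwell_entropy,
    estimate_speeds,
    haversine_km,
)

DEG_KM = 111.19492664455873  # 2*pi*6371/360


def _times(n, step_min=30.0, start="2025-03-03"):
    t0 = np.datetime64(start)
    return t0 + (np.arange(n) * step_min * 60).astype("timedelta64[s]")


class TestHaversine:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((10.0, 20.0), (10.0, 20.0), 0.0),
            ((0.0, 0.0), (0.0, 1.0), DEG_KM),  # one degree of arc on the equator
            ((0.0, 0.0), (0.0, 180.0), np.pi * 6371.0),  # antipodal
        ],
    )
    def test_closed_form(self, a, b, expected):
        assert haversine_km(a[0], a[1], b[0], b[1]) == pytest.approx(expected, rel=1e-9)

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        lat1, lat2 = rng.uniform(-80, 80, 2)
        lon1, lon2 = rng.uniform(-170, 170, 2)
        assert haversine_km(lat1, lon1, lat2, lon2) == pytest.approx(
            haversine_km(lat2, lon2, lat1, lon1)
        )

    @pytest.mark.parametrize("lat, lon", [(91.0, 0.0), (-90.5, 0.0), (0.0, 200.0), (np.nan, 0.0)])
    def test_rejects_out_of_range(self, lat, lon):
        with pytest.raises(ValidationError):
            haversine_km(lat, lon, 0.0, 0.0)


class TestSpeeds:
    def test_stationary_pair_zero_speed(self):
        s = estimate_speeds(_times(2, 10), [37.5, 37.5], [127.0, 127.0])
        assert s.tolist() == [0.0]

    def test_one_degree_per_hour(self):
        s = estimate_speeds(_times(2, 60), [0.0, 0.0], [0.0, 1.0])
        assert s[0] == pytest.approx(DEG_KM, rel=1e-9)

    def test_single_point_empty(self):
        assert estimate_speeds(_times(1), [0.0], [0.0]).size == 0

    def test_duplicate_timestamps_rejected(self):
        t = _times(2, 0.0)
        with pytest.raises(ValidationError):
            estimate_speeds(t, [0.0, 0.0], [0.0, 1.0])


class TestClassify:
    def test_threshold_rule(self):
        assert classify_segments([0.5, 1.5]).tolist() == [False, True]

    def test_exactly_at_threshold_is_moving(self):
        assert classify_segments([1.0]).tolist() == [True]

    def test_all_zero_all_stationary(self):
        assert not classify_segments(np.zeros(5)).any()

    def test_negative_speed_rejected(self):
        with pytest.raises(ValidationError):
            classify_segments([-0.1])


class TestClusterPlaces:
    def test_single_tight_place(self):
        rng = np.random.default_rng(1)
        lat = 37.55 + rng.normal(0, 5e-5, 40)  # ~ 5 m jitter
        lon = 127.0 + rng.normal(0, 5e-5, 40)
        cs = cluster_places(lat, lon, np.ones(40), seed=0)
        assert cs.k == 1
        assert cs.dwell_fraction.tolist() == [1.0]

    def test_two_separated_clouds_equal_dwell(self):
        rng = np.random.default_rng(2)
        lat = np.concatenate([37.50 + rng.normal(0, 1e-4, 50), 37.545 + rng.normal(0, 1e-4, 50)])
        lon = np.full(100, 127.0) + rng.normal(0, 1e-4, 100)
        cs = cluster_places(lat, lon, np.ones(100), seed=0)
        assert cs.k == 2
        assert sorted(cs.dwell_fraction.tolist()) == pytest.approx([0.5, 0.5])

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        lat = 37.5 + rng.normal(0, 0.01, 60)
        lon = 127.0 + rng.normal(0, 0.01, 60)
        a = cluster_places(lat, lon, seed=7)
        b = cluster_places(lat, lon, seed=7)
        assert np.array_equal(a.centroids, b.centroids)
        assert np.array_equal(a.labels, b.labels)

    def test_no_points_gives_empty_sentinel(self):
        cs = cluster_places([], [])
        assert cs.is_empty and cs.k == 0

    def test_matches_exhaustive_minimum_wcss(self):
        # on <= 8 points the chosen-k assignment must reach the global
        # minimum within-cluster sum of squares found by enumeration
        rng = np.random.default_rng(4)
        for trial in range(5):
            n = int(rng.integers(4, 9))
            lat = 37.5 + rng.normal(0, 0.02, n)
            lon = 127.0 + rng.normal(0, 0.02, n)
            cs = cluster_places(lat, lon, np.ones(n), seed=trial)
            pts = np.column_stack([lat, lon])

            def wcss(labels, k):
                tot = 0.0
                for c in range(k):
                    sub = pts[np.asarray(labels) == c]
                    if len(sub):
                        tot += ((sub - sub.mean(axis=0)) ** 2).sum()
                return tot

            best = min(
                wcss(lab, cs.k)
                for lab in itertools.product(range(cs.k), repeat=n)
                if len(set(lab)) == cs.k
            )
            assert wcss(cs.labels, cs.k) == pytest.approx(best, rel=1e-9, abs=1e-12)


class TestLocationFeatures:
    def test_motionless_day(self):
        f = compute_location_features(_times(10), np.full(10, 37.5), np.full(10, 127.0))
        assert f.total_distance_km == 0.0
        assert f.total_travel_time_min == 0.0
        assert f.location_entropy == 0.0
        assert f.normalized_entropy == 0.0

    def test_two_equal_places_max_entropy(self):
        # half the day at each of two places 5 km apart; the single
        # transition interval is moving and carries no dwell
        n = 48
        lat = np.concatenate([np.full(24, 37.500), np.full(24, 37.545)])
        lon = np.full(n, 127.0)
        f = compute_location_features(_times(n, 30), lat, lon)
        assert f.location_entropy == pytest.approx(np.log(2), abs=1e-9)
        assert f.normalized_entropy == pytest.approx(1.0, abs=1e-9)

    def test_skewed_dwell_entropy_value(self):
        assert dwell_entropy([0.9, 0.1]) == pytest.approx(0.3251, abs=5e-5)

    def test_insufficient_data_sentinel(self):
        with pytest.raises(InsufficientDataError):
            compute_location_features(_times(1), [37.5], [127.0])

    def test_invariants_on_random_days(self):
        rng = np.random.default_rng(5)
        day_span_min = 1440.0
        for trial in range(15):
            n = int(rng.integers(5, 80))
            t = np.datetime64("2025-03-03") + np.sort(
                rng.choice(np.arange(1, 86400), size=n, replace=False)
            ).astype("timedelta64[s]")
            lat = 37.5 + rng.normal(0, 0.02, n)
            lon = 127.0 + rng.normal(0, 0.02, n)
            f = compute_location_features(t, lat, lon, seed=trial)
            speeds = estimate_speeds(t, lat, lon)
            moving = classify_segments(speeds)
            stat_pts = int((~moving).sum())
            assert f.total_travel_time_min <= day_span_min
            assert f.total_distance_km >= 0
            assert 0.0 <= f.normalized_entropy <= 1.0
            if stat_pts:
                k_max = min(10, stat_pts)
                assert -1e-12 <= f.location_entropy <= np.log(max(k_max, 2)) + 1e-9
            assert int(moving.sum()) + stat_pts == n - 1

    def test_longitude_translation_invariance(self):
        rng = np.random.default_rng(6)
        n = 40
        t = _times(n, 20)
        lat = 37.5 + rng.normal(0, 0.01, n)
        lon = 127.0 + rng.normal(0, 0.01, n)
        f0 = compute_location_features(t, lat, lon, seed=1)
        f1 = compute_location_features(t, lat, lon + 5.0, seed=1)
        assert f1.total_distance_km == pytest.approx(f0.total_distance_km, rel=1e-6)
        assert f1.location_entropy == pytest.approx(f0.location_entropy, rel=1e-6)
        assert f1.location_variance == pytest.approx(f0.location_variance, rel=1e-6)
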