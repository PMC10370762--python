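"""Splicing: similarity, haversine, gate thresholds, weekly counting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glstm.dataio import CheckinRecord, POIRecord, TileID, tile_bounds
from glstm.splice import (
    SpliceParams,
    build_feature_vectors,
    haversine_km,
    match_checkin,
    similarity,
    tokenize,
    weekly_visit_frequency,
)
from glstm.synthetic import generate_checkins_for_poi


def brute_cosine10(p: dict, n: dict) -> float:
    vocab = set(p) | set(n)
    dot = sum(p.get(t, 0) * n.get(t, 0) for t in vocab)
    np_ = math.sqrt(sum(v * v for v in p.values()))
    nn = math.sqrt(sum(v * v for v in n.values()))
    return 0.0 if np_ * nn == 0 else 10.0 * dot / (np_ * nn)


class TestSimilarity:
    def test_identical_vectors_score_ten(self):
        v = {"burger": 2, "fries": 1}
        assert similarity(v, v) == pytest.approx(10.0)

    def test_disjoint_support_scores_zero(self):
        assert similarity({"a": 1}, {"b": 3}) == 0.0

    def test_matches_hand_computed_dot_product(self):
        # p=(1,1,0), n=(1,0,0) -> 10/sqrt(2)
        assert similarity(np.array([1, 1, 0]), np.array([1, 0, 0])) == pytest.approx(
            10.0 / math.sqrt(2.0), abs=1e-12
        )

    def test_zero_vector_gives_zero(self):
        assert similarity({}, {"a": 1}) == 0.0

    def test_negative_frequencies_rejected(self):
        with pytest.raises(ValueError):
            similarity(np.array([-1.0, 2.0]), np.array([1.0, 1.0]))

    @given(
        st.dictionaries(st.sampled_from("abcdef"), st.integers(0, 5), max_size=6),
        st.dictionaries(st.sampled_from("abcdef"), st.integers(0, 5), max_size=6),
    )
    @settings(max_examples=100, deadline=None)
    def test_equals_oracle_and_is_symmetric(self, p, n):
        s = similarity(p, n)
        assert s == pytest.approx(brute_cosine10(p, n), abs=1e-12)
        assert s == pytest.approx(similarity(n, p), abs=1e-12)
        assert 0.0 <= s <= 10.0 + 1e-12

    def test_scale_invariance(self):
        p = {"a": 1, "b": 2}
        n = {"a": 3, "c": 1}
        scaled = {k: 7 * v for k, v in p.items()}
        assert similarity(scaled, n) == pytest.approx(similarity(p, n), abs=1e-12)


class TestHaversine:
    def test_coincident_points(self):
        assert haversine_km((12.3, 45.6), (12.3, 45.6)) == 0.0

    def test_one_degree_along_equator(self):
        # closed-form arc: R * pi / 180
        assert haversine_km((0.0, 0.0), (0.0, 1.0)) == pytest.approx(
            6371.0 * math.pi / 180.0, abs=1e-3
        )

    def test_symmetry_and_triangle_inequality_random(self):
        rng = np.random.default_rng(11)
        pts = np.column_stack(
            [rng.uniform(-80, 80, 300), rng.uniform(-180, 180, 300)]
        )
        for a, b, c in pts.reshape(-1, 3, 2):
            ab = haversine_km(tuple(a), tuple(b))
            ba = haversine_km(tuple(b), tuple(a))
            assert ab == pytest.approx(ba, abs=1e-12)
            assert ab <= haversine_km(tuple(a), tuple(c)) + haversine_km(tuple(c), tuple(b)) + 1e-9


class TestTokenize:
    def test_lowercase_split_and_counts(self):
        assert tokenize("A nice Burger; burger time!") == {
            "a": 1, "nice": 1, "burger": 2, "time": 1,
        }


def _checkin(lat, lng, text, week_ts="2020-01-07T12:00:00+00:00"):
    from datetime import datetime

    return CheckinRecord(
        checkin_id="c1",
        user_id="u1",
        timestamp=datetime.fromisoformat(week_ts),
        lat=lat,
        lng=lng,
        text_tokens=text,
    )


class TestMatchCheckin:
    def test_single_qualifying_candidate(self, demo_poi):
        c = _checkin(demo_poi.lat, demo_poi.lng, {"burger": 1, "fries": 1})
        assert match_checkin(c, [demo_poi]) == demo_poi.poi_id

    def test_similarity_at_threshold_is_excluded(self, demo_poi):
        c = _checkin(demo_poi.lat, demo_poi.lng, {"burger": 1, "fries": 1})
        s = 10.0 * 2 / (math.sqrt(2) * math.sqrt(5))
        params = SpliceParams(sim_threshold=s)  # gate is strictly >
        assert match_checkin(c, [demo_poi], params) is None

    def test_highest_similarity_wins(self, demo_poi):
        other = POIRecord(
            poi_id="poi-weak",
            lat=demo_poi.lat,
            lng=demo_poi.lng,
            tile=demo_poi.tile,
            description_tokens={"burger": 1, "x": 1, "y": 1, "z": 1, "w": 1},
            categories=("A8",),
        )
        c = _checkin(demo_poi.lat, demo_poi.lng, {"burger": 1, "fries": 1, "combo": 1})
        assert match_checkin(c, [other, demo_poi]) == demo_poi.poi_id

    def test_empty_candidates_return_none(self, demo_poi):
        c = _checkin(demo_poi.lat, demo_poi.lng, {"burger": 1})
        assert match_checkin(c, []) is None


class TestWeeklyFrequency:
    def test_full_match_stream_sums_to_n(self, demo_poi):
        stream = generate_checkins_for_poi(demo_poi, 10, 1.0, 2.0, seed=5, n_weeks=4)
        f = weekly_visit_frequency(demo_poi, stream, n_weeks=4)
        assert f.sum() == 10

    def test_no_match_stream_sums_to_zero(self, demo_poi):
        stream = generate_checkins_for_poi(demo_poi, 10, 0.0, 2.0, seed=5, n_weeks=4)
        assert weekly_visit_frequency(demo_poi, stream, n_weeks=4).sum() == 0

    def test_half_match_stream(self, demo_poi):
        stream = generate_checkins_for_poi(demo_poi, 20, 0.5, 5.0, seed=9, n_weeks=6)
        assert weekly_visit_frequency(demo_poi, stream, n_weeks=6).sum() == 10

    def test_distance_exactly_at_gate_excluded(self, demo_poi):
        # place a check-in exactly 3.00 km east (numerically just on the gate)
        dlng = 3.0 / (111.195 * math.cos(math.radians(demo_poi.lat)))
        c = _checkin(demo_poi.lat, demo_poi.lng + dlng, dict(demo_poi.description_tokens))
        d = haversine_km((demo_poi.lat, demo_poi.lng), (c.lat, c.lng))
        params = SpliceParams(dist_threshold_km=d)  # gate is strictly <
        assert weekly_visit_frequency(demo_poi, [c], params, n_weeks=2).sum() == 0

    def test_adding_one_qualifying_checkin_increments_one_week(self, demo_poi):
        stream = generate_checkins_for_poi(demo_poi, 8, 0.5, 2.0, seed=3, n_weeks=5)
        base = weekly_visit_frequency(demo_poi, stream, n_weeks=5)
        extra = generate_checkins_for_poi(demo_poi, 1, 1.0, 1.0, seed=4, n_weeks=5)[0]
        bumped = weekly_visit_frequency(demo_poi, stream + [extra], n_weeks=5)
        diff = bumped - base
        assert diff.sum() == 1 and (diff >= 0).all()
        assert diff[extra.week - 1] == 1


class TestFeatureVectors:
    def test_corner_and_center_scaling(self, demo_poi):
        lat_min, lat_max, lng_min, lng_max = tile_bounds(demo_poi.tile)
        sw = POIRecord(
            poi_id="a-sw", lat=lat_min, lng=lng_min, tile=demo_poi.tile,
            description_tokens={"x": 1}, categories=("A1",),
        )
        center = POIRecord(
            poi_id="b-center",
            lat=(lat_min + lat_max) / 2, lng=(lng_min + lng_max) / 2,
            tile=demo_poi.tile, description_tokens={"y": 1}, categories=("A2",),
        )
        fv = build_feature_vectors([sw, center], [], tile=demo_poi.tile, n_weeks=3)
        assert (fv[0].scaled_lat, fv[0].scaled_lng) == (0.0, 0.0)
        assert fv[1].scaled_lat == pytest.approx(5.0)
        assert fv[1].scaled_lng == pytest.approx(5.0)

    def test_frequency_matrix_equals_independent_recount(self, demo_poi):
        params = SpliceParams()
        stream = generate_checkins_for_poi(demo_poi, 30, 0.6, 4.0, seed=21, n_weeks=5)
        fv = build_feature_vectors([demo_poi], stream, params, tile=demo_poi.tile, n_weeks=5)
        # five-line brute-force oracle
        expected = np.zeros(5, dtype=int)
        for c in stream:
            s = brute_cosine10(demo_poi.description_tokens, c.text_tokens)
            d = haversine_km((demo_poi.lat, demo_poi.lng), (c.lat, c.lng))
            if s > 3.5 and d < 3.0 and 1 <= c.week <= 5:
                expected[c.week - 1] += 1
        assert np.array_equal(fv[0].weekly_frequency, expected)

    def test_degenerate_bbox_scales_to_zero(self, demo_poi):
        fv = build_feature_vectors([demo_poi], [], tile=None, n_weeks=2)
        assert (fv[0].scaled_lat, fv[0].scaled_lng) == (0.0, 0.0)
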