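"""Generator determinism, planted-signal consistency, gate controllability."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from glstm.dataio import CATEGORIES
from glstm.splice import SpliceParams, haversine_km, similarity, splice_checkins
from glstm.synthetic import (
    SyntheticWorld,
    WorldConfig,
    generate_checkins_for_poi,
    generate_world,
    write_fixtures,
)


def world_equal(a: SyntheticWorld, b: SyntheticWorld) -> bool:
    if len(a.pois) != len(b.pois) or len(a.checkins) != len(b.checkins):
        return False
    for pa, pb in zip(a.pois, b.pois):
        if (pa.poi_id, pa.lat, pa.lng, pa.description_tokens) != (
            pb.poi_id, pb.lat, pb.lng, pb.description_tokens
        ):
            return False
    for ca, cb in zip(a.checkins, b.checkins):
        if (ca.checkin_id, ca.lat, ca.lng, ca.timestamp, ca.text_tokens) != (
            cb.checkin_id, cb.lat, cb.lng, cb.timestamp, cb.text_tokens
        ):
            return False
    return a.true_tile_score == b.true_tile_score and a.true_tile_risk == b.true_tile_risk


SMALL = dict(n_tiles=6, pois_per_tile=10, n_users=30, n_cases=12, n_weeks=4)


class TestGenerateWorld:
    def test_same_seed_gives_identical_worlds(self):
        cfg = WorldConfig(**SMALL, seed=42)
        assert world_equal(generate_world(cfg), generate_world(cfg))

    def test_different_seeds_differ(self):
        a = generate_world(WorldConfig(**SMALL, seed=1))
        b = generate_world(WorldConfig(**SMALL, seed=2))
        assert not world_equal(a, b)

    def test_zero_weights_zero_noise_give_zero_scores(self):
        cfg = WorldConfig(**SMALL, seed=5, category_weights=(0.0,) * 10, noise_sd=0.0)
        w = generate_world(cfg)
        assert all(v == 0.0 for v in w.true_tile_score.values())
        assert all(v == 0 for v in w.true_tile_risk.values())

    def test_every_tile_has_pois(self):
        w = generate_world(WorldConfig(**SMALL, seed=3))
        tiles_with_pois = {p.tile for p in w.pois}
        assert set(w.true_tile_risk) <= tiles_with_pois

    def test_pois_fall_inside_their_tile(self):
        from glstm.dataio import tile_bounds

        w = generate_world(WorldConfig(**SMALL, seed=3))
        for p in w.pois:
            lat_min, lat_max, lng_min, lng_max = tile_bounds(p.tile)
            assert lat_min <= p.lat <= lat_max
            assert lng_min <= p.lng <= lng_max

    def test_labels_threshold_the_scores(self):
        cfg = WorldConfig(**SMALL, seed=8, noise_sd=0.5)
        w = generate_world(cfg)
        for t, score in w.true_tile_score.items():
            assert w.true_tile_risk[t] == int(score > cfg.risk_threshold)

    def test_planted_score_matches_brute_force_recount(self):
        # independent pass: re-splice the emitted records and redo the dot product
        cfg = WorldConfig(**SMALL, seed=11, noise_sd=0.0)
        w = generate_world(cfg)
        params = SpliceParams()
        poi_by_id = {p.poi_id: p for p in w.pois}
        counts = {t: np.zeros(10) for t in w.true_tile_risk}
        for c in w.checkins:
            best = None
            for p in w.pois:
                s = similarity(p.description_tokens, c.text_tokens)
                d = haversine_km((p.lat, p.lng), (c.lat, c.lng))
                from glstm.dataio import tile_index

                if s > params.sim_threshold and d < params.dist_threshold_km \
                        and tile_index(c.lat, c.lng, p.tile.z) == p.tile:
                    key = (-s, d, p.poi_id)
                    if best is None or key < best:
                        best = key
            if best is not None:
                p = poi_by_id[best[2]]
                counts[p.tile][CATEGORIES.index(p.categories[0])] += 1
        weights = np.asarray(cfg.category_weights)
        for t in w.true_tile_risk:
            score = float(weights @ (counts[t] / cfg.n_weeks))
            assert score == pytest.approx(w.true_tile_score[t], abs=1e-9)
            assert w.true_tile_risk[t] == int(score > cfg.risk_threshold)

    def test_risky_tiles_score_higher_with_planted_weights(self):
        cfg = WorldConfig(n_tiles=10, pois_per_tile=20, n_users=50, n_cases=20,
                          n_weeks=6, seed=17,
                          category_weights=(0, 0, 0, 0, 0, 0, 0, 1.0, 0, 0))
        w = generate_world(cfg)
        # rank correlation of score vs the tile's A8 spliced frequency is exact
        splice_checkins(w.checkins, w.pois)
        poi_by_id = {p.poi_id: p for p in w.pois}
        freq = {t: 0.0 for t in w.true_tile_risk}
        for c in w.checkins:
            if c.matched_poi and poi_by_id[c.matched_poi].categories[0] == "A8":
                freq[poi_by_id[c.matched_poi].tile] += 1.0 / cfg.n_weeks
        tiles = sorted(w.true_tile_risk)
        rho = spearmanr([w.true_tile_score[t] for t in tiles], [freq[t] for t in tiles])[0]
        assert rho == pytest.approx(1.0)

    def test_record_stream_invariant_to_noise_sd(self):
        a = generate_world(WorldConfig(**SMALL, seed=21, noise_sd=0.0))
        b = generate_world(WorldConfig(**SMALL, seed=21, noise_sd=2.0))
        assert [c.checkin_id for c in a.checkins] == [c.checkin_id for c in b.checkins]
        assert a.noiseless_tile_score == b.noiseless_tile_score

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            WorldConfig(n_tiles=1)
        with pytest.raises(ValueError):
            WorldConfig(bbox=(90.0, 95.0, 0.0, 1.0))
        with pytest.raises(ValueError):
            WorldConfig(category_weights=(1.0,) * 9)
        with pytest.raises(ValueError):
            WorldConfig(noise_sd=-0.5)


class TestGenerateCheckinsForPoi:
    @pytest.mark.parametrize("n,frac,expected", [(10, 1.0, 10), (10, 0.0, 0), (20, 0.5, 10)])
    def test_pass_count_is_exact(self, demo_poi, n, frac, expected):
        stream = generate_checkins_for_poi(demo_poi, n, frac, 5.0, seed=2, n_weeks=4)
        params = SpliceParams()
        passing = sum(
            1
            for c in stream
            if similarity(demo_poi.description_tokens, c.text_tokens) > params.sim_threshold
            and haversine_km((demo_poi.lat, demo_poi.lng), (c.lat, c.lng)) < params.dist_threshold_km
        )
        assert passing == expected
        assert len(stream) == n

    def test_zero_records(self, demo_poi):
        assert generate_checkins_for_poi(demo_poi, 0, 1.0, 1.0, seed=1) == []

    def test_negative_offset_rejected(self, demo_poi):
        with pytest.raises(ValueError):
            generate_checkins_for_poi(demo_poi, 5, 0.5, -1.0, seed=1)

    def test_small_offset_forces_text_violations(self, demo_poi):
        # with max_offset_km < 3 the non-matching records must fail on text
        stream = generate_checkins_for_poi(demo_poi, 12, 0.25, 1.0, seed=6, n_weeks=3)
        fails = [
            c for c in stream
            if similarity(demo_poi.description_tokens, c.text_tokens) <= 3.5
        ]
        assert len(fails) == 9


class TestWriteFixtures:
    def test_round_trip_counts_and_determinism(self, tmp_path):
        cfg = WorldConfig(n_tiles=3, pois_per_tile=10, n_users=20, n_cases=6,
                          n_weeks=3, seed=31)
        w = generate_world(cfg)
        m1 = write_fixtures(w, tmp_path / "a")
        m2 = write_fixtures(generate_world(cfg), tmp_path / "b")
        assert m1 == m2  # byte-identical checksums for identical seeds
        assert set(m1) == {"pois.geojson", "checkins.jsonl", "cases.csv", "truth.csv"}
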