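"""Self-contained synthetic world: tiles, venues, check-in streams, cases.

The generator emulates the structure of a geotagged social-media corpus
joined to an open-map POI extract: venues cluster inside slippy tiles with
one of ten food-access categories; check-in texts are drawn from a closed
food vocabulary so that text similarity against the target venue is
controllable; timestamps bin into weeks from Monday 2020-01-06; and
diagnosed-case profiles carry weekly per-category visit counts.

The risk signal is planted at the tile level: half the tiles are "risky" and
emit more check-ins in the heavily weighted categories.  Each tile's true
score is the dot product of the category weight vector with the tile's mean
weekly per-category spliced check-in frequency (recomputed from the emitted
records, so the stored truth is exactly what a brute-force pass recovers),
plus optional Gaussian noise; the binary label thresholds that score.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from datetime import timedelta
from pathlib import Path

import numpy as np

from .dataio import (
    CATEGORIES,
    CATEGORY_NAMES,
    MAX_MERCATOR_LAT,
    CaseProfile,
    CheckinRecord,
    POIRecord,
    TileID,
    tile_bounds,
    tiles_in_bbox,
    week_start,
    write_cases,
    write_checkins,
    write_pois,
    write_truth,
)
from .splice import SpliceParams, haversine_km, similarity, splice_checkins

# closed vocabulary: six tokens per category (pairwise disjoint) plus a small
# shared pool, so cross-category text similarity stays below the 3.5 gate
CATEGORY_VOCAB = {
    "A1": ["corner", "discount", "ration", "bodega", "outlet", "surplus"],
    "A2": ["grocery", "produce", "aisle", "cart", "checkout", "pantry"],
    "A3": ["supercenter", "bulk", "warehouse", "mega", "hypermarket", "pallet"],
    "A4": ["club", "membership", "wholesale", "crate", "caselot", "bundle"],
    "A5": ["convenience", "snack", "soda", "counter", "kiosk", "express"],
    "A6": ["bakery", "butcher", "cheese", "deli", "spice", "seafood"],
    "A7": ["restaurant", "waiter", "menu", "entree", "reservation", "bistro"],
    "A8": ["burger", "fries", "drive", "combo", "nuggets", "shake"],
    "A9": ["cafeteria", "lunchroom", "tray", "student", "canteen", "recess"],
    "A10": ["farm", "orchard", "stand", "harvest", "pickyourown", "csa"],
}
COMMON_VOCAB = ["fresh", "local", "family", "daily"]
# off-topic chatter used by check-ins that must fail the similarity gate
CHATTER_VOCAB = ["traffic", "meeting", "game", "weather", "music", "news", "movie", "work"]


@dataclass
class WorldConfig:
    """Knobs of the synthetic world.

    The defaults are a desk-scale analogue of a multi-state corpus: 60 tiles
    of 20 venues each observed over 12 weeks, with the planted risk weight
    concentrated on supercenters (A3), convenience stores (A5) and fast-food
    restaurants (A8) — the venue types that dominate weekly food access in
    the source populations.
    """

    n_tiles: int = 60
    pois_per_tile: int = 20
    n_users: int = 500
    n_cases: int = 120
    n_weeks: int = 12
    category_weights: tuple = (0.0, 0.0, 0.3, 0.0, 0.3, 0.0, 0.0, 0.4, 0.0, 0.0)
    risk_threshold: float = 3.7
    noise_sd: float = 0.0
    bbox: tuple = (40.5, 44.5, -79.0, -72.0)
    zoom: int = 10
    seed: int = 0
    # emission rates (check-ins per tile-category-week); risky tiles add
    # ``risk_boost`` split across categories in proportion to their weight
    base_rate: float = 2.0
    risk_boost: float = 10.0
    chatter_fraction: float = 0.25
    case_visits_per_week: float = 4.0

    def __post_init__(self):
        if self.n_tiles < 2:
            raise ValueError("need at least 2 tiles")
        if self.n_weeks < 2:
            raise ValueError("need at least 2 weeks")
        if min(self.n_tiles, self.pois_per_tile, self.n_users, self.n_cases) <= 0:
            raise ValueError("all counts must be positive")
        lat_min, lat_max, lng_min, lng_max = self.bbox
        if not (-MAX_MERCATOR_LAT < lat_min < lat_max < MAX_MERCATOR_LAT):
            raise ValueError("bbox latitudes must be increasing and inside Mercator range")
        if not (lng_min < lng_max):
            raise ValueError("bbox longitudes must be increasing")
        if len(self.category_weights) != len(CATEGORIES):
            raise ValueError("category_weights must have 10 entries")
        if any(w < 0 for w in self.category_weights):
            raise ValueError("category_weights must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class SyntheticWorld:
    """Everything downstream stages consume, plus the planted truth."""

    config: WorldConfig
    pois: list[POIRecord]
    checkins: list[CheckinRecord]
    cases: list[CaseProfile]
    true_tile_risk: dict[TileID, int]
    true_tile_score: dict[TileID, float]
    noiseless_tile_score: dict[TileID, float] = field(default_factory=dict)

    @property
    def tiles(self) -> list[TileID]:
        return sorted(self.true_tile_risk)


# ---------------------------------------------------------------------------
# low-level samplers
# ---------------------------------------------------------------------------

def _sample_description(category: str, rng: np.random.Generator) -> dict[str, int]:
    toks = list(rng.choice(CATEGORY_VOCAB[category], size=4, replace=False))
    toks.append(str(rng.choice(COMMON_VOCAB)))
    return {t: 1 for t in toks}


def _point_in_disk_and_tile(
    poi: POIRecord, radius_km: float, rng: np.random.Generator
) -> tuple[float, float]:
    """Uniform point within ``radius_km`` of the venue and inside its tile."""
    lat_min, lat_max, lng_min, lng_max = tile_bounds(poi.tile)
    for _ in range(50):
        r = radius_km * math.sqrt(rng.uniform())
        theta = rng.uniform(0.0, 2.0 * math.pi)
        dlat = (r / 111.195) * math.cos(theta)
        dlng = (r / (111.195 * math.cos(math.radians(poi.lat)))) * math.sin(theta)
        lat, lng = poi.lat + dlat, poi.lng + dlng
        if (lat_min < lat < lat_max and lng_min < lng < lng_max
                and haversine_km((poi.lat, poi.lng), (lat, lng)) < radius_km):
            return lat, lng
    return poi.lat, poi.lng  # corner venue: collapse onto the venue itself


def _matching_text(poi: POIRecord, rng: np.random.Generator) -> dict[str, int]:
    """Text sharing >= 60% of the venue's description tokens (cosine > 0.35)."""
    desc = sorted(poi.description_tokens)
    k = max(2, math.ceil(0.6 * len(desc)))
    toks = list(rng.choice(desc, size=k, replace=False))
    return {t: 1 for t in toks}


def _chatter_text(rng: np.random.Generator) -> dict[str, int]:
    toks = rng.choice(CHATTER_VOCAB, size=3, replace=False)
    return {t: 1 for t in toks}


def _timestamp_in_week(week: int, rng: np.random.Generator):
    return week_start(week) + timedelta(seconds=float(rng.uniform(0, 7 * 24 * 3600)))


def generate_checkins_for_poi(
    poi: POIRecord,
    n: int,
    match_fraction: float,
    max_offset_km: float,
    seed: int,
    n_weeks: int = 52,
    id_prefix: str = "c",
) -> list[CheckinRecord]:
    """Check-in stream for one venue with a controlled pass rate.

    Exactly ``round(n * match_fraction)`` records pass BOTH splicing gates
    (similarity > 3.5 and distance < 3 km) against ``poi``; the rest violate
    at least one gate — off-topic text, a position pushed beyond 3 km when
    ``max_offset_km`` allows it, or both.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    if not (0.0 <= match_fraction <= 1.0):
        raise ValueError("match_fraction must lie in [0, 1]")
    if max_offset_km < 0:
        raise ValueError("max_offset_km must be nonnegative")
    rng = np.random.default_rng(seed)
    params = SpliceParams()
    n_match = round(n * match_fraction)
    out: list[CheckinRecord] = []
    for i in range(n):
        week = int(rng.integers(1, n_weeks + 1))
        if i < n_match:
            text = _matching_text(poi, rng)
            radius = min(max_offset_km, 0.97 * params.dist_threshold_km)
            lat, lng = _point_in_disk_and_tile(poi, radius, rng)
            assert similarity(poi.description_tokens, text) > params.sim_threshold
        else:
            mode = ["text", "dist", "both"][int(rng.integers(3))]
            if max_offset_km <= params.dist_threshold_km:
                mode = "text"
            if mode in ("text", "both"):
                text = _chatter_text(rng)
            else:
                text = _matching_text(poi, rng)
            if mode in ("dist", "both"):
                r = rng.uniform(1.05 * params.dist_threshold_km,
                                max(1.3 * params.dist_threshold_km, max_offset_km))
                theta = rng.uniform(0.0, 2.0 * math.pi)
                lat = poi.lat + (r / 111.195) * math.cos(theta)
                lng = poi.lng + (r / (111.195 * math.cos(math.radians(poi.lat)))) * math.sin(theta)
            else:
                lat, lng = _point_in_disk_and_tile(poi, 0.97 * params.dist_threshold_km, rng)
        out.append(
            CheckinRecord(
                checkin_id=f"{id_prefix}{poi.poi_id}-{i}",
                user_id=f"u{int(rng.integers(10_000))}",
                timestamp=_timestamp_in_week(week, rng),
                lat=float(lat),
                lng=float(lng),
                text_tokens=text,
            )
        )
    return out


# ---------------------------------------------------------------------------
# world generation
# ---------------------------------------------------------------------------

def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a deterministic world with a planted tile-level risk signal."""
    ss = np.random.SeedSequence(config.seed)
    rng_layout, rng_pois, rng_checkins, rng_cases, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    candidates = tiles_in_bbox(config.bbox, config.zoom)
    if len(candidates) < config.n_tiles:
        raise ValueError(
            f"bbox holds only {len(candidates)} tiles at zoom {config.zoom}; "
            f"{config.n_tiles} requested"
        )
    tiles = candidates[: config.n_tiles]
    # balanced risky/safe assignment
    order = rng_layout.permutation(config.n_tiles)
    risky = {tile: int(order[m] < config.n_tiles // 2) for m, tile in enumerate(tiles)}

    weights = np.asarray(config.category_weights, dtype=float)
    w_norm = weights / weights.sum() if weights.sum() > 0 else np.zeros_like(weights)

    # venues: categories round-robin over a per-tile shuffled order, so every
    # category present in every tile once pois_per_tile >= 10
    pois: list[POIRecord] = []
    pois_by_tile: dict[TileID, list[POIRecord]] = {t: [] for t in tiles}
    for m, tile in enumerate(tiles):
        lat_min, lat_max, lng_min, lng_max = tile_bounds(tile)
        cat_order = list(rng_pois.permutation(np.array(CATEGORIES)))
        for i in range(config.pois_per_tile):
            cat = str(cat_order[i % len(CATEGORIES)])
            lat = float(rng_pois.uniform(lat_min, lat_max))
            lng = float(rng_pois.uniform(lng_min, lng_max))
            poi = POIRecord(
                poi_id=f"poi-{tile.x}-{tile.y}-{i:03d}",
                lat=lat,
                lng=lng,
                tile=tile,
                name=f"{CATEGORY_NAMES[cat].title()} {i:03d}",
                description_tokens=_sample_description(cat, rng_pois),
                categories=(cat,),
                amenity=CATEGORY_NAMES[cat].replace(" ", "_"),
            )
            poi.validate()
            pois.append(poi)
            pois_by_tile[tile].append(poi)

    # check-in streams: per tile/category/week Poisson counts around venues
    # of that category, plus off-topic chatter that fails the text gate
    checkins: list[CheckinRecord] = []
    serial = 0
    for tile in tiles:
        by_cat: dict[str, list[POIRecord]] = {}
        for poi in pois_by_tile[tile]:
            by_cat.setdefault(poi.categories[0], []).append(poi)
        n_matched_tile = 0
        for j, cat in enumerate(CATEGORIES):
            rate = config.base_rate + risky[tile] * config.risk_boost * w_norm[j]
            cat_pois = by_cat.get(cat, [])
            if not cat_pois:
                continue
            for week in range(1, config.n_weeks + 1):
                for _ in range(int(rng_checkins.poisson(rate))):
                    poi = cat_pois[int(rng_checkins.integers(len(cat_pois)))]
                    lat, lng = _point_in_disk_and_tile(poi, 2.9, rng_checkins)
                    checkins.append(
                        CheckinRecord(
                            checkin_id=f"t{serial:07d}",
                            user_id=f"u{int(rng_checkins.integers(config.n_users)):05d}",
                            timestamp=_timestamp_in_week(week, rng_checkins),
                            lat=lat,
                            lng=lng,
                            text_tokens=_matching_text(poi, rng_checkins),
                        )
                    )
                    serial += 1
                    n_matched_tile += 1
        for _ in range(int(round(config.chatter_fraction * n_matched_tile))):
            poi = pois_by_tile[tile][int(rng_checkins.integers(len(pois_by_tile[tile])))]
            lat, lng = _point_in_disk_and_tile(poi, 2.9, rng_checkins)
            checkins.append(
                CheckinRecord(
                    checkin_id=f"t{serial:07d}",
                    user_id=f"u{int(rng_checkins.integers(config.n_users)):05d}",
                    timestamp=_timestamp_in_week(int(rng_checkins.integers(1, config.n_weeks + 1)), rng_checkins),
                    lat=lat,
                    lng=lng,
                    text_tokens=_chatter_text(rng_checkins),
                )
            )
            serial += 1

    # cases: tiles drawn uniformly; weekly category counts Poisson with rates
    # proportional to the planted weights (risky tiles visit more)
    cases: list[CaseProfile] = []
    for k in range(config.n_cases):
        tile = tiles[int(rng_cases.integers(len(tiles)))]
        weekly: dict[str, np.ndarray] = {}
        for j, cat in enumerate(CATEGORIES):
            rate = config.case_visits_per_week * (
                w_norm[j] if w_norm.sum() > 0 else 1.0 / len(CATEGORIES)
            ) * (1.0 + risky[tile])
            counts = rng_cases.poisson(max(rate, 0.2), size=config.n_weeks)
            if counts.any():
                weekly[cat] = counts.astype(int)
        case = CaseProfile(case_id=f"case-{k:04d}", tile=tile, weekly_counts=weekly)
        case.validate()
        cases.append(case)

    # planted truth, recomputed from the emitted records through the actual
    # splicing rule so that a brute-force pass reproduces it exactly
    splice_checkins(checkins, pois)
    poi_cat = {p.poi_id: p.categories[0] for p in pois}
    poi_tile = {p.poi_id: p.tile for p in pois}
    cat_counts = {t: np.zeros(len(CATEGORIES)) for t in tiles}
    for c in checkins:
        if c.matched_poi is not None:
            t = poi_tile[c.matched_poi]
            cat_counts[t][CATEGORIES.index(poi_cat[c.matched_poi])] += 1
    true_score: dict[TileID, float] = {}
    noiseless: dict[TileID, float] = {}
    true_risk: dict[TileID, int] = {}
    for tile in tiles:
        base = float(weights @ (cat_counts[tile] / config.n_weeks))
        eps = float(rng_noise.normal())  # drawn regardless of noise_sd so the
        # record stream is identical across noise settings
        score = base + config.noise_sd * eps
        noiseless[tile] = base
        true_score[tile] = score
        true_risk[tile] = int(score > config.risk_threshold)

    return SyntheticWorld(
        config=config,
        pois=pois,
        checkins=checkins,
        cases=cases,
        true_tile_risk=true_risk,
        true_tile_score=true_score,
        noiseless_tile_score=noiseless,
    )


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def write_fixtures(world: SyntheticWorld, out_dir) -> dict[str, str]:
    """Write pois.geojson, checkins.jsonl, cases.csv, truth.csv.

    Returns a manifest mapping file name to SHA-256 checksum; identical
    worlds produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_pois(world.pois, out / "pois.geojson")
    write_checkins(world.checkins, out / "checkins.jsonl")
    write_cases(world.cases, out / "cases.csv")
    write_truth(world, out / "truth.csv")
    manifest = {}
    for name in ("pois.geojson", "checkins.jsonl", "cases.csv", "truth.csv"):
        manifest[name] = hashlib.sha256((out / name).read_bytes()).hexdigest()
    return manifest
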