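"""Feature splicing: joining check-ins onto POIs and counting weekly visits.

A check-in is spliced onto a venue when its text is similar enough to the
venue description (cosine similarity on a 0-10 scale, strictly above 3.5) and
it was posted close enough (great-circle distance strictly below 3 km).
Spliced check-ins are binned into ISO-style weeks to give each POI a weekly
visit-frequency series, the temporal half of its feature vector.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np

from .dataio import CATEGORIES, CheckinRecord, POIRecord, tile_bounds

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

_TOKEN_RE = re.compile(r"[^0-9a-z]+")


def tokenize(text: str) -> dict[str, int]:
    """Lowercase, split on non-alphanumerics, return term frequencies."""
    counts: dict[str, int] = {}
    for tok in _TOKEN_RE.split(text.lower()):
        if tok:
            counts[tok] = counts.get(tok, 0) + 1
    return counts


@dataclass
class SpliceParams:
    """Thresholds of the splicing gates (strict inequalities)."""

    sim_threshold: float = 3.5
    dist_threshold_km: float = 3.0
    scale_max: float = 10.0

    def __post_init__(self):
        if self.sim_threshold <= 0 or self.dist_threshold_km <= 0:
            raise ValueError("thresholds must be positive")
        if self.sim_threshold >= self.scale_max:
            raise ValueError("sim_threshold must be below scale_max")


@dataclass
class PoiFeatureVector:
    """Per-POI node payload: scaled coordinates, category one-hot, weekly series."""

    poi_id: str
    scaled_lat: float
    scaled_lng: float
    category_onehot: np.ndarray
    weekly_frequency: np.ndarray

    def node_features(self, week: int) -> np.ndarray:
        """Feature row at week ``week`` (1-based): [lat, lng, one-hot, f_t]."""
        f = float(self.weekly_frequency[week - 1]) if 1 <= week <= len(self.weekly_frequency) else 0.0
        return np.concatenate(([self.scaled_lat, self.scaled_lng], self.category_onehot, [f]))


def similarity(p: dict[str, int] | np.ndarray, n: dict[str, int] | np.ndarray) -> float:
    """Description/text similarity: cosine of term-frequency vectors on [0, 10].

    The raw cosine is expressed as a percentage and rescaled by 0.1, i.e.
    ``10 * cos(p, n)``.  Either vector being all-zero gives 0.
    """
    if isinstance(p, dict) or isinstance(n, dict):
        if not (isinstance(p, dict) and isinstance(n, dict)):
            raise TypeError("both vectors must be dicts or both arrays")
        vocab = sorted(set(p) | set(n))
        pv = np.array([p.get(t, 0) for t in vocab], dtype=float)
        nv = np.array([n.get(t, 0) for t in vocab], dtype=float)
    else:
        pv = np.asarray(p, dtype=float)
        nv = np.asarray(n, dtype=float)
        if pv.shape != nv.shape:
            raise ValueError("term-frequency vectors must share a vocabulary")
    if np.any(pv < 0) or np.any(nv < 0):
        raise ValueError("term frequencies must be nonnegative")
    norm = math.sqrt(float(pv @ pv)) * math.sqrt(float(nv @ nv))
    if norm == 0.0:
        return 0.0
    return 10.0 * float(pv @ nv) / norm


def haversine_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km between ``(lat, lng)`` points, R = 6371 km."""
    lat1, lng1 = math.radians(a[0]), math.radians(a[1])
    lat2, lng2 = math.radians(b[0]), math.radians(b[1])
    dlat = lat2 - lat1
    dlng = lng2 - lng1
    h = math.sin(dlat / 2.0) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlng / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def match_checkin(
    checkin: CheckinRecord,
    candidates: list[POIRecord],
    params: SpliceParams | None = None,
) -> str | None:
    """POI the check-in splices onto, or ``None``.

    Among candidates passing both gates (similarity strictly above the
    threshold AND distance strictly below), the highest-similarity POI wins;
    ties break by smaller distance, then lexicographic ``poi_id``.
    """
    params = params or SpliceParams()
    best: tuple[float, float, str] | None = None
    for poi in candidates:
        s = similarity(poi.description_tokens, checkin.text_tokens)
        if s <= params.sim_threshold:
            continue
        d = haversine_km((poi.lat, poi.lng), (checkin.lat, checkin.lng))
        if d >= params.dist_threshold_km:
            continue
        key = (-s, d, poi.poi_id)
        if best is None or key < best:
            best = key
    return best[2] if best is not None else None


def splice_checkins(
    checkins: list[CheckinRecord],
    pois: list[POIRecord],
    params: SpliceParams | None = None,
) -> list[CheckinRecord]:
    """Set ``matched_poi``/``similarity``/``distance_km`` on every check-in.

    Candidates are restricted to POIs sharing the check-in's map tile.
    Returns the same records, mutated, for chaining.
    """
    params = params or SpliceParams()
    from .dataio import tile_index

    by_tile: dict = {}
    for poi in pois:
        by_tile.setdefault(poi.tile, []).append(poi)
    poi_by_id = {p.poi_id: p for p in pois}
    zooms = {p.tile.z for p in pois}
    zoom = zooms.pop() if len(zooms) == 1 else None
    for c in checkins:
        c.matched_poi = None
        c.similarity = None
        c.distance_km = None
        if zoom is None:
            continue
        tile = tile_index(c.lat, c.lng, zoom)
        candidates = by_tile.get(tile, [])
        pid = match_checkin(c, candidates, params)
        if pid is not None:
            poi = poi_by_id[pid]
            c.matched_poi = pid
            c.similarity = similarity(poi.description_tokens, c.text_tokens)
            c.distance_km = haversine_km((poi.lat, poi.lng), (c.lat, c.lng))
    return checkins


def weekly_visit_frequency(
    poi: POIRecord,
    checkins: list[CheckinRecord],
    params: SpliceParams | None = None,
    n_weeks: int | None = None,
) -> np.ndarray:
    """Weekly visit counts f(P)_t for ``poi`` over weeks t = 1..n_weeks.

    A check-in counts toward week t when both splicing gates pass against
    this POI and its timestamp falls in week t.  When ``n_weeks`` is omitted
    it is taken from the latest check-in week.
    """
    params = params or SpliceParams()
    weeks = []
    for c in checkins:
        s = similarity(poi.description_tokens, c.text_tokens)
        if s <= params.sim_threshold:
            continue
        d = haversine_km((poi.lat, poi.lng), (c.lat, c.lng))
        if d >= params.dist_threshold_km:
            continue
        weeks.append(c.week)
    if n_weeks is None:
        n_weeks = max(weeks, default=0)
    out = np.zeros(n_weeks, dtype=int)
    for w in weeks:
        if 1 <= w <= n_weeks:
            out[w - 1] += 1
    return out


def matched_weekly_frequency(
    poi: POIRecord, checkins: list[CheckinRecord], n_weeks: int
) -> np.ndarray:
    """Weekly counts of check-ins already spliced onto ``poi`` (by poi_id)."""
    out = np.zeros(n_weeks, dtype=int)
    for c in checkins:
        if c.matched_poi == poi.poi_id and 1 <= c.week <= n_weeks:
            out[c.week - 1] += 1
    return out


def build_feature_vectors(
    pois: list[POIRecord],
    checkins: list[CheckinRecord],
    params: SpliceParams | None = None,
    tile=None,
    n_weeks: int | None = None,
    use_matches: bool = False,
) -> list[PoiFeatureVector]:
    """Per-POI feature vectors for one tile, ordered by ``poi_id``.

    Coordinates are min-max scaled to [0, scale_max] within the tile's
    bounding box (or, absent a tile, the POIs' own bounding box).  With
    ``use_matches`` the weekly series reuses ``matched_poi`` assignments made
    by :func:`splice_checkins` (one check-in, one POI); otherwise each POI
    re-filters the stream through both gates independently.
    """
    params = params or SpliceParams()
    if not pois:
        return []
    if tile is not None:
        lat_min, lat_max, lng_min, lng_max = tile_bounds(tile)
    else:
        lats = [p.lat for p in pois]
        lngs = [p.lng for p in pois]
        lat_min, lat_max, lng_min, lng_max = min(lats), max(lats), min(lngs), max(lngs)
    lat_span = lat_max - lat_min
    lng_span = lng_max - lng_min
    degenerate = lat_span <= 0 or lng_span <= 0
    if degenerate:
        logger.warning("degenerate bounding box; scaled coordinates set to 0")
    if n_weeks is None:
        n_weeks = max((c.week for c in checkins), default=1)
    out = []
    for poi in sorted(pois, key=lambda p: p.poi_id):
        if degenerate:
            s_lat = s_lng = 0.0
        else:
            s_lat = (poi.lat - lat_min) / lat_span * params.scale_max
            s_lng = (poi.lng - lng_min) / lng_span * params.scale_max
        onehot = np.array([1.0 if c in poi.categories else 0.0 for c in CATEGORIES])
        if use_matches:
            freq = matched_weekly_frequency(poi, checkins, n_weeks)
        else:
            freq = weekly_visit_frequency(poi, checkins, params, n_weeks)
        out.append(
            PoiFeatureVector(
                poi_id=poi.poi_id,
                scaled_lat=float(s_lat),
                scaled_lng=float(s_lng),
                category_onehot=onehot,
                weekly_frequency=freq,
            )
        )
    return out
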