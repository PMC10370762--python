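"""Record types, slippy-map tile indexing, and file formats.

The pipeline partitions space into Web-Mercator slippy tiles (z/x/y); one tile
is one training unit.  Coordinate conventions: internally everything is
``(lat, lng)`` in WGS84 degrees; GeoJSON files use the standard ``(lng, lat)``
order.  Weeks are indexed from Monday 2020-01-06 (week 1); the week of a
timestamp is ``floor(days_since_epoch / 7) + 1``.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

MAX_MERCATOR_LAT = 85.0511

#: The ten food-access venue categories, ordered A1..A10.
CATEGORIES = tuple(f"A{i}" for i in range(1, 11))

#: Human-readable category names (editable mapping table; defaults follow the
#: conventional food-environment classification).
CATEGORY_NAMES = {
    "A1": "low access stores",
    "A2": "grocery stores",
    "A3": "supercenters",
    "A4": "club stores",
    "A5": "convenience stores",
    "A6": "specialized food stores",
    "A7": "full-service restaurants",
    "A8": "fast food restaurants",
    "A9": "school food service",
    "A10": "direct farm sales",
}

#: Monday starting the first indexed week.
WEEK_EPOCH = datetime(2020, 1, 6, tzinfo=timezone.utc)


def week_index(ts: datetime) -> int:
    """1-based week number of ``ts`` counted from :data:`WEEK_EPOCH`."""
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return int((ts - WEEK_EPOCH).days // 7) + 1


def week_start(t: int) -> datetime:
    """Monday 00:00 UTC opening week ``t``."""
    return WEEK_EPOCH + timedelta(weeks=t - 1)


# ---------------------------------------------------------------------------
# tile indexing
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class TileID:
    """Slippy-map tile address (zoom, column, row)."""

    z: int
    x: int
    y: int

    def __post_init__(self):
        n = 1 << self.z
        if not (0 <= self.x < n and 0 <= self.y < n):
            raise ValueError(f"tile ({self.z},{self.x},{self.y}) outside 0..2^z-1")

    def __str__(self) -> str:
        return f"{self.z}/{self.x}/{self.y}"

    @classmethod
    def parse(cls, s: str) -> "TileID":
        z, x, y = (int(v) for v in str(s).split("/"))
        return cls(z, x, y)


def tile_index(lat: float, lng: float, zoom: int) -> TileID:
    """Slippy tile containing ``(lat, lng)`` at ``zoom``.

    Uses the standard Web-Mercator formula; longitudes are wrapped into
    [-180, 180).
    """
    if abs(lat) > MAX_MERCATOR_LAT:
        raise ValueError(f"latitude {lat} outside Mercator range ±{MAX_MERCATOR_LAT}")
    lng = ((lng + 180.0) % 360.0) - 180.0
    n = 1 << zoom
    x = int(math.floor((lng + 180.0) / 360.0 * n))
    phi = math.radians(lat)
    y = int(math.floor((1.0 - math.log(math.tan(phi) + 1.0 / math.cos(phi)) / math.pi) / 2.0 * n))
    return TileID(zoom, min(x, n - 1), min(max(y, 0), n - 1))


def tile_bounds(tile: TileID) -> tuple[float, float, float, float]:
    """``(lat_min, lat_max, lng_min, lng_max)`` of ``tile``.

    The tile is half-open: its west and north edges belong to it, so
    ``tile_index`` of any interior point (and of the NW corner) returns
    ``tile``.
    """
    n = 1 << tile.z
    lng_min = tile.x / n * 360.0 - 180.0
    lng_max = (tile.x + 1) / n * 360.0 - 180.0

    def lat_of(y):
        t = math.pi * (1.0 - 2.0 * y / n)
        return math.degrees(math.atan(math.sinh(t)))

    lat_max = lat_of(tile.y)
    lat_min = lat_of(tile.y + 1)
    return (lat_min, lat_max, lng_min, lng_max)


def tile_center(tile: TileID) -> tuple[float, float]:
    lat_min, lat_max, lng_min, lng_max = tile_bounds(tile)
    return ((lat_min + lat_max) / 2.0, (lng_min + lng_max) / 2.0)


def tiles_in_bbox(bbox: tuple[float, float, float, float], zoom: int) -> list[TileID]:
    """All tiles whose extent intersects ``bbox``, row-major (y, then x)."""
    lat_min, lat_max, lng_min, lng_max = bbox
    nw = tile_index(lat_max, lng_min, zoom)
    se = tile_index(lat_min, lng_max, zoom)
    return [
        TileID(zoom, x, y)
        for y in range(nw.y, se.y + 1)
        for x in range(nw.x, se.x + 1)
    ]


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass
class POIRecord:
    """A food-access venue: coordinates, categories, and description tokens."""

    poi_id: str
    lat: float
    lng: float
    tile: TileID
    name: str = ""
    description_tokens: dict[str, int] = field(default_factory=dict)
    categories: tuple[str, ...] = ()
    address: str | None = None
    amenity: str | None = None
    cuisine: str | None = None

    def validate(self) -> None:
        if abs(self.lat) > MAX_MERCATOR_LAT:
            raise ValueError(f"POI {self.poi_id}: latitude {self.lat} out of range")
        if not (-180.0 <= self.lng < 180.0):
            raise ValueError(f"POI {self.poi_id}: longitude {self.lng} out of range")
        if not self.categories:
            raise ValueError(f"POI {self.poi_id}: empty category set")
        for c in self.categories:
            if c not in CATEGORIES:
                raise ValueError(f"POI {self.poi_id}: unknown category {c!r}")


@dataclass
class CheckinRecord:
    """A geotagged, timestamped post, optionally spliced onto a POI."""

    checkin_id: str
    user_id: str
    timestamp: datetime
    lat: float
    lng: float
    text_tokens: dict[str, int] = field(default_factory=dict)
    matched_poi: str | None = None
    similarity: float | None = None
    distance_km: float | None = None

    def validate(self) -> None:
        if abs(self.lat) > MAX_MERCATOR_LAT:
            raise ValueError(f"check-in {self.checkin_id}: latitude {self.lat} out of range")
        if not (-180.0 <= self.lng < 180.0):
            raise ValueError(f"check-in {self.checkin_id}: longitude {self.lng} out of range")
        if self.similarity is not None and not (0.0 <= self.similarity <= 10.0):
            raise ValueError(f"check-in {self.checkin_id}: similarity outside [0, 10]")
        if self.distance_km is not None and self.distance_km < 0:
            raise ValueError(f"check-in {self.checkin_id}: negative distance")

    @property
    def week(self) -> int:
        return week_index(self.timestamp)


@dataclass
class CaseProfile:
    """A diagnosed case's weekly venue-category visit counts (edge information)."""

    case_id: str
    tile: TileID
    weekly_counts: dict[str, np.ndarray] = field(default_factory=dict)

    def validate(self) -> None:
        for cat, counts in self.weekly_counts.items():
            if cat not in CATEGORIES:
                raise ValueError(f"case {self.case_id}: unknown category {cat!r}")
            if np.any(np.asarray(counts) < 0):
                raise ValueError(f"case {self.case_id}: negative count")

    def count(self, category: str, week: int) -> int:
        counts = self.weekly_counts.get(category)
        if counts is None or not (1 <= week <= len(counts)):
            return 0
        return int(counts[week - 1])


class RecordBatch(list):
    """A list of records plus the number of malformed inputs rejected."""

    def __init__(self, records=(), n_rejected: int = 0):
        super().__init__(records)
        self.n_rejected = n_rejected


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_ISO = "%Y-%m-%dT%H:%M:%S%z"


def _ts_to_str(ts: datetime) -> str:
    return ts.astimezone(timezone.utc).strftime("%Y-%m-%dT%H:%M:%S+00:00")


def read_pois(path) -> RecordBatch:
    """Read a GeoJSON FeatureCollection of POIs.

    Features failing validation are counted in ``.n_rejected`` and logged,
    never silently dropped.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    out = RecordBatch()
    for feat in doc.get("features", []):
        try:
            props = feat["properties"]
            lng, lat = feat["geometry"]["coordinates"]
            for col in ("poi_id", "tile", "categories", "description_tokens"):
                if col not in props:
                    raise KeyError(f"missing mandatory property {col!r}")
            rec = POIRecord(
                poi_id=str(props["poi_id"]),
                lat=float(lat),
                lng=float(lng),
                tile=TileID.parse(props["tile"]),
                name=props.get("name", ""),
                description_tokens={k: int(v) for k, v in props["description_tokens"].items()},
                categories=tuple(props["categories"]),
                address=props.get("address"),
                amenity=props.get("amenity"),
                cuisine=props.get("cuisine"),
            )
            rec.validate()
            out.append(rec)
        except (KeyError, ValueError, TypeError) as exc:
            out.n_rejected += 1
            logger.warning("rejected POI feature: %s", exc)
    return out


def write_pois(pois, path) -> None:
    feats = []
    for p in pois:
        props = {
            "poi_id": p.poi_id,
            "tile": str(p.tile),
            "name": p.name,
            "description_tokens": dict(sorted(p.description_tokens.items())),
            "categories": list(p.categories),
        }
        for k in ("address", "amenity", "cuisine"):
            v = getattr(p, k)
            if v is not None:
                props[k] = v
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [p.lng, p.lat]},
                "properties": props,
            }
        )
    _dump_geojson({"type": "FeatureCollection", "features": feats}, path)


def read_checkins(path) -> RecordBatch:
    """Read a JSON-lines file of check-ins (one object per line)."""
    out = RecordBatch()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                for col in ("checkin_id", "user_id", "timestamp", "lat", "lng"):
                    if col not in obj:
                        raise KeyError(f"missing mandatory field {col!r}")
                rec = CheckinRecord(
                    checkin_id=str(obj["checkin_id"]),
                    user_id=str(obj["user_id"]),
                    timestamp=datetime.strptime(obj["timestamp"], _ISO),
                    lat=float(obj["lat"]),
                    lng=float(obj["lng"]),
                    text_tokens={k: int(v) for k, v in obj.get("text_tokens", {}).items()},
                    matched_poi=obj.get("matched_poi"),
                    similarity=obj.get("similarity"),
                    distance_km=obj.get("distance_km"),
                )
                rec.validate()
                out.append(rec)
            except (KeyError, ValueError, TypeError, json.JSONDecodeError) as exc:
                out.n_rejected += 1
                logger.warning("rejected check-in line: %s", exc)
    return out


def write_checkins(checkins, path) -> None:
    with open(path, "w") as fh:
        for c in checkins:
            obj = {
                "checkin_id": c.checkin_id,
                "user_id": c.user_id,
                "timestamp": _ts_to_str(c.timestamp),
                "lat": c.lat,
                "lng": c.lng,
                "text_tokens": dict(sorted(c.text_tokens.items())),
            }
            if c.matched_poi is not None:
                obj["matched_poi"] = c.matched_poi
            if c.similarity is not None:
                obj["similarity"] = c.similarity
            if c.distance_km is not None:
                obj["distance_km"] = c.distance_km
            fh.write(json.dumps(obj, sort_keys=True) + "\n")


_CASE_COLS = ["case_id", "tile", "week"] + list(CATEGORIES)


def read_cases(path) -> RecordBatch:
    """Read the wide-format case CSV (case_id, tile, week, A1..A10)."""
    out = RecordBatch()
    rows: dict[str, dict] = {}
    rejected_cases: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _CASE_COLS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"{path}: missing mandatory column(s) {missing}")
        for row in reader:
            try:
                cid = row["case_id"]
                tile = TileID.parse(row["tile"])
                week = int(row["week"])
                counts = [int(row[c]) for c in CATEGORIES]
                if any(v < 0 for v in counts):
                    raise ValueError(f"case {cid}: negative count")
                entry = rows.setdefault(cid, {"tile": tile, "weeks": {}})
                entry["weeks"][week] = counts
            except (KeyError, ValueError, TypeError) as exc:
                if row.get("case_id"):
                    rejected_cases.add(row["case_id"])
                out.n_rejected += 1
                logger.warning("rejected case row: %s", exc)
    for cid, entry in rows.items():
        if cid in rejected_cases:
            continue
        n_weeks = max(entry["weeks"])
        mat = np.zeros((n_weeks, len(CATEGORIES)), dtype=int)
        for wk, counts in entry["weeks"].items():
            mat[wk - 1] = counts
        weekly = {
            cat: mat[:, j].copy()
            for j, cat in enumerate(CATEGORIES)
            if mat[:, j].any()
        }
        prof = CaseProfile(case_id=cid, tile=entry["tile"], weekly_counts=weekly)
        prof.validate()
        out.append(prof)
    return out


def write_cases(cases, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CASE_COLS)
        for case in cases:
            n_weeks = max((len(v) for v in case.weekly_counts.values()), default=0)
            for wk in range(1, n_weeks + 1):
                writer.writerow(
                    [case.case_id, str(case.tile), wk]
                    + [case.count(cat, wk) for cat in CATEGORIES]
                )


def _dump_geojson(doc: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True, separators=(",", ":"))
        fh.write("\n")


def tile_polygon(tile: TileID) -> list[list[float]]:
    """GeoJSON polygon ring (closed, lng-lat order) of a tile's rectangle."""
    lat_min, lat_max, lng_min, lng_max = tile_bounds(tile)
    return [
        [lng_min, lat_min],
        [lng_max, lat_min],
        [lng_max, lat_max],
        [lng_min, lat_max],
        [lng_min, lat_min],
    ]


def write_risk_geojson(surface, path) -> None:
    """Write a risk surface as one polygon feature per tile.

    Properties carry the tile address, the model risk score, the binary label
    at the 0.5 operating point, and the per-category geographic matching
    weights for that tile (``null`` where the tile holds no venue of the
    category).
    """
    if not surface.tiles:
        raise ValueError("empty risk surface")
    feats = []
    for r, tile in enumerate(surface.tiles):
        score = float(surface.scores[tile])
        col = surface.category_matrix[:, r]
        weights = {
            cat: (None if np.isnan(col[i]) else float(col[i]))
            for i, cat in enumerate(CATEGORIES)
        }
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [tile_polygon(tile)]},
                "properties": {
                    "tile": str(tile),
                    "risk_score": score,
                    "label": int(score > 0.5),
                    "category_weights": weights,
                },
            }
        )
    _dump_geojson({"type": "FeatureCollection", "features": feats}, path)


def write_truth(world, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["tile", "score", "label"])
        for tile in sorted(world.true_tile_risk):
            writer.writerow(
                [str(tile), repr(world.true_tile_score[tile]), world.true_tile_risk[tile]]
            )


def read_truth(path) -> tuple[dict[TileID, float], dict[TileID, int]]:
    scores: dict[TileID, float] = {}
    labels: dict[TileID, int] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            tile = TileID.parse(row["tile"])
            scores[tile] = float(row["score"])
            labels[tile] = int(row["label"])
    return scores, labels
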