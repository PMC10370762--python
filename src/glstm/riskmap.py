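"""Geographically weighted risk surfaces and four-layer map export.

Local calibration follows the geographically-weighted-aggregation idea: a
query location sees each venue through a Gaussian distance kernel
w_i = exp(-(d_i / bandwidth)^2), normalized to a probability vector, so that
category risk varies smoothly over space.  The category spatial weight
matrix crosses the ten food-access categories with regions (tiles by
default); entry (c, r) is the kernel-weighted mean of category-c venue risk
scores in region r, NaN where the region holds no such venue.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataio import (
    CATEGORIES,
    POIRecord,
    TileID,
    _dump_geojson,
    tile_center,
    tile_polygon,
    write_risk_geojson,
)
from .splice import haversine_km


@dataclass
class RiskSurface:
    """Per-tile risk scores plus the category x region matching matrix."""

    tiles: list[TileID]
    scores: dict[TileID, float]
    category_matrix: np.ndarray  # (10, R), NaN = category absent in region
    kernel_bandwidth_km: float = 3.0

    def __post_init__(self):
        if set(self.tiles) - set(self.scores):
            raise ValueError("every tile needs a score")
        finite = self.category_matrix[np.isfinite(self.category_matrix)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("matrix entries must lie in [0, 1]")


def geographic_weights(
    centers: list[tuple[float, float]],
    query: tuple[float, float],
    bandwidth_km: float,
) -> np.ndarray:
    """Normalized Gaussian kernel weights of ``centers`` around ``query``.

    w_i proportional to exp(-(d_i / bandwidth)^2) with great-circle d_i; the
    returned vector is nonnegative and sums to 1.
    """
    if not centers:
        raise ValueError("need at least one center")
    if bandwidth_km <= 0:
        raise ValueError("bandwidth must be positive")
    d = np.array([haversine_km(c, query) for c in centers])
    w = np.exp(-((d / bandwidth_km) ** 2))
    total = w.sum()
    if total == 0.0:  # all centers far beyond the kernel reach: fall back flat
        return np.full(len(centers), 1.0 / len(centers))
    return w / total


def category_weight_matrix(
    poi_scores: dict[str, float],
    pois: list[POIRecord],
    regions: list[TileID] | None = None,
    bandwidth_km: float = 3.0,
) -> np.ndarray:
    """Category x region matrix of kernel-weighted mean venue risk.

    Regions default to the tiles spanned by ``pois``; each region is queried
    at its center.  Entries are convex combinations of the member scores, so
    they stay within [min score, max score]; regions with no venue of a
    category are NaN (missing, not zero).
    """
    for p in pois:
        if p.poi_id not in poi_scores:
            raise ValueError(f"venue {p.poi_id} has no score")
    if regions is None:
        regions = sorted({p.tile for p in pois})
    mat = np.full((len(CATEGORIES), len(regions)), np.nan)
    by_region: dict[TileID, list[POIRecord]] = {r: [] for r in regions}
    for p in pois:
        if p.tile in by_region:
            by_region[p.tile].append(p)
    for r, region in enumerate(regions):
        query = tile_center(region)
        members = by_region[region]
        for ci, cat in enumerate(CATEGORIES):
            cat_pois = [p for p in members if cat in p.categories]
            if not cat_pois:
                continue
            w = geographic_weights([(p.lat, p.lng) for p in cat_pois], query, bandwidth_km)
            s = np.array([poi_scores[p.poi_id] for p in cat_pois])
            mat[ci, r] = float(w @ s)
    return mat


def build_risk_surface(
    tiles: list[TileID],
    tile_scores: dict[TileID, float],
    pois: list[POIRecord],
    poi_scores: dict[str, float],
    bandwidth_km: float = 3.0,
) -> RiskSurface:
    tiles = sorted(tiles)
    mat = category_weight_matrix(poi_scores, pois, regions=tiles, bandwidth_km=bandwidth_km)
    return RiskSurface(
        tiles=tiles,
        scores={t: float(tile_scores[t]) for t in tiles},
        category_matrix=mat,
        kernel_bandwidth_km=bandwidth_km,
    )


def export_layers(world, surface: RiskSurface, out_dir) -> dict[str, str]:
    """Write the four map layers as GeoJSON FeatureCollections.

    layer1: tile boundary polygons; layer2: check-in points; layer3: venue
    points with categories; layer4: the risk heatmap (tile polygons carrying
    scores).  Feature ordering is deterministic, so re-export is
    byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}

    boundary_feats = [
        {
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [tile_polygon(t)]},
            "properties": {"tile": str(t)},
        }
        for t in surface.tiles
    ]
    path = out / "layer1_boundaries.geojson"
    _dump_geojson({"type": "FeatureCollection", "features": boundary_feats}, path)
    files["layer1_boundaries"] = str(path)

    checkin_feats = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [c.lng, c.lat]},
            "properties": {
                "checkin_id": c.checkin_id,
                "user_id": c.user_id,
                "matched_poi": c.matched_poi,
            },
        }
        for c in sorted(world.checkins, key=lambda c: c.checkin_id)
    ]
    path = out / "layer2_checkins.geojson"
    _dump_geojson({"type": "FeatureCollection", "features": checkin_feats}, path)
    files["layer2_checkins"] = str(path)

    poi_feats = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [p.lng, p.lat]},
            "properties": {
                "poi_id": p.poi_id,
                "tile": str(p.tile),
                "name": p.name,
                "categories": list(p.categories),
                "amenity": p.amenity,
                "cuisine": p.cuisine,
                "address": p.address,
            },
        }
        for p in sorted(world.pois, key=lambda p: p.poi_id)
    ]
    path = out / "layer3_pois.geojson"
    _dump_geojson({"type": "FeatureCollection", "features": poi_feats}, path)
    files["layer3_pois"] = str(path)

    path = out / "layer4_risk.geojson"
    write_risk_geojson(surface, path)
    files["layer4_risk"] = str(path)
    return files
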