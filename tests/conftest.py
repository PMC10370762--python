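import numpy as np
import pytest

from glstm.dataio import CATEGORIES, POIRecord, TileID, tile_bounds
from glstm.splice import PoiFeatureVector
from glstm.synthetic import WorldConfig, generate_world


@pytest.fixture(scope="session")
def small_world():
    """A compact world reused by read-only tests (12 tiles, 6 weeks)."""
    cfg = WorldConfig(
        n_tiles=12, pois_per_tile=10, n_users=50, n_cases=24, n_weeks=6, seed=7
    )
    return generate_world(cfg)


@pytest.fixture
def demo_poi():
    tile = TileID(10, 300, 380)
    lat_min, lat_max, lng_min, lng_max = tile_bounds(tile)
    return POIRecord(
        poi_id="poi-demo",
        lat=(lat_min + lat_max) / 2,
        lng=(lng_min + lng_max) / 2,
        tile=tile,
        name="Demo Burger",
        description_tokens={"burger": 1, "fries": 1, "combo": 1, "shake": 1, "fresh": 1},
        categories=("A8",),
    )


def make_feature(poi_id: str, cats, freq, lat=1.0, lng=2.0) -> PoiFeatureVector:
    onehot = np.array([1.0 if c in cats else 0.0 for c in CATEGORIES])
    return PoiFeatureVector(
        poi_id=poi_id,
        scaled_lat=lat,
        scaled_lng=lng,
        category_onehot=onehot,
        weekly_frequency=np.asarray(freq, dtype=int),
    )
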