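"""GeoJSON round-trip for PA polygon records.

Polygons are stored as a GeoJSON FeatureCollection with the attribute set
``pa_id, name, country, iucn_cat, status, gis_area_km2`` in each feature's
properties.  Coordinates are in the scene's planar frame (metres).
"""

from __future__ import annotations

import json
from pathlib import Path

from shapely.geometry import mapping, shape

from .filters import PARecord

__all__ = ["write_pa_geojson", "read_pa_geojson"]


def write_pa_geojson(records: list[PARecord], path: str | Path) -> Path:
    path = Path(path)
    features = [
        {
            "type": "Feature",
            "properties": {
                "pa_id": r.pa_id,
                "name": r.name,
                "country": r.country,
                "iucn_cat": r.iucn_cat,
                "status": r.status,
                "gis_area_km2": r.gis_area_km2,
            },
            "geometry": mapping(r.geometry),
        }
        for r in records
    ]
    collection = {"type": "FeatureCollection", "features": features}
    path.write_text(json.dumps(collection, indent=1))
    return path


def read_pa_geojson(path: str | Path) -> list[PARecord]:
    data = json.loads(Path(path).read_text())
    if data.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    records = []
    for feat in data["features"]:
        props = feat["properties"]
        records.append(PARecord(
            pa_id=str(props["pa_id"]),
            name=str(props["name"]),
            country=str(props["country"]),
            iucn_cat=str(props["iucn_cat"]),
            status=str(props["status"]),
            gis_area_km2=float(props["gis_area_km2"]),
            geometry=shape(feat["geometry"]),
        ))
    return records
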