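"""Minimal GeoJSON reading/writing built on shapely + json.

Features carry a ``properties`` dict; geometry round-trips through
``shapely.geometry.shape`` / ``mapping``. Coordinates are in the package's
projected metric CRS (GeoJSON is used here as a container, not as WGS84).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry


def read_features(path: str | Path) -> list[tuple[BaseGeometry, dict]]:
    """Read a GeoJSON FeatureCollection into (geometry, properties) pairs."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    out = []
    for feat in doc.get("features", []):
        out.append((shape(feat["geometry"]), dict(feat.get("properties") or {})))
    return out


def write_features(
    features: Iterable[tuple[BaseGeometry, Mapping]], path: str | Path
) -> None:
    """Write (geometry, properties) pairs as a GeoJSON FeatureCollection."""
    doc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(geom),
                "properties": dict(props),
            }
            for geom, props in features
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_landcover(path: str | Path) -> list[tuple[BaseGeometry, str]]:
    """Landcover polygons with their ``class`` attribute."""
    out = []
    for geom, props in read_features(path):
        if "class" not in props:
            raise ValueError(f"{path}: landcover feature missing 'class' property")
        out.append((geom, str(props["class"])))
    return out


def read_points(path: str | Path) -> list[tuple[float, float]]:
    """Point coordinates from a GeoJSON file (e.g. perch structures)."""
    pts = []
    for geom, _ in read_features(path):
        if geom.geom_type != "Point":
            raise ValueError(f"{path}: expected Point features, got {geom.geom_type}")
        pts.append((float(geom.x), float(geom.y)))
    return pts
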