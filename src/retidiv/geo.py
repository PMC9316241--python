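"""Study-window geometry: GeoJSON I/O for the window polygon and fall line.

Coordinates are planar kilometres; no projection handling is attempted.
"""

from __future__ import annotations

import json
from pathlib import Path

from shapely.geometry import LineString, box, mapping, shape
from shapely.geometry.base import BaseGeometry


def window_box(xmin: float, ymin: float, xmax: float, ymax: float):
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("window must have positive extent")
    return box(xmin, ymin, xmax, ymax)


def write_window_geojson(
    window: BaseGeometry, fall_line_y: float, path: str | Path
) -> None:
    """Write the window polygon and the horizontal fall line as features."""
    xmin, _, xmax, _ = window.bounds
    fall = LineString([(xmin, fall_line_y), (xmax, fall_line_y)])
    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {"role": "window"},
             "geometry": mapping(window)},
            {"type": "Feature", "properties": {"role": "fall_line"},
             "geometry": mapping(fall)},
        ],
    }
    Path(path).write_text(json.dumps(fc, indent=1))


def read_window_geojson(path: str | Path) -> tuple[BaseGeometry, float]:
    """Return (window polygon, fall_line_y) from a feature collection."""
    fc = json.loads(Path(path).read_text())
    window = None
    fall_y = None
    for feat in fc.get("features", []):
        geom = shape(feat["geometry"])
        role = feat.get("properties", {}).get("role")
        if role == "window" or (role is None and geom.geom_type == "Polygon"):
            window = geom
        elif role == "fall_line" or geom.geom_type == "LineString":
            ys = [y for _, y in geom.coords]
            fall_y = sum(ys) / len(ys)
    if window is None:
        raise ValueError(f"no window polygon in {path}")
    if fall_y is None:
        raise ValueError(f"no fall line in {path}")
    return window, fall_y
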