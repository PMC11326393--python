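"""Planar geometry primitives: tumor masks and GeoJSON round-tripping.

All coordinates are in micrometres (image convention: origin top-left,
y increasing downward). Areas are reported in mm².
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import shapely
import shapely.affinity
from shapely.geometry import MultiPolygon, Polygon, box, mapping, shape
from shapely.ops import unary_union

from .errors import GeometryError

UM2_PER_MM2 = 1e6


def as_multipolygon(geom) -> MultiPolygon:
    if isinstance(geom, Polygon):
        return MultiPolygon([geom])
    if isinstance(geom, MultiPolygon):
        return geom
    raise GeometryError(f"expected Polygon/MultiPolygon, got {type(geom).__name__}")


@dataclass(frozen=True)
class TumorMask:
    """Tumor region: one or more simple polygons (holes allowed), µm frame."""

    geom: MultiPolygon = field()

    def __post_init__(self):
        g = as_multipolygon(self.geom)
        if not g.is_valid:
            raise GeometryError("tumor mask polygons are invalid (self-intersecting?)")
        if g.area <= 0:
            raise GeometryError("tumor mask has zero area")
        object.__setattr__(self, "geom", g)

    @property
    def area_mm2(self) -> float:
        return self.geom.area / UM2_PER_MM2

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self.geom.bounds

    def contains_points(self, x, y) -> np.ndarray:
        """Vectorized point-in-mask test (boundary counts as inside)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return shapely.intersects_xy(self.geom, x, y)

    def translate(self, dx: float, dy: float) -> "TumorMask":
        return TumorMask(shapely.affinity.translate(self.geom, dx, dy))

    @classmethod
    def rectangle(cls, width_um: float, height_um: float) -> "TumorMask":
        return cls(box(0.0, 0.0, width_um, height_um))

    def to_geojson(self, path, extra_properties: dict | None = None) -> None:
        props = {"units": "um", "layer": "tumor_mask"}
        if extra_properties:
            props.update(extra_properties)
        fc = {
            "type": "FeatureCollection",
            "features": [
                {"type": "Feature", "geometry": mapping(self.geom), "properties": props}
            ],
        }
        with open(path, "w") as fh:
            json.dump(fc, fh, sort_keys=True)

    @classmethod
    def from_geojson(cls, path) -> "TumorMask":
        with open(path) as fh:
            fc = json.load(fh)
        geoms = []
        for feat in fc.get("features", []):
            g = shape(feat["geometry"])
            geoms.append(g)
        if not geoms:
            raise GeometryError(f"no polygon features in {path}")
        return cls(as_multipolygon(unary_union(geoms)))


def sample_points_in_polygon(rng: np.random.Generator, geom, n: int) -> np.ndarray:
    """Draw ``n`` uniform points inside ``geom`` by rejection from its bbox.

    Deterministic under a fixed generator state.
    """
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = geom.bounds
    bbox_area = (maxx - minx) * (maxy - miny)
    frac = max(geom.area / bbox_area, 1e-6)
    out = []
    got = 0
    while got < n:
        m = max(64, int((n - got) / frac * 1.3))
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        keep = shapely.contains_xy(geom, xs, ys)
        pts = np.column_stack([xs[keep], ys[keep]])
        out.append(pts)
        got += len(pts)
    return np.concatenate(out)[:n]
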