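"""Synthetic study landscapes: parks, roads, a detection hotspot, distance fields.

The landscape stands in for the GIS layers of a real study region: a
rectangular extent gridded into square cells, protected-area polygons
(discs, so distances have closed forms), straight-segment roads, and one
designated detection hotspot at the centre of a park. The detection model
consumes two distance fields with deliberately different units — distance
to the hotspot in kilometres and distance to the nearest road in metres —
because the decay coefficients acting on them are only plausible on those
scales.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, Point, mapping, shape

from ._grid import cell_centres, min_distance_to_segments, read_ascii_grid, write_ascii_grid

__all__ = ["SyntheticLandscape", "make_landscape"]


@dataclass
class SyntheticLandscape:
    """A gridded study region with parks, roads and a detection hotspot.

    Attributes
    ----------
    extent : (width, height) in km.
    cell_size : cell edge in km (1 km default, the analysis resolution).
    park_polygons : shapely polygons of protected areas.
    hotspot : shapely Point, centre of the designated hotspot park.
    road_lines : shapely LineStrings (straight segments).
    road_distance : per-cell distance to the nearest road, in **metres**.
    hotspot_distance : per-cell distance to the hotspot, in **km**.
    park_mask : per-cell boolean, True inside a park.
    """

    extent: tuple[float, float]
    cell_size: float
    park_polygons: list
    hotspot: Point
    road_lines: list
    road_distance: np.ndarray
    hotspot_distance: np.ndarray
    park_mask: np.ndarray

    # -- geometry ----------------------------------------------------------
    @classmethod
    def from_geometry(cls, extent, parks, roads, hotspot, cell_size=1.0):
        """Build a landscape from explicit geometry, precomputing distance fields.

        ``parks`` is a list of (cx, cy, radius) discs; ``roads`` a list of
        ((ax, ay), (bx, by)) segments; ``hotspot`` an (x, y) pair that must
        fall inside a park.
        """
        width, height = extent
        if width <= 0 or height <= 0:
            raise ValueError("landscape extent must have positive area")
        xx, yy = cell_centres(extent, cell_size)
        hx, hy = hotspot
        in_park = np.zeros(xx.shape, dtype=bool)
        polys = []
        for cx, cy, r in parks:
            in_park |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
            polys.append(Point(cx, cy).buffer(r, quad_segs=32))
        if parks and not any((hx - cx) ** 2 + (hy - cy) ** 2 <= r * r for cx, cy, r in parks):
            raise ValueError("hotspot must lie inside a park")
        hotspot_km = np.hypot(xx - hx, yy - hy)
        road_m = min_distance_to_segments(xx, yy, roads) * 1000.0
        if not roads:
            road_m = np.zeros_like(hotspot_km)
        road_m[road_m < 1e-6] = 0.0  # snap sub-millimetre FP residue onto the road
        obj = cls(
            extent=(float(width), float(height)),
            cell_size=float(cell_size),
            park_polygons=polys,
            hotspot=Point(hx, hy),
            road_lines=[LineString([a, b]) for a, b in roads],
            road_distance=road_m,
            hotspot_distance=hotspot_km,
            park_mask=in_park,
        )
        return obj

    @property
    def shape(self):
        return self.park_mask.shape

    @property
    def n_cells(self):
        return self.park_mask.size

    @property
    def cell_area(self):
        return self.cell_size**2

    @property
    def area(self):
        return self.extent[0] * self.extent[1]

    def cell_centres(self):
        return cell_centres(self.extent, self.cell_size)

    def cell_index(self, x, y):
        """Row/col of the cell containing planar points (x, y)."""
        col = np.clip((np.asarray(x) / self.cell_size).astype(int), 0, self.shape[1] - 1)
        row = np.clip((np.asarray(y) / self.cell_size).astype(int), 0, self.shape[0] - 1)
        return row, col

    def contains(self, x, y):
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= 0) & (x <= self.extent[0]) & (y >= 0) & (y <= self.extent[1])

    def point_fields(self, x, y):
        """(in_park, hotspot_km, road_m) at arbitrary points, by containing cell.

        The detection field is defined on the analysis grid (piecewise
        constant within each cell), so point evaluation, the likelihood
        and the quadrature of the detection integral are all mutually
        consistent.
        """
        row, col = self.cell_index(x, y)
        return self.park_mask[row, col], self.hotspot_distance[row, col], self.road_distance[row, col]

    # -- persistence -------------------------------------------------------
    def to_dir(self, path):
        """Write distance fields as ASCII grids and geometry as GeoJSON."""
        os.makedirs(path, exist_ok=True)
        write_ascii_grid(os.path.join(path, "road_distance_m.asc"), self.road_distance, self.cell_size)
        write_ascii_grid(os.path.join(path, "hotspot_distance_km.asc"), self.hotspot_distance, self.cell_size)
        write_ascii_grid(os.path.join(path, "park_mask.asc"), self.park_mask.astype(float), self.cell_size)
        features = [{"type": "Feature", "properties": {"kind": "hotspot"}, "geometry": mapping(self.hotspot)}]
        features += [
            {"type": "Feature", "properties": {"kind": "park"}, "geometry": mapping(p)} for p in self.park_polygons
        ]
        features += [
            {"type": "Feature", "properties": {"kind": "road"}, "geometry": mapping(ln)} for ln in self.road_lines
        ]
        meta = {"extent": list(self.extent), "cell_size": self.cell_size, "units": {"road_distance": "m", "hotspot_distance": "km"}}
        with open(os.path.join(path, "geometry.geojson"), "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features, "properties": meta}, fh)

    @classmethod
    def from_dir(cls, path):
        road, cell = read_ascii_grid(os.path.join(path, "road_distance_m.asc"))
        hot, _ = read_ascii_grid(os.path.join(path, "hotspot_distance_km.asc"))
        mask, _ = read_ascii_grid(os.path.join(path, "park_mask.asc"))
        with open(os.path.join(path, "geometry.geojson")) as fh:
            gj = json.load(fh)
        meta = gj.get("properties", {})
        parks, roads, hotspot = [], [], None
        for feat in gj["features"]:
            geom = shape(feat["geometry"])
            kind = feat["properties"].get("kind")
            if kind == "hotspot":
                hotspot = geom
            elif kind == "park":
                parks.append(geom)
            elif kind == "road":
                roads.append(geom)
        ny, nx = road.shape
        extent = tuple(meta.get("extent", (nx * cell, ny * cell)))
        return cls(
            extent=extent,
            cell_size=cell,
            park_polygons=parks,
            hotspot=hotspot,
            road_lines=roads,
            road_distance=road,
            hotspot_distance=hot,
            park_mask=mask > 0.5,
        )


def make_landscape(extent=(50.0, 50.0), n_parks=2, n_roads=3, seed=0, cell_size=1.0):
    """Generate a reproducible random landscape.

    Parks are discs placed away from the border; the hotspot is the centre
    of the first park, snapped to the nearest cell centre so that exactly
    one cell has hotspot distance zero. Roads are straight chords across
    the extent.
    """
    width, height = extent
    if width <= 0 or height <= 0:
        raise ValueError("landscape extent must have positive area")
    rng = np.random.default_rng(seed)
    margin = 0.15
    parks = []
    for _ in range(n_parks):
        cx = rng.uniform(margin * width, (1 - margin) * width)
        cy = rng.uniform(margin * height, (1 - margin) * height)
        r = rng.uniform(0.06, 0.14) * min(width, height)
        parks.append((cx, cy, r))
    if parks:
        cx, cy, r = parks[0]
        # snap hotspot to the nearest cell centre inside the park
        hx = (np.floor(cx / cell_size) + 0.5) * cell_size
        hy = (np.floor(cy / cell_size) + 0.5) * cell_size
        if (hx - cx) ** 2 + (hy - cy) ** 2 > r * r:  # tiny park: recentre on the snap point
            parks[0] = (hx, hy, r)
        hotspot = (hx, hy)
    else:
        hotspot = (width / 2, height / 2)
    roads = []
    for _ in range(n_roads):
        if rng.random() < 0.5:  # west-east chord
            roads.append(((0.0, rng.uniform(0, height)), (width, rng.uniform(0, height))))
        else:
            roads.append(((rng.uniform(0, width), 0.0), (rng.uniform(0, width), height)))
    return SyntheticLandscape.from_geometry(extent, parks, roads, hotspot, cell_size=cell_size)
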