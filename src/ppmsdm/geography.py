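"""Binary range maps and range-size arithmetic on the sphere.

Continuous suitability is reclassified to suitable/unsuitable at a chosen
threshold; suitable area sums exact spherical quadrilateral cell areas
(using cell *edge* latitudes, which avoids the cos-latitude bias of
center-point approximations at coarse cells). Extent of occurrence follows
the IUCN convention: the area of the minimum convex polygon around all
occurrences, optionally restricted to a land mask.

Polygon edges are straight lines in longitude/latitude. Their spherical
area is computed exactly by densifying the edges and mapping to the
cylindrical equal-area plane (x = lon_rad, y = sin(lat)), where planar area
times R^2 equals the sphere area of any lon/lat-bounded region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Polygon

from .grid import EARTH_RADIUS_KM, GeoGrid


@dataclass
class BinaryRangeMap:
    """Suitable(1)/unsuitable(0) grid plus the threshold that produced it."""

    grid: GeoGrid
    threshold: float
    source: str = ""


def binarize(suitability: GeoGrid, threshold: float, source: str = "") -> BinaryRangeMap:
    """Cells >= threshold become 1, the rest 0; nodata is preserved."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    vals = np.where(suitability.mask,
                    (suitability.values >= threshold).astype(float), np.nan)
    return BinaryRangeMap(grid=suitability.with_values(vals),
                          threshold=float(threshold), source=source)


def area_km2(range_map: BinaryRangeMap) -> float:
    """Total spherical area of the suitable cells, km^2."""
    g = range_map.grid
    areas = g.cell_areas_km2()
    suitable = g.mask & (g.values > 0.5)
    return float(areas[suitable].sum())


def mcp(lon, lat) -> Polygon:
    """Minimum convex polygon (convex hull) of points, lon/lat degrees."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if len(lon) < 3:
        raise ValueError("minimum convex polygon needs at least 3 points")
    hull = MultiPoint(np.column_stack([lon, lat])).convex_hull
    if not isinstance(hull, Polygon):
        raise ValueError("points are collinear; no polygon exists")
    return hull


def polygon_area_km2(polygon: Polygon, densify_deg: float = 0.05) -> float:
    """Exact spherical area of a lon/lat polygon (straight lon/lat edges)."""
    def ring_area(coords) -> float:
        pts = np.asarray(coords, dtype=float)
        dense = [pts[0]]
        for a, b in zip(pts[:-1], pts[1:]):
            steps = max(1, int(np.hypot(*(b - a)) / densify_deg))
            for s in range(1, steps + 1):
                dense.append(a + (b - a) * s / steps)
        dense_arr = np.asarray(dense)
        x = np.radians(dense_arr[:, 0])
        y = np.sin(np.radians(dense_arr[:, 1]))
        # shoelace on the equal-area plane
        return 0.5 * abs(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))

    area = ring_area(polygon.exterior.coords)
    for interior in polygon.interiors:
        area -= ring_area(interior.coords)
    return float(area * EARTH_RADIUS_KM ** 2)


def eoo_area_km2(polygon: Polygon, landmask: GeoGrid | None = None) -> float:
    """Extent of occurrence: MCP area, optionally restricted to land cells.

    With a landmask, the area is the summed spherical area of unmasked
    (land) cells whose centers fall inside the polygon.
    """
    if landmask is None:
        return polygon_area_km2(polygon)
    rows, cols = np.nonzero(landmask.mask)
    lon, lat = landmask.cell_center(rows, cols)
    inside = shapely.contains_xy(polygon, lon, lat)
    areas = landmask.cell_areas_km2()
    return float(areas[rows[inside], cols[inside]].sum())


def to_geojson(polygon: Polygon) -> dict:
    return {"type": "Feature", "properties": {"derivation": "MCP"},
            "geometry": shapely.geometry.mapping(polygon)}
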