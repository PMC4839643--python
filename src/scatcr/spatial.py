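"""Minimum-convex-polygon activity areas from scat coordinates."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import MultiPoint
from shapely.geometry.polygon import orient

__all__ = ["RangeEstimate", "mcp", "overlap_area"]


@dataclass
class RangeEstimate:
    individual_id: str
    polygon: list[tuple[float, float]] | None  # CCW vertices, km
    area: float | None  # km^2
    n_points: int

    @property
    def insufficient(self) -> bool:
        return self.polygon is None


def mcp(points, individual_id: str = "") -> RangeEstimate:
    """Convex hull of planar points (km) with shoelace area.

    Fewer than 3 points, or collinear points, give an
    insufficient-points result instead of raising.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of planar km coordinates")
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if hull.geom_type != "Polygon":  # point or line: degenerate
        return RangeEstimate(individual_id, None, None, len(pts))
    hull = orient(hull, sign=1.0)  # counter-clockwise exterior
    verts = list(hull.exterior.coords)[:-1]
    return RangeEstimate(
        individual_id=individual_id,
        polygon=[(float(x), float(y)) for x, y in verts],
        area=float(hull.area),
        n_points=len(pts),
    )


def overlap_area(a: RangeEstimate, b: RangeEstimate) -> float:
    """Pairwise hull-intersection area (exploratory convenience)."""
    if a.insufficient or b.insufficient:
        return 0.0
    from shapely.geometry import Polygon

    return float(Polygon(a.polygon).intersection(Polygon(b.polygon)).area)
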