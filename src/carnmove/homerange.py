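"""Home-range estimation: adaptive local convex hulls and minimum convex
polygons, overall and by season.

The adaptive LoCoH builds, around every location, the convex hull of
that root point plus its nearest neighbors, added in ascending distance
while the cumulative sum of neighbor distances stays within the sphere
of influence ``a``; hulls are then unioned in ascending-area order
until the requested isopleth percentage of locations is covered. The
sphere of influence defaults to the maximum pairwise distance in the
data, per the adaptive ("a") method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.ops import unary_union

__all__ = ["HomeRange", "adaptive_a", "alocoh", "mcp", "seasonal_ranges"]


@dataclass
class HomeRange:
    animal_id: str
    method: str  # "aLoCoH" or "MCP"
    isopleth: float  # percent
    polygon: object  # shapely (Multi)Polygon
    area_km2: float
    season_scope: str = "all"  # all / snow / snow_free
    n_locations: int = 0

    def validate(self) -> None:
        if not (0 < self.isopleth <= 100):
            raise ValueError("isopleth must lie in (0, 100]")
        if self.area_km2 < 0 or not self.polygon.is_valid:
            raise ValueError("invalid home-range polygon")


def adaptive_a(points: np.ndarray) -> float:
    """Sphere of influence: the maximum pairwise distance (m)."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    return float(pdist(points).max())


def _local_hull(points: np.ndarray, root_idx: int, a: float) -> Polygon | None:
    root = points[root_idx]
    d = np.hypot(points[:, 0] - root[0], points[:, 1] - root[1])
    order = np.argsort(d, kind="stable")
    members = []
    cum = 0.0
    for j in order:
        if j == root_idx:
            members.append(j)
            continue
        if cum + d[j] > a:
            break
        cum += d[j]
        members.append(j)
    hull = MultiPoint(points[members]).convex_hull
    return hull if hull.geom_type == "Polygon" else None


def alocoh(points: np.ndarray, a: float | None = None, isopleth: float = 95.0, animal_id: str = "") -> HomeRange:
    """Adaptive local convex hull home range at the given isopleth.

    Duplicate coordinates are deduplicated before hull construction but
    the isopleth coverage is counted over all input points (boundary
    counts as covered). Hull-area ties break by fewer vertices, then
    construction order.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        raise ValueError("need at least 3 points")
    uniq = np.unique(points, axis=0)
    if len(uniq) < 3 or MultiPoint(uniq).convex_hull.geom_type != "Polygon":
        raise ValueError("points are collinear; home-range geometry degenerate")
    if a is None:
        a = adaptive_a(points)
    hulls = []
    for i in range(len(uniq)):
        h = _local_hull(uniq, i, a)
        if h is not None:
            hulls.append((h.area, len(h.exterior.coords), i, h))
    hulls.sort(key=lambda t: (t[0], t[1], t[2]))
    target = isopleth / 100.0 * len(points)
    shapely_pts = [Point(p) for p in points]
    covered = np.zeros(len(points), dtype=bool)
    union = None
    parts = []
    for _, _, _, h in hulls:
        parts.append(h)
        union = unary_union(parts)
        todo = np.nonzero(~covered)[0]
        for idx in todo:
            if union.covers(shapely_pts[idx]):
                covered[idx] = True
        if covered.sum() >= target - 1e-9:
            break
    hr = HomeRange(
        animal_id=animal_id,
        method="aLoCoH",
        isopleth=isopleth,
        polygon=union,
        area_km2=union.area / 1e6,
        n_locations=len(points),
    )
    hr.validate()
    return hr


def mcp(points: np.ndarray, isopleth: float = 95.0, animal_id: str = "") -> HomeRange:
    """Minimum convex polygon after trimming the farthest-from-centroid points.

    The (100 - isopleth)% of points farthest from the arithmetic mean
    location are removed before taking the convex hull.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        raise ValueError("need at least 3 points")
    centroid = points.mean(axis=0)
    d = np.hypot(points[:, 0] - centroid[0], points[:, 1] - centroid[1])
    n_keep = int(np.ceil(isopleth / 100.0 * len(points)))
    keep = np.argsort(d, kind="stable")[:n_keep]
    hull = MultiPoint(points[keep]).convex_hull
    if hull.geom_type != "Polygon":
        raise ValueError("kept points are collinear; MCP degenerate")
    hr = HomeRange(
        animal_id=animal_id,
        method="MCP",
        isopleth=isopleth,
        polygon=hull,
        area_km2=hull.area / 1e6,
        n_locations=len(points),
    )
    hr.validate()
    return hr


def seasonal_ranges(
    fixes: pd.DataFrame,
    isopleth: float = 95.0,
    min_locations: int = 30,
) -> tuple[list[HomeRange], list[dict]]:
    """Both estimators at 95% for all / snow / snow-free partitions.

    ``fixes`` needs x, y, id and a ``season`` column. Partitions with
    fewer than ``min_locations`` observed fixes are skipped with a
    logged reason; returns (ranges, skip log).
    """
    ranges: list[HomeRange] = []
    skipped: list[dict] = []
    obs = fixes[~fixes["x"].isna()]
    for animal, grp in obs.groupby("id", sort=False):
        scopes = {"all": grp}
        if "season" in grp.columns:
            for sname, sgrp in grp.groupby("season", sort=False):
                scopes[str(sname)] = sgrp
        for scope, sdf in scopes.items():
            pts = sdf[["x", "y"]].to_numpy(dtype=float)
            if len(pts) < min_locations:
                skipped.append(
                    {"id": str(animal), "scope": scope, "n": len(pts), "reason": f"fewer than {min_locations} locations"}
                )
                continue
            for fn in (alocoh, mcp):
                hr = fn(pts, isopleth=isopleth, animal_id=str(animal))
                hr.season_scope = scope
                ranges.append(hr)
    return ranges, skipped


def ranges_table(ranges: list[HomeRange]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": r.animal_id,
                "method": r.method,
                "scope": r.season_scope,
                "isopleth": r.isopleth,
                "area_km2": r.area_km2,
                "n": r.n_locations,
            }
            for r in ranges
        ]
    )
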