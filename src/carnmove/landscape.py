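"""Co-registered landscape layers: land cover, elevation, linear corridors.

Land-cover codes follow the four-class scheme used throughout the
analysis: forested, open, wetland/freshwater, and anthropogenic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import LineString, MultiLineString, mapping, shape

from .raster import Raster, read_ascii_grid, write_ascii_grid

__all__ = [
    "FOREST",
    "OPEN",
    "WETLAND",
    "ANTHROPOGENIC",
    "COVER_CLASSES",
    "LandscapeStack",
]

FOREST = 1
OPEN = 2
WETLAND = 3
ANTHROPOGENIC = 4
COVER_CLASSES = {"forest": FOREST, "open": OPEN, "wetland": WETLAND, "anthropogenic": ANTHROPOGENIC}


@dataclass
class LandscapeStack:
    """Co-registered rasters plus the linear-corridor layer.

    ``landcover`` holds integer class codes (see :data:`COVER_CLASSES`),
    ``dem`` elevations in meters. ``corridors`` is a list of shapely
    LineStrings in the same projected coordinates. Derived layers (slope,
    focal statistics) are cached lazily by the covariate module.
    """

    landcover: Raster
    dem: Raster
    corridors: list[LineString] = field(default_factory=list)
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.landcover.values.shape != self.dem.values.shape:
            raise ValueError("landcover and dem grids are not co-registered")
        if self.landcover.cellsize != self.dem.cellsize:
            raise ValueError("landcover and dem cell sizes differ")

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self.landcover.bounds

    @property
    def cellsize(self) -> float:
        return self.landcover.cellsize

    def corridor_multiline(self) -> MultiLineString:
        return MultiLineString(self.corridors)

    # -- text serialization (ASCII grids + GeoJSON) --------------------

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_ascii_grid(self.landcover, directory / "landcover.asc")
        write_ascii_grid(self.dem, directory / "dem.asc")
        features = [
            {"type": "Feature", "properties": {"kind": "corridor"}, "geometry": mapping(line)}
            for line in self.corridors
        ]
        geojson = {"type": "FeatureCollection", "features": features}
        (directory / "corridors.geojson").write_text(json.dumps(geojson))

    @classmethod
    def load(cls, directory) -> "LandscapeStack":
        directory = Path(directory)
        landcover = read_ascii_grid(directory / "landcover.asc")
        landcover.values = landcover.values.astype(int)
        dem = read_ascii_grid(directory / "dem.asc")
        lines = []
        geojson = json.loads((directory / "corridors.geojson").read_text())
        for feat in geojson["features"]:
            lines.append(shape(feat["geometry"]))
        return cls(landcover=landcover, dem=dem, corridors=lines)
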