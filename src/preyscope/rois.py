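"""Anatomical region map and ROI records shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from shapely.geometry import Point, Polygon, box

REGION_NAMES = (
    "OTc-SPV-L",
    "OTc-SPV-R",
    "OTc-Np-L",
    "OTc-Np-R",
    "Hb-L",
    "Hb-R",
    "TL",
)


@dataclass
class RegionMap:
    """Named, non-overlapping 2-D regions of the imaged field (um).

    Coordinates: x grows rightward (negative = left hemisphere), y grows
    caudally from the anterior edge of the field; the posterior-commissure
    landmark anchors anterior-posterior distance measurements.  Default
    geometry sketches a dorsal view of the anterior tectal field: bilateral
    habenulae (anterior), the midline torus longitudinalis, and bilateral
    tectal SPV flanked laterally by neuropil bands.
    """

    regions: dict[str, Polygon] = field(default_factory=dict)
    posterior_commissure: tuple[float, float] = (0.0, 140.0)

    @classmethod
    def default(cls) -> "RegionMap":
        regions = {
            "Hb-L": box(-90.0, 20.0, -15.0, 95.0),
            "Hb-R": box(15.0, 20.0, 90.0, 95.0),
            "TL": box(-45.0, 100.0, 45.0, 150.0),
            "OTc-SPV-L": box(-180.0, 160.0, -30.0, 420.0),
            "OTc-SPV-R": box(30.0, 160.0, 180.0, 420.0),
            "OTc-Np-L": box(-245.0, 160.0, -185.0, 420.0),
            "OTc-Np-R": box(185.0, 160.0, 245.0, 420.0),
        }
        return cls(regions=regions)

    def validate(self) -> None:
        names = list(self.regions)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                inter = self.regions[a].intersection(self.regions[b])
                if inter.area > 0:
                    raise ValueError(f"regions {a} and {b} overlap")

    def lookup(self, x: float, y: float) -> str:
        """Region name containing the point, or 'other'."""
        pt = Point(x, y)
        for name, poly in self.regions.items():
            if poly.contains(pt) or poly.touches(pt):
                return name
        return "other"

    def sample_point(
        self, name: str, rng: np.random.Generator, margin: float = 0.0
    ) -> tuple[float, float]:
        """Uniform random point inside a named region (rejection sampling)."""
        if name not in self.regions:
            raise KeyError(f"unknown region '{name}'")
        poly = self.regions[name]
        if margin > 0:
            poly = poly.buffer(-margin)
            if poly.is_empty:
                raise ValueError(f"region '{name}' empty at margin {margin}")
        minx, miny, maxx, maxy = poly.bounds
        for _ in range(10_000):
            x = rng.uniform(minx, maxx)
            y = rng.uniform(miny, maxy)
            if poly.contains(Point(x, y)):
                return float(x), float(y)
        raise RuntimeError(f"could not sample a point in region '{name}'")

    def ap_distance(self, x: float, y: float) -> float:
        """Anterior-posterior distance (um) from the posterior commissure."""
        return float(y - self.posterior_commissure[1])


def hemisphere_of(x: float, region: str) -> str:
    if region.endswith("-L"):
        return "L"
    if region.endswith("-R"):
        return "R"
    if region in ("TL",):
        return "none"
    return "L" if x < 0 else "R"


@dataclass
class ROIRecord:
    """One segmented (or planted) region of interest."""

    roi_id: int
    x: float                     # centroid, um
    y: float
    fish_id: int = 0
    plane_z: float = 0.0
    hemisphere: str = "none"     # 'L' / 'R' / 'none'
    region: str = "other"
    mask: Optional[np.ndarray] = None          # (n_px, 2) pixel coords
    radius_um: float = 3.0

    @classmethod
    def from_point(
        cls,
        roi_id: int,
        x: float,
        y: float,
        region_map: RegionMap,
        fish_id: int = 0,
        plane_z: float = 0.0,
    ) -> "ROIRecord":
        region = region_map.lookup(x, y)
        return cls(
            roi_id=roi_id,
            x=x,
            y=y,
            fish_id=fish_id,
            plane_z=plane_z,
            hemisphere=hemisphere_of(x, region),
            region=region,
        )
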