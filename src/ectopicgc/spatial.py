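"""Germinal-center geometry and the polarization-fraction statistic.

A germinal center (GC) is represented by its region-of-interest polygon
(delineated on CD95 staining, in µm) and the coordinates of typed cells
inside it (Tfh, GC B, FDC, ...). Three quantities are computed per GC:

* area of the region polygon (µm²),
* cell density: cells of a type per unit area (cells/µm²),
* the polarization fraction: draw the line through the GC centroid
  perpendicular to the axis joining the GC centroid and the cell-type
  centroid, count cells on each side, and report
  ``max(side counts) / n``. Uniformly spread cells give ≈0.5; a cell
  type confined to one half (e.g. the light zone) gives 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

__all__ = [
    "GCRegion",
    "CellPoint",
    "SpatialSample",
    "PolarizationResult",
    "DensityResult",
    "region_area",
    "region_centroid",
    "polarization_fraction",
    "cell_density",
]


@dataclass(frozen=True)
class GCRegion:
    """Simple polygon delimiting one GC, vertices in µm."""

    vertices: tuple[tuple[float, float], ...]
    pixel_size: float | None = None  # µm/pixel when traced from a mask

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            raise ValueError("polygon is self-intersecting or otherwise invalid")
        if poly.area <= 0:
            raise ValueError("degenerate polygon with zero area")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass(frozen=True)
class CellPoint:
    x: float
    y: float
    cell_type: str

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("cell coordinates must be finite")


@dataclass
class SpatialSample:
    """One GC: its region polygon plus typed cell coordinates."""

    gc_id: str
    region: GCRegion
    cells: list[CellPoint] = field(default_factory=list)

    def coords_of(self, cell_type: str, clip: bool = False) -> np.ndarray:
        """(n, 2) coordinates of cells of a type; optionally polygon-clipped."""
        types = {c.cell_type for c in self.cells}
        if cell_type not in types:
            raise ValueError(
                f"unknown cell type {cell_type!r}; available: {sorted(types)}"
            )
        pts = np.array(
            [(c.x, c.y) for c in self.cells if c.cell_type == cell_type], float
        )
        if clip and len(pts):
            poly = self.region.polygon
            keep = [poly.covers(Point(x, y)) for x, y in pts]
            pts = pts[np.array(keep, bool)]
        return pts.reshape(-1, 2)


@dataclass
class PolarizationResult:
    cell_type: str
    n_cells: int
    fraction: float
    degenerate: bool = False
    reason: str | None = None


@dataclass
class DensityResult:
    cell_type: str
    n_cells: int
    area: float
    density: float


def region_area(region: GCRegion) -> float:
    """Polygon (shoelace) area in µm², orientation-independent."""
    return region.polygon.area


def region_centroid(region: GCRegion) -> tuple[float, float]:
    """Area centroid of the polygon (continuous analogue of averaging
    the mask pixels)."""
    c = region.polygon.centroid
    return (c.x, c.y)


def polarization_fraction(sample: SpatialSample, cell_type: str,
                          tol: float = 0.0,
                          clip: bool = False) -> PolarizationResult:
    """Fraction of cells on the heavier side of the centroid-axis split.

    Let ``c`` be the region centroid and ``m`` the mean coordinate of
    the cells of ``cell_type``; cells are split by the line through
    ``c`` perpendicular to ``d = m − c`` and the larger side count is
    divided by the total. Cells whose projection onto ``d`` lies within
    ``tol`` of the line count half to each side. When ``|d| <= tol``
    (cell centroid coincides with the region centroid) or fewer than two
    cells are present, the direction is undefined and the maximally
    unpolarized value 0.5 is reported with ``degenerate=True``.
    """
    pts = sample.coords_of(cell_type, clip=clip)
    n = len(pts)
    if n == 0:
        return PolarizationResult(cell_type, 0, 0.5, True, "no cells")
    if n < 2:
        return PolarizationResult(cell_type, n, 0.5, True, "fewer than 2 cells")
    c = np.array(region_centroid(sample.region))
    d = pts.mean(axis=0) - c
    if np.hypot(*d) <= tol:
        return PolarizationResult(cell_type, n, 0.5, True,
                                  "cell centroid coincides with region centroid")
    proj = (pts - c) @ d
    pos = np.count_nonzero(proj > tol) + 0.5 * np.count_nonzero(np.abs(proj) <= tol)
    neg = np.count_nonzero(proj < -tol) + 0.5 * np.count_nonzero(np.abs(proj) <= tol)
    return PolarizationResult(cell_type, n, max(pos, neg) / n)


def cell_density(sample: SpatialSample, cell_type: str,
                 clip: bool = False) -> DensityResult:
    """Cells of a type per unit region area (cells/µm²)."""
    try:
        pts = sample.coords_of(cell_type, clip=clip)
    except ValueError:
        pts = np.empty((0, 2))
    area = region_area(sample.region)
    return DensityResult(cell_type, len(pts), area, len(pts) / area)


def summarize_sample(sample: SpatialSample, cell_types: Sequence[str],
                     tol: float = 0.0, clip: bool = False) -> pd.DataFrame:
    """Area, density, and polarization for each requested cell type."""
    rows = []
    for ct in cell_types:
        dens = cell_density(sample, ct, clip=clip)
        if dens.n_cells:
            pol = polarization_fraction(sample, ct, tol=tol, clip=clip)
        else:
            pol = PolarizationResult(ct, 0, 0.5, True, "no cells")
        rows.append(
            dict(gc_id=sample.gc_id, cell_type=ct, n=dens.n_cells,
                 area_um2=dens.area, density=dens.density,
                 polarization_fraction=pol.fraction, degenerate=pol.degenerate)
        )
    return pd.DataFrame(rows)
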