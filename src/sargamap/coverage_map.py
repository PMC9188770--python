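"""Choropleth tessellation: 30 m grid cells, five-level binning, GeoJSON.

Per-photo coverages are aggregated onto a square tessellation in a
projected metric CRS. Cells are ``cell_size_m`` squares (30 m by
default, matching the Landsat OLI/TIRS pixel footprint) with half-open
extents ``[x0, x0 + s) x [y0, y0 + s)``; a photo's cell is
``(floor(x / s), floor(y / s))`` after origin snapping. Cell means are
binned on the five 20-percent intervals [0, 20], (20, 40], (40, 60],
(60, 80], (80, 100] and colored dark green → light green → yellow →
orange → dark red.

The projection is WGS84 UTM (transverse Mercator, Snyder series —
implemented here; the zone is auto-selected from the mean longitude, or
fixed via :class:`GridSpec`). True Landsat-scene alignment is
scene-dependent; an explicit affine origin override (``origin_x`` /
``origin_y``) allows exact alignment to a user-supplied geotransform.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path

import numpy as np
from shapely.geometry import Point, Polygon, mapping

from .io_dataset import GeoPhotoRecord

__all__ = [
    "GridSpec",
    "GridCell",
    "BinScale",
    "utm_zone",
    "to_utm",
    "from_utm",
    "assign_cell",
    "cell_of_xy",
    "aggregate",
    "export_map",
    "temporal_filter",
]

# WGS84 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257223563
_E2 = _F * (2.0 - _F)
_EP2 = _E2 / (1.0 - _E2)
_K0 = 0.9996
_E4, _E6 = _E2**2, _E2**3


def utm_zone(longitude: float) -> int:
    """UTM zone number (1-60) for a longitude in decimal degrees."""
    return int((longitude + 180.0) // 6.0) % 60 + 1


def _central_meridian(zone: int) -> float:
    return -183.0 + 6.0 * zone


def to_utm(
    latitude: float, longitude: float, zone: int | None = None
) -> tuple[float, float, int]:
    """WGS84 geographic → UTM easting/northing (meters).

    Northern-hemisphere convention (no false northing offset for the
    south; the study-area abstraction is a single hemisphere grid).
    Returns ``(easting, northing, zone)``.
    """
    if zone is None:
        zone = utm_zone(longitude)
    phi = math.radians(latitude)
    lam = math.radians(longitude)
    lam0 = math.radians(_central_meridian(zone))
    sin_phi, cos_phi, tan_phi = math.sin(phi), math.cos(phi), math.tan(phi)
    n = _A / math.sqrt(1.0 - _E2 * sin_phi**2)
    t = tan_phi**2
    c = _EP2 * cos_phi**2
    a_ = cos_phi * (lam - lam0)
    m = _A * (
        (1 - _E2 / 4 - 3 * _E4 / 64 - 5 * _E6 / 256) * phi
        - (3 * _E2 / 8 + 3 * _E4 / 32 + 45 * _E6 / 1024) * math.sin(2 * phi)
        + (15 * _E4 / 256 + 45 * _E6 / 1024) * math.sin(4 * phi)
        - (35 * _E6 / 3072) * math.sin(6 * phi)
    )
    x = _K0 * n * (
        a_
        + (1 - t + c) * a_**3 / 6
        + (5 - 18 * t + t**2 + 72 * c - 58 * _EP2) * a_**5 / 120
    ) + 500000.0
    y = _K0 * (
        m
        + n
        * tan_phi
        * (
            a_**2 / 2
            + (5 - t + 9 * c + 4 * c**2) * a_**4 / 24
            + (61 - 58 * t + t**2 + 600 * c - 330 * _EP2) * a_**6 / 720
        )
    )
    return x, y, zone


def from_utm(easting: float, northing: float, zone: int) -> tuple[float, float]:
    """UTM easting/northing → WGS84 (latitude, longitude)."""
    x = easting - 500000.0
    y = northing
    m = y / _K0
    mu = m / (_A * (1 - _E2 / 4 - 3 * _E4 / 64 - 5 * _E6 / 256))
    e1 = (1 - math.sqrt(1 - _E2)) / (1 + math.sqrt(1 - _E2))
    phi1 = (
        mu
        + (3 * e1 / 2 - 27 * e1**3 / 32) * math.sin(2 * mu)
        + (21 * e1**2 / 16 - 55 * e1**4 / 32) * math.sin(4 * mu)
        + (151 * e1**3 / 96) * math.sin(6 * mu)
        + (1097 * e1**4 / 512) * math.sin(8 * mu)
    )
    sin1, cos1, tan1 = math.sin(phi1), math.cos(phi1), math.tan(phi1)
    n1 = _A / math.sqrt(1 - _E2 * sin1**2)
    r1 = _A * (1 - _E2) / (1 - _E2 * sin1**2) ** 1.5
    c1 = _EP2 * cos1**2
    t1 = tan1**2
    d = x / (n1 * _K0)
    phi = phi1 - (n1 * tan1 / r1) * (
        d**2 / 2
        - (5 + 3 * t1 + 10 * c1 - 4 * c1**2 - 9 * _EP2) * d**4 / 24
        + (61 + 90 * t1 + 298 * c1 + 45 * t1**2 - 252 * _EP2 - 3 * c1**2)
        * d**6
        / 720
    )
    lam = (
        d
        - (1 + 2 * t1 + c1) * d**3 / 6
        + (5 - 2 * c1 + 28 * t1 - 3 * c1**2 + 8 * _EP2 + 24 * t1**2) * d**5 / 120
    ) / cos1
    return math.degrees(phi), _central_meridian(zone) + math.degrees(lam)


# ---------------------------------------------------------------------------
# grid


@dataclass
class GridSpec:
    """Square-tessellation parameters.

    ``utm_zone`` fixes the projection zone (auto from data when None);
    ``origin_snap`` snaps the grid origin to integer multiples of the
    cell size; ``origin_x`` / ``origin_y`` shift the grid to align with
    an external geotransform (applied before snapping arithmetic).
    """

    cell_size_m: float = 30.0
    utm_zone: int | None = None
    origin_snap: bool = True
    origin_x: float = 0.0
    origin_y: float = 0.0

    def __post_init__(self) -> None:
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")


#: Default five-color scale (dark green → dark red).
_DEFAULT_COLORS = ("#1a9641", "#a6d96a", "#ffffbf", "#fdae61", "#d7191c")


@dataclass
class BinScale:
    """Five equal 20 % coverage intervals and their map colors.

    Interval closure: [0, 20], (20, 40], (40, 60], (60, 80], (80, 100] —
    every value in [0, 100] belongs to exactly one bin.
    """

    colors: tuple[str, ...] = _DEFAULT_COLORS

    def __post_init__(self) -> None:
        if len(self.colors) != 5 or len(set(self.colors)) != 5:
            raise ValueError("need 5 distinct colors")

    def bin_of(self, coverage_pct: float) -> int:
        if not 0.0 <= coverage_pct <= 100.0:
            raise ValueError(f"coverage {coverage_pct} outside [0, 100]")
        return max(1, math.ceil(coverage_pct / 20.0))

    def color_of(self, coverage_pct: float) -> str:
        return self.colors[self.bin_of(coverage_pct) - 1]


@dataclass
class GridCell:
    cell_id: tuple[int, int]  # (column, row) in the projected grid
    polygon_utm: list[tuple[float, float]]  # 4 corners, counter-clockwise
    polygon_wgs84: list[tuple[float, float]]  # (lon, lat) pairs
    mean_coverage: float
    n_photos: int
    bin: int
    color: str
    utm_zone: int = 0
    member_coverages: list[float] = field(default_factory=list)


def cell_of_xy(x: float, y: float, grid: GridSpec) -> tuple[int, int]:
    """Cell id ``(floor(x/s), floor(y/s))`` for projected coordinates.

    Cells are half-open ``[x0, x0+s) x [y0, y0+s)``: a point on a shared
    edge belongs to the cell whose lower-left corner it is.
    """
    s = grid.cell_size_m
    return (
        int(math.floor((x - grid.origin_x) / s)),
        int(math.floor((y - grid.origin_y) / s)),
    )


def assign_cell(
    record: GeoPhotoRecord, grid: GridSpec, zone: int | None = None
) -> tuple[int, int]:
    """Cell id of a record: project to the grid CRS, then floor-divide."""
    zone = zone if zone is not None else grid.utm_zone
    x, y, _ = to_utm(record.latitude, record.longitude, zone)
    return cell_of_xy(x, y, grid)


def aggregate(
    records: list[GeoPhotoRecord],
    grid: GridSpec | None = None,
    scale: BinScale | None = None,
) -> list[GridCell]:
    """Group records by grid cell; mean coverage, photo count, bin, color.

    All records must have defined coverage (undefined ones are excluded
    upstream). Cells with no photos are not emitted; output is sorted by
    cell id.
    """
    grid = grid or GridSpec()
    scale = scale or BinScale()
    if not records:
        return []
    for r in records:
        if r.coverage_pct is None:
            raise ValueError(f"record {r.image_id} has undefined coverage")
    zone = (
        grid.utm_zone
        if grid.utm_zone is not None
        else utm_zone(float(np.mean([r.longitude for r in records])))
    )
    groups: dict[tuple[int, int], list[float]] = {}
    for r in records:
        groups.setdefault(assign_cell(r, grid, zone), []).append(
            float(r.coverage_pct)  # type: ignore[arg-type]
        )
    s = grid.cell_size_m
    cells = []
    for cid in sorted(groups):
        col, row = cid
        x0 = grid.origin_x + col * s
        y0 = grid.origin_y + row * s
        corners = [(x0, y0), (x0 + s, y0), (x0 + s, y0 + s), (x0, y0 + s)]
        covs = groups[cid]
        mean = float(np.mean(covs))
        cells.append(
            GridCell(
                cell_id=cid,
                polygon_utm=corners,
                polygon_wgs84=[
                    (lon, lat)
                    for lat, lon in (from_utm(cx, cy, zone) for cx, cy in corners)
                ],
                mean_coverage=mean,
                n_photos=len(covs),
                bin=scale.bin_of(mean),
                color=scale.color_of(mean),
                utm_zone=zone,
                member_coverages=covs,
            )
        )
    return cells


def export_map(
    cells: list[GridCell],
    records: list[GeoPhotoRecord],
    out_dir: Path | str,
) -> dict[str, Path]:
    """Write GIS-ready layers: coverage-grid polygons and photo points.

    ``grid.geojson``: one polygon feature per cell (closed 5-vertex
    ring, WGS84) with cell_id, mean_coverage, n_photos, bin, color.
    ``photos.geojson``: one point per record with a presence flag
    (coverage > 0). ``cells.csv``: tabular cell summary. Feature order
    is deterministic (by cell id / record order).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    features = []
    for cell in sorted(cells, key=lambda c: c.cell_id):
        ring = cell.polygon_wgs84 + [cell.polygon_wgs84[0]]
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(Polygon(ring)),
                "properties": {
                    "cell_id": list(cell.cell_id),
                    "mean_coverage": cell.mean_coverage,
                    "n_photos": cell.n_photos,
                    "bin": cell.bin,
                    "color": cell.color,
                },
            }
        )
    grid_path = out_dir / "grid.geojson"
    with open(grid_path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)

    photo_features = []
    for r in records:
        photo_features.append(
            {
                "type": "Feature",
                "geometry": mapping(Point(r.longitude, r.latitude)),
                "properties": {
                    "image_id": r.image_id,
                    "coverage_pct": r.coverage_pct,
                    "presence": bool(
                        r.coverage_pct is not None and r.coverage_pct > 0
                    ),
                    "timestamp": r.timestamp.isoformat() if r.timestamp else None,
                },
            }
        )
    photos_path = out_dir / "photos.geojson"
    with open(photos_path, "w") as fh:
        json.dump(
            {"type": "FeatureCollection", "features": photo_features}, fh, indent=1
        )

    csv_path = out_dir / "cells.csv"
    with open(csv_path, "w") as fh:
        fh.write("column,row,mean_coverage,n_photos,bin\n")
        for cell in sorted(cells, key=lambda c: c.cell_id):
            fh.write(
                f"{cell.cell_id[0]},{cell.cell_id[1]},"
                f"{cell.mean_coverage!r},{cell.n_photos},{cell.bin}\n"
            )
    return {"grid": grid_path, "photos": photos_path, "cells": csv_path}


def temporal_filter(
    records: list[GeoPhotoRecord],
    date_range: tuple[date | datetime, date | datetime],
) -> list[GeoPhotoRecord]:
    """Inclusive date-range filter for per-date or per-season maps."""
    start, end = date_range
    out = []
    for r in records:
        if r.timestamp is None:
            raise ValueError(f"record {r.image_id} lacks a timestamp")
        t: date | datetime = r.timestamp
        if isinstance(start, date) and not isinstance(start, datetime):
            t = r.timestamp.date()
        if start <= t <= end:
            out.append(r)
    return out
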