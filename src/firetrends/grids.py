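"""Grid bookkeeping: regular lat/lon grids, forest masks, resampling, rasterization.

All rasters are row-major from the north-west corner; coordinates are
cell-center referenced. Grids are plain geographic latitude/longitude; the
GDA94 vs WGS84 datum offset (< 2 m) is sub-pixel at the resolutions used
here and is carried only as a label.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "R_EARTH_KM",
    "GridSpec",
    "ForestMask",
    "FirePerimeter",
    "cell_area_km2",
    "majority_resample",
    "nearest_neighbour_resample",
    "rasterize_perimeters",
    "rasterize_annual",
    "read_geojson_perimeters",
    "write_geotiff",
    "read_geotiff",
]

#: Mean Earth radius used for spherical cell areas, km.
R_EARTH_KM = 6371.0


@dataclass(frozen=True)
class GridSpec:
    """A regular geographic grid.

    ``lat_origin``/``lon_origin`` are the *edges* of the north-west corner
    cell (not its center); rows run southward, columns eastward.
    """

    nrows: int
    ncols: int
    lat_origin: float
    lon_origin: float
    cell_size: float
    datum: str = "GDA94"

    def __post_init__(self) -> None:
        if self.nrows <= 0 or self.ncols <= 0:
            raise ValueError("grid dimensions must be positive")
        if not (self.cell_size > 0):
            raise ValueError("cell size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def lat_edges(self) -> np.ndarray:
        return self.lat_origin - np.arange(self.nrows + 1) * self.cell_size

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_origin - (np.arange(self.nrows) + 0.5) * self.cell_size

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_origin + (np.arange(self.ncols) + 0.5) * self.cell_size

    def to_dict(self) -> dict:
        return {
            "nrows": self.nrows,
            "ncols": self.ncols,
            "lat_origin": self.lat_origin,
            "lon_origin": self.lon_origin,
            "cell_size": self.cell_size,
            "datum": self.datum,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(**d)


@dataclass
class ForestMask:
    """Static boolean forest/non-forest raster on a :class:`GridSpec`."""

    mask: np.ndarray
    grid: GridSpec
    classes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match grid {self.grid.shape}"
            )

    @property
    def n_forest(self) -> int:
        return int(self.mask.sum())


@dataclass
class FirePerimeter:
    """One mapped fire perimeter with its year and cause attribute."""

    geometry: BaseGeometry
    year: int | None
    cause: str = "wildfire"


def cell_area_km2(grid: GridSpec) -> np.ndarray:
    """Spherical-Earth cell areas, km² per cell.

    Area of a lat/lon quadrangle: R²·Δλ·(sin φ_top − sin φ_bottom). Constant
    along a latitude band, so the result is a (nrows, ncols) array with equal
    rows repeated.
    """
    dlam = np.radians(grid.cell_size)
    edges = np.radians(grid.lat_edges)
    band = R_EARTH_KM**2 * dlam * (np.sin(edges[:-1]) - np.sin(edges[1:]))
    return np.broadcast_to(band[:, None], grid.shape).copy()


def majority_resample(mask: ForestMask, factor: int) -> ForestMask:
    """Coarsen a forest mask by an integer factor using majority rule.

    A coarse cell is forest iff strictly more than half of its constituent
    fine cells are forest; an exact 50% tie resolves to non-forest
    (conservative mask).
    """
    if factor <= 0:
        raise ValueError("factor must be a positive integer")
    nr, nc = mask.grid.shape
    if nr % factor or nc % factor:
        raise ValueError(f"factor {factor} does not divide grid dimensions {nr}x{nc}")
    blocks = mask.mask.reshape(nr // factor, factor, nc // factor, factor)
    counts = blocks.sum(axis=(1, 3))
    coarse = counts * 2 > factor * factor  # strict majority; tie -> non-forest
    grid = GridSpec(
        nrows=nr // factor,
        ncols=nc // factor,
        lat_origin=mask.grid.lat_origin,
        lon_origin=mask.grid.lon_origin,
        cell_size=mask.grid.cell_size * factor,
        datum=mask.grid.datum,
    )
    return ForestMask(mask=coarse, grid=grid, classes=mask.classes)


def nearest_neighbour_resample(
    values: np.ndarray, source: GridSpec, target: GridSpec
) -> np.ndarray:
    """Resample a raster to a new grid by nearest cell-center assignment.

    Values are copied, never interpolated. Raises if the target grid has no
    overlap with the source extent.
    """
    values = np.asarray(values)
    if values.shape != source.shape:
        raise ValueError("raster shape does not match source grid")
    ri = np.rint((source.lat_origin - target.lat_centers) / source.cell_size - 0.5)
    ci = np.rint((target.lon_centers - source.lon_origin) / source.cell_size - 0.5)
    if ri.max() < 0 or ri.min() > source.nrows - 1 or ci.max() < 0 or ci.min() > source.ncols - 1:
        raise ValueError("target grid does not overlap the source extent")
    ri = np.clip(ri.astype(int), 0, source.nrows - 1)
    ci = np.clip(ci.astype(int), 0, source.ncols - 1)
    return values[np.ix_(ri, ci)]


def rasterize_perimeters(
    geometries: Iterable[BaseGeometry], grid: GridSpec
) -> np.ndarray:
    """Burn polygons onto a grid: a cell is marked iff its center lies inside
    (or on the boundary of) any polygon. Returns a boolean raster.
    """
    out = np.zeros(grid.shape, dtype=bool)
    latc = grid.lat_centers
    lonc = grid.lon_centers
    for geom in geometries:
        if geom is None or geom.is_empty:
            continue
        minx, miny, maxx, maxy = geom.bounds
        rows = np.nonzero((latc >= miny) & (latc <= maxy))[0]
        cols = np.nonzero((lonc >= minx) & (lonc <= maxx))[0]
        if rows.size == 0 or cols.size == 0:
            warnings.warn("perimeter outside grid extent; skipped", stacklevel=2)
            continue
        lon2, lat2 = np.meshgrid(lonc[cols], latc[rows])
        # intersects includes the boundary, so edge-touching centers count
        hit = shapely.intersects_xy(geom, lon2.ravel(), lat2.ravel())
        out[np.ix_(rows, cols)] |= hit.reshape(lat2.shape)
    return out


def rasterize_annual(
    perimeters: Iterable[FirePerimeter], grid: GridSpec
) -> dict[tuple[int, str], np.ndarray]:
    """Rasterize a perimeter collection into per-(year, cause) boolean rasters."""
    groups: dict[tuple[int, str], list[BaseGeometry]] = {}
    for p in perimeters:
        if p.year is None:
            raise ValueError("perimeter is missing its year attribute")
        groups.setdefault((int(p.year), p.cause), []).append(p.geometry)
    return {key: rasterize_perimeters(geoms, grid) for key, geoms in sorted(groups.items())}


def read_geojson_perimeters(
    path, year_field: str = "year", cause_field: str = "cause"
) -> list[FirePerimeter]:
    """Read fire perimeters from a GeoJSON FeatureCollection.

    Attribute field names are configurable since agency schemas differ.
    """
    with open(path) as fh:
        doc = json.load(fh)
    feats = doc["features"] if doc.get("type") == "FeatureCollection" else [doc]
    out = []
    for feat in feats:
        props = feat.get("properties") or {}
        year = props.get(year_field)
        out.append(
            FirePerimeter(
                geometry=shapely_shape(feat["geometry"]),
                year=None if year is None else int(year),
                cause=str(props.get(cause_field, "wildfire")),
            )
        )
    return out


# -- raster file I/O ---------------------------------------------------------

_GEOTIFF_PIXELSCALE = 33550
_GEOTIFF_TIEPOINT = 33922


def write_geotiff(path, array: np.ndarray, grid: GridSpec) -> None:
    """Write a raster (2-D, or 3-D with one band per year/month) as GeoTIFF.

    The grid is encoded both in standard GeoTIFF ModelPixelScale/ModelTiepoint
    tags and as JSON in the image description, which is what :func:`read_geotiff`
    round-trips.
    """
    import tifffile

    array = np.asarray(array)
    meta = {"grid": grid.to_dict(), "dtype": str(array.dtype)}
    if array.dtype == bool:
        array = array.astype(np.uint8)
    extratags = [
        (_GEOTIFF_PIXELSCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_GEOTIFF_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.lon_origin, grid.lat_origin, 0.0)),
    ]
    tifffile.imwrite(path, array, description=json.dumps(meta), extratags=extratags)


def read_geotiff(path) -> tuple[np.ndarray, GridSpec]:
    """Read a raster written by :func:`write_geotiff`."""
    import tifffile

    with tifffile.TiffFile(path) as tf:
        array = tf.asarray()
        desc = tf.pages[0].description
    meta = json.loads(desc)
    if meta.get("dtype") == "bool":
        array = array.astype(bool)
    return array, GridSpec.from_dict(meta["grid"])
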