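"""Georeferenced raster grids and GeoTIFF I/O.

A :class:`RasterGrid` is the universal exchange unit of the pipeline: one
single-band 2-D layer with an affine georeference, a CRS identifier and a
nodata sentinel.  Grids are read from and written to plain single-band
GeoTIFF files using the standard GeoTIFF tags (ModelPixelScale,
ModelTiepoint, GeoKeyDirectory) plus the GDAL_NODATA convention tag.

Only north-up grids (no rotation/shear) are supported; the analysis grid of
a study is the land-cover grid of the first date and every other layer is
aligned to it with :func:`align_to_grid`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "Affine",
    "RasterGrid",
    "RasterStack",
    "read_raster",
    "write_raster",
    "align_to_grid",
]

# GeoTIFF / GDAL tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey ids
_KEY_MODEL_TYPE = 1024
_KEY_RASTER_TYPE = 1025
_KEY_GEOGRAPHIC_CS = 2048
_KEY_PROJECTED_CS = 3072


@dataclass(frozen=True)
class Affine:
    """North-up affine georeference: ``x = c + a*col``, ``y = f + e*row``.

    ``a`` is the pixel width (map units), ``e`` the pixel height and is
    negative for the usual row-0-at-top orientation, ``(c, f)`` the map
    coordinates of the outer corner of pixel (0, 0).
    """

    a: float
    e: float
    c: float
    f: float

    @classmethod
    def from_origin(cls, west: float, north: float, xres: float, yres: float) -> "Affine":
        """Build a transform from the upper-left corner and pixel sizes (yres > 0)."""
        return cls(a=float(xres), e=-float(yres), c=float(west), f=float(north))

    def xy(self, row, col):
        """Map coordinates of the center of pixel (row, col)."""
        x = self.c + (np.asarray(col) + 0.5) * self.a
        y = self.f + (np.asarray(row) + 0.5) * self.e
        return x, y

    def rowcol_float(self, x, y):
        """Fractional (row, col) pixel-center coordinates of map point (x, y)."""
        col = (np.asarray(x) - self.c) / self.a - 0.5
        row = (np.asarray(y) - self.f) / self.e - 0.5
        return row, col

    def almost_equals(self, other: "Affine", tol: float = 1e-9) -> bool:
        return (
            math.isclose(self.a, other.a, rel_tol=0, abs_tol=tol * abs(self.a))
            and math.isclose(self.e, other.e, rel_tol=0, abs_tol=tol * abs(self.e))
            and math.isclose(self.c, other.c, rel_tol=0, abs_tol=max(tol, tol * abs(self.c)))
            and math.isclose(self.f, other.f, rel_tol=0, abs_tol=max(tol, tol * abs(self.f)))
        )


@dataclass
class RasterGrid:
    """One georeferenced 2-D layer.

    Parameters
    ----------
    values
        2-D array, shape (rows, cols).  Continuous layers conventionally use
        float dtype with NaN marking missing cells when ``nodata`` is None.
    transform
        Affine georeference of the grid.
    crs
        Coordinate system identifier, ``"EPSG:<code>"``.
    nodata
        Sentinel for missing cells; must not collide with a valid category
        code in categorical grids.  ``None`` means NaN-is-nodata for float
        grids and no missing data for integer grids.
    """

    values: np.ndarray
    transform: Affine
    crs: str = "EPSG:4326"
    nodata: float | int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("values must be a 2-D array with rows, cols >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells carrying data."""
        if self.nodata is not None:
            if np.issubdtype(self.values.dtype, np.floating) and np.isnan(self.nodata):
                return ~np.isnan(self.values)
            return self.values != self.nodata
        if np.issubdtype(self.values.dtype, np.floating):
            return ~np.isnan(self.values)
        return np.ones(self.shape, dtype=bool)

    def is_aligned_with(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and self.crs == other.crs
            and self.transform.almost_equals(other.transform)
        )

    def with_values(self, values: np.ndarray, nodata: float | int | None = None) -> "RasterGrid":
        """A new grid on the same georeference carrying different values."""
        return RasterGrid(values=values, transform=self.transform, crs=self.crs, nodata=nodata)

    def copy(self) -> "RasterGrid":
        return replace(self, values=self.values.copy())


@dataclass
class RasterStack:
    """An ordered set of mutually aligned layers with unique labels."""

    layers: list[RasterGrid]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.layers) != len(self.labels):
            raise ValueError("one label per layer required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        if self.layers:
            ref = self.layers[0]
            for lab, lay in zip(self.labels, self.layers):
                if not lay.is_aligned_with(ref):
                    raise ValueError(f"layer {lab!r} is not aligned with the first layer")

    def __len__(self) -> int:
        return len(self.layers)

    def __iter__(self):
        return iter(self.layers)

    def get(self, label: str) -> RasterGrid:
        try:
            return self.layers[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"no layer labelled {label!r}") from None

    def subset(self, labels: Sequence[str]) -> "RasterStack":
        return RasterStack([self.get(l) for l in labels], list(labels))

    def as_array(self) -> np.ndarray:
        """(n_layers, rows, cols) float array with nodata as NaN."""
        out = np.empty((len(self.layers),) + self.layers[0].shape, dtype=float)
        for i, lay in enumerate(self.layers):
            vals = lay.values.astype(float)
            vals[~lay.valid_mask()] = np.nan
            out[i] = vals
        return out


def _epsg_code(crs: str) -> int:
    try:
        auth, code = crs.split(":")
        if auth.upper() != "EPSG":
            raise ValueError
        return int(code)
    except Exception:
        raise ValueError(f"unreadable CRS {crs!r}; expected 'EPSG:<code>'") from None


def _geokeys_for(crs: str) -> tuple[int, ...]:
    code = _epsg_code(crs)
    geographic = 4000 <= code < 5000
    keys = [
        (_KEY_MODEL_TYPE, 0, 1, 2 if geographic else 1),
        (_KEY_RASTER_TYPE, 0, 1, 1),  # PixelIsArea
        (_KEY_GEOGRAPHIC_CS if geographic else _KEY_PROJECTED_CS, 0, 1, code),
    ]
    header = (1, 1, 0, len(keys))
    return header + tuple(v for key in keys for v in key)


def _crs_from_geokeys(directory: Sequence[int]) -> str:
    keys = np.asarray(directory).reshape(-1, 4)[1:]
    for key_id in (_KEY_PROJECTED_CS, _KEY_GEOGRAPHIC_CS):
        hit = keys[keys[:, 0] == key_id]
        if len(hit):
            return f"EPSG:{int(hit[0, 3])}"
    raise ValueError("unreadable CRS: GeoKeyDirectory lacks an EPSG code")


def write_raster(grid: RasterGrid, path: str | Path) -> None:
    """Write a grid as a single-band GeoTIFF.

    Integer grids round-trip bit-exactly; float grids are stored as float32
    (value error bounded by float32 resolution, < 1e-6 for ESI-scale data).
    """
    path = Path(path)
    values = grid.values
    if np.issubdtype(values.dtype, np.floating):
        values = values.astype(np.float32)
    t = grid.transform
    geokeys = _geokeys_for(grid.crs)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (abs(t.a), abs(t.e), 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.c, t.f, 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys),
    ]
    nodata_text = None
    if grid.nodata is not None:
        nodata_text = repr(grid.nodata)
    elif np.issubdtype(grid.values.dtype, np.floating):
        nodata_text = "nan"
    if nodata_text is not None:
        extratags.append((_TAG_GDAL_NODATA, "s", len(nodata_text) + 1, nodata_text))
    tifffile.imwrite(path, values, extratags=extratags)


def read_raster(path: str | Path) -> RasterGrid:
    """Read a single-band GeoTIFF written with standard georeference tags."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        if values.ndim == 3:
            raise ValueError(f"{path}: multi-band file; supply one band per file")
        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing georeference tags")
        sx, sy = tags[_TAG_MODEL_PIXEL_SCALE].value[:2]
        tp = tags[_TAG_MODEL_TIEPOINT].value
        # tie point maps raster (col=tp[0], row=tp[1]) corner to map (tp[3], tp[4])
        west = tp[3] - tp[0] * sx
        north = tp[4] + tp[1] * sy
        transform = Affine.from_origin(west, north, sx, sy)
        if _TAG_GEO_KEY_DIRECTORY not in tags:
            raise ValueError(f"{path}: unreadable CRS (no GeoKeyDirectory)")
        crs = _crs_from_geokeys(tags[_TAG_GEO_KEY_DIRECTORY].value)
        nodata: float | int | None = None
        if _TAG_GDAL_NODATA in tags:
            text = str(tags[_TAG_GDAL_NODATA].value).strip().strip("\x00")
            if text.lower() == "nan":
                nodata = None  # NaN convention for float grids
            elif np.issubdtype(values.dtype, np.integer):
                nodata = int(float(text))
            else:
                nodata = float(text)
    return RasterGrid(values=values, transform=transform, crs=crs, nodata=nodata)


def _is_categorical(grid: RasterGrid) -> bool:
    return np.issubdtype(grid.values.dtype, np.integer) or grid.values.dtype == bool


def align_to_grid(
    grid: RasterGrid,
    template: RasterGrid,
    resampling: str = "nearest",
) -> RasterGrid:
    """Resample ``grid`` onto the georeference of ``template``.

    ``nearest`` picks, for each template cell, the source category at the
    template cell center (mandatory for categorical layers); ``bilinear``
    interpolates the four surrounding source cell centers and is reserved
    for continuous layers.  Cells falling outside the source extent, or
    (for bilinear) touching a source nodata cell, come out nodata.
    """
    if resampling not in ("nearest", "bilinear"):
        raise ValueError(f"unknown resampling {resampling!r}")
    if resampling == "bilinear" and _is_categorical(grid):
        raise ValueError("bilinear resampling requested on categorical data")
    _epsg_code(grid.crs), _epsg_code(template.crs)
    if grid.crs != template.crs:
        raise ValueError(f"CRS mismatch ({grid.crs} vs {template.crs}); reproject upstream")
    if grid.is_aligned_with(template):
        return grid.copy()

    rows, cols = template.shape
    x, y = template.transform.xy(*np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij"))
    src_rowf, src_colf = grid.transform.rowcol_float(x, y)

    nr, nc = grid.shape
    if resampling == "nearest":
        # containing-cell lookup at the template cell center
        r_idx = np.floor(src_rowf + 0.5).astype(int)
        c_idx = np.floor(src_colf + 0.5).astype(int)
        inside = (r_idx >= 0) & (r_idx < nr) & (c_idx >= 0) & (c_idx < nc)
        if not inside.any():
            raise ValueError("no overlap between grid and template extents")
        if np.issubdtype(grid.values.dtype, np.floating):
            src = grid.values.copy()
            src[~grid.valid_mask()] = np.nan
            out = np.full(template.shape, np.nan, dtype=src.dtype)
            out[inside] = src[r_idx[inside], c_idx[inside]]
            return RasterGrid(out, template.transform, template.crs, nodata=None)
        out_nodata = grid.nodata if grid.nodata is not None else -1
        out = np.full(template.shape, out_nodata, dtype=np.result_type(grid.values.dtype, np.int8))
        out[inside] = grid.values[r_idx[inside], c_idx[inside]]
        return RasterGrid(out, template.transform, template.crs, nodata=out_nodata)

    src = grid.values.astype(float)
    src[~grid.valid_mask()] = np.nan
    out = ndimage.map_coordinates(
        src, [src_rowf, src_colf], order=1, mode="constant", cval=np.nan
    )
    if np.isnan(out).all():
        raise ValueError("no overlap between grid and template extents")
    return RasterGrid(out, template.transform, template.crs, nodata=None)


def read_stack(paths: Iterable[str | Path], labels: Sequence[str]) -> RasterStack:
    """Read several single-band files into an aligned stack."""
    return RasterStack([read_raster(p) for p in paths], list(labels))
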