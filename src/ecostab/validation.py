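"""Validation of the ESI surface: greenness correlation and reserve contrast.

Two checks mirror how a probability-of-persistence surface can be judged
without independent stability measurements: (i) Pearson correlation between
the multi-year mean ESI and mean enhanced vegetation index (EVI), which
should be significantly positive if the index tracks vegetated, persistent
land; and (ii) a zonal comparison of mean ESI inside vs. outside nature
reserves, where conservation should show up as a higher mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from shapely.geometry import shape
from shapely import intersects_xy, union_all

from .composite import CompositeESI, class_area_fractions, classify_esi
from .raster import RasterGrid

__all__ = [
    "ZonalReport",
    "pearson_correlation",
    "zonal_compare",
    "rasterize_reserves",
    "read_geojson_polygons",
]


@dataclass
class ZonalReport:
    """Summary of the ESI distribution within one zone."""

    zone: str
    mean_esi: float
    pixel_count: int
    class_fractions: dict[int, float] = field(default_factory=dict)


def pearson_correlation(a: RasterGrid, b: RasterGrid) -> dict[str, float]:
    """Pearson r between two aligned grids over their jointly valid pixels."""
    if not a.is_aligned_with(b):
        raise ValueError("grids are not aligned")
    joint = a.valid_mask() & b.valid_mask()
    n = int(joint.sum())
    if n < 3:
        raise ValueError(f"need >= 3 jointly valid pixels, got {n}")
    x = a.values[joint].astype(float)
    y = b.values[joint].astype(float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the grids")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": n}


def zonal_compare(esi: CompositeESI, zone_mask: RasterGrid) -> dict[str, object]:
    """Mean ESI and class fractions inside vs. outside a binary zone mask."""
    grid = esi.values
    if not grid.is_aligned_with(zone_mask):
        raise ValueError("zone mask is not aligned with the ESI grid")
    valid = grid.valid_mask() & zone_mask.valid_mask()
    inside = valid & (zone_mask.values == 1)
    outside = valid & (zone_mask.values == 0)
    if not inside.any() or not outside.any():
        raise ValueError("both zones must contain valid pixels")

    classes = classify_esi(esi).values.values
    reports = []
    for name, sel in (("inside", inside), ("outside", outside)):
        vals = grid.values[sel].astype(float)
        cls = classes[sel]
        n = int(sel.sum())
        fracs = {int(c): int((cls == c).sum()) / n for c in np.unique(cls)}
        reports.append(
            ZonalReport(zone=name, mean_esi=float(vals.mean()), pixel_count=n, class_fractions=fracs)
        )
    return {
        "inside": reports[0],
        "outside": reports[1],
        "mean_difference": reports[0].mean_esi - reports[1].mean_esi,
    }


def rasterize_reserves(polygons: list, template: RasterGrid) -> RasterGrid:
    """Burn polygons into a 1/0 mask by a cell-center-in-polygon test.

    A cell center lying on a polygon boundary counts as inside.  An empty
    polygon list yields an all-zero mask.
    """
    rows, cols = template.shape
    out = np.zeros(template.shape, dtype=np.uint8)
    if polygons:
        geom = union_all(list(polygons))
        if not geom.is_valid:
            raise ValueError("invalid reserve geometry")
        r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        x, y = template.transform.xy(r.ravel(), c.ravel())
        out.ravel()[intersects_xy(geom, x, y)] = 1
    return RasterGrid(out, template.transform, template.crs, nodata=None)


def read_geojson_polygons(path: str | Path) -> list:
    """Load polygon geometries from a (Multi)Polygon GeoJSON FeatureCollection."""
    doc = json.loads(Path(path).read_text())
    feats = doc["features"] if doc.get("type") == "FeatureCollection" else [doc]
    geoms = []
    for f in feats:
        g = shape(f["geometry"] if "geometry" in f else f)
        if g.geom_type not in ("Polygon", "MultiPolygon"):
            raise ValueError(f"unsupported geometry type {g.geom_type}")
        if not g.is_valid:
            raise ValueError("invalid geometry in reserve file")
        geoms.append(g)
    return geoms
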