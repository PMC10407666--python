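"""Regional ESI: maximum-value composite, multi-year mean, five-class map.

The per-landscape ESI surfaces are integrated into one regional surface by
the Maximum Value Composite (MVC),

    ESI = max{ESI_1, ESI_2, ..., ESI_n},

the multi-year average of which is classified into five stability levels:
very low [0, 0.2), low [0.2, 0.4), medium [0.4, 0.6), moderately high
[0.6, 0.8) and very high [0.8, 1].  Interval boundaries belong to the upper
class and the top interval is closed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .raster import RasterGrid
from .stability import ESILayer

__all__ = [
    "CompositeESI",
    "StabilityClassMap",
    "CLASS_NAMES",
    "CLASS_BREAKS",
    "mvc_composite",
    "multi_year_mean",
    "classify_esi",
    "class_area_fractions",
]

CLASS_BREAKS = (0.2, 0.4, 0.6, 0.8)
CLASS_NAMES = {
    1: "very low",
    2: "low",
    3: "medium",
    4: "moderately high",
    5: "very high",
}


@dataclass
class CompositeESI:
    """Regional ESI surface with provenance of the per-pixel maximum."""

    values: RasterGrid  # float in [0,1], NaN nodata
    source_landscape: RasterGrid | None = None  # argmax landscape id (lowest id on ties)
    years_averaged: list[str] = field(default_factory=list)


@dataclass
class StabilityClassMap:
    """Five-level categorical stability map (codes 1..5, nodata 0)."""

    values: RasterGrid
    legend: dict[int, str] = field(default_factory=lambda: dict(CLASS_NAMES))


def mvc_composite(layers: list[ESILayer]) -> CompositeESI:
    """Per-pixel maximum over the landscape ESI layers of one year.

    A pixel valid in at least one layer takes the maximum over its valid
    layers; argmax ties go to the lowest landscape id.  Pixels nodata in
    every layer stay nodata.
    """
    if not layers:
        raise ValueError("mvc_composite needs at least one layer")
    ref = layers[0].values
    for lay in layers[1:]:
        if not lay.values.is_aligned_with(ref):
            raise ValueError("ESI layers are not aligned")
    order = sorted(range(len(layers)), key=lambda i: layers[i].landscape_id)
    cube = np.stack([layers[i].values.values.astype(float) for i in order])
    ids = np.array([layers[i].landscape_id for i in order])

    with np.errstate(invalid="ignore"):
        allnan = np.isnan(cube).all(axis=0)
        filled = np.where(np.isnan(cube), -np.inf, cube)
        best = np.argmax(filled, axis=0)  # first (lowest-id) maximum wins ties
        vmax = np.take_along_axis(filled, best[None], axis=0)[0]
    vmax[allnan] = np.nan
    src = ids[best].astype(np.int16)
    src[allnan] = -1

    years = sorted({lay.year for lay in layers if lay.year})
    return CompositeESI(
        values=ref.with_values(vmax, nodata=None),
        source_landscape=ref.with_values(src, nodata=-1),
        years_averaged=years,
    )


def multi_year_mean(composites: list[CompositeESI]) -> CompositeESI:
    """Per-pixel arithmetic mean over years with valid data."""
    if not composites:
        raise ValueError("multi_year_mean needs at least one composite")
    ref = composites[0].values
    for c in composites[1:]:
        if not c.values.is_aligned_with(ref):
            raise ValueError("composites are not aligned")
    cube = np.stack([c.values.values.astype(float) for c in composites])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels stay NaN
        mean = np.nanmean(cube, axis=0)
    years = sorted({y for c in composites for y in c.years_averaged})
    return CompositeESI(values=ref.with_values(mean, nodata=None), years_averaged=years)


def classify_esi(esi: CompositeESI) -> StabilityClassMap:
    """Bin the ESI surface into the five stability classes (codes 1..5)."""
    v = esi.values.values
    valid = esi.values.valid_mask()
    vv = v[valid]
    if ((vv < 0) | (vv > 1)).any():
        raise ValueError("ESI values outside [0, 1]")
    codes = np.zeros(v.shape, dtype=np.uint8)
    # right=False: breaks belong to the upper class; 1.0 lands in class 5
    codes[valid] = np.digitize(vv, CLASS_BREAKS, right=False) + 1
    return StabilityClassMap(values=esi.values.with_values(codes, nodata=0))


def class_area_fractions(classes: StabilityClassMap) -> dict[int, float]:
    """Fraction of valid area in each stability class (sums to 1)."""
    v = classes.values.values
    valid = classes.values.valid_mask()
    n = int(valid.sum())
    if n == 0:
        raise ValueError("all-nodata class map")
    return {
        int(code): int((v[valid] == code).sum()) / n
        for code in np.unique(v[valid])
    }
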