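"""Steady-state (persistence) masks from a multi-date land-cover series.

A landscape pixel is *steady* when its land-cover class is unchanged over
every observation date; a pixel holding the class at the first date but
changing afterwards is *unsteady*.  Steady labels are optionally refined by
demoting pixels whose multi-year NDVI or GPP coefficient of variation is
implausibly high — those are treated as land-cover classification errors,
not as ecological change, and drop out of the analysis entirely.

Only ecological land-cover classes (forests, grasslands, wetlands) are
analysed; desert and urban classes have too little vegetation activity to
carry a stability signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster import RasterGrid, RasterStack

__all__ = [
    "SteadyMask",
    "compute_persistence",
    "refine_with_vegetation",
    "select_ecological_classes",
    "DEFAULT_CV_MAX",
]

NODATA = -1  # ternary mask sentinel; never a valid {0,1} label

#: Default ceiling on the multi-year vegetation coefficient of variation for
#: a pixel to keep its steady label.
DEFAULT_CV_MAX = 0.25

_ECOLOGICAL_TAGS = ("forest", "grassland", "grass", "meadow", "wetland", "shrub")
_EXCLUDED_TAGS = ("desert", "urban", "water", "ice", "glacier", "barren", "bare", "snow")


@dataclass
class SteadyMask:
    """Ternary persistence layer for one land-cover class.

    ``values`` holds 1 (steady), 0 (unsteady) or :data:`NODATA` (outside the
    class at the first date, missing data, or demoted by vegetation
    refinement).
    """

    landscape_code: int
    values: RasterGrid
    dates_used: list[str] = field(default_factory=list)

    def counts(self) -> dict[int, int]:
        v = self.values.values
        return {1: int((v == 1).sum()), 0: int((v == 0).sum())}


def compute_persistence(
    lulc_series: RasterStack, class_code: int, legend: dict[int, str] | None = None
) -> SteadyMask:
    """Label per-pixel persistence of ``class_code`` over the land-cover series.

    Pixels holding the class at every date are steady (1); pixels holding it
    at the first date but not all dates are unsteady (0); everything else —
    including pixels that enter the class only later, which would conflate
    gains with persistence — is nodata.  When a ``legend`` is supplied the
    class code is checked against it.
    """
    if len(lulc_series) < 2:
        raise ValueError("persistence needs at least two dates")
    if legend is not None and int(class_code) not in legend:
        raise ValueError(f"class code {class_code} absent from the legend")
    cube = np.stack([lay.values for lay in lulc_series.layers])
    valid = np.stack([lay.valid_mask() for lay in lulc_series.layers]).all(axis=0)

    first = cube[0] == class_code
    always = (cube == class_code).all(axis=0)
    out = np.full(cube.shape[1:], NODATA, dtype=np.int8)
    out[first & valid] = 0
    out[always & valid] = 1
    grid = lulc_series.layers[0].with_values(out, nodata=NODATA)
    return SteadyMask(landscape_code=int(class_code), values=grid, dates_used=list(lulc_series.labels))


def _cv(series: np.ndarray) -> np.ndarray:
    """Per-pixel coefficient of variation (sample sd / |mean|) over axis 0."""
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.nanmean(series, axis=0)
        sd = np.nanstd(series, axis=0, ddof=1)
        cv = sd / np.abs(mean)
    cv[np.isnan(mean)] = np.nan
    cv[(np.abs(mean) == 0) & (sd > 0)] = np.inf
    cv[(np.abs(mean) == 0) & (sd == 0)] = 0.0
    return cv


def refine_with_vegetation(
    mask: SteadyMask,
    ndvi_series: RasterStack,
    gpp_series: RasterStack,
    cv_max: float = DEFAULT_CV_MAX,
) -> SteadyMask:
    """Demote steady pixels with erratic vegetation to nodata.

    A steady pixel whose NDVI *or* GPP coefficient of variation over the
    available years exceeds ``cv_max`` is considered a land-cover
    classification error and removed (nodata), never relabelled unsteady.
    Unsteady (0) pixels are untouched.
    """
    if cv_max <= 0:
        raise ValueError("cv_max must be positive")
    for stack in (ndvi_series, gpp_series):
        if not stack.layers or not stack.layers[0].is_aligned_with(mask.values):
            raise ValueError("vegetation series must be aligned with the mask")
    ndvi = ndvi_series.as_array()
    gpp = gpp_series.as_array()
    if np.isnan(ndvi).all() and np.isnan(gpp).all():
        raise ValueError("all-nodata vegetation series")
    cv_ndvi = _cv(ndvi)
    cv_gpp = _cv(gpp)
    with np.errstate(invalid="ignore"):
        suspect = (cv_ndvi > cv_max) | (cv_gpp > cv_max)
    out = mask.values.values.copy()
    out[(out == 1) & suspect] = NODATA
    return SteadyMask(mask.landscape_code, mask.values.with_values(out, nodata=NODATA), mask.dates_used)


def select_ecological_classes(legend: dict[int, str]) -> list[int]:
    """Pick the land-cover codes to analyse (forest/grassland/wetland tags).

    Desert, urban, water/ice and barren classes are excluded.  Raises if a
    legend name matches no known tag, since silent inclusion/exclusion would
    be worse than an error.
    """
    if not legend:
        raise ValueError("empty legend")
    selected: list[int] = []
    for code, name in legend.items():
        lname = str(name).lower()
        if any(tag in lname for tag in _ECOLOGICAL_TAGS):
            selected.append(int(code))
        elif any(tag in lname for tag in _EXCLUDED_TAGS):
            continue
        else:
            raise ValueError(
                f"legend entry {code}:{name!r} carries no recognised ecological/non-ecological tag"
            )
    return sorted(selected)
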