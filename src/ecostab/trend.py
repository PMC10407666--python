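"""Per-pixel linear trend of the annual ESI with a slope t-test.

For every pixel the annual ESI series is regressed on calendar year by
ordinary least squares; the slope (ESI units per year) is tested two-sided
against zero with a t statistic on n - 2 degrees of freedom.  With the
usual four observation epochs that is only 2 df — low power, which simply
means the significance map is conservative.

Pixels with fewer than three valid years are nodata; a constant series has
slope 0 and p = 1 by convention, and an exactly linear series (zero
residual) with nonzero slope has p = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .raster import RasterGrid, RasterStack

__all__ = ["TrendMap", "per_pixel_trend"]

DEFAULT_ALPHA = 0.05


@dataclass
class TrendMap:
    """Slope, p-value and signed-significance layers of the ESI trend."""

    slope: RasterGrid  # ESI units per year, NaN nodata
    pvalue: RasterGrid  # in [0,1], NaN nodata
    sig_mask: RasterGrid  # {+1 sig. increase, -1 sig. decrease, 0 n.s.}, nodata -9
    alpha: float = DEFAULT_ALPHA


def per_pixel_trend(esi_series: RasterStack, alpha: float = DEFAULT_ALPHA) -> TrendMap:
    """OLS trend of ESI on year at every pixel.

    ``esi_series`` must be labelled with numeric years (e.g. "2000"); the
    regressor is the calendar year so the slope is in ESI per year.
    """
    if len(esi_series) < 3:
        raise ValueError("trend needs at least three time points")
    try:
        years = np.array([float(lab) for lab in esi_series.labels])
    except ValueError:
        raise ValueError("esi_series labels must be numeric years") from None
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")

    cube = esi_series.as_array()  # (t, rows, cols), NaN nodata
    valid = ~np.isnan(cube)
    n = valid.sum(axis=0).astype(float)
    enough = n >= 3

    t_grid = np.where(valid, years[:, None, None], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels stay NaN
        tbar = np.nanmean(t_grid, axis=0)
        ybar = np.nanmean(cube, axis=0)
        dt = t_grid - tbar
        dy = cube - ybar
        sxx = np.nansum(dt * dt, axis=0)
        sxy = np.nansum(dt * dy, axis=0)
        slope = sxy / sxx
        intercept = ybar - slope * tbar
        resid = cube - (intercept + slope * t_grid)
        sse = np.nansum(resid * resid, axis=0)
        # numerically-zero residuals: treat as exact fit
        sse = np.where(sse < 1e-24, 0.0, sse)
        s2 = sse / (n - 2)
        se_slope = np.sqrt(s2 / sxx)
        tstat = slope / se_slope

    df = n - 2
    pval = np.full(slope.shape, np.nan)
    ok = enough & np.isfinite(slope)
    # regular case: positive residual variance
    reg = ok & (se_slope > 0)
    pval[reg] = 2 * stats.t.sf(np.abs(tstat[reg]), df[reg])
    # degenerate cases: exact fit (p = 0 unless the series is constant, p = 1)
    exact = ok & (se_slope == 0)
    pval[exact & (slope != 0)] = 0.0
    pval[exact & (slope == 0)] = 1.0
    slope = np.where(ok, slope, np.nan)
    slope[exact & (np.abs(slope) < 1e-15)] = 0.0

    sig = np.full(slope.shape, -9, dtype=np.int8)
    sig[ok] = 0
    with np.errstate(invalid="ignore"):
        up = ok & (pval < alpha) & (slope > 0)
        dn = ok & (pval < alpha) & (slope < 0)
    sig[up] = 1
    sig[dn] = -1

    ref = esi_series.layers[0]
    return TrendMap(
        slope=ref.with_values(slope, nodata=None),
        pvalue=ref.with_values(pval, nodata=None),
        sig_mask=ref.with_values(sig, nodata=-9),
        alpha=alpha,
    )
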