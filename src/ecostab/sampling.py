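"""Per-landscape binary sample tables with min-max normalized covariates.

Each eligible pixel contributes one row {landscape_id, (row, col), label,
Z1..Zn}: label 1 for steady pixels, 0 for unsteady ones, and Z the
environmental factors rescaled to [0, 1] by

    Z = (X - X_min) / (X_max - X_min).

By default the min/max are computed per landscape over its own eligible
pixels, so every logistic fit sees covariates spanning the unit interval;
the scope can be widened to all eligible pixels ("global") or pinned to
externally supplied :class:`FactorSpec` bounds ("fixed"), e.g. the known
bounds of a simulated scene.

Steady pixels carry a landscape id from the type map; unsteady pixels are
attached to the nearest cluster centroid of their land-cover class in the
standardized feature space (they changed class, so the type map itself
cannot label them).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .landscapes import LandscapeTypeMap
from .persistence import NODATA, SteadyMask
from .raster import RasterGrid, RasterStack

__all__ = [
    "FactorSpec",
    "SampleTable",
    "normalize_factor",
    "build_samples",
    "samples_from_grids",
    "landscape_assignment",
    "combine_labels",
]


@dataclass(frozen=True)
class FactorSpec:
    """Normalization record for one factor: Z = (X - vmin)/(vmax - vmin)."""

    code: str  # X1..Xn
    name: str
    label: str  # layer label in the covariate stack
    vmin: float
    vmax: float

    def __post_init__(self) -> None:
        if not self.vmin < self.vmax:
            raise ValueError(f"degenerate factor {self.code}: min {self.vmin} >= max {self.vmax}")

    def apply(self, x: np.ndarray) -> np.ndarray:
        return normalize_factor(x, self.vmin, self.vmax)


def normalize_factor(x: np.ndarray, x_min: float, x_max: float) -> np.ndarray:
    """Min-max normalize to [0, 1], clipping out-of-range values; NaN propagates."""
    if not x_min < x_max:
        raise ValueError("degenerate factor: x_min must be < x_max")
    x = np.asarray(x, dtype=float)
    with np.errstate(invalid="ignore"):
        z = (x - x_min) / (x_max - x_min)
        return np.clip(z, 0.0, 1.0)


@dataclass
class SampleTable:
    """Long-format sample table plus the normalization bookkeeping.

    ``df`` has columns {landscape_id, row, col, label, Z1..Zn}; ``specs``
    maps landscape id -> list of FactorSpec in Z-column order; ``flags``
    collects per-landscape data problems (e.g. degenerate labels).
    """

    df: pd.DataFrame
    specs: dict[int, list[FactorSpec]]
    flags: dict[int, list[str]] = field(default_factory=dict)

    @property
    def z_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith("Z")]

    def for_landscape(self, landscape_id: int) -> pd.DataFrame:
        return self.df[self.df["landscape_id"] == landscape_id]

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


def landscape_assignment(
    type_map: LandscapeTypeMap,
    steady_masks: list[SteadyMask],
    veg_features: RasterStack | None = None,
) -> RasterGrid:
    """Landscape id for every eligible (steady or unsteady) pixel.

    Steady pixels take their id from the type map.  Unsteady pixels changed
    class, so they are attached to the nearest cluster centroid of their
    first-date land-cover class in the standardized feature space; for a
    single-type class that is simply the class's landscape id.
    """
    tm = type_map.values.values
    out = np.full(tm.shape, NODATA, dtype=np.int16)
    veg_cube = veg_features.as_array() if veg_features is not None else None
    for mask in steady_masks:
        m = mask.values.values
        steady = m == 1
        out[steady] = tm[steady]
        r0, c0 = np.nonzero(m == 0)
        if not len(r0):
            continue
        clustering = type_map.clusterings.get(mask.landscape_code)
        if clustering is None:
            continue  # class contributed no steady pixels -> no model anyway
        if len(clustering.landscape_ids) == 1 or veg_cube is None:
            out[r0, c0] = clustering.landscape_ids[0]
        else:
            feats = veg_cube[:, r0, c0].T
            feats = np.nan_to_num(feats, nan=np.nanmean(feats))
            out[r0, c0] = clustering.assign(feats)
    return type_map.values.with_values(out, nodata=NODATA)


def combine_labels(steady_masks: list[SteadyMask]) -> RasterGrid:
    """Merge per-class ternary masks into one steady/unsteady label layer."""
    if not steady_masks:
        raise ValueError("no steady masks supplied")
    ref = steady_masks[0].values
    out = np.full(ref.shape, NODATA, dtype=np.int8)
    for mask in steady_masks:
        m = mask.values.values
        labelled = m != NODATA
        if (labelled & (out != NODATA)).any():
            raise ValueError("steady masks overlap in labelled pixels")
        out[labelled] = m[labelled]
    return ref.with_values(out, nodata=NODATA)


def samples_from_grids(
    assignment: RasterGrid,
    labels: RasterGrid,
    factors: RasterStack,
    balance: str = "none",
    seed: int = 0,
    scope: str = "landscape",
    fixed_specs: list[FactorSpec] | None = None,
) -> SampleTable:
    """Build the sample table from an id-assignment grid and a label grid."""
    if balance not in ("none", "downsample"):
        raise ValueError(f"unknown balance mode {balance!r}")
    if scope not in ("landscape", "global", "fixed"):
        raise ValueError(f"unknown normalization scope {scope!r}")
    if scope == "fixed" and fixed_specs is None:
        raise ValueError("scope='fixed' requires fixed_specs")

    cube = factors.as_array()  # (n_factors, rows, cols), NaN nodata
    n_factors = len(factors.labels)
    z_cols = [f"Z{i + 1}" for i in range(n_factors)]

    a = assignment.values
    lab = labels.values
    eligible = assignment.valid_mask() & labels.valid_mask()
    rows, cols = np.nonzero(eligible)
    pix = np.stack([rows, cols], axis=1)
    lids = a[rows, cols].astype(int)
    y_all = lab[rows, cols].astype(int)

    rng = np.random.default_rng(seed)
    frames: list[pd.DataFrame] = []
    specs: dict[int, list[FactorSpec]] = {}
    flags: dict[int, list[str]] = {}

    if scope == "global":
        global_specs = _specs_from(cube, pix, factors.labels)

    for lid in np.unique(lids):
        lid = int(lid)
        in_l = lids == lid
        p = pix[in_l]
        y = y_all[in_l]
        if len(np.unique(y)) < 2:
            flags.setdefault(lid, []).append("degenerate labels")
        elif balance == "downsample":
            n_min = min((y == 0).sum(), (y == 1).sum())
            keep = np.concatenate(
                [
                    rng.choice(np.nonzero(y == lab_)[0], size=n_min, replace=False)
                    for lab_ in (0, 1)
                ]
            )
            keep.sort()
            p, y = p[keep], y[keep]

        x = cube[:, p[:, 0], p[:, 1]]  # (n_factors, n_samples)
        if np.isnan(x).all(axis=1).any():
            bad = [factors.labels[i] for i in np.nonzero(np.isnan(x).all(axis=1))[0]]
            raise ValueError(f"factor(s) {bad} all-nodata over landscape {lid}")
        if scope == "landscape":
            lspecs = _specs_from(cube, p, factors.labels)
        elif scope == "global":
            lspecs = global_specs
        else:
            lspecs = list(fixed_specs)  # type: ignore[arg-type]
            if len(lspecs) != n_factors:
                raise ValueError("fixed_specs length does not match the factor stack")
        z = np.stack([spec.apply(x[i]) for i, spec in enumerate(lspecs)])
        frame = pd.DataFrame(
            {
                "landscape_id": lid,
                "row": p[:, 0],
                "col": p[:, 1],
                "label": y,
            }
        )
        for i, colname in enumerate(z_cols):
            frame[colname] = z[i]
        frames.append(frame)
        specs[lid] = lspecs

    if not frames:
        raise ValueError("no landscape produced any samples")
    df = pd.concat(frames, ignore_index=True)
    return SampleTable(df=df, specs=specs, flags=flags)


def build_samples(
    type_map: LandscapeTypeMap,
    steady_masks: list[SteadyMask],
    factors: RasterStack,
    balance: str = "none",
    seed: int = 0,
    scope: str = "landscape",
    fixed_specs: list[FactorSpec] | None = None,
    veg_features: RasterStack | None = None,
) -> SampleTable:
    """Extract the sample grid-point table feeding the per-landscape fits.

    Parameters
    ----------
    balance
        "none" keeps every eligible pixel; "downsample" subsamples the
        majority label to the minority count per landscape (seeded).
    scope
        Normalization scope: "landscape" (default), "global" (min/max over
        all eligible pixels) or "fixed" (use ``fixed_specs`` verbatim).
    veg_features
        The clustering feature stack; needed to place unsteady pixels of a
        multi-type class (e.g. grassland) into their nearest landscape type.
    """
    assignment = landscape_assignment(type_map, steady_masks, veg_features)
    labels = combine_labels(steady_masks)
    table = samples_from_grids(
        assignment, labels, factors,
        balance=balance, seed=seed, scope=scope, fixed_specs=fixed_specs,
    )
    for lid in type_map.names:
        if lid not in table.specs:
            table.flags.setdefault(lid, []).append("no eligible pixels")
    return table


def _specs_from(cube: np.ndarray, pix: np.ndarray, labels: list[str]) -> list[FactorSpec]:
    vals = cube[:, pix[:, 0], pix[:, 1]]
    specs = []
    for i, lab in enumerate(labels):
        vmin = float(np.nanmin(vals[i]))
        vmax = float(np.nanmax(vals[i]))
        if vmin == vmax:
            raise ValueError(f"degenerate factor {lab}: constant over the sample")
        specs.append(FactorSpec(code=f"X{i + 1}", name=lab, label=lab, vmin=vmin, vmax=vmax))
    return specs
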