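"""Seeded synthetic scenes with known ground truth.

The generator emulates the ingredients of a landscape-persistence stability
study on a toy region: spatially autocorrelated environmental covariates, a
land-cover mosaic with forest / grassland / wetland / desert / urban
patches, a grassland coverage gradient that splits into sparse vs.
high-coverage types, and steady/unsteady pixel states drawn from a *known*
logistic model per landscape type.  Because the true coefficients, true
probabilities and realized labels are all retained, every pipeline stage
can be tested end-to-end without any external data:

* the emitted land-cover series changes class exactly once at the unsteady
  pixels, so persistence labelling must recover the realized labels exactly;
* covariates are min-max scaled to stated ranges, so the true normalized
  factors are known and fitted coefficients can be compared to the planted
  ones;
* EVI is generated as a monotone function of the true stability probability
  plus noise, giving the greenness validation a truthful positive control;
* reserve polygons are placed over the highest-probability block, so the
  reserve/non-reserve contrast has a known sign.

What the scenes do not emulate: real terrain structure, correlated factor
fields (each covariate is an independent random field), classification
noise beyond the label mechanism, or any actual geography.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit
from shapely.geometry import Polygon, mapping

from .raster import Affine, RasterGrid, RasterStack, read_raster, write_raster
from .sampling import FactorSpec

__all__ = [
    "SceneConfig",
    "SceneTruth",
    "generate_covariates",
    "generate_scene",
    "write_scene",
    "load_scene",
    "DEFAULT_FACTORS",
    "DEFAULT_LEGEND",
    "DEFAULT_TRUE_BETA",
]

#: The eleven environmental factors with plausible value ranges
#: (code, name, (min, max)): anthropogenic, climate, resource-access,
#: topographic and vegetation conditions.
DEFAULT_FACTORS: list[tuple[str, str, tuple[float, float]]] = [
    ("X1", "gdp", (0.0, 500.0)),            # 1e4 CNY km-2
    ("X2", "pop_density", (0.0, 100.0)),    # persons km-2
    ("X3", "precipitation", (50.0, 1200.0)),  # mm yr-1
    ("X4", "temperature", (-15.0, 20.0)),   # degC
    ("X5", "dist_waterways", (0.0, 50.0)),  # km
    ("X6", "dist_roads", (0.0, 80.0)),      # km
    ("X7", "aspect", (0.0, 360.0)),         # deg
    ("X8", "elevation", (2500.0, 6500.0)),  # m
    ("X9", "slope", (0.0, 45.0)),           # deg
    ("X10", "gpp", (0.0, 1500.0)),          # gC m-2 yr-1
    ("X11", "ndvi", (0.0, 0.9)),            # unitless
]

DEFAULT_LEGEND = {1: "forest", 2: "grassland", 3: "wetland", 4: "desert", 5: "urban"}

#: True logistic coefficients per landscape: (beta0, {factor code: beta}).
#: Remaining coefficients are zero.  Magnitudes stay modest so planted
#: probabilities are informative but never separable.
DEFAULT_TRUE_BETA: dict[str, tuple[float, dict[str, float]]] = {
    "forest": (0.8, {"X4": 1.5, "X10": 1.2, "X1": -0.8}),
    "grassland_sparse": (0.5, {"X3": 0.8, "X4": -0.4, "X9": -0.6}),
    "grassland_high": (-0.2, {"X3": 1.0, "X8": 1.5, "X4": -0.5}),
    "wetland": (0.3, {"X3": 2.0, "X4": 0.8, "X5": -1.0}),
}

#: Mean NDVI per (land-cover name, grassland subtype) used to synthesize
#: vegetation layers; the sparse/high gap is what landscape typing must find.
_NDVI_MEANS = {
    "forest": 0.75,
    "grassland_high": 0.60,
    "grassland_sparse": 0.25,
    "wetland": 0.45,
    "desert": 0.08,
    "urban": 0.15,
}
_GPP_SCALE = 1500.0  # GPP tracks NDVI on a gC m-2 yr-1 scale


@dataclass
class SceneConfig:
    """Study conditions of a synthetic scene (defaults are the canonical demo)."""

    shape: tuple[int, int] = (100, 100)
    years: tuple[int, ...] = (2000, 2005, 2010, 2015)
    smoothness: float = 5.0  # Gaussian kernel length-scale, pixels
    pixel_size: float = 1000.0  # m; the 1 km analysis resolution
    origin: tuple[float, float] = (500000.0, 4000000.0)
    crs: str = "EPSG:32646"
    legend: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LEGEND))
    class_fractions: dict[int, float] = field(
        default_factory=lambda: {1: 0.15, 2: 0.55, 3: 0.10, 4: 0.15, 5: 0.05}
    )
    high_coverage_fraction: float = 0.4  # of grassland pixels
    factors: list[tuple[str, str, tuple[float, float]]] = field(
        default_factory=lambda: list(DEFAULT_FACTORS)
    )
    true_beta: dict[str, tuple[float, dict[str, float]]] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_BETA)
    )
    temporal_jitter: float = 0.03  # per-year covariate drift, fraction of range
    ndvi_noise_sd: float = 0.02  # inter-annual vegetation noise (keeps CV low)
    evi_intercept: float = 0.1
    evi_slope: float = 0.6
    evi_noise_sd: float = 0.05

    @property
    def transform(self) -> Affine:
        return Affine.from_origin(self.origin[0], self.origin[1], self.pixel_size, self.pixel_size)

    #: landscape ids follow the typing convention: classes in code order,
    #: grassland split ranked by NDVI (sparse below high)
    @property
    def landscape_names(self) -> dict[int, str]:
        return {1: "forest", 2: "grassland_sparse", 3: "grassland_high", 4: "wetland"}


@dataclass
class SceneTruth:
    """A generated scene together with everything needed to check the pipeline."""

    config: SceneConfig
    seed: int
    factors_by_year: dict[int, RasterStack]  # 11 covariate layers per year
    factor_specs: list[FactorSpec]  # the min-max bounds the truth used
    lulc_by_year: dict[int, RasterGrid]
    ndvi_by_year: dict[int, RasterGrid]
    gpp_by_year: dict[int, RasterGrid]
    evi_mean: RasterGrid
    landscape_truth: RasterGrid  # true landscape id (1..4), nodata -1
    true_pi: RasterGrid  # true stability probability, NaN outside
    labels: RasterGrid  # realized steady (1) / unsteady (0), nodata -1
    true_beta: dict[int, np.ndarray]  # landscape id -> (beta0, beta1..betan)
    reserves: list[Polygon]

    @property
    def years(self) -> list[int]:
        return list(self.config.years)

    def lulc_stack(self) -> RasterStack:
        return RasterStack(
            [self.lulc_by_year[y] for y in self.years], [str(y) for y in self.years]
        )

    def ndvi_stack(self) -> RasterStack:
        return RasterStack(
            [self.ndvi_by_year[y] for y in self.years], [str(y) for y in self.years]
        )

    def gpp_stack(self) -> RasterStack:
        return RasterStack(
            [self.gpp_by_year[y] for y in self.years], [str(y) for y in self.years]
        )


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], smoothness: float) -> np.ndarray:
    """Gaussian-smoothed standard noise, rescaled to zero mean unit sd."""
    f = rng.standard_normal(shape)
    if smoothness > 0:
        f = gaussian_filter(f, sigma=smoothness, mode="reflect")
    sd = f.std()
    return (f - f.mean()) / (sd if sd > 0 else 1.0)


def generate_covariates(
    shape: tuple[int, int],
    n_factors: int,
    smoothness: float,
    seed: int,
    ranges: list[tuple[float, float]] | None = None,
    labels: list[str] | None = None,
    transform: Affine | None = None,
    crs: str = "EPSG:32646",
) -> RasterStack:
    """Spatially autocorrelated covariate fields, min-max scaled to their ranges.

    Each factor is independently smoothed white noise with the given kernel
    length-scale (``smoothness`` = 0 gives uncorrelated noise), linearly
    rescaled so its minimum and maximum equal the stated range endpoints
    exactly.  Deterministic in (shape, n_factors, smoothness, seed).
    """
    if min(shape) < 10:
        raise ValueError("scene must be at least 10x10")
    if smoothness < 0:
        raise ValueError("smoothness (length-scale) must be non-negative")
    rng = np.random.default_rng(seed)
    if ranges is None:
        ranges = [DEFAULT_FACTORS[i % len(DEFAULT_FACTORS)][2] for i in range(n_factors)]
    if labels is None:
        labels = [f"X{i + 1}" for i in range(n_factors)]
    transform = transform or Affine.from_origin(500000.0, 4000000.0, 1000.0, 1000.0)
    layers = []
    for (lo, hi) in ranges[:n_factors]:
        f = _smooth_field(rng, shape, smoothness)
        f = (f - f.min()) / (f.max() - f.min()) * (hi - lo) + lo
        layers.append(RasterGrid(f, transform, crs, nodata=None))
    return RasterStack(layers, list(labels[:n_factors]))


def _mosaic(rng: np.random.Generator, cfg: SceneConfig) -> tuple[np.ndarray, np.ndarray]:
    """Land-cover mosaic by quantile-thresholding a smooth field, plus the
    grassland subtype truth (1 = high coverage)."""
    base = _smooth_field(rng, cfg.shape, cfg.smoothness)
    codes = sorted(cfg.class_fractions)
    fr = np.array([cfg.class_fractions[c] for c in codes], dtype=float)
    fr = fr / fr.sum()
    qs = np.quantile(base, np.cumsum(fr)[:-1])
    lulc = np.full(cfg.shape, codes[-1], dtype=np.int16)
    idx = np.digitize(base, qs, right=True)
    for i, c in enumerate(codes):
        lulc[idx == i] = c

    sub = _smooth_field(rng, cfg.shape, cfg.smoothness)
    grass = lulc == 2
    high = np.zeros(cfg.shape, dtype=bool)
    if grass.any():
        thr = np.quantile(sub[grass], 1.0 - cfg.high_coverage_fraction)
        high[grass] = sub[grass] > thr
    return lulc, high


def _true_beta_matrix(cfg: SceneConfig) -> dict[int, np.ndarray]:
    codes = [code for code, _, _ in cfg.factors]
    out: dict[int, np.ndarray] = {}
    for lid, name in cfg.landscape_names.items():
        beta0, nz = cfg.true_beta[name]
        beta = np.zeros(len(codes) + 1)
        beta[0] = beta0
        for code, b in nz.items():
            beta[1 + codes.index(code)] = b
        out[lid] = beta
    return out


def _reserve_polygons(true_pi: np.ndarray, cfg: SceneConfig) -> list[Polygon]:
    """One rectangular reserve over the block with the highest mean true Pi."""
    rows, cols = cfg.shape
    h, w = max(rows // 3, 1), max(cols // 3, 1)
    best, best_rc = -np.inf, (0, 0)
    for r0 in range(0, rows - h + 1, max(h // 2, 1)):
        for c0 in range(0, cols - w + 1, max(w // 2, 1)):
            block = true_pi[r0 : r0 + h, c0 : c0 + w]
            if np.isnan(block).all():
                continue
            m = np.nanmean(block)
            if m > best:
                best, best_rc = m, (r0, c0)
    r0, c0 = best_rc
    t = cfg.transform
    x0 = t.c + c0 * t.a
    x1 = t.c + (c0 + w) * t.a
    y0 = t.f + r0 * t.e
    y1 = t.f + (r0 + h) * t.e
    return [Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])]


def generate_scene(config: SceneConfig | None = None, seed: int = 0) -> SceneTruth:
    """Generate a fully reproducible scene from (config, seed)."""
    cfg = config or SceneConfig()
    if len(cfg.years) < 2:
        raise ValueError("a scene needs at least two dates")
    for name, (_, nz) in cfg.true_beta.items():
        known = {c for c, _, _ in cfg.factors}
        if not set(nz) <= known:
            raise ValueError(f"true beta of {name} names unknown factors {set(nz) - known}")
    ss = np.random.SeedSequence(seed)
    rng_cov, rng_mosaic, rng_labels, rng_veg, rng_change = [
        np.random.default_rng(s) for s in ss.spawn(5)
    ]

    transform, crs = cfg.transform, cfg.crs
    ranges = [r for _, _, r in cfg.factors]
    codes = [c for c, _, _ in cfg.factors]

    base = generate_covariates(
        cfg.shape, len(cfg.factors), cfg.smoothness,
        seed=int(rng_cov.integers(2**31)), ranges=ranges, labels=codes,
        transform=transform, crs=crs,
    )
    factors_by_year: dict[int, RasterStack] = {cfg.years[0]: base}
    for year in cfg.years[1:]:
        layers = []
        for lay, (lo, hi) in zip(base.layers, ranges):
            jitter = _smooth_field(rng_cov, cfg.shape, cfg.smoothness)
            vals = np.clip(lay.values + jitter * cfg.temporal_jitter * (hi - lo), lo, hi)
            layers.append(RasterGrid(vals, transform, crs, nodata=None))
        factors_by_year[year] = RasterStack(layers, list(base.labels))

    factor_specs = [
        FactorSpec(code=code, name=name, label=code, vmin=lo, vmax=hi)
        for (code, name, (lo, hi)) in cfg.factors
    ]

    lulc0, high = _mosaic(rng_mosaic, cfg)
    landscape = np.full(cfg.shape, -1, dtype=np.int16)
    landscape[lulc0 == 1] = 1
    landscape[(lulc0 == 2) & ~high] = 2
    landscape[(lulc0 == 2) & high] = 3
    landscape[lulc0 == 3] = 4

    # true probability from the planted logistic model on the first-year Z
    z = np.stack([spec.apply(lay.values) for spec, lay in zip(factor_specs, base.layers)])
    true_beta = _true_beta_matrix(cfg)
    pi = np.full(cfg.shape, np.nan)
    for lid, beta in true_beta.items():
        sel = landscape == lid
        pi[sel] = expit(beta[0] + np.tensordot(beta[1:], z, axes=1))[sel]

    labels = np.full(cfg.shape, -1, dtype=np.int8)
    eco = landscape > 0
    labels[eco] = (rng_labels.random(cfg.shape)[eco] < pi[eco]).astype(np.int8)

    # land-cover series: steady pixels persist, unsteady ones change exactly once
    n_years = len(cfg.years)
    lulc_series = np.repeat(lulc0[None], n_years, axis=0)
    ur, uc = np.nonzero(labels == 0)
    if len(ur):
        change_at = rng_change.integers(1, n_years, size=len(ur))
        all_codes = np.array(sorted(cfg.legend))
        for i, (r, c) in enumerate(zip(ur, uc)):
            others = all_codes[all_codes != lulc0[r, c]]
            new = rng_change.choice(others)
            lulc_series[change_at[i]:, r, c] = new
    lulc_by_year = {
        y: RasterGrid(lulc_series[i].copy(), transform, crs, nodata=-1)
        for i, y in enumerate(cfg.years)
    }

    # vegetation layers consistent with the (possibly changing) classes
    spatial = 0.05 * _smooth_field(rng_veg, cfg.shape, cfg.smoothness)
    name_of = dict(cfg.legend)
    ndvi_by_year: dict[int, RasterGrid] = {}
    gpp_by_year: dict[int, RasterGrid] = {}
    for i, year in enumerate(cfg.years):
        mean = np.zeros(cfg.shape)
        for code, cname in name_of.items():
            sel = lulc_series[i] == code
            if cname == "grassland":
                mean[sel & high] = _NDVI_MEANS["grassland_high"]
                mean[sel & ~high] = _NDVI_MEANS["grassland_sparse"]
            else:
                mean[sel] = _NDVI_MEANS[cname]
        ndvi = np.clip(mean + spatial + rng_veg.normal(0, cfg.ndvi_noise_sd, cfg.shape), 0, 1)
        gpp = np.clip(
            _GPP_SCALE * (mean + spatial) + rng_veg.normal(0, cfg.ndvi_noise_sd * _GPP_SCALE, cfg.shape),
            0, None,
        )
        ndvi_by_year[year] = RasterGrid(ndvi, transform, crs, nodata=None)
        gpp_by_year[year] = RasterGrid(gpp, transform, crs, nodata=None)

    # EVI as a monotone function of true stability plus noise (positive control)
    evi = np.full(cfg.shape, np.nan)
    evi[eco] = cfg.evi_intercept + cfg.evi_slope * pi[eco]
    evi[~eco] = cfg.evi_intercept * (0.5 + spatial[~eco])
    evi = np.clip(evi + rng_veg.normal(0, cfg.evi_noise_sd, cfg.shape), 0, 1)
    evi_mean = RasterGrid(evi, transform, crs, nodata=None)

    reserves = _reserve_polygons(pi, cfg)

    return SceneTruth(
        config=cfg,
        seed=seed,
        factors_by_year=factors_by_year,
        factor_specs=factor_specs,
        lulc_by_year=lulc_by_year,
        ndvi_by_year=ndvi_by_year,
        gpp_by_year=gpp_by_year,
        evi_mean=evi_mean,
        landscape_truth=RasterGrid(landscape, transform, crs, nodata=-1),
        true_pi=RasterGrid(pi, transform, crs, nodata=None),
        labels=RasterGrid(labels, transform, crs, nodata=-1),
        true_beta=true_beta,
        reserves=reserves,
    )


def write_scene(scene: SceneTruth, outdir: str | Path) -> Path:
    """Write a scene as a directory of GeoTIFFs plus truth/legend JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = scene.config
    for year in cfg.years:
        write_raster(scene.lulc_by_year[year], outdir / f"lulc_{year}.tif")
        write_raster(scene.ndvi_by_year[year], outdir / f"ndvi_{year}.tif")
        write_raster(scene.gpp_by_year[year], outdir / f"gpp_{year}.tif")
        stack = scene.factors_by_year[year]
        for label, lay in zip(stack.labels, stack.layers):
            write_raster(lay, outdir / f"factor_{label}_{year}.tif")
    write_raster(scene.evi_mean, outdir / "evi_mean.tif")
    write_raster(scene.landscape_truth, outdir / "true_landscape.tif")
    write_raster(scene.true_pi, outdir / "true_pi.tif")
    write_raster(scene.labels, outdir / "true_labels.tif")
    (outdir / "legend.json").write_text(json.dumps({str(k): v for k, v in cfg.legend.items()}, indent=1))
    (outdir / "reserves.geojson").write_text(
        json.dumps(
            {
                "type": "FeatureCollection",
                "features": [
                    {"type": "Feature", "properties": {"name": f"reserve_{i}"}, "geometry": mapping(g)}
                    for i, g in enumerate(scene.reserves)
                ],
            }
        )
    )
    truth = {
        "seed": scene.seed,
        "years": list(cfg.years),
        "crs": cfg.crs,
        "landscape_names": {str(k): v for k, v in cfg.landscape_names.items()},
        "true_beta": {str(k): v.tolist() for k, v in scene.true_beta.items()},
        "factor_specs": [
            {"code": s.code, "name": s.name, "label": s.label, "vmin": s.vmin, "vmax": s.vmax}
            for s in scene.factor_specs
        ],
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
    return outdir


def load_scene(scene_dir: str | Path) -> dict:
    """Load a written scene directory into aligned stacks for the pipeline."""
    d = Path(scene_dir)
    truth = json.loads((d / "truth.json").read_text())
    years = [int(y) for y in truth["years"]]
    legend = {int(k): v for k, v in json.loads((d / "legend.json").read_text()).items()}
    specs = [FactorSpec(**s) for s in truth["factor_specs"]]
    codes = [s.code for s in specs]

    def stack(prefix: str) -> RasterStack:
        return RasterStack(
            [read_raster(d / f"{prefix}_{y}.tif") for y in years], [str(y) for y in years]
        )

    factors_by_year = {
        y: RasterStack([read_raster(d / f"factor_{c}_{y}.tif") for c in codes], list(codes))
        for y in years
    }
    return {
        "years": years,
        "legend": legend,
        "factor_specs": specs,
        "lulc": stack("lulc"),
        "ndvi": stack("ndvi"),
        "gpp": stack("gpp"),
        "factors_by_year": factors_by_year,
        "evi_mean": read_raster(d / "evi_mean.tif"),
        "true_beta": {int(k): np.asarray(v) for k, v in truth["true_beta"].items()},
        "landscape_names": {int(k): v for k, v in truth["landscape_names"].items()},
        "reserves_path": d / "reserves.geojson",
    }
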