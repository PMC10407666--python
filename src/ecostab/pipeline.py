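"""End-to-end pipeline: scene -> persistence -> typing -> fits -> ESI products.

The pipeline is driven by a single :class:`PipelineConfig` (YAML on disk)
that owns every threshold and seed, and it writes a run manifest echoing
the effective settings plus per-stage counts, so any run is auditable and
byte-reproducible from (config, seed).

Stage order: persistence labelling of each ecological class, vegetation-CV
refinement, landscape typing, per-year sample extraction, per-landscape and
per-year logistic fits, per-landscape ESI surfaces, maximum-value composite
per year, multi-year mean, five-class map, per-pixel trend, and validation
(ESI-EVI correlation, reserve contrast).  A separate model is fitted for
each factor year against the single persistence label, which is what makes
per-year factor contributions comparable over time.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .composite import (
    CLASS_NAMES,
    CompositeESI,
    class_area_fractions,
    classify_esi,
    multi_year_mean,
    mvc_composite,
)
from .landscapes import LandscapeTypeMap, type_landscapes
from .persistence import (
    DEFAULT_CV_MAX,
    SteadyMask,
    compute_persistence,
    refine_with_vegetation,
    select_ecological_classes,
)
from .raster import RasterGrid, RasterStack, read_raster, write_raster
from .sampling import (
    FactorSpec,
    SampleTable,
    combine_labels,
    landscape_assignment,
    samples_from_grids,
)
from .stability import (
    ESILayer,
    StabilityModel,
    factor_contributions,
    fit_from_samples,
    predict_esi,
)
from .synth import SceneConfig, generate_scene, load_scene, write_scene
from .trend import per_pixel_trend
from .validation import (
    pearson_correlation,
    rasterize_reserves,
    read_geojson_polygons,
    zonal_compare,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; round-trips losslessly through YAML."""

    scene_dir: str
    outdir: str
    cv_max: float = DEFAULT_CV_MAX
    k_per_class: dict[int, int] = field(default_factory=dict)  # defaults to grassland->2
    landscape_names: dict[int, list[str]] = field(default_factory=dict)
    balance: str = "none"
    scope: str = "landscape"
    tol: float = 1e-8
    max_iter: int = 100
    composite_order: str = "mvc_then_mean"  # or "mean_then_mvc"
    alpha: float = 0.05
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["k_per_class"] = {int(k): int(v) for k, v in (raw.get("k_per_class") or {}).items()}
        raw["landscape_names"] = {
            int(k): list(v) for k, v in (raw.get("landscape_names") or {}).items()
        }
        return cls(**raw)


def _default_k(legend: dict[int, str], k_per_class: dict[int, int]) -> dict[int, int]:
    """Grassland splits into sparse/high-coverage by default; others stay whole."""
    if k_per_class:
        return dict(k_per_class)
    return {
        code: (2 if "grass" in name.lower() else 1) for code, name in legend.items()
    }


def _default_names(legend: dict[int, str], k: dict[int, int]) -> dict[int, list[str]]:
    out = {}
    for code, name in legend.items():
        if k.get(code, 1) == 2 and "grass" in name.lower():
            out[code] = [f"{name}_sparse", f"{name}_high"]
        elif k.get(code, 1) == 1:
            out[code] = [name]
    return out


def _veg_feature_stack(data: dict) -> RasterStack:
    """Multi-year mean NDVI and GPP — the clustering features."""
    ndvi = data["ndvi"].as_array()
    gpp = data["gpp"].as_array()
    ref = data["ndvi"].layers[0]
    return RasterStack(
        [
            ref.with_values(np.nanmean(ndvi, axis=0), nodata=None),
            ref.with_values(np.nanmean(gpp, axis=0), nodata=None),
        ],
        ["ndvi_mean", "gpp_mean"],
    )


def stage_persist(data: dict, config: PipelineConfig) -> dict[int, SteadyMask]:
    codes = select_ecological_classes(data["legend"])
    masks: dict[int, SteadyMask] = {}
    for code in codes:
        raw = compute_persistence(data["lulc"], code, legend=data["legend"])
        masks[code] = refine_with_vegetation(raw, data["ndvi"], data["gpp"], config.cv_max)
    return masks


def stage_type(
    masks: dict[int, SteadyMask], data: dict, config: PipelineConfig
) -> tuple[LandscapeTypeMap, RasterGrid, RasterStack]:
    veg = _veg_feature_stack(data)
    k = _default_k(data["legend"], config.k_per_class)
    names = config.landscape_names or _default_names(data["legend"], k)
    type_map = type_landscapes(
        [masks[c] for c in sorted(masks)], veg, k, seed=config.seed, names=names
    )
    assignment = landscape_assignment(type_map, [masks[c] for c in sorted(masks)], veg)
    return type_map, assignment, veg


def stage_sample(
    assignment: RasterGrid,
    labels: RasterGrid,
    data: dict,
    config: PipelineConfig,
) -> dict[int, SampleTable]:
    fixed = data["factor_specs"] if config.scope == "fixed" else None
    return {
        year: samples_from_grids(
            assignment,
            labels,
            data["factors_by_year"][year],
            balance=config.balance,
            seed=config.seed,
            scope=config.scope,
            fixed_specs=fixed,
        )
        for year in data["years"]
    }


def stage_fit(
    samples: dict[int, SampleTable], config: PipelineConfig
) -> dict[tuple[int, int], StabilityModel]:
    models: dict[tuple[int, int], StabilityModel] = {}
    for year, table in samples.items():
        for lid in sorted(table.specs):
            if "degenerate labels" in table.flags.get(lid, []):
                continue
            models[(lid, year)] = fit_from_samples(
                table, lid, tol=config.tol, max_iter=config.max_iter
            )
    if not models:
        raise RuntimeError("missing samples: no landscape had both labels to fit")
    return models


def stage_map(
    models: dict[tuple[int, int], StabilityModel],
    assignment: RasterGrid,
    data: dict,
) -> dict[int, list[ESILayer]]:
    layers: dict[int, list[ESILayer]] = {y: [] for y in data["years"]}
    for (lid, year), model in sorted(models.items()):
        mask_vals = (assignment.values == lid).astype(np.uint8)
        mask = assignment.with_values(mask_vals, nodata=None)
        layers[year].append(
            predict_esi(model, data["factors_by_year"][year], mask, year=str(year))
        )
    return layers


def stage_composite(
    esi_layers: dict[int, list[ESILayer]], config: PipelineConfig
) -> dict:
    years = sorted(esi_layers)
    if config.composite_order == "mvc_then_mean":
        yearly = {y: mvc_composite(esi_layers[y]) for y in years}
        mean = multi_year_mean(list(yearly.values()))
    elif config.composite_order == "mean_then_mvc":
        # average each landscape over years first, then take the maximum
        by_lid: dict[int, list[ESILayer]] = {}
        for y in years:
            for lay in esi_layers[y]:
                by_lid.setdefault(lay.landscape_id, []).append(lay)
        import warnings

        lid_means = []
        for lid, lays in sorted(by_lid.items()):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels
                stack_vals = np.nanmean(
                    np.stack([l.values.values.astype(float) for l in lays]), axis=0
                )
            lid_means.append(
                ESILayer(lid, "mean", lays[0].values.with_values(stack_vals, nodata=None))
            )
        yearly = {y: mvc_composite(esi_layers[y]) for y in years}
        mean = mvc_composite(lid_means)
        mean = CompositeESI(values=mean.values, source_landscape=mean.source_landscape,
                            years_averaged=[str(y) for y in years])
    else:
        raise ValueError(f"unknown composite_order {config.composite_order!r}")
    classes = classify_esi(mean)
    fractions = class_area_fractions(classes)
    return {"yearly": yearly, "mean": mean, "classes": classes, "fractions": fractions}


def stage_trend(yearly: dict[int, CompositeESI], config: PipelineConfig):
    years = sorted(yearly)
    stack = RasterStack([yearly[y].values for y in years], [str(y) for y in years])
    return per_pixel_trend(stack, alpha=config.alpha)


def stage_validate(mean: CompositeESI, data: dict, config: PipelineConfig) -> dict:
    out: dict = {}
    evi = data.get("evi_mean")
    if evi is not None:
        out["esi_evi_pearson"] = pearson_correlation(mean.values, evi)
    reserves_path = data.get("reserves_path")
    if reserves_path and Path(reserves_path).exists():
        polys = read_geojson_polygons(reserves_path)
        zone = rasterize_reserves(polys, mean.values)
        z = zonal_compare(mean, zone)
        out["reserves"] = {
            "mean_inside": z["inside"].mean_esi,
            "mean_outside": z["outside"].mean_esi,
            "n_inside": z["inside"].pixel_count,
            "n_outside": z["outside"].pixel_count,
            "mean_difference": z["mean_difference"],
            "class_fractions_inside": z["inside"].class_fractions,
            "class_fractions_outside": z["outside"].class_fractions,
        }
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write all products plus a run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = load_scene(config.scene_dir)
    manifest: dict = {
        "package_version": __version__,
        "config": asdict(config),
        "stages": {},
        "outputs": [],
    }

    def save(grid: RasterGrid, rel: str) -> None:
        path = outdir / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        write_raster(grid, path)
        manifest["outputs"].append(rel)

    # 1. persistence + refinement
    masks = stage_persist(data, config)
    for code, m in masks.items():
        save(m.values, f"persist/steady_{code}.tif")
    labels = combine_labels([masks[c] for c in sorted(masks)])
    save(labels, "persist/labels.tif")
    manifest["stages"]["persist"] = {
        str(c): m.counts() for c, m in masks.items()
    }

    # 2. landscape typing
    type_map, assignment, veg = stage_type(masks, data, config)
    save(type_map.values, "type/landscape_types.tif")
    save(assignment, "type/landscape_assignment.tif")
    (outdir / "type").mkdir(exist_ok=True)
    (outdir / "type/landscape_legend.json").write_text(
        json.dumps({str(k): v for k, v in type_map.names.items()}, indent=1)
    )
    manifest["outputs"].append("type/landscape_legend.json")
    manifest["stages"]["type"] = {
        str(lid): int((assignment.values == lid).sum()) for lid in type_map.names
    }

    # 3. per-year samples
    samples = stage_sample(assignment, labels, data, config)
    (outdir / "samples").mkdir(exist_ok=True)
    for year, table in samples.items():
        table.to_csv(outdir / f"samples/samples_{year}.csv")
        manifest["outputs"].append(f"samples/samples_{year}.csv")
        (outdir / f"samples/specs_{year}.json").write_text(
            json.dumps(
                {
                    str(lid): [asdict(s) for s in specs]
                    for lid, specs in table.specs.items()
                },
                indent=1,
            )
        )
        manifest["outputs"].append(f"samples/specs_{year}.json")
    manifest["stages"]["sample"] = {
        str(y): int(len(t.df)) for y, t in samples.items()
    }

    # 4. per-landscape, per-year logistic fits
    models = stage_fit(samples, config)
    (outdir / "models").mkdir(exist_ok=True)
    contrib_frames = []
    for (lid, year), model in sorted(models.items()):
        model.save(outdir / f"models/model_L{lid}_{year}.json")
        manifest["outputs"].append(f"models/model_L{lid}_{year}.json")
        c = factor_contributions(model)
        c.insert(0, "landscape_id", lid)
        c.insert(1, "year", year)
        contrib_frames.append(c)
    contrib = pd.concat(contrib_frames, ignore_index=True)
    contrib.to_csv(outdir / "models/contributions.csv", index=False)
    manifest["outputs"].append("models/contributions.csv")
    manifest["stages"]["fit"] = {
        f"L{lid}_{year}": {"loglik": m.loglik, "converged": m.converged, "n": m.n_samples}
        for (lid, year), m in sorted(models.items())
    }

    # 5. ESI surfaces
    esi_layers = stage_map(models, assignment, data)
    for year, lays in esi_layers.items():
        for lay in lays:
            save(lay.values, f"esi/esi_L{lay.landscape_id}_{year}.tif")

    # 6. composite, mean, classes
    comp = stage_composite(esi_layers, config)
    for year, c in comp["yearly"].items():
        save(c.values, f"composite/esi_{year}.tif")
        if c.source_landscape is not None:
            save(c.source_landscape, f"composite/esi_source_{year}.tif")
    save(comp["mean"].values, "composite/esi_mean.tif")
    save(comp["classes"].values, "composite/stability_classes.tif")
    (outdir / "composite/class_legend.json").write_text(
        json.dumps({str(k): v for k, v in CLASS_NAMES.items()}, indent=1)
    )
    manifest["outputs"].append("composite/class_legend.json")
    pd.DataFrame(
        {
            "class": list(comp["fractions"]),
            "name": [CLASS_NAMES[c] for c in comp["fractions"]],
            "fraction": list(comp["fractions"].values()),
        }
    ).to_csv(outdir / "composite/class_fractions.csv", index=False)
    manifest["outputs"].append("composite/class_fractions.csv")
    manifest["stages"]["composite"] = {
        "order": config.composite_order,
        "fractions": {str(k): v for k, v in comp["fractions"].items()},
    }

    # 7. trend
    tr = stage_trend(comp["yearly"], config)
    save(tr.slope, "trend/slope.tif")
    save(tr.pvalue, "trend/pvalue.tif")
    save(tr.sig_mask, "trend/sig.tif")
    sig = tr.sig_mask.values
    valid = sig != -9
    nv = int(valid.sum())
    manifest["stages"]["trend"] = {
        "alpha": config.alpha,
        "frac_sig_increase": float((sig[valid] == 1).sum() / nv) if nv else float("nan"),
        "frac_sig_decrease": float((sig[valid] == -1).sum() / nv) if nv else float("nan"),
    }

    # 8. validation
    val = stage_validate(comp["mean"], data, config)
    (outdir / "validation").mkdir(exist_ok=True)
    (outdir / "validation/validation.json").write_text(json.dumps(val, indent=1))
    manifest["outputs"].append("validation/validation.json")
    manifest["stages"]["validate"] = val

    manifest["n_models"] = len(models)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def simulate_scene(
    outdir: str | Path, seed: int, shape: tuple[int, int] = (100, 100)
) -> Path:
    """Generate and write the canonical demo scene."""
    cfg = SceneConfig(shape=shape)
    scene = generate_scene(cfg, seed=seed)
    return write_scene(scene, outdir)
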