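"""End-to-end orchestration of the mapping workflow.

Stage order mirrors the field method: dark-object correction, cloud masking,
co-registration, seasonal median compositing, feature extraction, training,
kappa thresholding, (dual-forest) prediction, terrain masking, hectare
aggregation, and the stratified validation with corrected-extent estimation.
Both workflow variants run through the same stage implementations; only the
configuration differs.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import classify, features, postprocess, preprocess, validate
from .config import RunConfig
from .core import HectareCoverMap, MultibandPass, RegistrationFailureError
from .synthetic_scene import (
    DemParams,
    LandscapeSpec,
    PassSpec,
    SyntheticDataset,
    cloud_training_polygons,
    generate_dataset,
    make_phenology,
)
from .vector import TruthPolygon

log = logging.getLogger("reedmap")


@dataclass
class PipelineResult:
    """Artefacts of one pipeline run."""

    config: RunConfig
    composites: list
    stack: object
    model: classify.ReedModel
    probability: object            # ReedProbabilityMap
    cover: HectareCoverMap         # terrain-masked hectare cover
    cover_unmasked: HectareCoverMap
    extent_ha: float
    manifest: dict = field(default_factory=dict)
    validation: dict = field(default_factory=dict)


def _binarized_polygons(polygons: list[TruthPolygon]) -> list[TruthPolygon]:
    return [TruthPolygon(p.geometry, classify.binarize_label(p.label))
            for p in polygons]


def run_pipeline(
    config: RunConfig,
    dataset: SyntheticDataset,
    do_validation: bool = True,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Execute every stage on an in-memory dataset; optionally write artefacts."""
    manifest: dict = {"seed": config.seed, "workflow": config.workflow,
                      "stages": {}}
    rng_seed = config.seed

    # 1. dark-object subtraction
    passes = [preprocess.dark_object_subtract(p, config.dos_percentile)
              for p in dataset.passes]

    # 2. cloud model + masking (trained on simulator truth polygons)
    cloud_polys = cloud_training_polygons(dataset, seed=rng_seed)
    if cloud_polys:
        cmodel = preprocess.train_cloud_model(passes, cloud_polys, seed=rng_seed)
        manifest["stages"]["cloud_model_oob_error"] = cmodel.oob_error
        passes = [preprocess.mask_clouds(p, cmodel) for p in passes]
    else:
        manifest["stages"]["cloud_model_oob_error"] = None

    # 3. co-registration against the most complete pass
    ref_idx = int(np.argmax([p.valid_fraction for p in passes]))
    registered: list[MultibandPass] = []
    dropped = 0
    shifts = []
    for i, p in enumerate(passes):
        if i == ref_idx:
            registered.append(p)
            shifts.append((0, 0))
            continue
        try:
            s = preprocess.estimate_shift(
                passes[ref_idx], p, config.max_shift,
                min_valid_fraction=config.min_valid_fraction)
        except RegistrationFailureError:
            dropped += 1
            log.info("dropping pass %d (%s): registration failure", i, p.date)
            continue
        shifts.append(s)
        registered.append(preprocess.apply_shift(p, s))
    manifest["stages"]["passes_dropped_registration"] = dropped
    manifest["stages"]["estimated_shifts"] = [list(s) for s in shifts]
    manifest["stages"]["passes_used"] = len(registered)

    # 4. seasonal median composites
    composites = preprocess.seasonal_median_composite(
        registered, config.season_windows)

    # 5. features
    stack = features.build_feature_stack(composites, config.season_mode)

    # 6. training sample + model
    sample = classify.sample_training_points(
        _binarized_polygons(dataset.truth_polygons), stack,
        config.n_points_per_polygon, seed=rng_seed)
    model = classify.fit_reed_model(
        sample,
        balanced=config.balanced_second_forest,
        n_trees=config.n_trees,
        vars_per_split=config.vars_per_split,
        seeds=(rng_seed, rng_seed + 1),
    )

    # 7. kappa threshold from held-out (OOB-style) predictions of the
    # training points
    h = model.heldout_reed_proba
    oob_p = np.minimum(h[:, 0], h[:, 1]) if config.fusion == "dual_min" else h[:, 0]
    seen = np.isfinite(oob_p)
    model.threshold = classify.kappa_threshold(
        oob_p[seen], sample.y[seen] == classify.REED)
    manifest["stages"]["kappa_threshold"] = model.threshold

    # 8. prediction
    prob = classify.predict_probability(model, stack, fusion=config.fusion)
    prob.threshold = model.threshold
    presence = prob.presence

    # 9. hectare aggregation, then terrain masking at hectare scale
    cover_raw = postprocess.aggregate_to_hectare(presence, prob.valid)
    slope10 = postprocess.slope_from_dem(dataset.dem, cell_size=10.0)
    ones = np.ones_like(slope10, dtype=bool)
    slope_ha, _ = postprocess.block_reduce_mean(slope10, ones)
    alt_ha, _ = postprocess.block_reduce_mean(dataset.dem, ones)
    cover = postprocess.terrain_mask(cover_raw, slope_ha, alt_ha,
                                     config.slope_max, config.alt_max)
    extent = postprocess.total_extent(cover)
    manifest["stages"]["extent_ha"] = extent
    manifest["stages"]["extent_ha_unmasked"] = postprocess.total_extent(cover_raw)

    validation: dict = {}
    if do_validation:
        design = validate.ValidationDesign(seed=rng_seed)
        records = validate.collect_validation_records(
            cover, presence, prob.valid, dataset.reed_truth, design,
            landcover=dataset.class_map, landcover_labels=dataset.labels)
        if not records.empty and records["cell_obs"].nunique() > 1:
            m10 = validate.confusion_from_records(records, "tenm")
            validation["confusion_10m"] = m10.as_dict()
            ha_ok = records.drop_duplicates("hectare_id")["observed_cover"].nunique() > 1
            if ha_ok:
                mha = validate.confusion_from_records(records, "hectare")
                validation["confusion_ha"] = mha.as_dict()
            # AUC of map probability at visited cells (needs probability output)
            cells = records[["cell_row", "cell_col", "cell_obs"]]
            pvals = prob.p[cells["cell_row"], cells["cell_col"]]
            ok = np.isfinite(pvals)
            if ok.any() and cells["cell_obs"][ok].nunique() > 1:
                validation["auc_10m"] = validate.auc(
                    pvals[ok], cells["cell_obs"].to_numpy()[ok])
            validation["corrected_extent_ha"] = validate.extent_correction_from_metrics(
                extent, m10, "standard") if 0 < m10.omission_reed < 1 else None
        validation["records"] = records

    result = PipelineResult(config, composites, stack, model, prob, cover,
                            cover_raw, extent, manifest, validation)
    if outdir is not None:
        _write_artifacts(result, Path(outdir))
    return result


def _write_artifacts(result: PipelineResult, outdir: Path) -> None:
    from . import io as rio  # local import: keeps tifffile optional at runtime

    outdir.mkdir(parents=True, exist_ok=True)
    rio.write_raster(outdir / "feature_stack.tif",
                     result.stack.layers.astype(np.float32),
                     band_names=list(result.stack.names), nodata=float("nan"))
    if result.config.output == "probability":
        rio.write_raster(outdir / "probability.tif",
                         result.probability.p.astype(np.float32),
                         nodata=float("nan"))
    rio.write_raster(outdir / "presence.tif",
                     result.probability.presence.astype(np.uint8))
    rio.write_raster(outdir / "cover_ha.tif",
                     result.cover.cover.astype(np.float32), nodata=float("nan"))
    result.model.variable_importance.to_csv(outdir / "variable_importance.csv")
    pd_records = result.validation.get("records")
    if pd_records is not None and not pd_records.empty:
        pd_records.to_csv(outdir / "validation_records.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))


# ---------------------------------------------------------------------------
# Fixture
# ---------------------------------------------------------------------------

FIXTURE_FRACTIONS = {
    "reedbed": 0.012,
    "water": 0.08,
    "arable": 0.25,
    "grassland": 0.658,
}


def fixture_pass_specs(year: int = 2016, season_windows=None) -> list[PassSpec]:
    """Passes covering every season window, with clouds, shifts and gain error.

    Two-season calendars get 3 summer + 3 winter passes; four-season
    calendars get 7 passes spanning the four two-month windows.
    """
    if season_windows is not None and len(season_windows) == 4:
        return [
            PassSpec(dt.date(year, 2, 20), cloud_fraction=0.10, shadow_fraction=0.08,
                     shift=(1, -1), gain=1.02, offset=0.01),
            PassSpec(dt.date(year, 3, 15), cloud_fraction=0.0, gain=0.99),
            PassSpec(dt.date(year, 6, 15), cloud_fraction=0.12, shadow_fraction=0.08,
                     shift=(-1, 1), gain=1.01, offset=0.02),
            PassSpec(dt.date(year, 7, 20), cloud_fraction=0.0, shift=(0, 1), gain=0.98),
            PassSpec(dt.date(year, 8, 25), cloud_fraction=0.10, shadow_fraction=0.06,
                     shift=(2, 0), gain=1.02, offset=0.01),
            PassSpec(dt.date(year, 11, 20), cloud_fraction=0.05, shadow_fraction=0.05,
                     shift=(-2, 2), gain=1.03, offset=0.015),
            PassSpec(dt.date(year, 12, 10), cloud_fraction=0.0, shift=(0, -1), gain=1.0),
        ]
    return [
        PassSpec(dt.date(year, 6, 15), cloud_fraction=0.10, shadow_fraction=0.08,
                 shift=(1, -1), gain=1.02, offset=0.01),
        PassSpec(dt.date(year, 7, 20), cloud_fraction=0.0, shift=(0, 0), gain=0.99),
        PassSpec(dt.date(year, 8, 25), cloud_fraction=0.15, shadow_fraction=0.10,
                 shift=(-2, 1), gain=1.01, offset=0.02),
        PassSpec(dt.date(year, 11, 20), cloud_fraction=0.05, shadow_fraction=0.05,
                 shift=(2, 2), gain=1.03, offset=0.015),
        PassSpec(dt.date(year + 1, 1, 15), cloud_fraction=0.0, shift=(0, -1), gain=0.98),
        PassSpec(dt.date(year + 1, 3, 10), cloud_fraction=0.12, shadow_fraction=0.06,
                 shift=(-1, 0), gain=1.0, offset=0.01),
    ]


def make_fixture(size: int = 200, seed: int = 0,
                 season_windows=None, confusion_overlap: float = 0.6,
                 outdir: str | Path | None = None) -> SyntheticDataset:
    """Deterministic small dataset exercising every pipeline stage.

    Contains reedbed (rare, patchy), water, grassland, an arable confusion
    class, clouds with shadows, inter-pass shifts and per-pass gain/offset
    error.
    """
    from .core import TWO_SEASON_WINDOWS
    if season_windows is None:
        season_windows = TWO_SEASON_WINDOWS
    spec = LandscapeSpec(size, size, dict(FIXTURE_FRACTIONS),
                         reed_patch_size=60.0,
                         dem_params=DemParams(base_altitude=20.0, gradient=0.0,
                                              hill_amplitude=30.0),
                         seed=seed)
    seasons = tuple(season_windows)
    phen = make_phenology(seasons=seasons, confusion_overlap=confusion_overlap)
    dataset = generate_dataset(spec, fixture_pass_specs(season_windows=season_windows),
                               phen, season_windows)
    if outdir is not None:
        from . import io as rio
        rio.write_dataset(dataset, outdir)
    return dataset
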