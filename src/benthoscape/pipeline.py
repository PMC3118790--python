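"""End-to-end orchestration: survey -> predictors -> benchmark -> map.

The canonical predictor table has 34 columns: mean bathymetry, the 12
morphometric layers, the two terrain-type maps (6 m and 12 m scales), the
substratum class with its kernel Bray-Curtis dissimilarity and Pielou
evenness, and the 16 waveform statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from benthoscape import bench as bench_mod
from benthoscape import waveforms as wf
from benthoscape.config import BenthoscapeConfig
from benthoscape.diversity import RESPONSE_COLUMNS, index_table
from benthoscape.grids import CategoricalRaster, RasterGrid
from benthoscape.morphometry import MORPHO_LAYERS, classify_terrain, morpho_stack
from benthoscape.seafloor import (
    classify_seafloor,
    confusion_matrix,
    kernel_braycurtis,
    kernel_evenness,
    split_truth_pixels,
    train_substratum_classifier,
)
from benthoscape.simulate import (
    SUBSTRATUM_LEGEND,
    generate_benthoscape,
    generate_quadrats,
    sample_stations,
    simulate_waveform,
)
from benthoscape.spatial import knn_weights, morans_i, predict_map

logger = logging.getLogger(__name__)

#: Canonical order of the 34 predictor columns.
PREDICTOR_COLUMNS = (
    "bathymetry",
    *MORPHO_LAYERS,
    "terrain_6m",
    "terrain_12m",
    "substratum",
    "substratum_braycurtis",
    "substratum_evenness",
    *wf.FEATURE_COLUMNS,
)

WAVEFORM_SHAPE_FEATURES = ("ben_skewness", "ben_time_range")


@dataclass
class Survey:
    """A generated synthetic survey: grids, stations and quadrats."""

    config: BenthoscapeConfig
    depth: RasterGrid
    complexity: RasterGrid
    truth: CategoricalRaster
    stations: pd.DataFrame
    quadrats: pd.DataFrame


@dataclass
class PredictorProducts:
    """Cell-level predictor stack plus station-level predictor table."""

    stack: dict[str, np.ndarray]
    station_predictors: pd.DataFrame  # indexed like stations; NaN rows dropped
    station_rows: np.ndarray          # surviving station positional indices
    substratum_map: CategoricalRaster
    substratum_confusion: pd.DataFrame
    substratum_accuracy: float
    n_lost_soundings: int
    pca_components: int


def simulate_survey(config: BenthoscapeConfig) -> Survey:
    """Generate grids, place stations and score their quadrats (seeded)."""
    depth, complexity, truth = generate_benthoscape(config)
    stations = sample_stations(depth, complexity, config.n_stations,
                               seed=config.seed + 10_000)
    stations = stations.assign(
        substratum=truth.codes[stations["row"], stations["col"]]
    )
    quadrats = generate_quadrats(stations, config, seed=config.seed + 20_000)
    return Survey(config, depth, complexity, truth, stations, quadrats)


def extract_cell_features(survey: Survey) -> pd.DataFrame:
    """Simulate one sounding per grid cell and extract its 16 features.

    Returns one row per cell in row-major order; cells whose bottom return
    is undetectable carry NaN features.
    """
    cfg = survey.config
    rng = np.random.default_rng(cfg.seed + 30_000)
    rows, cols = survey.depth.shape
    records = np.full((rows * cols, len(wf.FEATURE_COLUMNS)), np.nan)
    lost = 0
    for flat in range(rows * cols):
        r, c = divmod(flat, cols)
        w = simulate_waveform(
            survey.depth.values[r, c],
            survey.complexity.values[r, c],
            cfg.waveform_noise_sd,
            rng,
            reflectance_sd=cfg.reflectance_sd,
            sounding_id=f"r{r}c{c}",
        )
        try:
            row = wf.extract_feature_row(w)
        except wf.BottomSignalLostError:
            lost += 1
            continue
        records[flat] = [row[k] for k in wf.FEATURE_COLUMNS]
    if lost:
        logger.info("lost bottom signal on %d of %d cells", lost, rows * cols)
    out = pd.DataFrame(records, columns=list(wf.FEATURE_COLUMNS))
    out.insert(0, "depth", survey.depth.values.ravel())
    return out


def build_predictors(
    survey: Survey, cell_features: pd.DataFrame | None = None
) -> PredictorProducts:
    """Assemble the 34-band predictor stack and the station predictor table."""
    cfg = survey.config
    if cell_features is None:
        cell_features = extract_cell_features(survey)
    rows, cols = survey.depth.shape
    feat_vals = cell_features[list(wf.FEATURE_COLUMNS)].to_numpy()
    valid = np.all(np.isfinite(feat_vals), axis=1)
    n_lost = int((~valid).sum())

    # Substratum map: depth-detrended features -> PCA -> SVM.
    feats_ok = cell_features.loc[valid].copy()
    resid = wf.depth_normalize(feats_ok)
    scores, pca = wf.pca_reduce(resid)
    pc_cols = [c for c in scores.columns if c.startswith("PC")]
    pc_rasters = np.full((len(pc_cols), rows * cols), np.nan)
    pc_rasters[:, valid] = scores[pc_cols].to_numpy().T
    pc_rasters = pc_rasters.reshape(len(pc_cols), rows, cols)

    truth_masked = CategoricalRaster(
        np.where(valid.reshape(rows, cols), survey.truth.codes, CategoricalRaster.NODATA),
        survey.truth.legend, cell_size=cfg.cell_size,
    )
    pix = split_truth_pixels(truth_masked, seed=cfg.seed + 40_000)
    Xtr = pc_rasters[:, pix.train_idx[:, 0], pix.train_idx[:, 1]].T
    svm = train_substratum_classifier(Xtr, pix.train_labels, seed=cfg.seed % (2**31))
    sub_map = classify_seafloor(svm, pc_rasters, SUBSTRATUM_LEGEND, cfg.cell_size)
    cm, overall, _ = confusion_matrix(sub_map, pix)

    bc = kernel_braycurtis(sub_map, radius_m=6.0)
    evenness = kernel_evenness(sub_map, radius_m=6.0)

    stack_obj = morpho_stack(survey.depth)
    stack: dict[str, np.ndarray] = {"bathymetry": stack_obj.bathymetry}
    stack.update(stack_obj.layers)
    # Aspect is undefined (NaN) on perfectly flat cells; encode as -1 so flat
    # cells stay usable by the learners.
    stack["aspect"] = np.nan_to_num(stack["aspect"], nan=-1.0)
    stack["terrain_6m"] = classify_terrain(survey.depth, 6.0).codes.astype(float)
    stack["terrain_12m"] = classify_terrain(survey.depth, 12.0).codes.astype(float)
    sub_codes = sub_map.codes.astype(float)
    sub_codes[sub_map.codes == CategoricalRaster.NODATA] = np.nan
    stack["substratum"] = sub_codes
    stack["substratum_braycurtis"] = bc
    stack["substratum_evenness"] = evenness
    for i, col in enumerate(wf.FEATURE_COLUMNS):
        stack[col] = feat_vals[:, i].reshape(rows, cols)

    st = survey.stations
    flat = st["row"].to_numpy() * cols + st["col"].to_numpy()
    table = pd.DataFrame(
        {name: stack[name].ravel()[flat] for name in PREDICTOR_COLUMNS}
    )
    ok = np.all(np.isfinite(table.to_numpy()), axis=1)
    if (~ok).any():
        logger.info("dropping %d station(s) with incomplete predictors", int((~ok).sum()))
    return PredictorProducts(
        stack=stack,
        station_predictors=table.loc[ok].reset_index(drop=True),
        station_rows=np.flatnonzero(ok),
        substratum_map=sub_map,
        substratum_confusion=cm,
        substratum_accuracy=overall,
        n_lost_soundings=n_lost,
        pca_components=len(pc_cols),
    )


@dataclass
class PipelineResult:
    survey: Survey
    predictors: PredictorProducts
    indices: pd.DataFrame
    cube: pd.DataFrame
    selected: tuple[str, str, int]
    selected_learner: object
    selected_edges: np.ndarray
    selected_scores: dict
    moran: dict
    predicted_map: object
    manifest: dict = field(default_factory=dict)


def run_pipeline(
    config: BenthoscapeConfig,
    out_dir: str | Path | None = None,
    responses: tuple[str, ...] = RESPONSE_COLUMNS,
    ks: tuple[int, ...] = bench_mod.DEFAULT_KS,
    test_n: int = bench_mod.TEST_N,
) -> PipelineResult:
    """Run the full analysis on a synthetic survey and optionally write outputs."""
    survey = simulate_survey(config)
    products = build_predictors(survey)
    idx = index_table(survey.quadrats, quadrat_area=config.quadrat_area,
                      biotic_labels=config.species_pool)
    idx = idx.iloc[products.station_rows].reset_index(drop=True)

    resp_df = idx[list(responses)]
    cube = bench_mod.sweep(
        products.station_predictors, resp_df, ks=ks, test_n=test_n, seed=config.seed
    )
    selected = bench_mod.select_model(cube)
    resp, learner_name, k = selected

    values = resp_df[resp].to_numpy()
    disc = bench_mod.equal_width_discretize(
        values, k, bench_mod.BOUNDED_RANGES.get(resp), name=resp
    )
    X = products.station_predictors.to_numpy(dtype=float)
    tr, te = bench_mod.split_train_test(len(X), test_n=test_n, seed=config.seed)
    proba, learner = bench_mod.train_and_predict(
        learner_name, X[tr], disc.labels[tr], X[te], k, seed=config.seed
    )
    scores = bench_mod.roc_and_confusion(proba, disc.labels[te], k)

    coords = survey.stations[["easting", "northing"]].to_numpy()[products.station_rows]
    weights = knn_weights(coords, k=8)
    moran = {
        "initial": morans_i(values, weights, seed=config.seed),
    }

    legend = bench_mod.THREE_CLASS_LABELS if k == 3 else tuple(f"class{i}" for i in range(k))
    pmap = predict_map(
        learner, products.stack, list(PREDICTOR_COLUMNS), disc.edges, legend,
        cell_size=config.cell_size,
    )
    pred_at_stations = pmap.classes.codes[
        survey.stations["row"].to_numpy()[products.station_rows],
        survey.stations["col"].to_numpy()[products.station_rows],
    ]
    moran["predicted"] = morans_i(pred_at_stations.astype(float), weights,
                                  seed=config.seed + 1)

    manifest = {
        "config": config.to_dict(),
        "n_stations_used": len(products.station_predictors),
        "n_lost_soundings": products.n_lost_soundings,
        "pca_components": products.pca_components,
        "substratum_accuracy": products.substratum_accuracy,
        "selected_model": {"response": resp, "learner": learner_name, "k": k},
        "moran": moran,
    }
    result = PipelineResult(
        survey=survey, predictors=products, indices=idx, cube=cube,
        selected=selected, selected_learner=learner, selected_edges=disc.edges,
        selected_scores=scores, moran=moran, predicted_map=pmap,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    from benthoscape import io as bio

    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = result.survey.config
    bio.write_ascii_grid(out_dir / "depth.asc", result.survey.depth)
    bio.write_ascii_grid(out_dir / "complexity.asc", result.survey.complexity)
    bio.write_ascii_grid(out_dir / "substratum_truth.asc", result.survey.truth)
    bio.write_ascii_grid(out_dir / "substratum_map.asc", result.predictors.substratum_map)
    bio.write_ascii_grid(out_dir / "predicted_map.asc", result.predicted_map.classes)
    result.survey.stations.to_csv(out_dir / "stations.csv", index=False)
    result.survey.quadrats.to_csv(out_dir / "quadrats.csv", index=False)
    result.indices.to_csv(out_dir / "indices.csv", index=False)
    result.predictors.station_predictors.to_csv(out_dir / "predictors.csv", index=False)
    result.cube.to_csv(out_dir / "evalcube.csv", index=False)
    bio.save_config(out_dir / "config.yaml", cfg)
    bio.save_manifest(out_dir / "manifest.json", result.manifest)
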