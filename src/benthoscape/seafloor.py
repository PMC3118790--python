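"""Supervised substratum mapping and kernel beta-diversity rasters.

A radial-kernel support vector machine, trained on ground-truth polygons
(2/3 of truth pixels for training, 1/3 for validation), classifies the
principal-component summary of the depth-detrended waveform features into a
2 m substratum map.  Two moving-kernel layers then summarize the map's
beta-diversity: a Bray-Curtis dissimilarity (%) between the class
composition of a focal disc and that of an equal-area surrounding annulus,
and a Pielou evenness of the class composition within the disc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from benthoscape.grids import CategoricalRaster


@dataclass
class TruthPixels:
    """Ground-truth pixel sets: disjoint training (2/3) and validation (1/3)."""

    train_idx: np.ndarray  # (n, 2) row/col
    train_labels: np.ndarray
    valid_idx: np.ndarray
    valid_labels: np.ndarray


def split_truth_pixels(
    truth: CategoricalRaster,
    n_per_class: int = 60,
    train_fraction: float = 2.0 / 3.0,
    seed: int | np.random.Generator = 0,
) -> TruthPixels:
    """Sample ground-truth pixels per class and split 2/3 train, 1/3 validation."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tr_i, tr_y, va_i, va_y = [], [], [], []
    for code in range(truth.n_classes):
        cells = np.argwhere(truth.codes == code)
        if len(cells) == 0:
            continue
        take = min(n_per_class, len(cells))
        chosen = cells[rng.choice(len(cells), size=take, replace=False)]
        n_train = int(round(train_fraction * take))
        tr_i.append(chosen[:n_train])
        tr_y.append(np.full(n_train, code))
        va_i.append(chosen[n_train:])
        va_y.append(np.full(take - n_train, code))
    return TruthPixels(
        np.concatenate(tr_i), np.concatenate(tr_y),
        np.concatenate(va_i), np.concatenate(va_y),
    )


def train_substratum_classifier(
    pc_table: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
) -> Pipeline:
    """Fit the RBF-kernel SVM on standardized PC scores.

    Hyperparameters (C, gamma) are chosen by a small grid search with
    stratified cross-validation.
    """
    X = np.asarray(pc_table, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 substratum classes to train")
    model = Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel="rbf", random_state=seed)),
    ])
    n_splits = int(min(3, np.bincount(pd.factorize(y)[0]).min()))
    if n_splits >= 2:
        grid = GridSearchCV(
            model,
            {"svm__C": [1.0, 10.0, 100.0], "svm__gamma": ["scale", 0.1]},
            cv=StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed),
            n_jobs=1,
        )
        grid.fit(X, y)
        return grid.best_estimator_
    model.fit(X, y)
    return model


def classify_seafloor(
    model: Pipeline,
    pc_rasters: np.ndarray,
    legend: tuple[str, ...],
    cell_size: float = 2.0,
    valid_mask: np.ndarray | None = None,
) -> CategoricalRaster:
    """Predict the substratum class of every valid cell.

    ``pc_rasters`` has shape (n_pc, rows, cols).  No post-classification
    resampling is applied.
    """
    n_pc, rows, cols = pc_rasters.shape
    X = pc_rasters.reshape(n_pc, -1).T
    codes = np.full(rows * cols, CategoricalRaster.NODATA, dtype=int)
    ok = np.all(np.isfinite(X), axis=1)
    if valid_mask is not None:
        ok &= valid_mask.ravel()
    if ok.any():
        codes[ok] = model.predict(X[ok])
    return CategoricalRaster(codes.reshape(rows, cols), legend, cell_size=cell_size)


def confusion_matrix(
    predicted: CategoricalRaster, truth_pixels: TruthPixels
) -> tuple[pd.DataFrame, float, pd.Series]:
    """Confusion matrix on the validation pixels, with overall and per-class
    accuracy (rows: true class, columns: predicted class)."""
    n = predicted.n_classes
    cm = np.zeros((n, n), dtype=int)
    idx, y = truth_pixels.valid_idx, truth_pixels.valid_labels
    pred = predicted.codes[idx[:, 0], idx[:, 1]]
    for t, p in zip(y, pred):
        if p != CategoricalRaster.NODATA:
            cm[t, p] += 1
    cm_df = pd.DataFrame(cm, index=predicted.legend, columns=predicted.legend)
    total = cm.sum()
    overall = float(np.trace(cm) / total) if total else float("nan")
    row_sums = cm.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = pd.Series(np.diag(cm) / row_sums, index=predicted.legend)
    return cm_df, overall, per_class


def _disc_footprint(radius_cells: float) -> np.ndarray:
    r = int(np.floor(radius_cells))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2 <= radius_cells**2).astype(float)


def _class_fractions(map_: CategoricalRaster, footprint: np.ndarray) -> np.ndarray:
    """Per-class composition fractions under a footprint, shape (k, rows, cols)."""
    valid = (map_.codes != CategoricalRaster.NODATA).astype(float)
    denom = ndimage.convolve(valid, footprint, mode="constant", cval=0.0)
    fracs = np.empty((map_.n_classes, *map_.shape))
    with np.errstate(invalid="ignore", divide="ignore"):
        for k in range(map_.n_classes):
            counts = ndimage.convolve(
                (map_.codes == k).astype(float), footprint, mode="constant", cval=0.0
            )
            fracs[k] = counts / denom
    fracs[:, denom == 0] = np.nan
    return fracs


def kernel_braycurtis(
    map_: CategoricalRaster, radius_m: float = 6.0, against: str = "annulus"
) -> np.ndarray:
    """Moving-kernel Bray-Curtis dissimilarity (0-100%).

    Compares the substratum composition of the disc of ``radius_m`` around
    each cell with, by default, an equal-area surrounding annulus (outer
    radius radius_m * sqrt(2)); ``against='map'`` compares with the map-wide
    composition instead.  0 between identical compositions, 100 between
    compositions sharing no class.
    """
    if radius_m < map_.cell_size:
        raise ValueError("kernel radius must be at least one cell")
    r = radius_m / map_.cell_size
    inner = _disc_footprint(r)
    x = _class_fractions(map_, inner)
    if against == "annulus":
        outer = _disc_footprint(r * np.sqrt(2.0))
        pad = (outer.shape[0] - inner.shape[0]) // 2
        annulus = outer - np.pad(inner, pad)
        y = _class_fractions(map_, annulus)
    elif against == "map":
        valid = map_.codes != CategoricalRaster.NODATA
        overall = np.array(
            [np.mean(map_.codes[valid] == k) for k in range(map_.n_classes)]
        )
        y = np.broadcast_to(overall[:, None, None], x.shape)
    else:
        raise ValueError(f"unknown comparison {against!r}")
    num = np.sum(np.abs(x - y), axis=0)
    den = np.sum(x + y, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        bc = 100.0 * num / den
    bc[~np.isfinite(bc)] = np.nan
    return bc


def kernel_evenness(map_: CategoricalRaster, radius_m: float = 6.0) -> np.ndarray:
    """Moving-kernel Pielou evenness of the substratum composition (0-1).

    0 when a single class covers the kernel; 1 when all classes present in
    the kernel occupy equal proportions (normalized by ln of the number of
    classes present, R >= 2).
    """
    if radius_m < map_.cell_size:
        raise ValueError("kernel radius must be at least one cell")
    fracs = _class_fractions(map_, _disc_footprint(radius_m / map_.cell_size))
    present = (fracs > 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        plogp = np.where(fracs > 0, fracs * np.log(fracs), 0.0)
        h = -np.sum(plogp, axis=0)
        j = np.where(present >= 2, h / np.log(present), 0.0)
    j[np.isnan(fracs).any(axis=0)] = np.nan
    return j
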