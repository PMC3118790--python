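"""Moran's I spatial autocorrelation and predictive mapping.

Moran's I compares differences between neighbouring samples and the mean:

    I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

with S0 the sum of all weights.  Its expectation under no autocorrelation is
-1/(n-1); significance is assessed by a seeded permutation test.  Station
weights default to row-standardized 8-nearest-neighbour; rook and queen
contiguity builders are provided for raster data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.spatial import cKDTree

from benthoscape.grids import CategoricalRaster


@dataclass
class SpatialWeights:
    """Sparse neighbour weights with zero diagonal."""

    matrix: csr_matrix
    scheme: str

    def __post_init__(self) -> None:
        if np.any(self.matrix.diagonal() != 0):
            raise ValueError("self-weights w_ii must be zero")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def knn_weights(coords: np.ndarray, k: int = 8, row_standardize: bool = True) -> SpatialWeights:
    """k-nearest-neighbour weights (default k=8, row-standardized)."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if k >= n:
        raise ValueError(f"k={k} must be below n={n}")
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=k + 1)
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()
    w = np.full(n * k, 1.0 / k if row_standardize else 1.0)
    return SpatialWeights(csr_matrix((w, (rows, cols)), shape=(n, n)), scheme=f"knn{k}")


def grid_contiguity_weights(
    shape: tuple[int, int], scheme: str = "rook", row_standardize: bool = True
) -> SpatialWeights:
    """Rook or queen contiguity weights for the cells of a raster grid."""
    rows, cols = shape
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if scheme == "queen":
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    elif scheme != "rook":
        raise ValueError(f"unknown scheme {scheme!r}")
    ii, jj, ww = [], [], []
    index = np.arange(rows * cols).reshape(rows, cols)
    for dr, dc in offsets:
        src = index[max(0, -dr) : rows - max(0, dr), max(0, -dc) : cols - max(0, dc)]
        dst = index[max(0, dr) : rows + min(0, dr), max(0, dc) : cols + min(0, dc)]
        ii.append(src.ravel())
        jj.append(dst.ravel())
    ii, jj = np.concatenate(ii), np.concatenate(jj)
    W = csr_matrix((np.ones(len(ii)), (ii, jj)), shape=(rows * cols, rows * cols))
    if row_standardize:
        deg = np.asarray(W.sum(axis=1)).ravel()
        W = csr_matrix(W.multiply(1.0 / deg[:, None]))
    return SpatialWeights(W, scheme=scheme)


def morans_i(
    values: np.ndarray,
    weights: SpatialWeights,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> dict[str, float]:
    """Global Moran's I with its expectation and a permutation pseudo p-value.

    The p-value is two-tailed-ish in the usual pseudo-significance sense:
    the fraction of permuted statistics at least as extreme (relative to the
    expectation) as the observed one, including the observed arrangement.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 samples")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("constant values have undefined Moran's I")
    W = weights.matrix
    s0 = float(W.sum())
    scale = n / (s0 * denom)

    def stat(zv: np.ndarray) -> float:
        return scale * float(zv @ (W @ zv))

    i_obs = stat(z)
    expected = -1.0 / (n - 1)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perms = np.empty(n_perm)
    for b in range(n_perm):
        perms[b] = stat(rng.permutation(z))
    extreme = np.abs(perms - expected) >= abs(i_obs - expected) - 1e-15
    p = (1 + int(extreme.sum())) / (n_perm + 1)
    return {"I": i_obs, "expected": expected, "p_value": float(p), "n_perm": n_perm}


@dataclass
class PredictedMap:
    """Categorical prediction raster with per-class probability layers."""

    classes: CategoricalRaster
    probabilities: np.ndarray  # (k, rows, cols), NaN on no-data
    edges: np.ndarray


def predict_map(
    learner,
    stack: dict[str, np.ndarray],
    predictor_names: list[str],
    edges: np.ndarray,
    legend: tuple[str, ...],
    cell_size: float = 2.0,
) -> PredictedMap:
    """Apply a fitted learner across a predictor raster stack.

    ``stack`` maps band names to 2-D arrays; bands must cover the learner's
    training predictor names.  No-data (non-finite) cells propagate.
    """
    missing = [p for p in predictor_names if p not in stack]
    if missing:
        raise KeyError(f"stack lacks predictor bands {missing}")
    shape = next(iter(stack.values())).shape
    X = np.column_stack([np.asarray(stack[p], dtype=float).ravel() for p in predictor_names])
    ok = np.all(np.isfinite(X), axis=1)
    k = len(legend)
    proba = np.full((X.shape[0], k), np.nan)
    codes = np.full(X.shape[0], CategoricalRaster.NODATA, dtype=int)
    if ok.any():
        p = learner.predict_proba(X[ok])
        proba[ok] = p
        codes[ok] = np.argmax(p, axis=1)
    return PredictedMap(
        classes=CategoricalRaster(codes.reshape(shape), legend, cell_size=cell_size),
        probabilities=proba.T.reshape(k, *shape),
        edges=np.asarray(edges, dtype=float),
    )
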