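"""The core benchmark: responses x learners x class counts.

Each of the eight biotic responses is discretized into k = 2..10
equal-width classes; each of the seven learners is trained on a fixed
200-station training split and scored on the held-out 100-station test set
with the four evaluators.  Decay of each evaluator with k is summarized by
an ordinary least-squares fit on 1/k, and the best non-binary model (k >= 3,
maximal CA, ties broken by lower Brier score, then by fixed learner order)
is selected for ROC/confusion reporting and predictive mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_curve

from benthoscape.evaluation import class_priors, evaluate
from benthoscape.learners import LEARNER_ORDER, make_learner

logger = logging.getLogger(__name__)

DEFAULT_KS = tuple(range(2, 11))
TEST_N = 100

#: Responses binned over their theoretical interval rather than the
#: observed range (the Simpson index is bounded on [0, 1]).
BOUNDED_RANGES: dict[str, tuple[float, float]] = {"D": (0.0, 1.0)}

THREE_CLASS_LABELS = ("low", "medium", "high")


@dataclass
class DiscretizedResponse:
    """Equal-width class labels of a continuous response."""

    name: str
    k: int
    edges: np.ndarray
    labels: np.ndarray


def equal_width_discretize(
    values: np.ndarray,
    k: int,
    value_range: tuple[float, float] | None = None,
    name: str = "",
) -> DiscretizedResponse:
    """Partition a response into k equal-width, right-open classes.

    The last class is closed on the right.  ``value_range`` defaults to the
    observed min/max; a degenerate range raises.
    """
    x = np.asarray(values, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    lo, hi = value_range if value_range is not None else (x.min(), x.max())
    if not hi > lo:
        raise ValueError(f"degenerate range [{lo}, {hi}] for response {name!r}")
    edges = np.linspace(lo, hi, k + 1)
    labels = np.clip(np.digitize(x, edges[1:-1], right=False), 0, k - 1)
    return DiscretizedResponse(name=name, k=k, edges=edges, labels=labels)


def split_train_test(
    n: int, test_n: int = TEST_N, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test index split with exactly test_n test rows."""
    if not 0 < test_n < n:
        raise ValueError(f"test_n={test_n} incompatible with n={n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(n)
    return np.sort(perm[test_n:]), np.sort(perm[:test_n])


def train_and_predict(
    learner_name: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    n_classes: int,
    seed: int = 0,
):
    """Fit one learner and return (test probability rows, fitted learner)."""
    y_train = np.asarray(y_train, dtype=int)
    if len(np.unique(y_train)) < 2:
        raise ValueError("need at least 2 classes in the training labels")
    learner = make_learner(learner_name, n_classes=n_classes, seed=seed)
    learner.fit(np.asarray(X_train, dtype=float), y_train)
    proba = learner.predict_proba(np.asarray(X_test, dtype=float))
    return proba, learner


def sweep(
    predictors: pd.DataFrame,
    responses: pd.DataFrame,
    learners: tuple[str, ...] = LEARNER_ORDER,
    ks: tuple[int, ...] = DEFAULT_KS,
    test_n: int = TEST_N,
    seed: int = 0,
    response_ranges: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Evaluate every (response, learner, k) cell on a fixed train/test split.

    Returns a tidy frame with columns response, learner, k, CA, AUC, IS, Bs;
    cells whose training collapses (e.g. a single occupied class) are logged
    and reported as NaN, never fatal.
    """
    ranges = dict(BOUNDED_RANGES)
    ranges.update(response_ranges or {})
    X = predictors.select_dtypes(include=[np.number]).to_numpy(dtype=float)
    train_idx, test_idx = split_train_test(len(X), test_n=test_n, seed=seed)

    rows = []
    for resp in responses.columns:
        values = responses[resp].to_numpy(dtype=float)
        for k in ks:
            try:
                disc = equal_width_discretize(values, k, ranges.get(resp), name=resp)
            except ValueError as exc:
                logger.warning("discretization failed for %s k=%d: %s", resp, k, exc)
                for learner in learners:
                    rows.append({"response": resp, "learner": learner, "k": k})
                continue
            y_train, y_test = disc.labels[train_idx], disc.labels[test_idx]
            priors = class_priors(y_train, k)
            for learner in learners:
                cell = {"response": resp, "learner": learner, "k": k}
                try:
                    proba, _ = train_and_predict(
                        learner, X[train_idx], y_train, X[test_idx], k, seed=seed
                    )
                    cell.update(evaluate(proba, y_test, priors))
                except Exception as exc:
                    logger.warning("cell (%s, %s, k=%d) failed: %s", resp, learner, k, exc)
                rows.append(cell)
    return pd.DataFrame(rows, columns=["response", "learner", "k", "CA", "AUC", "IS", "Bs"])


@dataclass
class TrendFit:
    """OLS fit of an evaluator series against the inverse class count."""

    intercept: float
    slope: float
    r2: float
    r2_adj: float


def inverse_trend_fit(ks: np.ndarray, metric: np.ndarray) -> TrendFit:
    """Fit metric = a + b / k by ordinary least squares."""
    ks = np.asarray(ks, dtype=float)
    y = np.asarray(metric, dtype=float)
    ok = np.isfinite(y)
    X = sm.add_constant(1.0 / ks[ok])
    res = sm.OLS(y[ok], X).fit()
    n = int(ok.sum())
    # A constant series has no variance to explain: R^2 = 0 by convention.
    r2 = float(res.rsquared) if res.centered_tss > 0 else 0.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return TrendFit(float(res.params[0]), float(res.params[1]), r2, r2_adj)


def select_model(
    cube: pd.DataFrame,
    exclude_k: tuple[int, ...] = (2,),
    learners: tuple[str, ...] = LEARNER_ORDER,
) -> tuple[str, str, int]:
    """Best non-binary cell: maximal CA, ties by lower Bs, then learner order.

    Binary discretizations oversimplify the ecological classes and are
    excluded by default.
    """
    df = cube[~cube["k"].isin(exclude_k)].dropna(subset=["CA"]).copy()
    if df.empty:
        raise ValueError("no eligible cells to select from")
    df["learner_rank"] = df["learner"].map({l: i for i, l in enumerate(learners)})
    df = df.sort_values(
        by=["CA", "Bs", "learner_rank", "k"], ascending=[False, True, True, True]
    )
    top = df.iloc[0]
    return str(top["response"]), str(top["learner"]), int(top["k"])


def roc_and_confusion(
    probabilities: np.ndarray, y_true: np.ndarray, n_classes: int
) -> dict:
    """Per-class one-vs-rest ROC with the equal-cost optimum, plus confusion.

    The equal-cost optimal threshold maximizes TPR - FPR (the tangency point
    of the unit-slope iso-performance line).  The confusion matrix reports
    counts with predicted and true proportions of the diagonal.
    """
    P = np.asarray(probabilities, dtype=float)
    y = np.asarray(y_true, dtype=int)
    pred = np.argmax(P, axis=1)
    roc = {}
    for c in range(n_classes):
        pos = (y == c).astype(int)
        if pos.sum() in (0, len(y)):
            continue
        fpr, tpr, thresholds = roc_curve(pos, P[:, c], drop_intermediate=False)
        youden = int(np.argmax(tpr - fpr))
        roc[c] = {
            "fpr": fpr,
            "tpr": tpr,
            "thresholds": thresholds,
            "optimal_threshold": float(thresholds[youden]),
            "optimal_point": (float(fpr[youden]), float(tpr[youden])),
        }
    cm = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(y, pred):
        cm[t, p] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        true_prop = np.diag(cm) / cm.sum(axis=1)
        pred_prop = np.diag(cm) / cm.sum(axis=0)
    return {
        "roc": roc,
        "confusion": cm,
        "true_proportions": true_prop,
        "predicted_proportions": pred_prop,
    }


def binned_trend(
    response: np.ndarray,
    predictor: np.ndarray,
    bin_size: int = 20,
    model: str = "poly2",
) -> dict:
    """Block-averaged response/predictor trend with a fitted curve.

    Stations are sorted by the predictor and averaged in consecutive blocks
    of ``bin_size``; a degree-2/3 polynomial or natural-log model is fitted
    to the block means and reported with its R^2.
    """
    r = np.asarray(response, dtype=float)
    p = np.asarray(predictor, dtype=float)
    order = np.argsort(p, kind="stable")
    n_bins = len(r) // bin_size
    if n_bins < 2:
        raise ValueError("need at least 2 full bins")
    idx = order[: n_bins * bin_size].reshape(n_bins, bin_size)
    mean_r = r[idx].mean(axis=1)
    mean_p = p[idx].mean(axis=1)

    if model == "poly2":
        design = np.column_stack([mean_p**2, mean_p, np.ones(n_bins)])
    elif model == "poly3":
        design = np.column_stack([mean_p**3, mean_p**2, mean_p, np.ones(n_bins)])
    elif model == "log":
        if np.any(mean_p <= 0):
            raise ValueError("log model requires positive predictor means")
        design = np.column_stack([np.log(mean_p), np.ones(n_bins)])
    else:
        raise ValueError(f"unknown model {model!r}")
    coef, *_ = np.linalg.lstsq(design, mean_r, rcond=None)
    fitted = design @ coef
    ss_res = float(np.sum((mean_r - fitted) ** 2))
    ss_tot = float(np.sum((mean_r - mean_r.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return {
        "bin_response": mean_r,
        "bin_predictor": mean_p,
        "coefficients": coef,
        "fitted": fitted,
        "r2": r2,
    }
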