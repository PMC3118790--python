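"""The seven supervised learners of the benchmark.

Naive Bayes, the two CART-style trees, the random forest and the RBF
support vector machine delegate to scikit-learn estimators configured to the
benchmark's fixed settings (binary splits, no split below 10 samples,
m-estimate probability smoothing with m = 5, 10-tree forest with 6-variable
split subsets, standardized inputs for the SVM).  C4.5 (gain-ratio splits
with pessimistic-error pruning at 25% confidence) and CN2 (beam-searched
ordered rule list with Laplace rule evaluation and likelihood-ratio
significance pruning) are implemented here directly.

Every learner exposes ``fit(X, y)`` and ``predict_proba(X)`` returning one
probability row per sample over the ``n_classes`` discretization classes
(classes absent from training get zero probability).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import beta as beta_dist
from scipy.stats import chi2
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

#: Fixed learner order, also the deterministic tie-break order of selection.
LEARNER_ORDER = (
    "naive_bayes",
    "regression_tree",
    "classification_tree",
    "c45",
    "random_forest",
    "svm",
    "cn2",
)

MIN_SPLIT = 10       # no node with fewer samples is split, across all trees
M_ESTIMATE = 5.0     # m-estimate smoothing of tree leaf probabilities
C45_CONFIDENCE = 0.25
CN2_BEAM = 5
CN2_ALPHA = 0.05
CN2_STOPPING_ALPHA = 0.2


def _align_proba(p: np.ndarray, classes: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((p.shape[0], n_classes))
    out[:, np.asarray(classes, dtype=int)] = p
    return out


class NaiveBayesLearner:
    """Gaussian naive Bayes with relative-frequency class priors."""

    def __init__(self, n_classes: int, seed: int = 0):
        self.n_classes = n_classes
        self.clf = GaussianNB()

    def fit(self, X, y):
        self.clf.fit(X, y)
        return self

    def predict_proba(self, X):
        return _align_proba(self.clf.predict_proba(X), self.clf.classes_, self.n_classes)


class RegressionTreeLearner:
    """CART regressor on the numeric class index; predictions are rounded
    back to the nearest class and reported with certainty (one-hot)."""

    def __init__(self, n_classes: int, seed: int = 0):
        self.n_classes = n_classes
        self.clf = DecisionTreeRegressor(min_samples_split=MIN_SPLIT, random_state=seed)

    def fit(self, X, y):
        self.clf.fit(X, np.asarray(y, dtype=float))
        return self

    def predict_proba(self, X):
        pred = np.clip(np.rint(self.clf.predict(X)), 0, self.n_classes - 1).astype(int)
        out = np.zeros((len(pred), self.n_classes))
        out[np.arange(len(pred)), pred] = 1.0
        return out


class ClassificationTreeLearner:
    """CART classifier with information-gain splits and m-estimate (m = 5)
    smoothing of the leaf class probabilities toward the training priors."""

    def __init__(self, n_classes: int, seed: int = 0):
        self.n_classes = n_classes
        self.clf = DecisionTreeClassifier(
            criterion="entropy", min_samples_split=MIN_SPLIT, random_state=seed
        )

    def fit(self, X, y):
        self.clf.fit(X, y)
        y = np.asarray(y)
        self.priors_ = np.bincount(y, minlength=self.n_classes) / len(y)
        return self

    def predict_proba(self, X):
        leaves = self.clf.apply(np.asarray(X, dtype=np.float32))
        counts = self.clf.tree_.value[leaves, 0, :] * self.clf.tree_.weighted_n_node_samples[leaves][:, None]
        counts = _align_proba(counts, self.clf.classes_, self.n_classes)
        n = counts.sum(axis=1, keepdims=True)
        return (counts + M_ESTIMATE * self.priors_) / (n + M_ESTIMATE)


@dataclass
class _TreeNode:
    counts: np.ndarray
    feature: int = -1
    threshold: float = 0.0
    left: "_TreeNode | None" = None
    right: "_TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-np.sum(p * np.log2(p)))


def _pessimistic_errors(counts: np.ndarray, cf: float) -> float:
    """Quinlan-style upper confidence bound on the leaf error count."""
    n = int(counts.sum())
    if n == 0:
        return 0.0
    e = n - int(counts.max())
    if e >= n:
        return float(n)
    # Clopper-Pearson upper bound of the binomial error rate.
    return float(n * beta_dist.ppf(1.0 - cf, e + 1, n - e))


class C45Learner:
    """Gain-ratio decision tree with binary numeric splits.

    Pre-pruning forbids splitting nodes below ``MIN_SPLIT`` samples;
    post-pruning replaces a subtree by a leaf whenever the leaf's pessimistic
    error bound (confidence ``C45_CONFIDENCE``) does not exceed the sum of
    its children's.
    """

    def __init__(self, n_classes: int, seed: int = 0, max_depth: int = 25):
        self.n_classes = n_classes
        self.max_depth = max_depth

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self.priors_ = np.bincount(y, minlength=self.n_classes) / len(y)
        self.root_ = self._grow(X, y, depth=0)
        self._prune(self.root_)
        return self

    def _grow(self, X, y, depth) -> _TreeNode:
        counts = np.bincount(y, minlength=self.n_classes).astype(float)
        node = _TreeNode(counts=counts)
        n = len(y)
        if n < MIN_SPLIT or depth >= self.max_depth or counts.max() == n:
            return node
        base = _entropy(counts)
        best_gr, best = 0.0, None
        onehot = np.eye(self.n_classes)[y]

        def _row_entropy(cnt: np.ndarray, tot: np.ndarray) -> np.ndarray:
            with np.errstate(divide="ignore", invalid="ignore"):
                p = cnt / tot[:, None]
                h = np.where(p > 0, -p * np.log2(p), 0.0)
            return h.sum(axis=1)

        for j in range(X.shape[1]):
            xj = X[:, j]
            order = np.argsort(xj, kind="stable")
            xs = xj[order]
            left = np.cumsum(onehot[order], axis=0)[:-1]       # counts left of each cut
            nl = np.arange(1, n)
            valid = xs[:-1] != xs[1:]
            if not valid.any():
                continue
            right = counts - left
            gain = base - (nl * _row_entropy(left, nl) + (n - nl) * _row_entropy(right, n - nl)) / n
            pl = nl / n
            split_info = -(pl * np.log2(pl) + (1 - pl) * np.log2(1 - pl))
            with np.errstate(divide="ignore", invalid="ignore"):
                gr = np.where(valid & (gain > 1e-12), gain / split_info, -np.inf)
            i = int(np.argmax(gr))
            if gr[i] > best_gr:
                best_gr = float(gr[i])
                best = (j, 0.5 * (xs[i] + xs[i + 1]))
        if best is None:
            return node
        j, thr = best
        mask = X[:, j] <= thr
        node.feature, node.threshold = j, thr
        node.left = self._grow(X[mask], y[mask], depth + 1)
        node.right = self._grow(X[~mask], y[~mask], depth + 1)
        return node

    def _prune(self, node: _TreeNode) -> float:
        """Return the pessimistic error estimate of the (possibly pruned) subtree."""
        leaf_err = _pessimistic_errors(node.counts, C45_CONFIDENCE)
        if node.is_leaf:
            return leaf_err
        subtree_err = self._prune(node.left) + self._prune(node.right)
        if leaf_err <= subtree_err:
            node.left = node.right = None
            node.feature = -1
            return leaf_err
        return subtree_err

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        out = np.empty((len(X), self.n_classes))
        for i, x in enumerate(X):
            node = self.root_
            while not node.is_leaf:
                node = node.left if x[node.feature] <= node.threshold else node.right
            c = node.counts
            out[i] = (c + M_ESTIMATE * self.priors_) / (c.sum() + M_ESTIMATE)
        return out


class RandomForestLearner:
    """10-tree random forest, majority vote, 6-variable split subsets.

    The split-subset size is 6 for the canonical 34-predictor table and
    round(sqrt(p)) otherwise; nodes below 10 samples are not split.
    """

    def __init__(self, n_classes: int, seed: int = 0, n_features: int | None = None):
        self.n_classes = n_classes
        self.seed = seed
        self.n_features = n_features

    def fit(self, X, y):
        p = np.asarray(X).shape[1] if self.n_features is None else self.n_features
        max_features = 6 if p == 34 else max(1, int(round(np.sqrt(p))))
        self.clf = RandomForestClassifier(
            n_estimators=10,
            max_features=min(max_features, np.asarray(X).shape[1]),
            min_samples_split=MIN_SPLIT,
            random_state=self.seed,
            n_jobs=1,
        )
        self.clf.fit(X, y)
        return self

    def predict_proba(self, X):
        return _align_proba(self.clf.predict_proba(X), self.clf.classes_, self.n_classes)

    @property
    def feature_importances_(self) -> np.ndarray:
        return self.clf.feature_importances_


class SVMLearner:
    """RBF-kernel SVM on standardized inputs with probability outputs."""

    def __init__(self, n_classes: int, seed: int = 0):
        self.n_classes = n_classes
        self.clf = Pipeline([
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="rbf", probability=True, random_state=seed)),
        ])

    def fit(self, X, y):
        import warnings

        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*probability.*", category=FutureWarning)
            self.clf.fit(X, y)
        return self

    def predict_proba(self, X):
        return _align_proba(
            self.clf.predict_proba(X), self.clf.named_steps["svm"].classes_, self.n_classes
        )


@dataclass
class _Rule:
    selectors: tuple[tuple[int, int, float], ...]  # (feature, 0 for <= / 1 for >, thr)
    counts: np.ndarray = field(default=None)

    def covers(self, X: np.ndarray) -> np.ndarray:
        mask = np.ones(len(X), dtype=bool)
        for j, op, thr in self.selectors:
            mask &= (X[:, j] <= thr) if op == 0 else (X[:, j] > thr)
        return mask


def _lrs(covered: np.ndarray, expected_dist: np.ndarray) -> float:
    """Likelihood-ratio statistic of a rule's class distribution against an
    expected distribution (both as counts / probabilities)."""
    n = covered.sum()
    if n == 0:
        return 0.0
    f = covered / n
    e = np.clip(expected_dist, 1e-12, None)
    mask = f > 0
    return float(2.0 * n * np.sum(f[mask] * np.log(f[mask] / e[mask])))


class CN2Learner:
    """Ordered CN2 rule inducer with beam search and exclusive covering.

    Complexes are conjunctions of threshold tests (thresholds at the deciles
    of each feature); the beam keeps the ``CN2_BEAM`` best complexes by
    Laplace accuracy.  A specialization must be significant at
    ``CN2_STOPPING_ALPHA`` against its parent's coverage, and an accepted
    rule must be significant at ``CN2_ALPHA`` against the remaining
    examples' class distribution.  Covered examples are removed and search
    repeats; prediction walks the ordered list and reports the
    Laplace-smoothed class distribution of the first matching rule.
    """

    def __init__(self, n_classes: int, seed: int = 0, max_rule_length: int = 5,
                 max_rules: int = 30):
        self.n_classes = n_classes
        self.max_rule_length = max_rule_length
        self.max_rules = max_rules

    def _selectors(self, X: np.ndarray) -> list[tuple[int, int, float]]:
        sels = []
        for j in range(X.shape[1]):
            thr = np.unique(np.percentile(X[:, j], np.arange(10, 100, 10)))
            for t in thr:
                sels.append((j, 0, float(t)))
                sels.append((j, 1, float(t)))
        return sels

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self.priors_ = np.bincount(y, minlength=self.n_classes) / len(y)
        selectors = self._selectors(X)
        sel_masks = np.stack([
            (X[:, j] <= t) if op == 0 else (X[:, j] > t) for j, op, t in selectors
        ])
        onehot = np.eye(self.n_classes)[y]

        self.rules_: list[_Rule] = []
        remaining = np.ones(len(y), dtype=bool)
        while remaining.sum() >= MIN_SPLIT and len(self.rules_) < self.max_rules:
            default_counts = onehot[remaining].sum(axis=0)
            default_dist = default_counts / default_counts.sum()
            best = self._find_rule(sel_masks, selectors, onehot, remaining, default_dist)
            if best is None:
                break
            rule, counts = best
            if _lrs(counts, default_dist) < chi2.ppf(1 - CN2_ALPHA, self.n_classes - 1):
                break
            rule.counts = counts
            self.rules_.append(rule)
            remaining &= ~rule.covers(X)
        self.default_counts_ = onehot[remaining].sum(axis=0) if remaining.any() else onehot.sum(axis=0)
        return self

    def _find_rule(self, sel_masks, selectors, onehot, remaining, default_dist):
        n_cls = self.n_classes
        stop_thr = chi2.ppf(1 - CN2_STOPPING_ALPHA, n_cls - 1)

        def laplace(counts):
            return (counts.max(axis=-1) + 1.0) / (counts.sum(axis=-1) + n_cls)

        beam: list[tuple[tuple, np.ndarray]] = [((), remaining.copy())]
        best_rule, best_score, best_counts = None, -np.inf, None
        for _ in range(self.max_rule_length):
            candidates: list[tuple[float, tuple, np.ndarray, np.ndarray]] = []
            seen = set()
            for sel_idx_tuple, cover in beam:
                parent_counts = onehot[cover].sum(axis=0)
                new_covers = cover[None, :] & sel_masks
                counts = new_covers.astype(float) @ onehot
                scores = laplace(counts)
                order = np.argsort(-scores)[: 4 * CN2_BEAM]
                for s in order:
                    if counts[s].sum() < 1 or counts[s].sum() == parent_counts.sum():
                        continue
                    key = tuple(sorted(sel_idx_tuple + (s,)))
                    if key in seen:
                        continue
                    seen.add(key)
                    candidates.append((float(scores[s]), key, new_covers[s], counts[s]))
            if not candidates:
                break
            candidates.sort(key=lambda c: -c[0])
            new_beam = []
            for score, key, cover, counts in candidates[:CN2_BEAM]:
                parent_dist = default_dist
                if _lrs(counts, parent_dist) < stop_thr:
                    continue
                new_beam.append((key, cover))
                if score > best_score:
                    best_score = score
                    best_rule = _Rule(tuple(selectors[i] for i in key))
                    best_counts = counts
            if not new_beam:
                break
            beam = new_beam
        if best_rule is None:
            return None
        return best_rule, best_counts

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        out = np.empty((len(X), self.n_classes))
        unmatched = np.ones(len(X), dtype=bool)
        for rule in self.rules_:
            hit = rule.covers(X) & unmatched
            if hit.any():
                out[hit] = (rule.counts + 1.0) / (rule.counts.sum() + self.n_classes)
                unmatched &= ~hit
        if unmatched.any():
            dc = self.default_counts_
            out[unmatched] = (dc + 1.0) / (dc.sum() + self.n_classes)
        return out


_LEARNERS = {
    "naive_bayes": NaiveBayesLearner,
    "regression_tree": RegressionTreeLearner,
    "classification_tree": ClassificationTreeLearner,
    "c45": C45Learner,
    "random_forest": RandomForestLearner,
    "svm": SVMLearner,
    "cn2": CN2Learner,
}


def make_learner(name: str, n_classes: int, seed: int = 0):
    """Instantiate a learner by its benchmark name."""
    if name not in _LEARNERS:
        raise KeyError(f"unknown learner {name!r}; choose from {LEARNER_ORDER}")
    return _LEARNERS[name](n_classes=n_classes, seed=seed)
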