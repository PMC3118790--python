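"""The four learner evaluators: CA, AUC, Information Score and Brier score.

* ``CA`` — classification accuracy of the argmax decision.
* ``AUC`` — macro-averaged one-vs-rest rank probability that a positive
  sample is scored above a negative one (ties count 1/2).
* ``IS`` — Kononenko-Bratko information score: the average information (in
  bits) a prediction supplies beyond the class priors.  For a sample of true
  class c with prior P(c) and predicted probability P'(c), the contribution
  is -log2 P(c) + log2 P'(c) when P'(c) >= P(c) and
  -(-log2(1 - P(c)) + log2(1 - P'(c))) otherwise.
* ``Bs`` — half the mean squared deviation between the probability rows and
  the one-hot outcomes, so a confidently wrong predictor scores 1 and a
  perfect one 0.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

_EPS = 1e-12


def class_priors(y_train: np.ndarray, n_classes: int) -> np.ndarray:
    """Relative-frequency class priors of a training label vector."""
    y = np.asarray(y_train, dtype=int)
    return np.bincount(y, minlength=n_classes) / len(y)


def _auc_one_vs_rest(scores: np.ndarray, positive: np.ndarray) -> float:
    ranks = rankdata(scores)
    n_pos = int(positive.sum())
    n_neg = len(scores) - n_pos
    return float((ranks[positive].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate(
    probabilities: np.ndarray,
    y_true: np.ndarray,
    priors: np.ndarray,
) -> dict[str, float]:
    """Score a probabilistic prediction set with all four evaluators.

    ``probabilities`` is (n_samples, n_classes) with rows summing to 1
    (tolerance 1e-6); ``priors`` are the training relative frequencies.
    """
    P = np.asarray(probabilities, dtype=float)
    y = np.asarray(y_true, dtype=int)
    if P.ndim != 2 or len(P) != len(y):
        raise ValueError("probabilities must be (n_samples, n_classes)")
    if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("probability rows must sum to 1 (tolerance 1e-6)")
    n, k = P.shape

    ca = float(np.mean(np.argmax(P, axis=1) == y))

    aucs = []
    for c in range(k):
        pos = y == c
        if 0 < pos.sum() < n:
            aucs.append(_auc_one_vs_rest(P[:, c], pos))
    auc = float(np.mean(aucs)) if aucs else float("nan")

    pri = np.clip(np.asarray(priors, dtype=float), _EPS, 1 - _EPS)
    p_true = P[np.arange(n), y]
    prior_true = pri[y]
    gain = -np.log2(prior_true) + np.log2(np.clip(p_true, _EPS, None))
    loss = -(-np.log2(1 - prior_true) + np.log2(np.clip(1 - p_true, _EPS, None)))
    is_score = float(np.mean(np.where(p_true >= prior_true, gain, loss)))

    onehot = np.eye(k)[y]
    bs = float(np.sum((P - onehot) ** 2) / (2 * n))

    return {"CA": ca, "AUC": auc, "IS": is_score, "Bs": bs}
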