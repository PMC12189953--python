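"""Evaluation metrics for presence/pseudoabsence classifiers.

ROC AUC is computed by the rank (Mann–Whitney) formulation, exactly equal to
the fraction of (positive, negative) pairs ranked concordantly with ties
counted as ½.  TSS = sensitivity + specificity − 1, with the prediction
positive iff score ≥ threshold; the TSS-optimal threshold is found by an
exact scan over the midpoints between consecutive distinct scores.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .errors import UndefinedMetricError


def _check_two_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == 0
    if not pos.any() or not neg.any():
        raise UndefinedMetricError("metric requires both classes present")
    return pos, neg


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve.

    Equals P(score_pos > score_neg) + ½ P(score_pos = score_neg) over all
    (positive, negative) pairs.
    """
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_two_classes(labels)
    ranks = rankdata(scores)  # average ranks handle ties as ½
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def tss_at_threshold(scores, labels, threshold: float) -> float:
    """True skill statistic of the thresholded classifier.

    Prediction is positive iff score ≥ threshold;
    TSS = sensitivity + specificity − 1 ∈ [−1, 1].
    """
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_two_classes(labels)
    pred = scores >= threshold
    sens = pred[pos].mean()
    spec = (~pred[neg]).mean()
    return float(sens + spec - 1.0)


def optimize_threshold(scores, labels) -> tuple[float, float]:
    """TSS-maximizing threshold.

    Candidates are the midpoints between consecutive distinct sorted scores
    plus the two extremes (all-positive / all-negative classifiers).  Ties go
    to the smallest maximizing candidate, so the returned threshold is the
    midpoint of the first maximizing interval.
    """
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_two_classes(labels)
    uniq = np.unique(scores)
    candidates = np.concatenate([
        uniq[:1],                      # all predictions positive (score >= min)
        (uniq[:-1] + uniq[1:]) / 2.0,  # midpoints of consecutive distinct scores
        [uniq[-1] + np.spacing(uniq[-1])],  # all predictions negative
    ])
    pos_sorted = np.sort(scores[pos])
    neg_sorted = np.sort(scores[neg])
    # counts of scores >= t via binary search, vectorized over candidates
    sens = 1.0 - np.searchsorted(pos_sorted, candidates, side="left") / pos_sorted.size
    spec = np.searchsorted(neg_sorted, candidates, side="left") / neg_sorted.size
    tss = sens + spec - 1.0
    best = int(np.argmax(tss > tss.max() - 1e-12))  # smallest maximizing candidate
    return float(candidates[best]), float(tss[best])
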