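"""Co-membership scores, precision-recall curves, and max-F1 summaries.

Evaluation is pairwise: the positives are vertex pairs sharing a planted
group label, and a method is judged by how its pairwise scores rank those
positives.  Tied scores are processed as a block (all pairs at a threshold
enter the confusion counts together), which matters for baselines that
assign p = 1 to many pairs at once.
"""

from __future__ import annotations

import numpy as np

from .network import Membership


def co_membership(tau: Membership | np.ndarray) -> np.ndarray:
    """Probability that two vertices occupy the same leaf.

    ``score(i, j) = sum_u tau_iu tau_ju`` — symmetric, in [0, 1], equal to
    ``1/G`` when both rows are uniform; the diagonal is set to 1.
    """
    T = tau.tau if isinstance(tau, Membership) else np.asarray(tau, float)
    co = T @ T.T
    np.fill_diagonal(co, 1.0)
    return co


def pair_scores_and_labels(
    score_matrix: np.ndarray, truth_labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Flatten a symmetric score matrix and group labels into pair vectors.

    Returns ``(scores, labels)`` over the strict upper triangle, where a
    label of 1 marks a same-group (positive) pair.
    """
    score_matrix = np.asarray(score_matrix, float)
    truth_labels = np.asarray(truth_labels)
    n = score_matrix.shape[0]
    if truth_labels.shape[0] != n:
        raise ValueError("truth labels do not cover the scored vertices")
    iu = np.triu_indices(n, k=1)
    scores = score_matrix[iu]
    labels = (truth_labels[iu[0]] == truth_labels[iu[1]]).astype(int)
    return scores, labels


def pr_curve(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Tie-blocked precision-recall curve over descending score thresholds.

    At each distinct score value, all pairs with at least that score are
    predicted positive; returns the ``(precision, recall)`` sequences in
    threshold order.  Raises if the truth contains no positive pair.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length vectors")
    P = labels.sum()
    if P == 0:
        raise ValueError("no positive pairs in the truth")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    tp = np.cumsum(y)
    pred = np.arange(1, len(y) + 1)
    # block boundaries: last index of each tied-score run
    last = np.flatnonzero(np.r_[s[1:] != s[:-1], True])
    precision = tp[last] / pred[last]
    recall = tp[last] / P
    return precision, recall


def f1_max(precision: np.ndarray, recall: np.ndarray) -> float:
    """Maximum harmonic mean of precision and recall along a curve."""
    p = np.asarray(precision, float)
    r = np.asarray(recall, float)
    if p.size == 0:
        raise ValueError("empty curve")
    ok = (p + r) > 0
    if not ok.any():
        return 0.0
    return float(np.max(2 * p[ok] * r[ok] / (p[ok] + r[ok])))


def aggregate_pr(
    replicates: list[tuple[np.ndarray, np.ndarray]]
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled precision-recall over replicate ``(scores, labels)`` pairs.

    Confusion counts are amassed across replicates at each score
    threshold before computing precision and recall — pooling, not
    curve averaging, so replicates with more pairs weigh more.
    """
    if len(replicates) == 0:
        raise ValueError("need at least one replicate")
    scores = np.concatenate([np.asarray(s, float) for s, _ in replicates])
    labels = np.concatenate([np.asarray(l, int) for _, l in replicates])
    return pr_curve(scores, labels)
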