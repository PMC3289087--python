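"""Evaluation metrics: BCubed clustering scores, Van Rijsbergen's F, target
prediction at a posterior threshold, and Pearson recovery correlations."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ClusteringEval",
    "bcubed",
    "f_metric",
    "target_prediction_eval",
    "pearson_recovery",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusteringEval:
    precision: float
    recall: float
    f: float


def f_metric(precision: float, recall: float) -> float:
    """Van Rijsbergen's F: harmonic mean of precision and recall (0 if either is 0)."""
    for name, v in (("precision", precision), ("recall", recall)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if precision == 0 or recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def bcubed(pred_labels, true_labels, mask=None) -> ClusteringEval:
    """BCubed precision/recall of a predicted clustering against categories.

    For each item, precision is the fraction of items sharing its predicted
    cluster (itself included) that also share its true category; recall swaps
    the roles.  Scores are averaged over items.  ``mask`` (boolean) restricts
    the evaluation to a subset, e.g. to exclude unclassified outlier samples.
    """
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape or pred.ndim != 1:
        raise ValueError("label vectors must be 1-D with equal length")
    if mask is not None:
        keep = np.asarray(mask, dtype=bool)
        pred, true = pred[keep], true[keep]
    n = pred.size
    if n == 0:
        raise ValueError("empty input")
    # contingency counts n_{cluster, category}
    _, pred_i = np.unique(pred, return_inverse=True)
    _, true_i = np.unique(true, return_inverse=True)
    table = np.zeros((pred_i.max() + 1, true_i.max() + 1))
    np.add.at(table, (pred_i, true_i), 1.0)
    cluster_sizes = table.sum(axis=1)
    category_sizes = table.sum(axis=0)
    # item in cell (c, t) has precision n_{c,t}/n_c and recall n_{c,t}/n_t
    precision = float((table**2 / cluster_sizes[:, None]).sum() / n)
    recall = float((table**2 / category_sizes[None, :]).sum() / n)
    return ClusteringEval(precision, recall, f_metric(precision, recall))


def target_prediction_eval(
    edge_prob: np.ndarray,
    true_edges,
    threshold: float = 0.5,
    gene_labels=None,
    tf_labels=None,
) -> ClusteringEval:
    """Precision/recall/F of thresholded posterior edges against the truth.

    ``edge_prob`` is the G x L posterior matrix; pairs with posterior >=
    ``threshold`` are predicted as regulations.  ``true_edges`` may be a set of
    (gene, tf) label pairs (with ``gene_labels``/``tf_labels`` supplied) or a
    boolean/0-1 matrix of the same shape.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    edge_prob = np.asarray(edge_prob, dtype=float)
    pred = edge_prob >= threshold
    if isinstance(true_edges, np.ndarray):
        truth = np.asarray(true_edges).astype(bool)
        if truth.shape != edge_prob.shape:
            raise ValueError("truth matrix shape mismatch")
    else:
        if gene_labels is None or tf_labels is None:
            raise ValueError("label lists required when true_edges is a pair set")
        g_idx = {g: i for i, g in enumerate(gene_labels)}
        t_idx = {t: j for j, t in enumerate(tf_labels)}
        truth = np.zeros(edge_prob.shape, dtype=bool)
        for g, t in true_edges:
            truth[g_idx[g], t_idx[t]] = True
    tp = float(np.sum(pred & truth))
    n_pred = float(pred.sum())
    n_true = float(truth.sum())
    if n_pred == 0:
        logger.info("no edges predicted at threshold %.3f; precision set to 0", threshold)
        precision = 0.0
    else:
        precision = tp / n_pred
    recall = tp / n_true if n_true > 0 else 0.0
    return ClusteringEval(precision, recall, f_metric(precision, recall))


def pearson_recovery(estimate: np.ndarray, truth: np.ndarray) -> float:
    """Pearson correlation of flattened matrices, matched entry by entry.

    No column permutation or sign flipping is applied: the database prior
    fixes factor order and non-negativity fixes sign, so recovered quantities
    are directly comparable with the truth.
    """
    est = np.asarray(estimate, dtype=float).ravel()
    tru = np.asarray(truth, dtype=float).ravel()
    if est.shape != tru.shape:
        raise ValueError("shape mismatch")
    if est.size < 2 or np.ptp(est) == 0 or np.ptp(tru) == 0:
        raise ValueError("inputs must be non-constant with at least 2 entries")
    return float(np.corrcoef(est, tru)[0, 1])
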