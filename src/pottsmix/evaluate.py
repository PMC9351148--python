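"""Clustering evaluation: ARI, NMI, optimal label matching, rare-type scores,
composition RMSE."""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import (
    adjusted_rand_score,
    f1_score,
    matthews_corrcoef,
    normalized_mutual_info_score,
)

__all__ = [
    "ari",
    "nmi",
    "match_labels",
    "matching_permutation",
    "rare_type_scores",
    "composition_rmse",
]


def _check_lengths(pred, truth) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError("pred and truth must be 1-D and of equal length")
    return pred, truth


def ari(pred, truth) -> float:
    """Adjusted Rand index between two partitions (1 identical, ~0 independent)."""
    pred, truth = _check_lengths(pred, truth)
    return float(adjusted_rand_score(truth, pred))


def nmi(pred, truth) -> float:
    """Mutual information normalized by the arithmetic mean of the entropies."""
    pred, truth = _check_lengths(pred, truth)
    if len(np.unique(pred)) < 2 or len(np.unique(truth)) < 2:
        warnings.warn("single-class labeling; NMI defined as 0")
        return 0.0
    return float(normalized_mutual_info_score(truth, pred, average_method="arithmetic"))


def matching_permutation(pred, truth) -> dict:
    """Optimal-assignment matching of predicted classes to truth classes.

    The contingency table is padded to square so predicted and true class
    counts may differ; unmatched predicted classes receive fresh labels not
    present in the truth. Returns a dict mapping predicted label -> matched
    label.
    """
    pred, truth = _check_lengths(pred, truth)
    classes_p = np.unique(pred)
    classes_t = np.unique(truth)
    kp, kt = len(classes_p), len(classes_t)
    K = max(kp, kt)
    table = np.zeros((K, K))
    pi = {v: i for i, v in enumerate(classes_p)}
    ti = {v: i for i, v in enumerate(classes_t)}
    for p, t in zip(pred, truth):
        table[pi[p], ti[t]] += 1
    rows, cols = linear_sum_assignment(-table)
    fresh = int(classes_t.max()) + 1 if np.issubdtype(classes_t.dtype, np.integer) else None
    mapping = {}
    for r, ccol in zip(rows, cols):
        if r >= kp:
            continue
        if ccol < kt:
            mapping[classes_p[r]] = classes_t[ccol]
        else:
            # unmatched predicted class: fresh label beyond the truth's range
            if fresh is None:
                mapping[classes_p[r]] = classes_p[r]
            else:
                mapping[classes_p[r]] = fresh
                fresh += 1
    return mapping


def match_labels(pred, truth) -> np.ndarray:
    """Relabel pred by the permutation maximizing contingency-table agreement."""
    pred, truth = _check_lengths(pred, truth)
    mapping = matching_permutation(pred, truth)
    return np.asarray([mapping[p] for p in pred])


def rare_type_scores(pred, truth, rare_type_ids) -> dict:
    """One-vs-rest F1 and MCC for each rare type on already matched labels.

    Summary values are unweighted means over the rare types; a rare type never
    predicted scores F1 = 0.
    """
    pred, truth = _check_lengths(pred, truth)
    per_type = {}
    for t in rare_type_ids:
        yt = (truth == t).astype(int)
        yp = (pred == t).astype(int)
        f1 = float(f1_score(yt, yp, zero_division=0))
        mcc = float(matthews_corrcoef(yt, yp)) if yp.any() or yt.any() else 0.0
        per_type[t] = {"f1": f1, "mcc": mcc}
    return {
        "f1": float(np.mean([v["f1"] for v in per_type.values()])),
        "mcc": float(np.mean([v["mcc"] for v in per_type.values()])),
        "per_type": per_type,
    }


def composition_rmse(
    pi_hat: np.ndarray,
    pi_true: np.ndarray,
    perm_c: np.ndarray | None = None,
    perm_z: np.ndarray | None = None,
) -> float:
    """Element-wise RMSE between composition matrices after label matching.

    ``perm_c`` / ``perm_z`` reorder the rows (cell types) and columns
    (domains) of ``pi_hat`` before comparison; identity when omitted.
    """
    pi_hat = np.asarray(pi_hat, dtype=float)
    pi_true = np.asarray(pi_true, dtype=float)
    if perm_c is not None:
        pi_hat = pi_hat[np.asarray(perm_c)]
    if perm_z is not None:
        pi_hat = pi_hat[:, np.asarray(perm_z)]
    if pi_hat.shape != pi_true.shape:
        raise ValueError("composition matrices must share a shape after matching")
    return float(np.sqrt(np.mean((pi_hat - pi_true) ** 2)))
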