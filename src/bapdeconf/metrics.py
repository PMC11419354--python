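"""Confounding-recovery scoring against simulated ground truth.

The estimated confounding structure (selected bow-free pairs, or a
binarized loading outer-product for the PCA competitor) is compared to the
true off-diagonal support of the simulated error covariance over all
unordered variable pairs, giving the usual confusion-matrix rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

import numpy as np


@dataclass
class RecoveryMetrics:
    """Confusion counts and rates over unordered off-diagonal pairs.

    ``fdp`` is FP/(TP+FP), the false-discovery proportion; ``fpr`` is
    FP/(FP+TN).  Both are reported because a discovery-free negative
    control (TP = 0) makes fdp degenerate while fpr stays meaningful.
    Undefined ratios are None, never 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]
    fpr: Optional[float]
    fdp: Optional[float]

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "precision": self.precision, "recall": self.recall,
            "f1": self.f1, "fpr": self.fpr, "fdp": self.fdp,
        }


def binarize_confounding(M: np.ndarray, threshold: float) -> np.ndarray:
    """Indicator of |M_jk| > threshold with a zero diagonal."""
    M = np.asarray(M, dtype=float)
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("M must be square symmetric")
    out = (np.abs(M) > threshold).astype(int)
    np.fill_diagonal(out, 0)
    return out


def pairs_to_adjacency(
    pairs: Iterable[Tuple[str, str]], names: Tuple[str, ...]
) -> np.ndarray:
    """Binary symmetric adjacency of a set of unordered node pairs."""
    idx = {v: i for i, v in enumerate(names)}
    A = np.zeros((len(names), len(names)), dtype=int)
    for a, b in pairs:
        A[idx[a], idx[b]] = A[idx[b], idx[a]] = 1
    return A


def confusion(true_adj: np.ndarray, est_adj: np.ndarray) -> RecoveryMetrics:
    """Score an estimated confounding adjacency against the truth."""
    T = np.asarray(true_adj)
    E = np.asarray(est_adj)
    if T.shape != E.shape:
        raise ValueError("dimension mismatch")
    p = T.shape[0]
    iu = np.triu_indices(p, k=1)
    t = T[iu].astype(bool)
    e = E[iu].astype(bool)
    tp = int(np.sum(t & e))
    fp = int(np.sum(~t & e))
    fn = int(np.sum(t & ~e))
    tn = int(np.sum(~t & ~e))

    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    if precision is None or recall is None:
        f1 = None
    elif precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    fpr = fp / (fp + tn) if (fp + tn) > 0 else None
    fdp = fp / (tp + fp) if (tp + fp) > 0 else None
    return RecoveryMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        precision=precision, recall=recall, f1=f1, fpr=fpr, fdp=fdp,
    )
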