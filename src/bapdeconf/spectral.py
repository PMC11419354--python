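"""Data-only deconfounding competitors: PCA proxies and the trim transform.

These methods assume *dense* (pervasive) confounding — a few latent factors
loading on many variables — and need no graph input.  PCA deconfounding
appends the scores of the leading principal components to the data as proxy
source variables; the number of components is chosen by a permutation test
on the singular values.  The trim transform instead caps the singular values
of the data at their median, flattening the dominant (confounded) directions
while keeping the singular vectors intact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .graph import DirectedAcyclicGraph
from .result import DeconfoundResult, augment_dag


@dataclass
class SVDFactors:
    """Thin SVD of the (standardized) data matrix: Y = P diag(d) Q'."""

    P: np.ndarray  # n x r left singular vectors
    Q: np.ndarray  # p x r right singular vectors
    d: np.ndarray  # singular values, descending


def svd_factors(Y: pd.DataFrame) -> SVDFactors:
    X = Y.to_numpy(dtype=float)
    P, d, Qt = np.linalg.svd(X, full_matrices=False)
    return SVDFactors(P=P, Q=Qt.T, d=d)


def select_q_permutation(
    Y: pd.DataFrame,
    n_perm: int = 100,
    alpha_perm: float = 0.05,
    seed: int = 0,
) -> int:
    """Parallel-analysis choice of the hidden-factor count.

    Each column of Y is permuted independently (destroying between-column
    correlation while keeping the margins); a singular value is deemed
    signal if it exceeds the (1 - alpha_perm) quantile of the matching
    singular value across permuted copies.  q is the length of the leading
    run of signal components.
    """
    if n_perm < 19:
        raise ValueError("need n_perm >= 19 for a meaningful quantile")
    X = Y.to_numpy(dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    d_obs = np.linalg.svd(X, compute_uv=False)
    null = np.empty((n_perm, d_obs.size))
    Xp = np.empty_like(X)
    for b in range(n_perm):
        for j in range(p):
            Xp[:, j] = X[rng.permutation(n), j]
        null[b] = np.linalg.svd(Xp, compute_uv=False)
    thresh = np.quantile(null, 1.0 - alpha_perm, axis=0)
    q = 0
    for i in range(d_obs.size):
        if d_obs[i] > thresh[i]:
            q += 1
        else:
            break
    return q


def pca_proxies(
    dag: Optional[DirectedAcyclicGraph],
    Y: pd.DataFrame,
    q: int,
) -> DeconfoundResult:
    """Augment data and DAG with the first q principal-component scores.

    Each proxy becomes a new source node wired to every observed node (the
    dense-confounding assumption).  The original data columns are untouched.
    """
    X = Y.to_numpy(dtype=float)
    n, p = X.shape
    if not 1 <= q < min(n, p):
        raise ValueError(f"q must satisfy 1 <= q < min(n, p) = {min(n, p)}")
    fac = svd_factors(Y)
    P = X @ fac.Q[:, :q]
    sd = P.std(axis=0, ddof=1)
    P = (P - P.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    scores = pd.DataFrame(P, index=Y.index, columns=[f"LV{i + 1}" for i in range(q)])
    if dag is None:
        dag = DirectedAcyclicGraph(list(Y.columns))
    lv_edges = {f"LV{i + 1}": dag.nodes for i in range(q)}
    new_dag = augment_dag(dag, lv_edges)
    out = pd.concat([scores, Y], axis=1)
    return DeconfoundResult(data=out, dag=new_dag, algorithm="pc", q=q)


def trim_transform(Y: pd.DataFrame) -> pd.DataFrame:
    """Spectral trim: cap the singular values of Y at their median.

    Z = P diag(min(d_i, median(d))) Q' with labels preserved; directions are
    unchanged, only the spectrum is flattened from the top.
    """
    fac = svd_factors(Y)
    tau = float(np.median(fac.d))
    d_cap = np.minimum(fac.d, tau)
    Z = fac.P @ (d_cap[:, None] * fac.Q.T)
    return pd.DataFrame(Z, index=Y.index, columns=Y.columns)
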