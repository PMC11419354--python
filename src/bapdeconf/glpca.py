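"""Stage 2b: graph-Laplacian PCA proxies for the selected covariance graph.

Instead of whitening, the selected bow-free covariance structure can be
summarised by a small number of latent-variable proxies.  The selected pairs
form an undirected graph C; weighting it by the sample covariance gives
A = S * C (elementwise), whose normalized Laplacian enters a combined matrix

    G_beta = (1 - beta) (I_p - Y'Y / e1) + beta (L / e2 + 11'/n)

trading off data variance (the PCA part) against smoothness on the
covariance graph.  The eigenvectors of the q smallest eigenvalues of G_beta
give a basis W; the projected scores P = Y W are appended to the data as
latent-variable proxy columns, and the DAG is extended with one source node
per covariance cluster, wired to that cluster's members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .graph import DirectedAcyclicGraph
from .result import DeconfoundResult, augment_dag

logger = logging.getLogger(__name__)


class EmptyCovarianceError(ValueError):
    """No covariance structure; gLPCA is not applicable."""


@dataclass
class LaplacianInput:
    """Weighted covariance-graph Laplacian.

    ``C`` is the binary symmetric adjacency of selected pairs, ``A = S * C``
    its covariance weighting, ``D`` the diagonal of row sums of A, and ``L``
    the normalized Laplacian D^{-1/2} (D - A) D^{-1/2} on the non-isolated,
    positive-degree nodes (zero rows elsewhere).
    """

    C: np.ndarray
    A: np.ndarray
    D: np.ndarray
    L: np.ndarray
    active: np.ndarray  # boolean mask of nodes entering the Laplacian block


@dataclass
class GLPCAResult:
    W: np.ndarray                  # p x q orthonormal basis
    P: pd.DataFrame                # n x q standardized scores, LV1..LVq
    q: int
    beta: float
    e1: float
    e2: float
    cluster_assignment: Dict[str, int] = field(default_factory=dict)


def build_laplacian(S: np.ndarray, C: np.ndarray) -> LaplacianInput:
    """Normalized Laplacian of the covariance-weighted selection graph."""
    S = np.asarray(S, dtype=float)
    C = np.asarray(C)
    p = S.shape[0]
    if C.shape != (p, p):
        raise ValueError("S and C must have the same shape")
    if not np.array_equal(C, C.T):
        raise ValueError("C must be symmetric")
    if np.any(np.diag(C) != 0):
        raise ValueError("C must have a zero diagonal")
    C = (C != 0).astype(float)
    A = S * C
    d = A.sum(axis=1)
    # nodes with no selected pair are isolated; non-positive degrees (possible
    # with negative covariances) are dropped from the Laplacian block
    isolated = C.sum(axis=1) == 0
    nonpos = (~isolated) & (d <= 0)
    if nonpos.any():
        logger.warning(
            "dropping %d node(s) with non-positive Laplacian degree", nonpos.sum()
        )
    active = (~isolated) & (d > 0)
    L = np.zeros((p, p))
    if active.any():
        ia = np.where(active)[0]
        Asub = A[np.ix_(ia, ia)]
        dsub = Asub.sum(axis=1)
        dsub = np.where(dsub > 0, dsub, 1.0)
        inv_sqrt = 1.0 / np.sqrt(dsub)
        Lsub = np.diag(np.ones(len(ia))) - (inv_sqrt[:, None] * Asub * inv_sqrt[None, :])
        L[np.ix_(ia, ia)] = 0.5 * (Lsub + Lsub.T)
    return LaplacianInput(C=C, A=A, D=np.diag(d), L=L, active=active)


def count_clusters(
    C: np.ndarray, names: Optional[Tuple[str, ...]] = None
) -> Tuple[int, Dict[str, int]]:
    """Leading-eigenvector community detection on the selection graph.

    Communities are found on the unweighted graph restricted to non-isolated
    nodes; ``q`` is the number of communities of size >= 2 and the
    assignment maps member nodes to cluster ids 0..q-1.
    """
    import random

    import igraph as ig

    # the leading-eigenvector solver uses a random ARPACK start; pin it so
    # identical inputs always give identical communities
    ig.set_random_number_generator(random.Random(0))

    C = (np.asarray(C) != 0).astype(int)
    p = C.shape[0]
    if names is None:
        names = tuple(str(i) for i in range(p))
    keep = np.where(C.sum(axis=1) > 0)[0]
    if keep.size == 0:
        raise EmptyCovarianceError("no covariance structure; gLPCA not applicable")
    sub = C[np.ix_(keep, keep)]
    edges = [(i, j) for i in range(len(keep)) for j in range(i + 1, len(keep)) if sub[i, j]]
    g = ig.Graph(n=len(keep), edges=edges)
    membership = g.community_leading_eigenvector().membership
    sizes: Dict[int, int] = {}
    for m in membership:
        sizes[m] = sizes.get(m, 0) + 1
    big = sorted(m for m, s in sizes.items() if s >= 2)
    relabel = {m: i for i, m in enumerate(big)}
    assignment = {
        names[keep[i]]: relabel[m]
        for i, m in enumerate(membership)
        if m in relabel
    }
    return len(big), assignment


def default_beta(q: int) -> float:
    """beta = 0.75, switching to the full-Laplacian weight beta = 1 when the
    cluster count exceeds 3 (guards against overfitting many components)."""
    return 1.0 if q > 3 else 0.75


def _fix_signs(W: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Deterministic eigenvector signs: first non-negligible loading positive."""
    W = W.copy()
    for c in range(W.shape[1]):
        col = W[:, c]
        nz = np.where(np.abs(col) > tol)[0]
        if nz.size and col[nz[0]] < 0:
            W[:, c] = -col
    return W


def glpca_scores(
    Y: pd.DataFrame,
    laplacian: LaplacianInput,
    q: int,
    beta: float,
    cluster_assignment: Optional[Dict[str, int]] = None,
) -> GLPCAResult:
    """Scores on the q smallest eigenvectors of the combined matrix G_beta.

    ``e1`` is the largest eigenvalue of Y'Y and ``e2`` the largest
    eigenvalue of L, normalising the two parts to comparable scale.
    """
    X = Y.to_numpy(dtype=float)
    n, p = X.shape
    if not 1 <= q < p:
        raise ValueError(f"q must satisfy 1 <= q < p, got q={q}, p={p}")
    if not 0 < beta <= 1:
        raise ValueError(f"beta must be in (0, 1], got {beta}")
    G_data = X.T @ X
    e1 = float(np.linalg.eigvalsh(G_data)[-1])
    e2 = float(np.linalg.eigvalsh(laplacian.L)[-1])
    e1 = e1 if e1 > 0 else 1.0
    e2 = e2 if e2 > 0 else 1.0
    G = (1.0 - beta) * (np.eye(p) - G_data / e1) + beta * (
        laplacian.L / e2 + np.ones((p, p)) / n
    )
    G = 0.5 * (G + G.T)
    vals, vecs = np.linalg.eigh(G)
    W = _fix_signs(vecs[:, :q])
    P = X @ W
    sd = P.std(axis=0, ddof=1)
    P = (P - P.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    scores = pd.DataFrame(
        P, index=Y.index, columns=[f"LV{i + 1}" for i in range(q)]
    )
    return GLPCAResult(
        W=W,
        P=scores,
        q=q,
        beta=beta,
        e1=e1,
        e2=e2,
        cluster_assignment=dict(cluster_assignment or {}),
    )


def augment(
    dag: DirectedAcyclicGraph,
    data: pd.DataFrame,
    glpca: GLPCAResult,
) -> DeconfoundResult:
    """Prepend LV score columns and wire one source node per cluster.

    The proxy node for cluster ``c`` points to every observed node assigned
    to that cluster; original edges are untouched, so the result is acyclic.
    """
    lv_edges: Dict[str, Tuple[str, ...]] = {}
    for i in range(glpca.q):
        members = tuple(
            v for v, c in glpca.cluster_assignment.items() if c == i
        )
        if not members:  # no cluster info: wire to all observed nodes
            members = dag.nodes
        lv_edges[f"LV{i + 1}"] = members
    new_dag = augment_dag(dag, lv_edges)
    out = pd.concat([glpca.P, data], axis=1)
    return DeconfoundResult(
        data=out,
        dag=new_dag,
        algorithm="glpc",
        q=glpca.q,
        cluster_assignment=dict(glpca.cluster_assignment),
        info={"beta": glpca.beta, "e1": glpca.e1, "e2": glpca.e2},
    )
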