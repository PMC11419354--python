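"""Two-stage deconfounding pipeline tying search and adjustment together.

``deconfound`` dispatches on the algorithm name:

* ``cggm`` - d-separation (or glasso) search, constrained precision fit,
  Mahalanobis whitening of the standardized data;
* ``glpc`` - the same search, then graph-Laplacian PCA proxies appended to
  the data and wired into the DAG cluster-wise;
* ``pc``   - PCA proxies with a permutation-selected component count
  (no graph needed for the search stage);
* ``trim`` - the spectral trim transform (data only).

All algorithms standardize the data (mean 0, variance 1 per column) first
and return the common :class:`~bapdeconf.result.DeconfoundResult` bundle.
"""

from __future__ import annotations

import logging
from typing import Optional, Union

import numpy as np
import pandas as pd

from .cggm import fit_cggm, whiten
from .glpca import (
    build_laplacian,
    count_clusters,
    default_beta,
    glpca_scores,
    augment,
)
from .graph import DirectedAcyclicGraph, align_columns
from .metrics import binarize_confounding, pairs_to_adjacency
from .result import DeconfoundResult
from .search import (
    SearchConfig,
    _covariance_for_search,
    dsep_search,
    glasso_search,
)
from .spectral import pca_proxies, select_q_permutation, trim_transform

logger = logging.getLogger(__name__)

ALGORITHMS = ("cggm", "glpc", "pc", "trim")


def standardize(data: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scoring (ddof = 1)."""
    sd = data.std(ddof=1)
    bad = sd.index[sd <= 0].tolist()
    if bad:
        raise ValueError(f"constant column(s): {bad}")
    return (data - data.mean()) / sd


def deconfound(
    graph: Optional[DirectedAcyclicGraph],
    data: pd.DataFrame,
    dalgo: str = "cggm",
    method: str = "BH",
    alpha: float = 0.05,
    hcount: Union[str, int] = "auto",
    cmax: Union[None, int, str] = None,
    limit: int = 200,
    seed: int = 0,
) -> DeconfoundResult:
    """Run one deconfounding algorithm end to end.

    Parameters mirror the search configuration: ``alpha``/``method``/``cmax``
    govern the d-separation stage, ``limit`` switches to the glasso search
    for graphs with more than ``limit`` nodes, ``hcount`` is the latent
    count for ``pc`` ("auto" = permutation selection), and ``seed`` drives
    the permutation null.
    """
    if dalgo == "pcss":
        raise ValueError(
            "dalgo='pcss' is not implemented; 'trim' is the available "
            "spectral-transform competitor"
        )
    if dalgo not in ALGORITHMS:
        raise ValueError(f"unknown dalgo {dalgo!r}; choose from {ALGORITHMS}")

    if dalgo in ("cggm", "glpc"):
        if graph is None:
            raise ValueError(f"dalgo={dalgo!r} requires a graph input")
        cols = align_columns(graph, data.columns)
        z = standardize(data[cols])
        config = SearchConfig(alpha=alpha, method=method, cmax=cmax, limit=limit)
        if graph.n_nodes <= limit:
            table, selected = dsep_search(graph, z, config)
        else:
            logger.info(
                "p = %d > limit = %d: switching to glasso search",
                graph.n_nodes, limit,
            )
            selected, _ = glasso_search(graph, z)
            table = None
        if not selected:
            logger.info("no covariances selected; returning standardized data")
            return DeconfoundResult(
                data=z, dag=graph, guu=frozenset(), dsep=table, algorithm=dalgo
            )
        if dalgo == "cggm":
            S = _covariance_for_search(z.to_numpy(dtype=float), None)
            est = fit_cggm(S, selected, names=cols)
            wd = whiten(z, est)
            cidx = {v: i for i, v in enumerate(cols)}
            omega_pairs = {
                (a, b): float(est.omega[cidx[a], cidx[b]]) for a, b in selected
            }
            return DeconfoundResult(
                data=wd.z, dag=graph, guu=selected, dsep=table,
                algorithm="cggm",
                info={
                    "iterations": est.iterations,
                    "loglik": est.loglik,
                    "omega_pairs": omega_pairs,
                },
            )
        # glpc
        S = _covariance_for_search(z.to_numpy(dtype=float), None)
        C = pairs_to_adjacency(selected, tuple(cols))
        q, assignment = count_clusters(C, tuple(cols))
        if q == 0:
            logger.info("no cluster of size >= 2; returning standardized data")
            return DeconfoundResult(
                data=z, dag=graph, guu=selected, dsep=table, algorithm="glpc"
            )
        lap = build_laplacian(S, C)
        res = glpca_scores(z, lap, q, default_beta(q), assignment)
        out = augment(graph, z, res)
        out.guu = selected
        out.dsep = table
        return out

    # SVD-only methods
    if graph is not None:
        cols = align_columns(graph, data.columns)
        data = data[cols]
    z = standardize(data)
    if dalgo == "trim":
        adj = trim_transform(z)
        dag = graph if graph is not None else DirectedAcyclicGraph(list(z.columns))
        return DeconfoundResult(data=adj, dag=dag, algorithm="trim")
    # pc
    if hcount == "auto":
        q = select_q_permutation(z, seed=seed)
    else:
        q = int(hcount)
    if q == 0:
        logger.info("hidden count 0; returning standardized data")
        dag = graph if graph is not None else DirectedAcyclicGraph(list(z.columns))
        return DeconfoundResult(data=z, dag=dag, algorithm="pc", q=0)
    return pca_proxies(graph, z, q)


def estimated_confounding(
    result: DeconfoundResult,
    observed_dag: DirectedAcyclicGraph,
    threshold: float = 0.05,
) -> Optional[np.ndarray]:
    """Estimated confounding adjacency over the observed variables.

    For the BAP-search algorithms this is the selected-pair adjacency
    itself.  For ``pc`` it is the binarized outer product Gamma Gamma' of
    the per-node regression coefficients on the proxy scores (the implied
    common-factor covariance); with no proxies it is the zero matrix.
    ``trim`` exposes no confounding estimate (returns None).
    """
    names = tuple(observed_dag.nodes)
    if result.algorithm in ("cggm", "glpc"):
        return pairs_to_adjacency(result.guu or frozenset(), names)
    if result.algorithm == "pc":
        p = len(names)
        if result.q == 0:
            return np.zeros((p, p), dtype=int)
        from .semfit import fit_dag_ols

        fit = fit_dag_ols(result.dag, result.data)
        lvs = [f"LV{i + 1}" for i in range(result.q)]
        gamma = np.zeros((p, result.q))
        for (src, tgt), b in fit.b_hat.items():
            if src in lvs and tgt in names:
                gamma[names.index(tgt), lvs.index(src)] = b
        return binarize_confounding(gamma @ gamma.T, threshold)
    return None
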