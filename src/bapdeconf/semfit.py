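"""Nodewise least-squares SEM fitting, goodness of fit and group perturbation.

A DAG over observed (and possibly latent-proxy) variables is fit one
equation at a time: each endogenous node is regressed on its graph parents.
With Gaussian errors this equation-by-equation OLS is the maximum-likelihood
estimate of the path coefficients.  The implied covariance

    Sigma_hat = (I - B_hat)^-1 D_psi (I - B_hat)^-T

(with residual variances and source-node variances on the diagonal D_psi)
is compared to the sample covariance through the standardized root mean
square residual (SRMR) and the deviance/df ratio.  A binary group variable
can enter every node equation as an extra covariate; one-sided p-values of
its coefficient are combined as P = 2 min(P+, P-) to flag differentially
regulated nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .graph import DirectedAcyclicGraph


@dataclass
class FitResult:
    b_hat: Dict[Tuple[str, str], float]      # (source, target) -> coefficient
    resid_var: Dict[str, float]
    sigma_implied: pd.DataFrame
    srmr: float
    deviance: float
    df: int
    dev_df: Optional[float]
    loglik: float
    n: int


@dataclass
class PerturbationResult:
    table: pd.DataFrame   # node, beta_group, p_plus, p_minus, p_node, p_adj, significant
    nlog10p: float
    vcountp: int


def srmr(S_sample: np.ndarray, sigma_implied: np.ndarray) -> float:
    """Root mean square of standardized covariance residuals.

    Mean over the p(p+1)/2 unique entries (diagonal included) of
    ((s_jk - sigma_jk) / sqrt(s_jj s_kk))^2, then square root.
    """
    S = np.asarray(S_sample, dtype=float)
    Sig = np.asarray(sigma_implied, dtype=float)
    if S.shape != Sig.shape:
        raise ValueError("dimension mismatch between sample and implied covariance")
    p = S.shape[0]
    d = np.sqrt(np.diag(S))
    resid = (S - Sig) / np.outer(d, d)
    iu = np.triu_indices(p)
    return float(np.sqrt(np.mean(resid[iu] ** 2)))


def deviance_df(
    S_sample: np.ndarray,
    sigma_implied: np.ndarray,
    n: int,
    df: int,
) -> Tuple[float, Optional[float]]:
    """Likelihood-ratio deviance against the saturated model, and its ratio
    to the model degrees of freedom (missing-edge count).

    deviance = (n - 1) * [tr(S Sigma^-1) - ln det(S Sigma^-1) - p]; the
    ratio is reported as None when df = 0 (saturated model).
    """
    S = np.asarray(S_sample, dtype=float)
    Sig = np.asarray(sigma_implied, dtype=float)
    if S.shape != Sig.shape:
        raise ValueError("dimension mismatch")
    p = S.shape[0]
    M = np.linalg.solve(Sig, S)
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0 or not math.isfinite(logdet):
        # singular sample covariance (e.g. exact linear proxy columns):
        # the likelihood-ratio deviance is undefined
        return math.nan, None
    dev = (n - 1) * (np.trace(M) - logdet - p)
    dev = float(max(dev, 0.0))
    return dev, (dev / df if df > 0 else None)


def fit_dag_ols(dag: DirectedAcyclicGraph, data: pd.DataFrame) -> FitResult:
    """Equation-by-equation OLS fit of the DAG to the data.

    All regressions are computed from the sample covariance (equivalent to
    OLS with intercept on raw data), so the fit is exact in the usual
    regression identities: a single edge a -> b on standardized data yields
    b_hat = corr(a, b).
    """
    cols = list(dag.nodes)
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"data matrix lacks columns: {missing}")
    X = data[cols].to_numpy(dtype=float)
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    S = (Xc.T @ Xc) / (n - 1)
    idx = {v: i for i, v in enumerate(cols)}

    B = np.zeros((p, p))
    d_psi = np.zeros(p)
    b_hat: Dict[Tuple[str, str], float] = {}
    resid_var: Dict[str, float] = {}
    for v in cols:
        j = idx[v]
        pa = sorted(dag.parents(v), key=idx.get)
        if not pa:
            d_psi[j] = S[j, j]
            resid_var[v] = S[j, j]
            continue
        pi = [idx[u] for u in pa]
        Spp = S[np.ix_(pi, pi)]
        spj = S[pi, j]
        try:
            beta = np.linalg.solve(Spp, spj)
        except np.linalg.LinAlgError:
            raise ValueError(
                f"rank-deficient parent block for node {v!r}"
            ) from None
        rv = float(S[j, j] - spj @ beta)
        if rv <= 0:
            raise ValueError(f"non-positive residual variance for node {v!r}")
        for u, b in zip(pa, beta):
            B[j, idx[u]] = b
            b_hat[(u, v)] = float(b)
        d_psi[j] = rv
        resid_var[v] = rv

    IB_inv = np.linalg.inv(np.eye(p) - B)
    Sigma = IB_inv @ np.diag(d_psi) @ IB_inv.T
    Sigma = 0.5 * (Sigma + Sigma.T)
    model_df = len(dag.missing_edges())
    dev, dev_ratio = deviance_df(S, Sigma, n, model_df)
    sign, logdet = np.linalg.slogdet(Sigma)
    ll = -0.5 * (n - 1) * (logdet + np.trace(np.linalg.solve(Sigma, S)))
    return FitResult(
        b_hat=b_hat,
        resid_var=resid_var,
        sigma_implied=pd.DataFrame(Sigma, index=cols, columns=cols),
        srmr=srmr(S, Sigma),
        deviance=dev,
        df=model_df,
        dev_df=dev_ratio,
        loglik=float(ll),
        n=n,
    )


def group_perturbation(
    dag: DirectedAcyclicGraph,
    data: pd.DataFrame,
    group: np.ndarray,
    alpha: float = 0.05,
    method: str = "BH",
    nodes: Optional[Sequence[str]] = None,
) -> PerturbationResult:
    """Per-node group effect over a common model.

    The binary group indicator enters each node's regression alongside the
    node's parents.  ``P+`` and ``P-`` are the one-sided p-values of the
    group coefficient (activation / inhibition); they are combined as
    ``P = min(1, 2 min(P+, P-))``.  ``vcountp`` counts nodes significant
    after multiplicity correction; ``nlog10p`` is the mean of -log10(P)
    over nodes, a global perturbation level.
    """
    g = np.asarray(group, dtype=float).ravel()
    classes = np.unique(g)
    if classes.size != 2:
        raise ValueError(f"group must contain exactly two classes, got {classes}")
    if nodes is None:
        nodes = list(dag.nodes)
    if len(g) != len(data):
        raise ValueError("group length does not match number of samples")

    rows = []
    for v in nodes:
        pa = sorted(dag.parents(v))
        Xd = np.column_stack(
            [np.ones(len(g))]
            + [data[u].to_numpy(dtype=float) for u in pa]
            + [g]
        )
        y = data[v].to_numpy(dtype=float)
        beta, _, rank, _ = np.linalg.lstsq(Xd, y, rcond=None)
        dfree = len(y) - Xd.shape[1]
        if dfree <= 0 or rank < Xd.shape[1]:
            raise ValueError(f"degenerate design for node {v!r}")
        resid = y - Xd @ beta
        s2 = float(resid @ resid) / dfree
        XtX_inv = np.linalg.inv(Xd.T @ Xd)
        se = math.sqrt(s2 * XtX_inv[-1, -1])
        t = beta[-1] / se if se > 0 else math.inf
        p_plus = float(stats.t.sf(t, dfree))
        p_minus = float(stats.t.cdf(t, dfree))
        p_node = min(1.0, 2.0 * min(p_plus, p_minus))
        rows.append(
            {
                "node": v,
                "beta_group": float(beta[-1]),
                "p_plus": p_plus,
                "p_minus": p_minus,
                "p_node": p_node,
            }
        )
    tab = pd.DataFrame(rows)
    from .search import _adjust_pvalues

    tab["p_adj"] = _adjust_pvalues(tab["p_node"].to_numpy(), method)
    tab["significant"] = tab["p_adj"] < alpha
    nlog10p = float(np.mean(-np.log10(np.clip(tab["p_node"], 1e-300, None))))
    return PerturbationResult(
        table=tab, nlog10p=nlog10p, vcountp=int(tab["significant"].sum())
    )
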