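"""Stage 1: bow-free covariance search over the missing edges of a DAG.

Every missing edge of a causal DAG implies a conditional-independence claim.
Shipley's basis set collects one claim per missing edge — the later node (in
causal order) is tested against the earlier one given the union of both
parent sets — and those claims are mutually independent, so each can be
tested with a Fisher z test of the partial correlation and corrected for
multiplicity as a flat family.  Pairs whose claim is rejected receive a
bidirected (bow-free) edge: an unobserved confounder is acting on the pair.

For graphs too large for testing one pair at a time, the same screening is
done with a zero-constrained graphical lasso: an L1-penalised precision
matrix estimate in which the DAG-edge positions are hard zeros, so every
surviving off-diagonal element is a bow-free covariance by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .graph import DirectedAcyclicGraph, validate_bap


class DegenerateDataError(ValueError):
    """Raised when data are numerically unusable (constant column, exact
    collinearity) for a correlation-based test."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SearchConfig:
    """Settings of the bow-free covariance search.

    alpha
        Significance level applied to adjusted p-values (default 0.05).
    method
        Multiple-testing correction: ``"BH"`` (Benjamini-Hochberg, default),
        ``"bonferroni"``, or ``"none"``.
    cmax
        Maximum conditioning-set size.  ``None`` = unlimited, ``"auto"`` =
        the sparsity index floor(sqrt(n)/ln(p)).  Basis-set claims with more
        conditioning variables are skipped (excluded from correction and
        from Fisher's C).
    limit
        Node count above which callers should switch from per-pair testing
        to the glasso search (default 200).
    shrink
        Force (True) or forbid (False) the shrinkage covariance estimator;
        ``None`` = automatic (shrink when n <= p + 1 or the sample
        covariance is not positive definite).
    """

    alpha: float = 0.05
    method: str = "BH"
    cmax: Union[None, int, str] = None
    limit: int = 200
    shrink: Optional[bool] = None

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.method not in ("BH", "bonferroni", "none"):
            raise ValueError(f"unknown correction method {self.method!r}")
        if isinstance(self.cmax, str) and self.cmax != "auto":
            raise ValueError("cmax must be None, an integer >= 0, or 'auto'")
        if isinstance(self.cmax, int) and self.cmax < 0:
            raise ValueError("cmax must be >= 0")
        if self.limit < 1:
            raise ValueError("limit must be >= 1")

    def resolve_cmax(self, n: int, p: int) -> float:
        if self.cmax is None:
            return math.inf
        if self.cmax == "auto":
            return sparsity_index(n, p)
        return self.cmax


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

@dataclass
class DSepRecord:
    """One tested (or skipped) missing edge."""

    pair: Tuple[str, str]          # (j, k); j is later in causal order
    cond_set: FrozenSet[str]
    cond_size: int
    r: float = math.nan
    z: float = math.nan
    p: float = math.nan
    p_adj: float = math.nan
    selected: bool = False
    skipped: bool = False
    skip_reason: str = ""


@dataclass
class DSepTable:
    """All d-separation test records plus the global Fisher's C statistic.

    Fisher's C = -2 * sum(ln p) over the performed tests follows a
    chi-square distribution with 2k degrees of freedom when the DAG (with
    diagonal error covariance) is correct, because the basis-set tests are
    mutually independent.
    """

    records: List[DSepRecord] = field(default_factory=list)
    fisher_c: float = 0.0
    fisher_df: int = 0
    fisher_p: float = 1.0

    @property
    def n_selected(self) -> int:
        return sum(r.selected for r in self.records)

    @property
    def n_performed(self) -> int:
        return sum(not r.skipped for r in self.records)

    def selected_pairs(self) -> FrozenSet[Tuple[str, str]]:
        return frozenset(
            tuple(sorted(r.pair)) for r in self.records if r.selected
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "lhs": r.pair[0],
                "rhs": r.pair[1],
                "cond_set": ",".join(sorted(r.cond_set)),
                "n_cond": r.cond_size,
                "r": r.r,
                "z": r.z,
                "p": r.p,
                "p_adj": r.p_adj,
                "selected": r.selected,
                "skipped": r.skipped,
            }
            for r in self.records
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "lhs", "rhs", "cond_set", "n_cond", "r", "z", "p",
                "p_adj", "selected", "skipped",
            ],
        )

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def summary(self) -> Dict[str, float]:
        return {
            "fisher_c": self.fisher_c,
            "fisher_df": self.fisher_df,
            "fisher_p": self.fisher_p,
            "n_tests": self.n_performed,
            "n_skipped": len(self.records) - self.n_performed,
            "n_selected": self.n_selected,
        }


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def sparsity_index(n: int, p: int) -> int:
    """floor(sqrt(n) / ln(p)): the conditioning-set size up to which
    high-dimensional partial-correlation tests stay reliable."""
    if n < 1 or p < 2:
        raise ValueError("need n >= 1 and p >= 2")
    return int(math.floor(math.sqrt(n) / math.log(p)))


def shipley_basis_set(
    dag: DirectedAcyclicGraph,
) -> List[Tuple[str, str, FrozenSet[str]]]:
    """One independence claim per missing edge.

    Returns triples ``(j, k, cond)`` with ``j`` later than ``k`` in the
    causal (topological) order and ``cond = pa(j) | pa(k)`` minus the pair
    itself.  The number of triples equals the number of missing edges, i.e.
    the model degrees of freedom.
    """
    rank = {v: i for i, v in enumerate(dag.topological_order())}
    out: List[Tuple[str, str, FrozenSet[str]]] = []
    for u, v in dag.missing_edges():
        j, k = (u, v) if rank[u] > rank[v] else (v, u)
        cond = (dag.parents(j) | dag.parents(k)) - {j, k}
        out.append((j, k, cond))
    return out


def shrink_covariance(data: Union[pd.DataFrame, np.ndarray]) -> np.ndarray:
    """James-Stein-type shrinkage covariance (Schafer-Strimmer style).

    Off-diagonal correlations are shrunk toward zero with the analytic
    intensity  lambda* = sum(var_hat(r_jk)) / sum(r_jk^2)  (clipped to
    [0, 1]); variances are kept at their sample values.  The result is
    symmetric positive definite whenever lambda* > 0.
    """
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    sd = X.std(axis=0, ddof=1)
    const = np.where(sd <= 0)[0]
    if const.size:
        names = (
            [data.columns[i] for i in const]
            if isinstance(data, pd.DataFrame)
            else list(const)
        )
        raise DegenerateDataError(f"constant column(s): {names}")
    Xs = (X - X.mean(axis=0)) / sd
    R = (Xs.T @ Xs) / (n - 1)
    np.fill_diagonal(R, 1.0)

    # var_hat(r_jk) = n / (n-1)^3 * sum_i (w_ijk - mean_w)^2, w_ijk = x_ij x_ik
    W_mean = R * (n - 1) / n
    sum_w2 = np.einsum("ij,ik->jk", Xs**2, Xs**2)
    var_r = n / (n - 1.0) ** 3 * (sum_w2 - n * W_mean**2)
    off = ~np.eye(p, dtype=bool)
    denom = float((R[off] ** 2).sum())
    lam = 1.0 if denom == 0 else float(np.clip(var_r[off].sum() / denom, 0.0, 1.0))
    R_shrunk = (1.0 - lam) * R
    np.fill_diagonal(R_shrunk, 1.0)
    return R_shrunk * np.outer(sd, sd)


def partial_correlation(
    data: pd.DataFrame,
    j: str,
    k: str,
    cond_set: Sequence[str] = (),
    method: str = "residual",
) -> float:
    """Sample partial correlation of columns ``j`` and ``k`` given ``cond_set``.

    ``method="residual"`` correlates the least-squares residuals of each
    variable on the conditioning block; ``method="precision"`` inverts the
    covariance submatrix.  The two agree to numerical precision.
    """
    cols = [j, k, *cond_set]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"columns not in data: {missing}")
    X = data[cols].to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    if method == "precision":
        cov = (X.T @ X) / (len(X) - 1)
        return _pcor_from_cov(cov, 0, 1, list(range(2, len(cols))), pair=(j, k))
    if method != "residual":
        raise ValueError(f"unknown method {method!r}")
    y1, y2, Z = X[:, 0], X[:, 1], X[:, 2:]
    if Z.shape[1]:
        beta1, *_ = np.linalg.lstsq(Z, y1, rcond=None)
        beta2, *_ = np.linalg.lstsq(Z, y2, rcond=None)
        r1, r2 = y1 - Z @ beta1, y2 - Z @ beta2
    else:
        r1, r2 = y1, y2
    n1, n2 = np.linalg.norm(r1), np.linalg.norm(r2)
    if n1 <= 1e-12 * np.linalg.norm(y1) or n1 == 0 or n2 <= 1e-12 * np.linalg.norm(y2) or n2 == 0:
        raise DegenerateDataError(
            f"zero residual variance for pair ({j}, {k}) given {sorted(cond_set)}"
        )
    return float(np.clip(r1 @ r2 / (n1 * n2), -1.0, 1.0))


def _pcor_from_cov(
    cov: np.ndarray,
    i: int,
    j: int,
    cond: Sequence[int],
    pair: Tuple[str, str] = ("?", "?"),
) -> float:
    """Partial correlation from a covariance matrix by submatrix inversion."""
    idx = [i, j, *cond]
    sub = cov[np.ix_(idx, idx)]
    try:
        omega = np.linalg.inv(sub)
    except np.linalg.LinAlgError:
        raise DegenerateDataError(
            f"singular conditioning block for pair {pair}"
        ) from None
    d = omega[0, 0] * omega[1, 1]
    if d <= 0:
        raise DegenerateDataError(f"singular conditioning block for pair {pair}")
    return float(np.clip(-omega[0, 1] / math.sqrt(d), -1.0, 1.0))


def fisher_z_test(r: float, n: int, cond_size: int) -> Tuple[float, float]:
    """Fisher z test of a partial correlation against zero.

    z = atanh(r) * sqrt(n - cond_size - 3); the p-value is the two-sided
    standard-normal tail probability.
    """
    df = n - cond_size - 3
    if df <= 0:
        raise ValueError(
            f"insufficient sample size: n - cond_size - 3 = {df} <= 0"
        )
    if abs(r) >= 1.0:
        warnings.warn("|r| = 1: degenerate partial correlation, p set to 0")
        return math.copysign(math.inf, r), 0.0
    z = math.atanh(r) * math.sqrt(df)
    p = 2.0 * stats.norm.sf(abs(z))
    return z, float(p)


def _adjust_pvalues(pvals: np.ndarray, method: str) -> np.ndarray:
    if method == "none" or len(pvals) == 0:
        return pvals.copy()
    from statsmodels.stats.multitest import multipletests

    key = {"BH": "fdr_bh", "bonferroni": "bonferroni"}[method]
    return multipletests(pvals, method=key)[1]


# ---------------------------------------------------------------------------
# searches
# ---------------------------------------------------------------------------

def _covariance_for_search(
    X: np.ndarray, shrink: Optional[bool]
) -> np.ndarray:
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    S = (Xc.T @ Xc) / (n - 1)
    if shrink is False:
        return S
    if shrink is None:
        needs = n <= p + 1
        if not needs:
            try:
                np.linalg.cholesky(S + 1e-12 * np.eye(p))
            except np.linalg.LinAlgError:
                needs = True
        if not needs:
            return S
    return shrink_covariance(X)


def dsep_search(
    dag: DirectedAcyclicGraph,
    data: pd.DataFrame,
    config: Optional[SearchConfig] = None,
) -> Tuple[DSepTable, FrozenSet[Tuple[str, str]]]:
    """Test every basis-set claim and select significant bow-free pairs.

    Claims whose conditioning set exceeds ``cmax`` (or whose conditioning
    set is too large for the sample size) are marked skipped and excluded
    from the correction and from Fisher's C.  Selected pairs are missing
    edges of the DAG, hence bow-free by construction.
    """
    config = config or SearchConfig()
    cols = [v for v in dag.nodes]
    missing_cols = [v for v in cols if v not in data.columns]
    if missing_cols:
        raise KeyError(f"data matrix lacks columns: {missing_cols}")
    X = data[cols].to_numpy(dtype=float)
    n, p = X.shape
    sd = X.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        bad = [cols[i] for i in np.where(sd <= 0)[0]]
        raise DegenerateDataError(f"constant column(s): {bad}")
    cov = _covariance_for_search(X, config.shrink)

    idx = {v: i for i, v in enumerate(cols)}
    cmax = config.resolve_cmax(n, p)
    records: List[DSepRecord] = []
    for j, k, cond in shipley_basis_set(dag):
        rec = DSepRecord(pair=(j, k), cond_set=cond, cond_size=len(cond))
        if len(cond) > cmax:
            rec.skipped, rec.skip_reason = True, "cond_size > cmax"
        elif n - len(cond) - 3 <= 0:
            rec.skipped, rec.skip_reason = True, "n too small for cond set"
        else:
            try:
                r = _pcor_from_cov(
                    cov, idx[j], idx[k], [idx[c] for c in cond], pair=(j, k)
                )
                rec.r = r
                rec.z, rec.p = fisher_z_test(r, n, len(cond))
            except DegenerateDataError as exc:
                rec.skipped, rec.skip_reason = True, str(exc)
        records.append(rec)

    performed = [r for r in records if not r.skipped]
    pvals = np.array([r.p for r in performed])
    padj = _adjust_pvalues(pvals, config.method)
    for rec, pa in zip(performed, padj):
        rec.p_adj = float(pa)
        rec.selected = bool(pa < config.alpha)

    if len(performed):
        logs = np.log(np.clip(pvals, 1e-300, None))
        C = float(-2.0 * logs.sum())
        df = 2 * len(performed)
        fisher_p = float(stats.chi2.sf(C, df))
    else:
        C, df, fisher_p = 0.0, 0, 1.0
    table = DSepTable(records=records, fisher_c=C, fisher_df=df, fisher_p=fisher_p)
    selected = table.selected_pairs()
    validate_bap(dag, selected)  # bow-free by construction; assert anyway
    return table, selected


def default_glasso_rho(n: int, p: int) -> float:
    """Default glasso penalty: sqrt(ln(p) / n)."""
    return math.sqrt(math.log(p) / n)


def glasso_search(
    dag: DirectedAcyclicGraph,
    data: pd.DataFrame,
    rho: Optional[float] = None,
    shrink: Optional[bool] = None,
    tol: float = 1e-4,
    max_iter: int = 1000,
) -> Tuple[FrozenSet[Tuple[str, str]], np.ndarray]:
    """Zero-constrained graphical lasso screening of bow-free covariances.

    The precision matrix is estimated with an L1 penalty ``rho`` on the
    missing-edge positions and a hard zero (infinite penalty) at every
    DAG-edge position.  Returns the selected missing pairs (nonzero
    precision entries) and the estimated precision matrix.
    """
    cols = list(dag.nodes)
    X = data[cols].to_numpy(dtype=float)
    n, p = X.shape
    if rho is None:
        rho = default_glasso_rho(n, p)
    if rho <= 0:
        raise ValueError("rho must be > 0")
    sd = X.std(axis=0, ddof=1)
    Xs = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    if np.any(sd <= 0):
        bad = [cols[i] for i in np.where(sd <= 0)[0]]
        raise DegenerateDataError(f"constant column(s): {bad}")
    S = _covariance_for_search(Xs, shrink)

    idx = {v: i for i, v in enumerate(cols)}
    P = np.full((p, p), rho)
    np.fill_diagonal(P, rho)
    for u, v, _ in dag.edges:
        P[idx[u], idx[v]] = P[idx[v], idx[u]] = math.inf
    omega = _glasso(S, P, tol=tol, max_iter=max_iter)

    selected = set()
    pairs = set()
    for u, v in dag.missing_edges():
        pairs.add((u, v))
        if omega[idx[u], idx[v]] != 0.0:
            selected.add(tuple(sorted((u, v))))
    # hard constraint: DAG-edge positions are exactly zero
    for u, v, _ in dag.edges:
        assert omega[idx[u], idx[v]] == 0.0
    return frozenset(selected), omega


def _lasso_cd(
    V: np.ndarray,
    s: np.ndarray,
    pen: np.ndarray,
    beta: np.ndarray,
    tol: float = 1e-7,
    max_iter: int = 500,
) -> np.ndarray:
    """Coordinate descent for 0.5 b'Vb - s'b + sum(pen |b|).

    Infinite penalties pin coefficients at exactly zero.
    """
    beta = beta.copy()
    active = np.isfinite(pen)
    beta[~active] = 0.0
    grad = V @ beta  # maintained as V @ beta
    order = np.where(active)[0]
    for _ in range(max_iter):
        delta = 0.0
        for i in order:
            old = beta[i]
            x = s[i] - (grad[i] - V[i, i] * old)
            new = math.copysign(max(abs(x) - pen[i], 0.0), x) / V[i, i]
            if new != old:
                grad += V[:, i] * (new - old)
                beta[i] = new
                delta = max(delta, abs(new - old))
        if delta < tol:
            break
    return beta


def _glasso(
    S: np.ndarray,
    P: np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 1000,
) -> np.ndarray:
    """Graphical lasso with an element-wise penalty matrix ``P``.

    Block coordinate descent on the covariance estimate W (Friedman-style):
    column j is updated by a lasso regression against W11.  Entries with
    ``P = inf`` are hard zeros of the precision matrix.
    """
    p = S.shape[0]
    W = S.copy()
    W[np.diag_indices(p)] += np.diag(P)
    B = np.zeros((p, p))
    converged = False
    for _ in range(max_iter):
        W_old = W.copy()
        for j in range(p):
            idx = np.r_[0:j, j + 1 : p]
            V = W[np.ix_(idx, idx)]
            beta = _lasso_cd(V, S[idx, j], P[idx, j], B[idx, j])
            B[idx, j] = beta
            w12 = V @ beta
            W[idx, j] = w12
            W[j, idx] = w12
        if np.max(np.abs(W - W_old)) < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"glasso did not converge in {max_iter} sweeps "
            f"(last max |dW| = {np.max(np.abs(W - W_old)):.3e})"
        )
    omega = np.zeros((p, p))
    for j in range(p):
        idx = np.r_[0:j, j + 1 : p]
        beta = B[idx, j]
        denom = W[j, j] - W[idx, j] @ beta
        om_jj = 1.0 / denom
        omega[j, j] = om_jj
        omega[idx, j] = -beta * om_jj
    # symmetrize without destroying exact zeros
    zero = (omega == 0.0) | (omega.T == 0.0)
    omega = 0.5 * (omega + omega.T)
    omega[zero & ~np.eye(p, dtype=bool)] = 0.0
    return omega
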