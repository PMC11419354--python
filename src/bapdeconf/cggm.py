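"""Stage 2a: constrained Gaussian graphical model fit and Mahalanobis whitening.

Once stage 1 has selected the bow-free covariance pairs, the error precision
matrix Omega = Psi^-1 is estimated by maximum likelihood under a fixed zero
pattern: off-diagonal entries are free only on the selected pairs, and exact
zeros everywhere else (in particular at every DAG-edge position, by
bow-freeness).  The fitted precision is then used to de-correlate the data
through Mahalanobis whitening, Z = Y @ Omega^{1/2}, which removes the
confounding covariance while leaving a model that a plain DAG can fit with
independent errors.

The fit uses the classical regression-based algorithm for Gaussian graphical
models with known structure: cycling over variables, each column of the
working covariance W is replaced by its best prediction from the variable's
free partners only, which is exactly coordinate ascent on the constrained
log-likelihood  log det(Omega) - tr(Omega S).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class NotPositiveDefiniteError(ValueError):
    """Raised when a covariance input is not positive definite; apply the
    shrinkage estimator upstream (see search.shrink_covariance)."""


class ConvergenceError(RuntimeError):
    pass


@dataclass
class PrecisionEstimate:
    """MLE of the precision matrix under a fixed off-diagonal support."""

    omega: np.ndarray
    free_pairs: FrozenSet[Tuple[str, str]]
    loglik: float
    iterations: int
    converged: bool
    names: Tuple[str, ...] = ()
    objective_path: List[float] = field(default_factory=list)


@dataclass
class WhitenedData:
    """De-correlated data ``z = data @ transform`` with labels preserved."""

    z: pd.DataFrame
    transform: np.ndarray


def _as_index_pairs(
    free_pairs: Iterable[Tuple[str, str]], names: Sequence[str]
) -> List[Tuple[int, int]]:
    idx = {v: i for i, v in enumerate(names)}
    out = []
    for a, b in free_pairs:
        if a not in idx or b not in idx:
            raise KeyError(f"free pair ({a}, {b}) not among variable names")
        i, j = idx[a], idx[b]
        if i == j:
            raise ValueError(f"free pair may not be a self-pair: ({a}, {b})")
        out.append((min(i, j), max(i, j)))
    return out


def fit_cggm(
    S: np.ndarray,
    free_pairs: Iterable[Tuple[str, str]] = (),
    names: Optional[Sequence[str]] = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> PrecisionEstimate:
    """MLE of Omega with off-diagonal support exactly ``free_pairs``.

    Parameters
    ----------
    S
        Sample covariance, symmetric positive definite.
    free_pairs
        Unordered pairs of variable names (or integer indices if ``names``
        is omitted) whose precision entries are free; all other off-diagonal
        entries are constrained to exactly zero.
    names
        Variable labels for the rows/columns of ``S``; defaults to
        ``"0", "1", ...``.

    At convergence the implied covariance ``inv(omega)`` matches ``S`` on
    the diagonal and on every free pair (the stationarity condition of the
    constrained likelihood).
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if S.shape != (p, p) or not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("S must be square symmetric")
    S = 0.5 * (S + S.T)
    if names is None:
        names = tuple(str(i) for i in range(p))
    names = tuple(names)
    try:
        np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        raise NotPositiveDefiniteError(
            "S is not positive definite; use a shrinkage covariance estimate"
        ) from None

    pairs = _as_index_pairs(free_pairs, names)
    nbrs: List[List[int]] = [[] for _ in range(p)]
    for i, j in set(pairs):
        nbrs[i].append(j)
        nbrs[j].append(i)
    nbrs = [sorted(v) for v in nbrs]

    W = S.copy()
    Beta = np.zeros((p, p))  # Beta[:, j] has support nbrs[j]
    omega_prev = None
    objective_path: List[float] = []
    converged = False
    last_delta = math.inf
    it = 0
    for it in range(1, max_iter + 1):
        for j in range(p):
            F = nbrs[j]
            if F:
                WFF = W[np.ix_(F, F)]
                try:
                    betaF = np.linalg.solve(WFF, S[F, j])
                except np.linalg.LinAlgError:
                    raise ConvergenceError(
                        f"singular working block at variable {names[j]!r}"
                    ) from None
                w_col = W[:, F] @ betaF
            else:
                betaF = np.zeros(0)
                w_col = np.zeros(p)
            mask = np.ones(p, dtype=bool)
            mask[j] = False
            W[mask, j] = w_col[mask]
            W[j, mask] = w_col[mask]
            Beta[:, j] = 0.0
            Beta[F, j] = betaF
        omega = _assemble_omega(S, W, Beta, nbrs)
        objective_path.append(_gauss_objective(omega, S))
        if omega_prev is not None:
            last_delta = float(np.max(np.abs(omega - omega_prev)))
            if last_delta < tol:
                converged = True
                omega_prev = omega
                break
        omega_prev = omega

    omega = omega_prev
    if not converged:
        raise ConvergenceError(
            f"CGGM did not converge in {max_iter} sweeps "
            f"(last max |d omega| = {last_delta:.3e})"
        )
    # exact zero pattern
    free_mask = np.zeros((p, p), dtype=bool)
    for i, j in pairs:
        free_mask[i, j] = free_mask[j, i] = True
    omega[~(free_mask | np.eye(p, dtype=bool))] = 0.0
    omega = 0.5 * (omega + omega.T)
    try:
        np.linalg.cholesky(omega)
    except np.linalg.LinAlgError:
        raise ConvergenceError("fitted precision matrix is not positive definite")

    return PrecisionEstimate(
        omega=omega,
        free_pairs=frozenset(tuple(sorted(pr)) for pr in free_pairs),
        loglik=objective_path[-1],
        iterations=it,
        converged=converged,
        names=names,
        objective_path=objective_path,
    )


def _assemble_omega(S, W, Beta, nbrs) -> np.ndarray:
    p = S.shape[0]
    omega = np.zeros((p, p))
    for j in range(p):
        F = nbrs[j]
        betaF = Beta[F, j]
        denom = S[j, j] - W[F, j] @ betaF if F else S[j, j]
        om_jj = 1.0 / denom
        omega[j, j] = om_jj
        omega[F, j] = -betaF * om_jj
    return 0.5 * (omega + omega.T)


def _gauss_objective(omega: np.ndarray, S: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(omega)
    if sign <= 0:
        return -math.inf
    return float(logdet - np.trace(omega @ S))


def spd_sqrt(omega: np.ndarray) -> np.ndarray:
    """Symmetric square root V L^{1/2} V' of an SPD matrix via its spectral
    decomposition."""
    omega = np.asarray(omega, dtype=float)
    if not np.allclose(omega, omega.T, atol=1e-8):
        raise ValueError("matrix must be symmetric")
    vals, vecs = np.linalg.eigh(0.5 * (omega + omega.T))
    if vals.min() <= 0:
        raise NotPositiveDefiniteError(
            f"matrix has a non-positive eigenvalue ({vals.min():.3e})"
        )
    return (vecs * np.sqrt(vals)) @ vecs.T


def whiten(data: pd.DataFrame, precision: PrecisionEstimate) -> WhitenedData:
    """Mahalanobis whitening: right-multiply the data by Omega^{1/2}.

    Column labels must match the precision estimate's variable names.
    """
    if precision.names and tuple(data.columns) != tuple(precision.names):
        raise KeyError("data columns do not match precision variable names")
    T = spd_sqrt(precision.omega)
    z = pd.DataFrame(
        data.to_numpy(dtype=float) @ T, index=data.index, columns=data.columns
    )
    return WhitenedData(z=z, transform=T)
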