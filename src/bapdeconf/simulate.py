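"""Synthetic-data engine: DAG signal plus six error-covariance regimes.

Data are generated from a linear Gaussian SEM on a random DAG.  Errors
E ~ N(mu, Psi) propagate through the graph as Y = E (I - B)^-T (rows are
samples), so the control-group covariance is (I-B)^-1 Psi (I-B)^-T.  The
error covariance Psi encodes the confounding regime:

* ``one_lv_all``       - one latent factor loading U(0.64, 0.81) on every variable;
* ``three_lv_cluster`` - three latent factors on disjoint equal blocks, loadings U(0.2, 0.7);
* ``three_lv_overlap`` - as above with adjacent blocks overlapping by 20%,
                         overlap variables loading U(0.7, 0.9) on both factors;
* ``hdlv_sporadic``    - floor(p/4) node-disjoint pairs with covariance U(0, 1);
* ``hdlv_interconnected`` - covariance support from a Watts-Strogatz small
                         world (nei = 5, rewiring 0.9), magnitudes U(0, 1);
* ``dag_null``         - diagonal Psi (negative control, no confounding).

Diagonal entries of Psi are the row-wise mean of the absolute nonzero
off-diagonal entries plus a U(0.1, 0.9) term; source-node variances are set
to 1.  A binary case/control design shifts the error means of a random 25%
of variables by U(0.05, 0.75) in cases, so differential expression
propagates through the DAG like any other signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .graph import DirectedAcyclicGraph

logger = logging.getLogger(__name__)

SCENARIOS = (
    "one_lv_all",
    "three_lv_cluster",
    "three_lv_overlap",
    "hdlv_sporadic",
    "hdlv_interconnected",
    "dag_null",
)
DENSE_SCENARIOS = SCENARIOS[:3]
SPARSE_SCENARIOS = SCENARIOS[3:5]

#: edge counts used for the benchmark graph sizes (small and large pathway
#: subgraphs of matching size/density)
DEFAULT_EDGE_COUNTS = {32: 47, 190: 259}


@dataclass
class ScenarioSpec:
    """One cell of the simulation design."""

    scenario: str = "one_lv_all"
    p: int = 32
    n: int = 400
    n_edges: Optional[int] = None
    n_reps: int = 1
    seed: int = 0
    frac_de: float = 0.25
    mean_range: Tuple[float, float] = (0.05, 0.75)
    weight_range: Tuple[float, float] = (0.1, 1.0)

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}"
            )
        if not 0 <= self.frac_de <= 1:
            raise ValueError("frac_de must be in [0, 1]")
        if self.mean_range[0] <= 0 or self.weight_range[0] <= 0:
            raise ValueError("ranges must be positive")
        if self.n_edges is None:
            self.n_edges = DEFAULT_EDGE_COUNTS.get(self.p, int(round(1.5 * self.p)))


@dataclass
class SimulatedDataset:
    dag: DirectedAcyclicGraph
    psi: np.ndarray
    true_confounding: np.ndarray       # binary, zero diagonal, symmetric
    data: pd.DataFrame                 # n x p, columns = dag nodes
    group: np.ndarray                  # binary n-vector (1 = case)
    gamma: Optional[np.ndarray] = None # p x q loadings for FA scenarios
    de_nodes: Tuple[str, ...] = ()
    mu: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def random_dag(
    p: int,
    n_edges: int,
    seed,
    weight_range: Tuple[float, float] = (0.1, 1.0),
) -> DirectedAcyclicGraph:
    """Uniform random DAG with the node order as topological order.

    Edge magnitudes are U(weight_range) with Bernoulli(0.5) signs.
    """
    if n_edges > p * (p - 1) // 2:
        raise ValueError(f"cannot place {n_edges} edges on {p} nodes")
    rng = np.random.default_rng(seed)
    nodes = [f"V{i + 1}" for i in range(p)]
    forward = [(i, j) for i in range(p) for j in range(i + 1, p)]
    chosen = rng.choice(len(forward), size=n_edges, replace=False)
    lo, hi = weight_range
    edges = []
    for c in sorted(chosen):
        i, j = forward[c]
        w = rng.uniform(lo, hi) * (1.0 if rng.random() < 0.5 else -1.0)
        edges.append((nodes[i], nodes[j], float(w)))
    return DirectedAcyclicGraph(nodes, edges)


def _blocks(p: int, n_blocks: int = 3, overlap_frac: float = 0.0) -> List[np.ndarray]:
    """Contiguous equal blocks; adjacent blocks share overlap_frac of a block."""
    size = p // n_blocks
    bounds = [(b * size, (b + 1) * size if b < n_blocks - 1 else p) for b in range(n_blocks)]
    ov = int(round(overlap_frac * size))
    out = []
    for b, (lo, hi) in enumerate(bounds):
        lo2 = max(0, lo - (ov if b > 0 else 0))
        out.append(np.arange(lo2, hi))
    return out


def make_psi(
    spec: ScenarioSpec,
    dag: DirectedAcyclicGraph,
    seed,
) -> Tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]:
    """Scenario-specific error covariance, its binary support, and (for the
    factor-analysis scenarios) the loading matrix."""
    rng = np.random.default_rng(seed)
    p = spec.p
    gamma: Optional[np.ndarray] = None
    off = np.zeros((p, p))

    if spec.scenario == "one_lv_all":
        gamma = rng.uniform(0.64, 0.81, size=(p, 1))
        off = gamma @ gamma.T
    elif spec.scenario in ("three_lv_cluster", "three_lv_overlap"):
        overlap = 0.2 if spec.scenario == "three_lv_overlap" else 0.0
        blocks = _blocks(p, 3, overlap)
        gamma = np.zeros((p, 3))
        for b, members in enumerate(blocks):
            gamma[members, b] = rng.uniform(0.2, 0.7, size=members.size)
        shared = np.sum(gamma != 0, axis=1) > 1
        for j in np.where(shared)[0]:
            for b in np.where(gamma[j] != 0)[0]:
                gamma[j, b] = rng.uniform(0.7, 0.9)
        off = gamma @ gamma.T
    elif spec.scenario == "hdlv_sporadic":
        n_pairs = max(1, p // 4)
        perm = rng.permutation(p)
        for k in range(n_pairs):
            i, j = perm[2 * k], perm[2 * k + 1]
            off[i, j] = off[j, i] = rng.uniform(0.0, 1.0)
    elif spec.scenario == "hdlv_interconnected":
        import networkx as nx

        ws = nx.watts_strogatz_graph(
            n=p, k=10, p=0.9, seed=int(rng.integers(2**31 - 1))
        )
        for i, j in ws.edges():
            off[i, j] = off[j, i] = rng.uniform(0.0, 1.0)
    elif spec.scenario != "dag_null":
        raise ValueError(f"unknown scenario {spec.scenario!r}")

    np.fill_diagonal(off, 0.0)
    support = (np.abs(off) > 1e-12).astype(int)
    source_idx = {dag.index(v) for v in dag.source_nodes()}

    def build_diag(rng_local) -> np.ndarray:
        d = np.empty(p)
        for j in range(p):
            row = np.abs(off[j])
            nz = row[row > 1e-12]
            base = nz.mean() if nz.size else 0.0
            d[j] = base + rng_local.uniform(0.1, 0.9)
        for j in source_idx:
            d[j] = 1.0
        return d

    psi = None
    for attempt in range(10):
        d = build_diag(rng)
        cand = off.copy()
        np.fill_diagonal(cand, d)
        try:
            np.linalg.cholesky(cand)
            psi = cand
            break
        except np.linalg.LinAlgError:
            logger.debug("psi not PD, retry %d", attempt + 1)
    if psi is None:
        # deterministic fallback: inflate every variance just past the
        # spectral shortfall.  (Clipping the eigenvalue spectrum instead
        # cancels the intended covariances along the offending directions
        # and destroys the scenario signal.)
        cand = off.copy()
        np.fill_diagonal(cand, build_diag(rng))
        lam = np.linalg.eigvalsh(cand).min()
        cand[np.diag_indices(p)] += abs(lam) + 0.1
        logger.info("psi diagonal inflated by %.3f to restore PD", abs(lam) + 0.1)
        psi = cand
    return psi, support, gamma


def simulate_dataset(
    dag: DirectedAcyclicGraph,
    psi: np.ndarray,
    n: int,
    frac_de: float = 0.25,
    mean_range: Tuple[float, float] = (0.05, 0.75),
    seed=0,
) -> SimulatedDataset:
    """Draw errors, shift case means, and propagate through the DAG.

    Rows are samples; cases are the first ceil(n/2) rows.  The mean shift is
    applied to the errors of a random ``frac_de`` share of variables, so it
    propagates downstream like any other source of variation.
    """
    rng = np.random.default_rng(seed)
    p = dag.n_nodes
    psi = np.asarray(psi, dtype=float)
    np.linalg.cholesky(psi)  # PD required
    n_cases = n // 2
    if n % 2:
        logger.info("odd n=%d: %d cases vs %d controls", n, n_cases, n - n_cases)
    group = np.zeros(n, dtype=int)
    group[:n_cases] = 1

    mu = np.zeros(p)
    n_de = int(round(frac_de * p))
    de_idx = rng.choice(p, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    if n_de:
        mu[de_idx] = rng.uniform(*mean_range, size=n_de)

    E = rng.multivariate_normal(np.zeros(p), psi, size=n, method="cholesky")
    E[group == 1] += mu
    B = dag.coefficient_matrix()
    Y = E @ np.linalg.inv(np.eye(p) - B).T
    data = pd.DataFrame(Y, columns=list(dag.nodes))
    true_conf = (np.abs(psi - np.diag(np.diag(psi))) > 1e-12).astype(int)
    return SimulatedDataset(
        dag=dag,
        psi=psi,
        true_confounding=true_conf,
        data=data,
        group=group,
        de_nodes=tuple(dag.nodes[i] for i in sorted(de_idx)),
        mu=mu,
    )


def simulate_scenario(spec: ScenarioSpec, seed=None) -> SimulatedDataset:
    """Generate one replication of a scenario cell (DAG, Psi, data)."""
    seed = spec.seed if seed is None else seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_dag, s_psi, s_data = ss.spawn(3)
    dag = random_dag(spec.p, spec.n_edges, s_dag, spec.weight_range)
    psi, support, gamma = make_psi(spec, dag, s_psi)
    ds = simulate_dataset(
        dag, psi, spec.n, spec.frac_de, spec.mean_range, s_data
    )
    ds.gamma = gamma
    return ds


# ---------------------------------------------------------------------------
# benchmark driver
# ---------------------------------------------------------------------------

@dataclass
class ReplicationResult:
    scenario: str
    p: int
    n: int
    method: str
    rep: int
    status: str = "ok"
    error: str = ""
    metrics: Dict[str, Optional[float]] = field(default_factory=dict)

    def as_row(self) -> Dict:
        row = {
            "scenario": self.scenario, "p": self.p, "n": self.n,
            "method": self.method, "rep": self.rep, "status": self.status,
        }
        row.update(self.metrics)
        return row


def run_design(
    spec: ScenarioSpec,
    methods: Sequence[str] = ("cggm", "glpc", "pc", "trim"),
    threshold: float = 0.05,
    include_unadjusted: bool = True,
) -> List[ReplicationResult]:
    """Simulate ``spec.n_reps`` replications and score every method on each.

    Per replication: simulate, deconfound with each method, score
    confounding recovery against the true Psi support, and refit the DAG on
    the adjusted data for SRMR / deviance / perturbation metrics.  Failures
    are recorded (status != "ok") and excluded from summaries, never
    silently averaged.
    """
    from .pipeline import deconfound, estimated_confounding

    valid = {"cggm", "glpc", "pc", "trim"}
    bad = set(methods) - valid
    if bad:
        raise ValueError(f"unknown methods {sorted(bad)}; choose from {sorted(valid)}")

    ss = np.random.SeedSequence(spec.seed)
    rep_seeds = ss.spawn(spec.n_reps)
    out: List[ReplicationResult] = []
    for rep in range(spec.n_reps):
        ds = simulate_scenario(spec, seed=rep_seeds[rep])
        todo = (["unadjusted"] if include_unadjusted else []) + list(methods)
        for method in todo:
            res = ReplicationResult(
                scenario=spec.scenario, p=spec.p, n=spec.n, method=method, rep=rep
            )
            try:
                res.metrics = _score_method(ds, method, threshold, rep_seeds[rep])
            except Exception as exc:  # per-replication failures are logged
                res.status = "failed"
                res.error = f"{type(exc).__name__}: {exc}"
                logger.warning(
                    "replication %d method %s failed: %s", rep, method, res.error
                )
            out.append(res)
    n_failed = sum(r.status != "ok" for r in out)
    if n_failed:
        logger.warning("%d of %d method runs failed", n_failed, len(out))
    return out


def _score_method(
    ds: SimulatedDataset, method: str, threshold: float, seed
) -> Dict[str, Optional[float]]:
    from .metrics import confusion
    from .pipeline import deconfound, estimated_confounding
    from .semfit import fit_dag_ols, group_perturbation

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child_seed = int(ss.generate_state(1)[0] % (2**31))
    if method == "unadjusted":
        sd = ds.data.std(ddof=1)
        z = (ds.data - ds.data.mean()) / sd
        fit = fit_dag_ols(ds.dag, z)
        pert = group_perturbation(ds.dag, z, ds.group)
        return {
            "srmr": fit.srmr, "dev_df": fit.dev_df,
            "nlog10P": pert.nlog10p, "vcountP": pert.vcountp,
        }

    result = deconfound(ds.dag, ds.data, dalgo=method, seed=child_seed)
    metrics: Dict[str, Optional[float]] = {}
    est = estimated_confounding(result, ds.dag, threshold=threshold)
    if est is not None:
        rec = confusion(ds.true_confounding, est)
        metrics.update(rec.as_dict())
    fit = fit_dag_ols(result.dag, result.data)
    pert = group_perturbation(
        result.dag, result.data, ds.group, nodes=list(ds.dag.nodes)
    )
    metrics.update(
        {
            "srmr": fit.srmr, "dev_df": fit.dev_df,
            "nlog10P": pert.nlog10p, "vcountP": pert.vcountp,
            "n_selected": result.n_selected if result.guu is not None else None,
            "q": result.q,
        }
    )
    return metrics


def design_table(results: Sequence[ReplicationResult]) -> pd.DataFrame:
    """Tidy per-replication table."""
    return pd.DataFrame([r.as_row() for r in results])


def summarize_design(results: Sequence[ReplicationResult]) -> pd.DataFrame:
    """Mean and sd per (scenario, p, n, method) over successful replications."""
    tab = design_table(results)
    ok = tab[tab["status"] == "ok"].drop(columns=["status", "error"], errors="ignore")
    if ok.empty:
        return ok
    keys = ["scenario", "p", "n", "method"]
    num = ok.select_dtypes("number").columns.difference(["p", "n", "rep"])
    agg = ok.groupby(keys, sort=False)[list(num)].agg(["mean", "std"])
    agg.columns = [f"{a}_{b}" for a, b in agg.columns]
    return agg.reset_index()
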