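"""Common output contract of the deconfounding algorithms.

Every algorithm produces the same four-object bundle: the (possibly
augmented) DAG, the undirected graph of selected bow-free covariances
(``guu``; empty for the SVD-only methods), the table of d-separation / CI
tests (``dsep``; empty likewise), and the adjusted data matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Optional, Tuple

import pandas as pd

from .graph import DirectedAcyclicGraph
from .search import DSepTable


@dataclass
class DeconfoundResult:
    """Adjusted data plus the graphs describing what was removed or added.

    ``data`` is either the whitened matrix (same columns as the input) or
    the input matrix with latent-proxy score columns (LV1..LVq) prepended.
    """

    data: pd.DataFrame
    dag: DirectedAcyclicGraph
    guu: Optional[FrozenSet[Tuple[str, str]]] = None
    dsep: Optional[DSepTable] = None
    algorithm: str = ""
    q: int = 0
    cluster_assignment: Dict[str, int] = field(default_factory=dict)
    info: Dict = field(default_factory=dict)

    @property
    def n_selected(self) -> int:
        return 0 if self.guu is None else len(self.guu)

    def write(self, outdir) -> None:
        """Write the four-object bundle as plain-text artifacts."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.dag.write_graphml(outdir / "dag.graphml")
        self.data.to_csv(outdir / "data_adjusted.tsv", sep="\t", index=False)
        omega = self.info.get("omega_pairs", {})
        with open(outdir / "guu.tsv", "w") as fh:
            fh.write("node1\tnode2\tomega\n" if omega else "node1\tnode2\n")
            if self.guu:
                for a, b in sorted(self.guu):
                    if omega:
                        fh.write(f"{a}\t{b}\t{omega.get((a, b), float('nan')):.8g}\n")
                    else:
                        fh.write(f"{a}\t{b}\n")
        if self.dsep is not None:
            self.dsep.write_tsv(outdir / "dsep.tsv")
            with open(outdir / "dsep_summary.json", "w") as fh:
                json.dump(self.dsep.summary(), fh, indent=1)
        else:
            (outdir / "dsep.tsv").write_text(
                "lhs\trhs\tcond_set\tn_cond\tr\tz\tp\tp_adj\tselected\tskipped\n"
            )
        if self.cluster_assignment:
            with open(outdir / "clusters.tsv", "w") as fh:
                fh.write("node\tcluster\n")
                for node, c in self.cluster_assignment.items():
                    fh.write(f"{node}\t{c}\n")


def augment_dag(
    dag: DirectedAcyclicGraph,
    lv_edges: Dict[str, Tuple[str, ...]],
) -> DirectedAcyclicGraph:
    """Add latent-proxy source nodes wired to the given observed targets.

    New nodes have no incoming edges, so acyclicity is preserved; the
    original edges and weights are untouched.  Raises on name collision.
    """
    collisions = [lv for lv in lv_edges if lv in dag.nodes]
    if collisions:
        raise ValueError(f"latent-proxy name collision with DAG nodes: {collisions}")
    nodes = list(lv_edges) + list(dag.nodes)
    edges = [
        (lv, tgt, 1.0) for lv, targets in lv_edges.items() for tgt in targets
    ] + dag.edges
    return DirectedAcyclicGraph(nodes, edges)
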