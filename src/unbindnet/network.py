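"""Transition networks from node assignments.

Nodes are snapshot clusters; a directed edge (i, j) counts the direct
transitions i -> j between consecutive frames of the same run at the saving
interval (the lag), including self-transitions i -> i.  No transition is
counted across a run boundary.  The node partition function Z_i is the number
of counted transitions out of i (row sum), Z is the total count, and the
transition probabilities are p_ij = n_ij / Z_i.  Detailed balance is imposed
by replacing n_ij and n_ji with their arithmetic mean, which leaves every Z_i
(and Z) unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "TransitionNetwork",
    "build_network",
    "network_from_counts",
    "symmetrize",
    "restrict_nodes",
    "to_networkx",
    "write_edge_list",
    "write_node_table",
]


@dataclass
class TransitionNetwork:
    counts: sp.csr_matrix  # n_ij, possibly half-integer after symmetrization
    dt: float  # lag (ps)
    symmetrized: bool = False
    node_com: np.ndarray | None = None  # mean COM distance per node (Å)
    node_ids: np.ndarray | None = None  # original node labels after restriction

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        if self.node_ids is None:
            self.node_ids = np.arange(self.counts.shape[0])

    @property
    def n_nodes(self) -> int:
        return self.counts.shape[0]

    @property
    def Z_i(self) -> np.ndarray:
        """Per-node partition function: transitions out of the node."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    @property
    def Z(self) -> float:
        """Total partition function: number of counted frame pairs."""
        return float(self.counts.sum())

    @property
    def p(self) -> sp.csr_matrix:
        """Row-stochastic transition probabilities (rows with Z_i = 0 are
        left empty)."""
        z = self.Z_i
        inv = np.divide(1.0, z, out=np.zeros_like(z), where=z > 0)
        return sp.diags(inv) @ self.counts


def build_network(
    assignments: pd.DataFrame, dt: float, n_nodes: int | None = None
) -> TransitionNetwork:
    """Count transitions from a time-ordered assignment table.

    ``assignments`` columns: run_id, frame, node (com_distance optional; if
    present the per-node mean COM is attached to the network).  Frames must be
    strictly increasing within each run.
    """
    req = {"run_id", "frame", "node"}
    if not req <= set(assignments.columns):
        raise ValueError(f"assignment table needs columns {sorted(req)}")
    runs = assignments["run_id"].to_numpy()
    frames = assignments["frame"].to_numpy()
    nodes = assignments["node"].to_numpy()
    same_run = runs[1:] == runs[:-1]
    if np.any(same_run & (frames[1:] <= frames[:-1])):
        bad = np.flatnonzero(same_run & (frames[1:] <= frames[:-1]))[0]
        raise ValueError(
            f"non-monotone frames within run {runs[bad]} at row {bad + 1}"
        )
    K = int(n_nodes) if n_nodes is not None else int(nodes.max()) + 1
    src = nodes[:-1][same_run]
    dst = nodes[1:][same_run]
    C = sp.coo_matrix(
        (np.ones(len(src)), (src, dst)), shape=(K, K)
    ).tocsr()

    node_com = None
    if "com_distance" in assignments.columns:
        com = assignments["com_distance"].to_numpy(dtype=float)
        sums = np.bincount(nodes, weights=com, minlength=K)
        cnts = np.bincount(nodes, minlength=K)
        node_com = np.divide(sums, cnts, out=np.full(K, np.nan), where=cnts > 0)

    return TransitionNetwork(counts=C, dt=dt, node_com=node_com)


def network_from_counts(
    counts: np.ndarray, dt: float, node_com: np.ndarray | None = None,
    symmetrized: bool = False,
) -> TransitionNetwork:
    """Wrap an explicit (possibly exact expected) count matrix."""
    return TransitionNetwork(
        counts=sp.csr_matrix(np.asarray(counts, dtype=float)),
        dt=dt,
        node_com=None if node_com is None else np.asarray(node_com, float),
        symmetrized=symmetrized,
    )


def symmetrize(net: TransitionNetwork) -> TransitionNetwork:
    """Impose detailed balance: n'_ij = n'_ji = (n_ij + n_ji) / 2."""
    C = (net.counts + net.counts.T) * 0.5
    return replace(net, counts=sp.csr_matrix(C), symmetrized=True)


def restrict_nodes(net: TransitionNetwork, keep) -> TransitionNetwork:
    """Induced subnetwork on the nodes selected by ``keep``.

    ``keep`` is a boolean mask over nodes or a callable applied to the
    per-node mean COM distance (e.g. ``lambda com: com < 15.0``).
    """
    if callable(keep):
        if net.node_com is None:
            raise ValueError("predicate on COM requires node_com on the network")
        mask = np.asarray(keep(net.node_com), dtype=bool)
    else:
        mask = np.asarray(keep, dtype=bool)
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise ValueError("restriction removed every node")
    C = net.counts[idx, :][:, idx]
    return TransitionNetwork(
        counts=sp.csr_matrix(C),
        dt=net.dt,
        symmetrized=net.symmetrized,
        node_com=None if net.node_com is None else net.node_com[idx],
        node_ids=net.node_ids[idx],
    )


def to_networkx(net: TransitionNetwork):
    """Export as a networkx DiGraph (nodes annotated with Z_i and COM)."""
    import networkx as nx

    G = nx.DiGraph(dt=net.dt, symmetrized=net.symmetrized)
    z = net.Z_i
    for k in range(net.n_nodes):
        attrs = {"Z": float(z[k])}
        if net.node_com is not None and np.isfinite(net.node_com[k]):
            attrs["com_distance"] = float(net.node_com[k])
        G.add_node(int(net.node_ids[k]), **attrs)
    coo = net.counts.tocoo()
    for i, j, c in zip(coo.row, coo.col, coo.data):
        G.add_edge(int(net.node_ids[i]), int(net.node_ids[j]), count=float(c))
    return G


def write_graphml(net: TransitionNetwork, path) -> None:
    import networkx as nx

    nx.write_graphml(to_networkx(net), path)


def write_edge_list(net: TransitionNetwork, path) -> None:
    coo = net.counts.tocoo()
    pd.DataFrame(
        {"i": net.node_ids[coo.row], "j": net.node_ids[coo.col], "count": coo.data}
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_node_table(net: TransitionNetwork, path) -> None:
    df = pd.DataFrame({"node_id": net.node_ids, "Z": net.Z_i})
    if net.node_com is not None:
        df["mean_com_distance"] = net.node_com
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
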