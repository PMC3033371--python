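"""Leader-algorithm clustering of snapshots at a DRMS threshold.

Single pass in stream order: each snapshot joins the first existing leader
within the threshold, otherwise it founds a new cluster and becomes its
leader.  Leaders are the founding snapshot's feature vector and are never
updated, so the result is deterministic given the input order (run-major:
run 0 frames, then run 1, ...).  A 1 Å threshold on heavy-atom intermolecular
DRMS is the conventional operating point; profiles downstream are robust for
thresholds in the 0.8–1.0 Å range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ClusterModel", "leader_cluster", "threshold_sweep"]


@dataclass
class ClusterModel:
    threshold: float
    leaders: np.ndarray  # (K, N) leader feature vectors, creation order
    assignment: np.ndarray  # (n,) node id per snapshot
    node_sizes: np.ndarray  # (K,) snapshots per node

    @property
    def n_nodes(self) -> int:
        return len(self.leaders)

    def assignment_table(self, frames: pd.DataFrame) -> pd.DataFrame:
        """Assignment TSV dialect: run_id, frame, node (plus com if present)."""
        cols = {"run_id": frames["run_id"], "frame": frames["frame"]}
        out = pd.DataFrame(cols)
        out["node"] = self.assignment
        if "com_distance" in frames.columns:
            out["com_distance"] = frames["com_distance"].to_numpy()
        return out

    def node_summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": np.arange(self.n_nodes),
                "size": self.node_sizes,
                "leader_index": self._leader_rows,
            }
        )


def leader_cluster(
    X: np.ndarray, threshold: float, assign: str = "first"
) -> ClusterModel:
    """Cluster feature vectors with the leader algorithm.

    Parameters
    ----------
    X : (n_snapshots, N) distance vectors in stream order.
    threshold : DRMS cutoff in Å (> 0).
    assign : ``"first"`` (classical leader algorithm, default) or
        ``"nearest"`` — join the nearest leader within threshold instead of
        the first.  Leader creation is identical for both.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("need a non-empty (n, N) feature array")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if assign not in ("first", "nearest"):
        raise ValueError("assign must be 'first' or 'nearest'")

    n, N = X.shape
    leaders = np.empty((min(n, 1024), N))
    leader_rows = []
    assignment = np.empty(n, dtype=np.int64)
    k = 0
    for i in range(n):
        if k:
            d2 = np.mean((leaders[:k] - X[i]) ** 2, axis=1)
            if assign == "first":
                hits = np.flatnonzero(d2 <= threshold * threshold)
                j = hits[0] if len(hits) else -1
            else:
                j = int(np.argmin(d2))
                if d2[j] > threshold * threshold:
                    j = -1
        else:
            j = -1
        if j >= 0:
            assignment[i] = j
        else:
            if k == len(leaders):
                leaders = np.vstack([leaders, np.empty_like(leaders)])
            leaders[k] = X[i]
            leader_rows.append(i)
            assignment[i] = k
            k += 1

    sizes = np.bincount(assignment, minlength=k)
    model = ClusterModel(
        threshold=float(threshold),
        leaders=leaders[:k].copy(),
        assignment=assignment,
        node_sizes=sizes,
    )
    model._leader_rows = np.asarray(leader_rows)
    return model


def threshold_sweep(
    X: np.ndarray, thresholds: list[float], assign: str = "first"
) -> tuple[dict[float, ClusterModel], pd.DataFrame]:
    """Cluster at several thresholds; used for robustness checks of the
    downstream profiles (chain each model through the network/profile stages
    and overlay)."""
    if len(thresholds) < 2:
        raise ValueError("a sweep needs at least 2 thresholds")
    models = {float(t): leader_cluster(X, t, assign=assign) for t in thresholds}
    report = pd.DataFrame(
        {
            "threshold": list(models),
            "n_nodes": [m.n_nodes for m in models.values()],
            "largest_node": [int(m.node_sizes.max()) for m in models.values()],
        }
    )
    return models, report
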