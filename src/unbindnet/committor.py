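"""Unbinding probability (committor), transition-state ensemble, Hammond shift.

Under the assumption that structurally similar conformations share kinetic
behaviour, every snapshot of a node has the same probability of unbinding:
the trajectory following each member snapshot is checked for the unbinding
condition (COM separation > 15 Å) within a commitment time much shorter than
the unbinding time, and the node's p_u is the fraction of members that
unbind.  Nodes with p_u in [0.45, 0.55] and at least 20 snapshots form the
transition-state ensemble (TSE); for ensemble statistics only TSE nodes with
network weight above 5 are kept, since very light nodes add noise.

The Hammond shift compares TSE positions across ligands: the weaker the
binding, the closer (in COM distance) the TSE sits to the bound state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .cfep import MfptVector
from .network import TransitionNetwork

__all__ = [
    "CommittorTable",
    "TseReport",
    "node_committor",
    "select_tse",
    "hammond_shift",
    "mfpt_distance_correlation",
]


@dataclass
class CommittorTable:
    nodes: pd.DataFrame  # node_id, p_u, n_snapshots, n_unbinding, Z, mean_com
    commitment_time: float  # ps
    unbind_cut: float
    snapshot_success: pd.DataFrame | None = None  # scored snapshots (node, com, success)


@dataclass
class TseReport:
    nodes: pd.DataFrame  # TSE nodes with p_u, n_snapshots, Z, mean_com
    band: tuple[float, float]
    min_snapshots: int
    min_weight: float
    com_values: np.ndarray | None = None  # per-snapshot COM over TSE members

    @property
    def node_ids(self) -> np.ndarray:
        return self.nodes["node_id"].to_numpy()

    @property
    def mean_com(self) -> float:
        """Snapshot-weighted mean COM distance of the TSE."""
        if len(self.nodes) == 0:
            return float("nan")
        w = self.nodes["n_snapshots"].to_numpy(dtype=float)
        return float(np.average(self.nodes["mean_com"], weights=w))

    @property
    def spread_com(self) -> float:
        if len(self.nodes) < 2:
            return float("nan")
        w = self.nodes["n_snapshots"].to_numpy(dtype=float)
        mu = self.mean_com
        return float(np.sqrt(np.average((self.nodes["mean_com"] - mu) ** 2, weights=w)))


def node_committor(
    assignments: pd.DataFrame,
    commitment_time: float,
    dt: float,
    unbind_cut: float = 15.0,
    rebind_cut: float = 10.0,
    net: TransitionNetwork | None = None,
    score_after_rebind: bool = True,
    fitted_tau: float | None = None,
    keep_snapshots: bool = False,
) -> CommittorTable:
    """Per-node unbinding probability within the commitment time.

    ``assignments`` columns: run_id, frame, node, com_distance, time-ordered
    within runs.  A snapshot succeeds if the COM distance exceeds
    ``unbind_cut`` at any of the following ``H = commitment_time/dt`` frames
    of its own run.  Scoring rules:

    * snapshots within the horizon of their run's end are excluded (their
      outcome is censored);
    * snapshots at or after the run's first unbinding are excluded until the
      ligand has rebound below ``rebind_cut`` (the committor describes the
      bound process); set ``score_after_rebind=False`` to drop everything
      after the first unbinding instead.

    Node weight Z comes from ``net`` when given, else the snapshot count.
    """
    H = int(round(commitment_time / dt))
    if H < 1:
        raise ValueError("commitment_time must be at least one saving interval")
    if fitted_tau is not None and commitment_time > fitted_tau / 3.0:
        warnings.warn(
            f"commitment time {commitment_time:.0f} ps exceeds tau/3 "
            f"({fitted_tau / 3.0:.0f} ps); committor values may saturate",
            RuntimeWarning,
            stacklevel=2,
        )

    nodes_all, com_all, succ_parts = [], [], []
    for _, g in assignments.groupby("run_id", sort=True):
        com = g["com_distance"].to_numpy(dtype=float)
        node = g["node"].to_numpy()
        L = len(com)
        if L <= H:
            continue
        over = com > unbind_cut
        # success[f]: any unbinding among frames f+1 .. f+H (cumulative-sum window)
        cs = np.concatenate([[0], np.cumsum(over.astype(np.int64))])
        upper = np.minimum(np.arange(L) + H, L - 1)
        success = (cs[upper + 1] - cs[1 : L + 1]) > 0

        eligible = np.arange(L) + H <= L - 1
        if over.any():
            state_unbound = np.zeros(L, dtype=bool)
            unbound = False
            for k in range(L):
                if not unbound and com[k] > unbind_cut:
                    unbound = True
                elif unbound and score_after_rebind and com[k] < rebind_cut:
                    unbound = False
                state_unbound[k] = unbound
            eligible &= ~state_unbound
        mask = eligible
        nodes_all.append(node[mask])
        com_all.append(com[mask])
        succ_parts.append(success[mask])

    if not nodes_all:
        raise ValueError("no snapshot has a full commitment horizon; runs too short")
    node_v = np.concatenate(nodes_all)
    com_v = np.concatenate(com_all)
    succ_v = np.concatenate(succ_parts)

    K = int(assignments["node"].max()) + 1
    n_snap = np.bincount(node_v, minlength=K)
    n_unb = np.bincount(node_v, weights=succ_v.astype(float), minlength=K)
    com_sum = np.bincount(node_v, weights=com_v, minlength=K)
    present = n_snap > 0
    p_u = np.divide(n_unb, n_snap, out=np.zeros(K), where=present)
    mean_com = np.divide(com_sum, n_snap, out=np.full(K, np.nan), where=present)

    if net is not None:
        z = np.zeros(K)
        z[net.node_ids] = net.Z_i
    else:
        z = n_snap.astype(float)

    table = pd.DataFrame(
        {
            "node_id": np.arange(K),
            "p_u": p_u,
            "n_snapshots": n_snap,
            "n_unbinding": n_unb.astype(int),
            "Z": z,
            "mean_com": mean_com,
        }
    )
    table = table[table["n_snapshots"] > 0].reset_index(drop=True)
    snap = (
        pd.DataFrame({"node": node_v, "com_distance": com_v, "success": succ_v})
        if keep_snapshots
        else None
    )
    return CommittorTable(
        nodes=table,
        commitment_time=commitment_time,
        unbind_cut=unbind_cut,
        snapshot_success=snap,
    )


def select_tse(
    table: CommittorTable,
    band: tuple[float, float] = (0.45, 0.55),
    min_snapshots: int = 20,
    min_weight: float = 5.0,
) -> TseReport:
    """Filter the committor table down to the transition-state ensemble."""
    df = table.nodes
    in_band = (df["p_u"] >= band[0]) & (df["p_u"] <= band[1])
    enough = df["n_snapshots"] >= min_snapshots
    heavy = df["Z"] > min_weight
    tse = df[in_band & enough & heavy].reset_index(drop=True)
    if len(tse) == 0:
        nearest = df.iloc[(df["p_u"] - 0.5).abs().argsort()[:3]]
        warnings.warn(
            "empty TSE; nearest committor values: "
            + ", ".join(
                f"node {int(r.node_id)}: p_u={r.p_u:.3f} (n={int(r.n_snapshots)})"
                for r in nearest.itertuples()
            ),
            RuntimeWarning,
            stacklevel=2,
        )
    com_values = None
    if table.snapshot_success is not None and len(tse):
        keep = table.snapshot_success["node"].isin(tse["node_id"])
        com_values = table.snapshot_success.loc[keep, "com_distance"].to_numpy()
    return TseReport(
        nodes=tse,
        band=band,
        min_snapshots=min_snapshots,
        min_weight=min_weight,
        com_values=com_values,
    )


@dataclass
class HammondReport:
    per_dataset: pd.DataFrame  # dataset, stability, tse_mean_com, n_tse_nodes
    rank_correlation: float  # Spearman rho of TSE mean COM vs stability
    p_value: float


def hammond_shift(
    reports: dict[str, TseReport], stability: dict[str, float]
) -> HammondReport:
    """Rank-correlate TSE position with bound-state stability across ligands.

    ``stability`` orders the datasets by how stable the bound state is (e.g.
    planted well depth, fitted tau, or -ΔG).  Hammond behaviour predicts a
    positive rank correlation: destabilizing the bound state pulls the
    transition state toward it (smaller TSE COM distance for weaker binders).
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 datasets to compare TSE positions")
    names = sorted(reports)
    rows = [
        {
            "dataset": k,
            "stability": stability[k],
            "tse_mean_com": reports[k].mean_com,
            "n_tse_nodes": len(reports[k].nodes),
        }
        for k in names
    ]
    df = pd.DataFrame(rows)
    rho, p = spearmanr(df["stability"], df["tse_mean_com"])
    return HammondReport(per_dataset=df, rank_correlation=float(rho), p_value=float(p))


def mfpt_distance_correlation(
    mfpt: MfptVector, node_com: np.ndarray, com_cutoff: float = 30.0
) -> float:
    """Pearson correlation of node mfpt with node COM distance (nodes with
    mean COM below the cutoff), measuring how well the intuitive geometric
    coordinate predicts kinetic distance to the reference."""
    com = np.asarray(node_com, dtype=float)
    if len(com) != len(mfpt.mfpt):
        raise ValueError("mfpt and COM must be defined on the same nodes")
    mask = np.isfinite(com) & (com <= com_cutoff)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 nodes below the COM cutoff")
    r, _ = pearsonr(mfpt.mfpt[mask], com[mask])
    return float(r)


def commitment_sweep(
    assignments: pd.DataFrame,
    commitment_times: tuple[float, ...],
    dt: float,
    unbind_cut: float = 15.0,
    net: TransitionNetwork | None = None,
    **tse_kwargs,
) -> pd.DataFrame:
    """TSE position as a function of commitment time (robustness report)."""
    rows = []
    for tc in commitment_times:
        tab = node_committor(assignments, tc, dt=dt, unbind_cut=unbind_cut, net=net)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            tse = select_tse(tab, **tse_kwargs)
        rows.append(
            {
                "commitment_time_ps": tc,
                "tse_mean_com": tse.mean_com,
                "n_tse_nodes": len(tse.nodes),
                "n_tse_snapshots": int(tse.nodes["n_snapshots"].sum()),
            }
        )
    return pd.DataFrame(rows)
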