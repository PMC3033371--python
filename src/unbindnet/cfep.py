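"""Cut-based free-energy profiles from transition networks.

The mean first passage time (mfpt) of node i to a reference node obeys

    mfpt_i = dt + sum_j p_ij * mfpt_j ,    mfpt_ref = 0 ,

a sparse linear system solved directly.  Sorting nodes by increasing mfpt and
sweeping a cut through the ordering, each cut splits the network into the
reactant group A (containing the reference) and its complement B; the point

    ( x, y ) = ( Z_A / Z ,  -kT * ln(Z_AB / Z) )

is added to the profile, where Z_A is the partition function of A and Z_AB
counts the transitions crossing the cut.  The profile preserves barrier
heights and is invariant under any strictly increasing transform of the
ordering variable.  Profiles referenced at the most populated node of each
unassigned region, peeled iteratively at the first barrier, decompose the
bound state into subbasins (binding modes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.csgraph import breadth_first_order

from .network import TransitionNetwork, build_network, restrict_nodes, symmetrize

__all__ = [
    "MfptVector",
    "CutFEP",
    "SubbasinDecomposition",
    "solve_mfpt",
    "cut_profile",
    "detect_subbasins",
    "diffusivity_check",
]

KB_KCAL = 0.0019872041  # kcal / (mol K)
DIFFUSIVE_LAG2_OFFSET_KT = 0.5 * np.log(2.0)


@dataclass
class MfptVector:
    mfpt: np.ndarray  # per-node mfpt to the reference (ps)
    reference: int
    dt: float


@dataclass
class CutFEP:
    """Ordered profile points.

    ``points`` columns: x (= Z_A/Z), y_kT, y_kcal, cut_value (ordering value
    at the cut), Z_A, Z_AB, infinite (flag for Z_AB = 0 cuts).  The final cut
    (A = all nodes) is included with an infinite barrier flag.
    """

    points: pd.DataFrame
    temperature: float
    ordering_name: str = "mfpt"

    def barrier_height(self) -> float:
        """Highest finite barrier (kT) on the profile."""
        y = self.points.loc[~self.points["infinite"], "y_kT"]
        return float(y.max())


@dataclass
class SubbasinDecomposition:
    labels: np.ndarray  # per-node subbasin id (0..S-1)
    references: list[int]  # most populated node of each subbasin
    populations: np.ndarray  # Z-weighted population per subbasin

    @property
    def n_subbasins(self) -> int:
        return len(self.references)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subbasin": np.arange(self.n_subbasins),
                "reference_node": self.references,
                "population": self.populations,
            }
        )


def solve_mfpt(net: TransitionNetwork, reference: int) -> MfptVector:
    """Solve the mfpt linear system with the reference fixed at zero.

    Raises if some nodes have no path to the reference (they would make the
    system singular); the error names the trapped nodes.
    """
    n = net.n_nodes
    if not 0 <= reference < n:
        raise ValueError(f"reference node {reference} out of range")
    P = net.p
    # nodes from which the reference is reachable = predecessors in the
    # transition graph = reachable from ref in the transposed graph
    order = breadth_first_order(
        sp.csr_matrix(P.T), reference, directed=True, return_predecessors=False
    )
    reachable = np.zeros(n, dtype=bool)
    reachable[order] = True
    counted = net.Z_i > 0
    trapped = np.flatnonzero(~reachable & counted)
    if len(trapped):
        raise ValueError(
            f"{len(trapped)} nodes cannot reach the reference "
            f"(e.g. {trapped[:10].tolist()}); restrict the network first"
        )

    free = np.flatnonzero(np.arange(n) != reference)
    A = sp.eye(n, format="csr") - P
    A_ff = A[free, :][:, free]
    b = np.full(len(free), net.dt)
    if n <= 600:
        m_free = np.linalg.solve(A_ff.toarray(), b)
    else:
        m_free = spla.spsolve(A_ff.tocsc(), b)
    mfpt = np.zeros(n)
    mfpt[free] = m_free
    resid = np.abs(A_ff @ m_free - b).max()
    if resid > 1e-8 * net.dt:
        raise ArithmeticError(f"mfpt solve residual {resid:.2e} exceeds tolerance")
    return MfptVector(mfpt=mfpt, reference=reference, dt=net.dt)


def cut_profile(
    net: TransitionNetwork,
    ordering: MfptVector | np.ndarray,
    temperature: float = 310.0,
) -> CutFEP:
    """Sweep cuts through the node ordering and emit the profile.

    Nodes with tied ordering values enter the reactant group A together
    (atomic groups — they sit at the same kinetic distance).  A cut with
    Z_AB = 0 before the final one signals disconnected sampling and is
    emitted flagged infinite.
    """
    if isinstance(ordering, MfptVector):
        score = ordering.mfpt
        name = "mfpt"
    else:
        score = np.asarray(ordering, dtype=float)
        name = "score"
    if len(score) != net.n_nodes:
        raise ValueError("ordering must assign a value to every node")

    C = sp.csr_matrix(net.counts)
    Z = net.Z
    z_i = net.Z_i
    values = np.unique(score)
    xs, ys_kT, cut_vals, z_as, z_abs, inf_flags = [], [], [], [], [], []
    in_A = np.zeros(net.n_nodes, dtype=bool)
    W_A = 0.0
    intra = 0.0
    for v in values:
        group = np.flatnonzero((score == v) & ~in_A)
        # incremental intra-A count: edges group->A_new plus A_old->group
        in_A[group] = True
        sub = C[group, :]
        intra += sub[:, in_A].sum()
        prev = in_A.copy()
        prev[group] = False
        if prev.any():
            intra += C[prev, :][:, group].sum()
        W_A += z_i[group].sum()
        z_ab = W_A - intra
        x = W_A / Z
        infinite = z_ab <= 0
        xs.append(x)
        z_as.append(W_A)
        z_abs.append(max(z_ab, 0.0))
        cut_vals.append(v)
        inf_flags.append(bool(infinite))
        ys_kT.append(np.inf if infinite else -np.log(z_ab / Z))

    kT_kcal = KB_KCAL * temperature
    pts = pd.DataFrame(
        {
            "x": xs,
            "y_kT": ys_kT,
            "y_kcal": [y * kT_kcal if np.isfinite(y) else np.inf for y in ys_kT],
            "cut_value": cut_vals,
            "Z_A": z_as,
            "Z_AB": z_abs,
            "infinite": inf_flags,
        }
    )
    interior_inf = pts["infinite"].to_numpy()[:-1]
    if interior_inf.any():
        warnings.warn(
            f"{int(interior_inf.sum())} interior cut(s) have Z_AB = 0: "
            "sampling is disconnected across the cut",
            RuntimeWarning,
            stacklevel=2,
        )
    return CutFEP(points=pts, temperature=temperature, ordering_name=name)


def first_barrier_index(profile: CutFEP, min_drop_kT: float = 0.5) -> int | None:
    """Index (into profile points) of the first local maximum of y followed by
    a drop exceeding ``min_drop_kT``; None if the profile has no such barrier."""
    pts = profile.points
    finite = pts[~pts["infinite"]]
    y = finite["y_kT"].to_numpy()
    idx = finite.index.to_numpy()
    if len(y) < 2:
        return None
    peak_i = 0
    for k in range(1, len(y)):
        if y[k] > y[peak_i]:
            peak_i = k
        elif y[peak_i] - y[k] > min_drop_kT:
            return int(idx[peak_i])
    return None


def detect_subbasins(
    net: TransitionNetwork,
    temperature: float = 310.0,
    min_drop_kT: float = 0.5,
) -> SubbasinDecomposition:
    """Iteratively peel subbasins off the (bound-state) network.

    Repeat until every node is assigned: take the most populated unassigned
    node as reference, compute the cut profile over the unassigned subnetwork,
    and assign to a new subbasin every node at or left of the first barrier
    (first local maximum of y followed by a drop > ``min_drop_kT``).  A
    profile with no interior barrier yields a single subbasin.  Nodes that
    cannot reach the current reference stay for later rounds.
    """
    n = net.n_nodes
    labels = np.full(n, -1, dtype=int)
    references: list[int] = []
    z_all = net.Z_i
    s = 0
    while (labels < 0).any():
        unassigned = np.flatnonzero(labels < 0)
        sub = restrict_nodes(net, labels < 0)
        ref_local = int(np.argmax(sub.Z_i))
        # work on the connected component of the reference only
        comp = _component_of(sub, ref_local)
        subc = restrict_nodes(sub, comp)
        refc = int(np.searchsorted(np.flatnonzero(comp), ref_local))
        local_ids = unassigned[np.flatnonzero(comp)]
        mfpt = solve_mfpt(subc, refc)
        profile = cut_profile(subc, mfpt, temperature=temperature)
        bidx = first_barrier_index(profile, min_drop_kT=min_drop_kT)
        if bidx is None:
            members_local = np.arange(subc.n_nodes)
        else:
            cut_val = profile.points.loc[bidx, "cut_value"]
            members_local = np.flatnonzero(mfpt.mfpt <= cut_val)
        labels[local_ids[members_local]] = s
        references.append(int(local_ids[refc]))
        s += 1
    pops = np.array([z_all[labels == k].sum() for k in range(s)])
    return SubbasinDecomposition(labels=labels, references=references, populations=pops)


def _component_of(net: TransitionNetwork, node: int) -> np.ndarray:
    adj = sp.csr_matrix((net.counts + net.counts.T) > 0)
    order = breadth_first_order(adj, node, directed=False, return_predecessors=False)
    mask = np.zeros(net.n_nodes, dtype=bool)
    mask[order] = True
    return mask


@dataclass
class DiffusivityReport:
    offset_kT: float  # median vertical offset y(lag dt) - y(lag 2dt)
    expected_kT: float  # (1/2) ln 2, the free-diffusion lag-doubling value
    relative_deviation: float
    n_shared_points: int


def diffusivity_check(
    assignments: pd.DataFrame,
    dt: float,
    reference: int | str = "most_populated",
    temperature: float = 310.0,
    x_range: tuple[float, float] = (0.05, 0.95),
) -> DiffusivityReport:
    """Lag-doubling test of diffusive behaviour.

    Builds the symmetrized network at lag dt and, from every second frame, at
    lag 2 dt; computes both mfpt-ordered profiles and reports the median
    vertical offset between them over the shared x-range.  For diffusive
    dynamics the number of cut crossings scales as sqrt(lag), so the lag-2dt
    profile sits lower by (1/2) ln 2 kT; a large deviation from that value
    flags non-diffusive (e.g. instantaneous-jump) behaviour of the clustering.
    """
    half = assignments[assignments["frame"] % 2 == 0].copy()
    half["frame"] = half["frame"] // 2
    n_nodes = int(assignments["node"].max()) + 1

    offsets = {}
    profiles = {}
    for label, (table, lag) in {
        "lag1": (assignments, dt),
        "lag2": (half, 2 * dt),
    }.items():
        net = symmetrize(build_network(table, dt=lag, n_nodes=n_nodes))
        keep = net.Z_i > 0
        net = restrict_nodes(net, keep)
        if reference == "most_populated":
            ref = int(np.argmax(net.Z_i))
        else:
            ref = int(np.flatnonzero(net.node_ids == reference)[0])
        comp = _component_of(net, ref)
        if comp.sum() < net.n_nodes:
            ref = int(np.flatnonzero(np.flatnonzero(comp) == ref)[0])
            net = restrict_nodes(net, comp)
        mfpt = solve_mfpt(net, ref)
        profiles[label] = cut_profile(net, mfpt, temperature=temperature)

    p1 = profiles["lag1"].points
    p2 = profiles["lag2"].points
    f1 = p1[~p1["infinite"]]
    f2 = p2[~p2["infinite"]]
    lo = max(x_range[0], f1["x"].min(), f2["x"].min())
    hi = min(x_range[1], f1["x"].max(), f2["x"].max())
    grid = np.linspace(lo, hi, 201)
    y1 = np.interp(grid, f1["x"], f1["y_kT"])
    y2 = np.interp(grid, f2["x"], f2["y_kT"])
    offset = float(np.median(y1 - y2))
    return DiffusivityReport(
        offset_kT=offset,
        expected_kT=float(DIFFUSIVE_LAG2_OFFSET_KT),
        relative_deviation=float(
            abs(offset - DIFFUSIVE_LAG2_OFFSET_KT) / DIFFUSIVE_LAG2_OFFSET_KT
        ),
        n_shared_points=len(grid),
    )


def write_profile_tsv(profile: CutFEP, path) -> None:
    profile.points.to_csv(path, sep="\t", index=False, float_format="%.10g")
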