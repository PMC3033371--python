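"""Synthetic unbinding trajectories with exact ground truth.

The generator emulates the free-energy landscape of a small ligand leaving a
protein binding site: a bound region made of several metastable subbasins
(binding modes) separated by low barriers, a single dominant unbinding barrier,
and an unbound region in which the ligand can either rebind or drift away until
the run is stopped.  The dynamics are a discrete-time Markov chain whose states
carry a center-of-mass (COM) distance, so every downstream quantity — mean
first passage times, cut-based profile barriers, committor probabilities,
unbinding times — has an exact, enumerable reference value.

States of the generated chain:

* ``n_subbasins * n_micro`` bound micro-states (COM < 10 Å), grouped into
  subbasins with relative stationary weights ``basin_weights``;
* one "near-rim" unbound state at 16 Å, reached by crossing the unbinding
  barrier (``escape_prob`` per step) and from which the ligand rebinds with
  ``rebind_prob`` per step;
* one "far" state at 32 Å that triggers the stop rule, mirroring simulation
  protocols that terminate a run once the intermolecular distance exceeds 30 Å.

The chain is reversible by construction (Metropolis moves within the bound
region, weight-proportional rebinding), so its stationary distribution is known
in closed form and detailed-balance symmetrization of counted transitions is
exact in expectation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

__all__ = [
    "LandscapeSpec",
    "GroundTruth",
    "MarkovChain",
    "TrajectorySet",
    "EnergyModel",
    "build_markov_landscape",
    "ladder_landscape",
    "funnel_landscape",
    "emit_trajectories",
    "embed_geometry",
]

NEAR_RIM_COM = 16.0
FAR_COM = 32.0


@dataclass(frozen=True)
class LandscapeSpec:
    """Parameters of the generating landscape.

    Per-step probabilities are dimensionless (one step = one saving interval
    ``dt``).  The invariant ``escape_prob << intra_hop`` encodes the defining
    feature of the landscape: equilibration among binding modes is much faster
    than unbinding, which is what produces single-exponential dissociation
    kinetics.

    Parameters
    ----------
    n_subbasins : number of metastable bound subbasins (binding modes).
    basin_weights : relative stationary probabilities of the subbasins
        (normalized internally; default equal).
    intra_hop : per-step proposal probability of hopping between two subbasins.
    escape_prob : per-step probability of crossing the unbinding barrier from a
        bound micro-state into the near-rim unbound state.
    rebind_prob : per-step probability of re-entering the bound region from the
        near-rim state.
    advance_prob, return_prob : near-rim <-> far kinetics of the unbound region.
    n_micro : micro-states per subbasin; >1 gives each binding mode internal
        structure so that cut-profile subbasin detection has within-basin flux
        to contrast against between-basin flux.
    micro_hop : per-step hop probability between micro-states of one subbasin.
    dt : saving interval in ps.
    seed : RNG seed controlling every emission derived from this spec.
    """

    n_subbasins: int = 3
    basin_weights: tuple[float, ...] | None = None
    intra_hop: float = 0.05
    escape_prob: float = 1e-3
    rebind_prob: float = 0.05
    advance_prob: float = 0.02
    return_prob: float = 0.01
    n_micro: int = 1
    micro_hop: float = 0.25
    dt: float = 4.0
    seed: int = 2011

    def weights(self) -> np.ndarray:
        w = (
            np.ones(self.n_subbasins)
            if self.basin_weights is None
            else np.asarray(self.basin_weights, dtype=float)
        )
        if len(w) != self.n_subbasins or np.any(w <= 0):
            raise ValueError("basin_weights must be positive, one per subbasin")
        return w / w.sum()

    def validate(self) -> None:
        probs = [
            self.intra_hop,
            self.escape_prob,
            self.rebind_prob,
            self.advance_prob,
            self.return_prob,
            self.micro_hop,
        ]
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all per-step probabilities must lie in [0, 1]")
        if self.n_subbasins < 1 or self.n_micro < 1:
            raise ValueError("n_subbasins and n_micro must be >= 1")
        if self.n_subbasins > 1 and self.intra_hop == 0.0:
            raise ValueError("reducible bound region: intra_hop = 0 with >1 subbasin")
        if self.n_subbasins > 1 and not self.escape_prob < self.intra_hop:
            raise ValueError(
                "escape_prob must be << intra_hop (bound-state equilibration "
                "faster than unbinding)"
            )
        if self.dt <= 0:
            raise ValueError("dt must be positive")


class MarkovChain:
    """Discrete-state generating chain with per-state COM distances."""

    def __init__(
        self,
        P: np.ndarray,
        com: np.ndarray,
        bound_mask: np.ndarray,
        dt: float,
        state_names: Sequence[str] | None = None,
        stop_states: Sequence[int] = (),
    ):
        P = np.asarray(P, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("P must be square")
        if np.any(P < -1e-12):
            raise ValueError("negative transition probability")
        rows = P.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-10):
            raise ValueError("rows of P must sum to 1 (remainder is the self-move)")
        self.P = P
        self.com = np.asarray(com, dtype=float)
        self.bound_mask = np.asarray(bound_mask, dtype=bool)
        self.dt = float(dt)
        self.n_states = P.shape[0]
        self.state_names = (
            list(state_names)
            if state_names is not None
            else [f"s{i}" for i in range(self.n_states)]
        )
        self.stop_states = tuple(stop_states)

    # ---- exact quantities -------------------------------------------------

    def stationary(self) -> np.ndarray:
        """Stationary distribution (unique; the chain is irreducible)."""
        n = self.n_states
        A = np.vstack([self.P.T - np.eye(n), np.ones(n)])
        b = np.zeros(n + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()

    def hitting_time(self, target: np.ndarray) -> np.ndarray:
        """Exact mean hitting time (ps) of the target set from every state."""
        target = np.asarray(target, dtype=bool)
        t = np.zeros(self.n_states)
        free = ~target
        Q = self.P[np.ix_(free, free)]
        t[free] = np.linalg.solve(np.eye(Q.shape[0]) - Q, self.dt * np.ones(Q.shape[0]))
        return t

    def committor_within(self, horizon_steps: int, target: np.ndarray) -> np.ndarray:
        """P(hit target within ``horizon_steps`` steps | start), exactly.

        The target is absorbing for the purpose of the recursion; this is the
        finite-horizon analogue of the splitting probability and is the
        quantity the trajectory-based unbinding probability estimates.
        """
        target = np.asarray(target, dtype=bool)
        g = target.astype(float)
        for _ in range(int(horizon_steps)):
            g = np.where(target, 1.0, self.P @ g)
        return g

    def expected_counts(self, total_transitions: float) -> np.ndarray:
        """Expected transition-count matrix at equilibrium (already symmetric
        for a reversible chain after detailed-balance averaging)."""
        pi = self.stationary()
        C = pi[:, None] * self.P
        C = 0.5 * (C + C.T)
        return C * (total_transitions / C.sum())

    # ---- sampling ---------------------------------------------------------

    def simulate(
        self,
        n_runs: int,
        max_len: int,
        rng: np.random.Generator,
        initial: np.ndarray | str = "most_populated_bound",
        stop_states: Sequence[int] | None = None,
    ) -> list[np.ndarray]:
        """Sample ``n_runs`` label sequences, each stopped at ``max_len`` or on
        first visit to a stop state (the visit itself is recorded).

        Vectorized over runs: all active runs advance one step per iteration.
        """
        if n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if max_len < 1:
            raise ValueError("max_len must be >= 1")
        stop = set(self.stop_states if stop_states is None else stop_states)
        stop_arr = np.zeros(self.n_states, dtype=bool)
        for s in stop:
            stop_arr[s] = True

        cur = self._initial_states(n_runs, rng, initial)
        cum = np.cumsum(self.P, axis=1)
        out = np.full((n_runs, max_len), -1, dtype=np.int32)
        lengths = np.full(n_runs, max_len, dtype=np.int64)
        active = np.ones(n_runs, dtype=bool)
        for t in range(max_len):
            out[active, t] = cur[active]
            hit = active & stop_arr[cur]
            lengths[hit] = t + 1
            active = active & ~hit
            if t == max_len - 1 or not active.any():
                break
            u = rng.random(int(active.sum()))
            rows = cum[cur[active]]
            cur[active] = (rows < u[:, None]).sum(axis=1)
        return [out[i, : lengths[i]].copy() for i in range(n_runs)]

    def _initial_states(
        self, n_runs: int, rng: np.random.Generator, initial: np.ndarray | str
    ) -> np.ndarray:
        if isinstance(initial, str):
            pi = self.stationary()
            if initial == "most_populated_bound":
                s0 = int(np.argmax(np.where(self.bound_mask, pi, -1.0)))
                return np.full(n_runs, s0, dtype=np.int64)
            if initial == "stationary":
                p = pi
            elif initial == "stationary_bound":
                p = np.where(self.bound_mask, pi, 0.0)
                p = p / p.sum()
            else:
                raise ValueError(f"unknown initial-state rule {initial!r}")
            return rng.choice(self.n_states, size=n_runs, p=p)
        initial = np.asarray(initial)
        if initial.shape == (self.n_states,):
            p = initial / initial.sum()
            return rng.choice(self.n_states, size=n_runs, p=p)
        return np.broadcast_to(initial, (n_runs,)).astype(np.int64).copy()


@dataclass
class GroundTruth:
    """Exact reference values for the generating chain.

    Everything here is derived analytically (linear algebra or exhaustive
    enumeration), never by sampling.
    """

    true_tau: float  # expected unbinding time (ps), bound-conditional start
    true_committor: np.ndarray  # per-state P(unbind within default horizon)
    committor_horizon_steps: int
    true_profile_x: np.ndarray  # Z_A/Z at every mfpt-ordered cut
    true_profile_y: np.ndarray  # -ln(Z_AB/Z) in kT at every cut
    profile_order: np.ndarray  # state ids in cut order
    stationary: np.ndarray
    chain: MarkovChain

    def committor(self, horizon_steps: int) -> np.ndarray:
        """Exact finite-horizon unbinding probability per state."""
        return self.chain.committor_within(horizon_steps, ~self.chain.bound_mask)


def _metropolis_block(weights: np.ndarray, proposal: np.ndarray) -> np.ndarray:
    """Off-diagonal transition probabilities satisfying detailed balance with
    respect to ``weights`` given a symmetric proposal matrix."""
    w = weights
    acc = np.minimum(1.0, w[None, :] / w[:, None])
    T = proposal * acc
    np.fill_diagonal(T, 0.0)
    return T


def build_markov_landscape(spec: LandscapeSpec) -> tuple[MarkovChain, GroundTruth]:
    """Construct the generating chain and its exact ground truth.

    Raises
    ------
    ValueError
        If the spec invariants fail or the bound region is reducible.
    """
    spec.validate()
    K, m = spec.n_subbasins, spec.n_micro
    nb = K * m
    n = nb + 2  # + near-rim, far
    NEAR, FAR = nb, nb + 1

    w_basin = spec.weights()
    w_state = np.repeat(w_basin / m, m)  # relative weights of bound micro-states
    basin_of = np.repeat(np.arange(K), m)

    # symmetric proposal: micro_hop within a subbasin, intra_hop/m across
    prop = np.where(
        basin_of[:, None] == basin_of[None, :], spec.micro_hop, spec.intra_hop / m
    )
    T_bound = _metropolis_block(w_state, prop)

    P = np.zeros((n, n))
    P[:nb, :nb] = T_bound
    P[:nb, NEAR] = spec.escape_prob
    P[NEAR, :nb] = spec.rebind_prob * w_state / w_state.sum()
    P[NEAR, FAR] = spec.advance_prob
    P[FAR, NEAR] = spec.return_prob
    diag = 1.0 - P.sum(axis=1)
    if np.any(diag < -1e-12):
        raise ValueError("outgoing probabilities exceed 1 for some state")
    P[np.diag_indices(n)] = np.clip(diag, 0.0, 1.0)

    # reducibility check on the bound block
    adj = (T_bound > 0).astype(int)
    ncomp, _ = connected_components(adj, directed=False)
    if nb > 1 and ncomp > 1:
        raise ValueError("reducible bound region: no path between some subbasins")

    com = np.empty(n)
    if K == 1:
        basin_com = np.array([4.0])
    else:
        basin_com = np.linspace(3.0, 8.0, K)
    rng = np.random.default_rng(spec.seed)
    jitter = 0.2 * rng.standard_normal(nb) if m > 1 else np.zeros(nb)
    com[:nb] = np.clip(basin_com[basin_of] + jitter, 1.0, 9.5)
    com[NEAR], com[FAR] = NEAR_RIM_COM, FAR_COM

    bound_mask = np.zeros(n, dtype=bool)
    bound_mask[:nb] = True
    names = [f"b{basin_of[i]}.{i % m}" for i in range(nb)] + ["near", "far"]
    chain = MarkovChain(P, com, bound_mask, spec.dt, names, stop_states=(FAR,))

    pi = chain.stationary()
    t_hit = chain.hitting_time(~bound_mask)
    p_bound = pi[:nb] / pi[:nb].sum()
    true_tau = float(p_bound @ t_hit[:nb])

    horizon = max(1, int(round(800.0 / spec.dt)))  # default 0.8 ns commitment time
    q = chain.committor_within(horizon, ~bound_mask)

    if n <= 20:
        x, y, order = _exact_cut_profile(chain)
    else:
        x = y = order = np.array([])

    gt = GroundTruth(
        true_tau=true_tau,
        true_committor=q,
        committor_horizon_steps=horizon,
        true_profile_x=x,
        true_profile_y=y,
        profile_order=order,
        stationary=pi,
        chain=chain,
    )
    return chain, gt


def _exact_cut_profile(chain: MarkovChain) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exhaustively enumerate every mfpt-ordered cut of the chain using exact
    expected counts (the sampling-free reference for the cut-based profile)."""
    pi = chain.stationary()
    C = pi[:, None] * chain.P
    C = 0.5 * (C + C.T)
    Z = C.sum()
    ref = int(np.argmax(np.where(chain.bound_mask, pi, -1.0)))
    target = np.zeros(chain.n_states, dtype=bool)
    target[ref] = True
    mfpt = chain.hitting_time(target)
    order = np.argsort(mfpt, kind="stable")
    xs, ys = [], []
    for k in range(1, chain.n_states):
        A = order[:k]
        B = order[k:]
        z_a = C[A, :].sum()
        z_ab = C[np.ix_(A, B)].sum()
        xs.append(z_a / Z)
        ys.append(-np.log(z_ab / Z) if z_ab > 0 else np.inf)
    return np.asarray(xs), np.asarray(ys), order


def ladder_landscape(
    escape_prob: float,
    n_transit: int = 10,
    forward: float = 0.12,
    backward: float = 0.18,
    reentry: float = 0.30,
    rebind_prob: float = 0.05,
    advance_prob: float = 0.05,
    return_prob: float = 0.01,
    dt: float = 4.0,
    transit_com: tuple[float, float] = (5.0, 14.0),
) -> MarkovChain:
    """Bound well + 1-D transit ladder toward the unbound region.

    A transit-resolved variant of the landscape used for committor and
    transition-state studies: the unbinding barrier is climbed through
    ``n_transit`` nearest-neighbour states with COM distances spanning
    ``transit_com``, biased back toward the well (``backward > forward``).
    ``escape_prob`` (well -> first rung) sets the bound-state depth, so a
    family of chains differing only in ``escape_prob`` represents ligands of
    different affinity on an otherwise identical landscape.
    """
    if n_transit < 2:
        raise ValueError("need at least 2 transit states")
    n = 1 + n_transit + 2  # well, ladder, near-rim, far
    WELL, NEAR, FAR = 0, 1 + n_transit, 2 + n_transit
    P = np.zeros((n, n))
    P[WELL, 1] = escape_prob
    P[1, WELL] = reentry
    for r in range(1, n_transit + 1):
        if r < n_transit:
            P[r, r + 1] = forward
        else:
            P[r, NEAR] = forward
        if r > 1:
            P[r, r - 1] = backward
    P[NEAR, n_transit] = rebind_prob
    P[NEAR, FAR] = advance_prob
    P[FAR, NEAR] = return_prob
    diag = 1.0 - P.sum(axis=1)
    if np.any(diag < 0):
        raise ValueError("ladder probabilities exceed 1; reduce rates")
    P[np.diag_indices(n)] = diag

    com = np.empty(n)
    com[WELL] = 3.0
    com[1 : n_transit + 1] = np.linspace(*transit_com, n_transit)
    com[NEAR], com[FAR] = NEAR_RIM_COM, FAR_COM
    bound = com < 15.0
    names = ["well"] + [f"t{r}" for r in range(1, n_transit + 1)] + ["near", "far"]
    return MarkovChain(P, com, bound, dt, names, stop_states=(FAR,))


def funnel_landscape(
    escape_prob: float,
    n_layers: int = 8,
    states_per_layer: int = 16,
    structure_seed: int = 101,
    forward: tuple[float, float] = (0.25, 0.49),
    backward: tuple[float, float] = (0.25, 0.49),
    rebind_prob: float = 0.30,
    advance_prob: float = 0.01,
    return_prob: float = 0.01,
    dt: float = 4.0,
    transit_com: tuple[float, float] = (5.0, 14.0),
) -> MarkovChain:
    """Layered funnel between the bound well and the unbound region.

    Transit states are organised in layers with heterogeneous random
    forward/backward rates (drawn once from ``structure_seed``), giving a
    dense spectrum of committor values while keeping the barrier traverse
    fast; parallel routes through the layers emulate the multiple unbinding
    pathways seen in unbinding networks.  Each transit state's COM distance
    is assigned by the rank of its splitting probability toward the unbound
    side, so the geometric coordinate faithfully orders kinetic progress (the
    funnel property).  ``escape_prob`` (well -> first layer) sets the
    bound-state depth; chains differing only in ``escape_prob`` represent
    ligands of different affinity on an identical transit landscape.
    """
    rng = np.random.default_rng(structure_seed)
    nt = n_layers * states_per_layer
    WELL, NEAR, FAR = 0, 1 + nt, 2 + nt
    n = nt + 3
    P = np.zeros((n, n))

    def idx(layer: int, s: int) -> int:
        return 1 + layer * states_per_layer + s

    for layer in range(n_layers):
        for s in range(states_per_layer):
            i = idx(layer, s)
            ftot = rng.uniform(*forward)
            btot = rng.uniform(*backward)
            if layer < n_layers - 1:
                tgt = rng.choice(states_per_layer, 3, replace=False)
                wts = rng.dirichlet(np.ones(3))
                for t, wt in zip(tgt, wts):
                    P[i, idx(layer + 1, t)] += ftot * wt
            else:
                P[i, NEAR] = ftot
            if layer > 0:
                tgt = rng.choice(states_per_layer, 3, replace=False)
                wts = rng.dirichlet(np.ones(3))
                for t, wt in zip(tgt, wts):
                    P[i, idx(layer - 1, t)] += btot * wt
            else:
                P[i, WELL] = btot
    first = [idx(0, s) for s in range(states_per_layer)]
    last = [idx(n_layers - 1, s) for s in range(states_per_layer)]
    P[WELL, first] = escape_prob / states_per_layer
    P[NEAR, last] = rebind_prob / states_per_layer
    P[NEAR, FAR] = advance_prob
    P[FAR, NEAR] = return_prob
    P[np.diag_indices(n)] = 0.0
    diag = 1.0 - P.sum(axis=1)
    if np.any(diag < -1e-12):
        raise ValueError("funnel rates exceed 1 for some state; reduce rate ranges")
    P[np.diag_indices(n)] = np.clip(diag, 0.0, 1.0)

    # COM by rank of the exact splitting probability toward the unbound side
    trans = np.arange(1, nt + 1)
    Q = P[np.ix_(trans, trans)]
    r = P[trans, NEAR] + P[trans, FAR]
    q_split = np.linalg.solve(np.eye(nt) - Q, r)
    com = np.empty(n)
    com[WELL], com[NEAR], com[FAR] = 3.0, NEAR_RIM_COM, FAR_COM
    ranks = np.argsort(np.argsort(q_split))
    com[trans] = transit_com[0] + (transit_com[1] - transit_com[0]) * ranks / (nt - 1)
    bound = com < 15.0
    names = (
        ["well"]
        + [f"L{layer}.{s}" for layer in range(n_layers) for s in range(states_per_layer)]
        + ["near", "far"]
    )
    return MarkovChain(P, com, bound, dt, names, stop_states=(FAR,))


# ---------------------------------------------------------------------------
# trajectory containers and emission
# ---------------------------------------------------------------------------


@dataclass
class TrajectorySet:
    """Time-ordered multi-run snapshot table.

    ``frames`` columns: run_id, frame, time plus whichever feature columns are
    present (state_truth, com_distance, d_1..d_N, e_elec, e_vdw).  Frames are
    strictly increasing within a run; run boundaries are the run_id changes.
    """

    frames: pd.DataFrame
    dt: float

    @property
    def distance_cols(self) -> list[str]:
        return [c for c in self.frames.columns if c.startswith("d_")]

    @property
    def n_runs(self) -> int:
        return self.frames["run_id"].nunique()

    def run_lengths(self) -> pd.Series:
        return self.frames.groupby("run_id").size()

    def to_tsv(self, path) -> None:
        self.frames.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, dt: float) -> "TrajectorySet":
        return cls(pd.read_csv(path, sep="\t"), dt=dt)


def emit_trajectories(
    chain: MarkovChain,
    n_runs: int,
    max_len: int,
    stop_rule: str | None = "stop_states",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    initial: np.ndarray | str = "most_populated_bound",
) -> TrajectorySet:
    """Sample a multi-run label trajectory set from the generating chain.

    ``stop_rule`` is ``"stop_states"`` (terminate on the chain's designated
    stop states, i.e. the 30 Å-style distance cutoff) or ``None`` (always run
    to ``max_len``).  The RNG is fully determined by ``seed``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    stop = chain.stop_states if stop_rule == "stop_states" else ()
    runs = chain.simulate(n_runs, max_len, rng, initial=initial, stop_states=stop)
    parts = []
    for i, labels in enumerate(runs):
        f = np.arange(len(labels))
        parts.append(
            pd.DataFrame(
                {
                    "run_id": i,
                    "frame": f,
                    "time": f * chain.dt,
                    "state_truth": labels,
                }
            )
        )
    return TrajectorySet(pd.concat(parts, ignore_index=True), dt=chain.dt)


@dataclass(frozen=True)
class EnergyModel:
    """State-conditional Gaussian interaction energies (kcal/mol).

    Bound states carry favourable means relative to the unbound baseline; the
    planted bound-minus-unbound deltas are therefore exactly
    ``(bound_elec, bound_vdw)`` minus ``(unbound_elec, unbound_vdw)``.
    """

    bound_elec: float = -2.0
    bound_vdw: float = -5.0
    unbound_elec: float = 0.0
    unbound_vdw: float = 0.0
    sigma: float = 1.0


def state_centroids(
    n_states: int, n_distances: int, separation: float = 4.0, seed: int = 0
) -> np.ndarray:
    """Deterministic per-state distance-vector centroids with guaranteed
    pairwise DRMS separation of at least ``separation - 1`` Å."""
    rng = np.random.default_rng(seed)
    base = 5.0 + rng.random(n_distances)
    cent = base[None, :] + separation * np.arange(n_states)[:, None]
    cent += 0.5 * (rng.random((n_states, n_distances)) - 0.5)
    return cent


def embed_geometry(
    ts: TrajectorySet,
    chain: MarkovChain,
    n_distances: int = 10,
    noise: float = 0.25,
    com_noise: float = 0.25,
    with_distances: bool = True,
    with_energies: bool = False,
    energy_model: EnergyModel = EnergyModel(),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> TrajectorySet:
    """Attach geometric (and optionally energetic) observables to labels.

    Each snapshot's distance vector is its state centroid plus isotropic
    Gaussian noise; its COM distance is the state's COM plus noise.  Rejects
    centroid sets whose pairwise DRMS separation is below 3x the within-state
    noise scale (``sqrt(2) * noise``), because leader clustering could not
    recover the planted states in that regime.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    labels = ts.frames["state_truth"].to_numpy()
    n_snap = len(labels)
    out = ts.frames.copy()

    out["com_distance"] = chain.com[labels] + (
        com_noise * rng.standard_normal(n_snap) if com_noise > 0 else 0.0
    )

    if with_distances:
        cent = state_centroids(chain.n_states, n_distances, seed=seed or 0)
        diffs = cent[:, None, :] - cent[None, :, :]
        d2 = (diffs**2).mean(axis=2) ** 0.5
        np.fill_diagonal(d2, np.inf)
        min_sep = d2.min()
        noise_scale = np.sqrt(2.0) * noise
        if noise > 0 and min_sep <= 3.0 * noise_scale:
            raise ValueError(
                f"centroid DRMS separation {min_sep:.2f} Å is below 3x the "
                f"within-state noise scale {noise_scale:.2f} Å; planted states "
                "would not be recoverable"
            )
        X = cent[labels]
        if noise > 0:
            X = X + noise * rng.standard_normal(X.shape)
        for j in range(n_distances):
            out[f"d_{j + 1}"] = X[:, j]

    if with_energies:
        bound = chain.bound_mask[labels]
        mu_e = np.where(bound, energy_model.bound_elec, energy_model.unbound_elec)
        mu_v = np.where(bound, energy_model.bound_vdw, energy_model.unbound_vdw)
        out["e_elec"] = mu_e + energy_model.sigma * rng.standard_normal(n_snap)
        out["e_vdw"] = mu_v + energy_model.sigma * rng.standard_normal(n_snap)

    return TrajectorySet(out, dt=ts.dt)


def write_ground_truth(gt: GroundTruth, path) -> None:
    """Key-value sidecar with the exact reference values."""
    import yaml

    payload = {
        "true_tau_ps": float(gt.true_tau),
        "committor_horizon_steps": int(gt.committor_horizon_steps),
        "true_committor": [float(v) for v in gt.true_committor],
        "stationary": [float(v) for v in gt.stationary],
        "true_profile_x": [float(v) for v in gt.true_profile_x],
        "true_profile_y_kT": [float(v) for v in gt.true_profile_y],
        "state_com_A": [float(v) for v in gt.chain.com],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def spec_to_dict(spec: LandscapeSpec) -> dict:
    return dataclasses.asdict(spec)
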