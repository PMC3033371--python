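"""Unbinding probability, TSE selection, Hammond comparison."""

import warnings

import numpy as np
import pandas as pd
import pytest

from unbindnet.cfep import MfptVector, solve_mfpt
from unbindnet.committor import (
    CommittorTable,
    commitment_sweep,
    hammond_shift,
    mfpt_distance_correlation,
    node_committor,
    select_tse,
)
from unbindnet.network import network_from_counts
from unbindnet.synthetic import (
    LandscapeSpec,
    build_markov_landscape,
    emit_trajectories,
    funnel_landscape,
)


def assignment_frame(com_series_per_run, node_per_run, dt=4.0):
    rows = []
    for rid, (coms, nodes) in enumerate(zip(com_series_per_run, node_per_run)):
        for f, (c, n) in enumerate(zip(coms, nodes)):
            rows.append(
                {"run_id": rid, "frame": f, "time": f * dt, "node": n,
                 "com_distance": c}
            )
    return pd.DataFrame(rows)


class TestNodeCommittor:
    def test_all_members_unbind_gives_unit_probability(self):
        # 10 runs, node 0 at frame 0, crossing at frame 2, long tail
        coms = [[5, 5, 16] + [16] * 3 for _ in range(10)]
        nodes = [[0, 1, 2, 2, 2, 2] for _ in range(10)]
        df = assignment_frame(coms, nodes)
        tab = node_committor(df, commitment_time=8.0, dt=4.0)
        row = tab.nodes.set_index("node_id").loc[0]
        assert row["p_u"] == 1.0 and row["n_snapshots"] == 10

    def test_half_crossing_node(self):
        coms = [[5, 16, 16] if r < 5 else [5, 5, 5] for r in range(10)]
        nodes = [[0, 1, 1] for _ in range(10)]
        df = assignment_frame(coms, nodes)
        tab = node_committor(df, commitment_time=8.0, dt=4.0)
        assert tab.nodes.set_index("node_id").loc[0, "p_u"] == 0.5
        # fewer than 20 snapshots -> excluded from the TSE
        with pytest.warns(RuntimeWarning, match="empty TSE"):
            tse = select_tse(tab)
        assert len(tse.nodes) == 0

    def test_horizon_shorter_than_dt_rejected(self):
        df = assignment_frame([[5, 5, 5]], [[0, 0, 0]])
        with pytest.raises(ValueError, match="commitment_time"):
            node_committor(df, commitment_time=1.0, dt=4.0)

    def test_snapshots_near_run_end_are_excluded(self):
        df = assignment_frame([[5.0] * 6], [[0] * 6])
        tab = node_committor(df, commitment_time=8.0, dt=4.0)
        # frames 0..3 have a full 2-frame horizon; 4,5 do not
        assert tab.nodes.loc[0, "n_snapshots"] == 4

    def test_post_unbinding_snapshots_not_scored_until_rebound(self):
        coms = [[5, 16, 12, 9, 5, 5, 5, 5, 5, 5]]
        nodes = [[0] * 10]
        df = assignment_frame(coms, nodes)
        tab = node_committor(df, commitment_time=8.0, dt=4.0)
        # frame 0 (pre-unbind) + frames 3..7 (after rebind at 9 Å) scored
        assert tab.nodes.loc[0, "n_snapshots"] == 6

    def test_p_u_monotone_in_commitment_time(self):
        """Successes within a shorter horizon are a subset of those within a
        longer one, node by node."""
        chain, _ = build_markov_landscape(LandscapeSpec(escape_prob=5e-3, seed=3))
        ts = emit_trajectories(chain, 50, 800, stop_rule=None, seed=41)
        df = ts.frames.rename(columns={"state_truth": "node"})
        df["com_distance"] = chain.com[df["node"].to_numpy()]
        tabs = [
            node_committor(df, commitment_time=tc, dt=4.0).nodes.set_index("node_id")
            for tc in (200.0, 400.0, 800.0)
        ]
        shared = set.intersection(*(set(t.index) for t in tabs))
        for n in shared:
            p = [t.loc[n, "p_u"] for t in tabs]
            # note: eligible snapshot sets shrink with horizon; compare on the
            # common eligibility by tolerance
            assert p[0] <= p[1] + 0.05 and p[1] <= p[2] + 0.05

    def test_matches_exact_committor_on_generating_chain(self):
        """Sampled p_u within 3 binomial SE of the exact finite-horizon
        commitment probability (independent short-run protocol)."""
        chain, gt = build_markov_landscape(LandscapeSpec(escape_prob=2e-3, seed=5))
        H = 50
        ts = emit_trajectories(
            chain, 4000, H + 1, stop_rule=None, seed=51, initial="stationary_bound"
        )
        df = ts.frames.rename(columns={"state_truth": "node"})
        df["com_distance"] = chain.com[df["node"].to_numpy()]
        tab = node_committor(df, commitment_time=H * 4.0, dt=4.0).nodes
        q = gt.committor(H)
        for _, row in tab.iterrows():
            if row["n_snapshots"] < 50:
                continue
            p = q[int(row["node_id"])]
            se = np.sqrt(max(p * (1 - p), 1e-12) / row["n_snapshots"])
            assert abs(row["p_u"] - p) <= 3 * se + 1e-12


class TestSelectTse:
    def _table(self, p_u, n_snap, z):
        nodes = pd.DataFrame(
            {
                "node_id": np.arange(len(p_u)),
                "p_u": p_u,
                "n_snapshots": n_snap,
                "n_unbinding": (np.array(p_u) * np.array(n_snap)).astype(int),
                "Z": z,
                "mean_com": np.linspace(5, 14, len(p_u)),
            }
        )
        return CommittorTable(nodes=nodes, commitment_time=800.0, unbind_cut=15.0)

    def test_band_and_population_filters(self):
        tab = self._table([0.1, 0.5, 0.5, 0.9], [100, 100, 5, 100], [50, 50, 50, 50])
        tse = select_tse(tab)
        assert tse.nodes["node_id"].tolist() == [1]

    def test_low_weight_node_excluded(self):
        tab = self._table([0.5, 0.5], [100, 100], [50, 3])
        tse = select_tse(tab)
        assert tse.nodes["node_id"].tolist() == [0]

    def test_empty_band_warns_with_diagnostics(self):
        tab = self._table([0.1, 0.9], [100, 100], [50, 50])
        with pytest.warns(RuntimeWarning, match="nearest committor"):
            tse = select_tse(tab)
        assert len(tse.nodes) == 0

    def test_selection_idempotent_and_order_independent(self):
        tab = self._table([0.5, 0.47, 0.9], [100, 30, 100], [50, 50, 50])
        tse1 = select_tse(tab)
        shuffled = CommittorTable(
            nodes=tab.nodes.sample(frac=1.0, random_state=0).reset_index(drop=True),
            commitment_time=800.0, unbind_cut=15.0,
        )
        tse2 = select_tse(shuffled)
        assert set(tse1.nodes["node_id"]) == set(tse2.nodes["node_id"])


class TestHammond:
    def test_identical_datasets_zero_shift(self):
        tab = pd.DataFrame(
            {"node_id": [0], "p_u": [0.5], "n_snapshots": [100],
             "n_unbinding": [50], "Z": [60.0], "mean_com": [9.0]}
        )
        from unbindnet.committor import TseReport

        rep = TseReport(nodes=tab, band=(0.45, 0.55), min_snapshots=20, min_weight=5)
        out = hammond_shift({"a": rep, "b": rep}, {"a": 1.0, "b": 2.0})
        assert out.per_dataset["tse_mean_com"].nunique() == 1

    def test_two_depths_shift_toward_destabilized_state(self):
        """Shallower well (larger escape) puts the isocommittor closer to the
        bound state along the COM coordinate — exact computation."""
        means = []
        for escape in (0.004, 0.02):
            ch = funnel_landscape(escape)
            q = ch.committor_within(200, ~ch.bound_mask)
            pi = ch.stationary()
            band = (q >= 0.45) & (q <= 0.55) & ch.bound_mask
            means.append(float(np.average(ch.com[band], weights=pi[band])))
        assert means[1] < means[0] - 0.3

    def test_needs_two_datasets(self):
        with pytest.raises(ValueError):
            hammond_shift({}, {})


class TestMfptDistanceCorrelation:
    def test_affine_relation_gives_unit_correlation(self):
        m = MfptVector(mfpt=np.linspace(0, 100, 20), reference=0, dt=4.0)
        com = 3.0 + 0.1 * m.mfpt
        assert mfpt_distance_correlation(m, com) == pytest.approx(1.0)

    def test_funnel_landscape_exceeds_point_nine(self):
        """COM distance is a good kinetic predictor on a funnel."""
        ch = funnel_landscape(0.01)
        C = ch.expected_counts(1e6)
        net = network_from_counts(C, dt=4.0, node_com=ch.com)
        ref = int(np.argmax(net.Z_i))
        m = solve_mfpt(net, ref)
        r = mfpt_distance_correlation(m, ch.com, com_cutoff=30.0)
        assert r > 0.9

    def test_permuted_distances_decorrelate(self):
        rng = np.random.default_rng(8)
        mfpt = np.sort(rng.random(100)) * 1000
        com = 3 + 0.01 * mfpt
        m = MfptVector(mfpt=mfpt, reference=0, dt=4.0)
        r = mfpt_distance_correlation(m, rng.permutation(com))
        assert abs(r) < 0.2

    def test_needs_three_nodes(self):
        m = MfptVector(mfpt=np.array([0.0, 4.0]), reference=0, dt=4.0)
        with pytest.raises(ValueError):
            mfpt_distance_correlation(m, np.array([3.0, 5.0]))


def test_commitment_sweep_reports_each_time():
    chain, _ = build_markov_landscape(LandscapeSpec(escape_prob=5e-3, seed=9))
    ts = emit_trajectories(chain, 30, 1200, stop_rule=None, seed=61)
    df = ts.frames.rename(columns={"state_truth": "node"})
    df["com_distance"] = chain.com[df["node"].to_numpy()]
    out = commitment_sweep(df, (400.0, 800.0), dt=4.0)
    assert out["commitment_time_ps"].tolist() == [400.0, 800.0]
    assert (out["n_tse_snapshots"] >= 0).all()
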