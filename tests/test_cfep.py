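"""mfpt solver, cut profiles, subbasin detection, diffusivity check."""

import numpy as np
import pandas as pd
import pytest

from conftest import assignments_from_labels, simulate_fpt_mc
from unbindnet.cfep import (
    cut_profile,
    detect_subbasins,
    diffusivity_check,
    first_barrier_index,
    solve_mfpt,
)
from unbindnet.network import network_from_counts, restrict_nodes, symmetrize
from unbindnet.synthetic import (
    LandscapeSpec,
    MarkovChain,
    build_markov_landscape,
    emit_trajectories,
)


def two_state_network(p=0.5, dt=4.0, weight=1000.0):
    """Chain where node 1 moves to node 0 (reference) with probability p."""
    C = np.array([[weight, 0.0], [weight * p, weight * (1 - p)]])
    return network_from_counts(C, dt=dt)


class TestSolveMfpt:
    def test_reference_is_zero(self):
        net = two_state_network()
        assert solve_mfpt(net, 0).mfpt[0] == 0.0

    def test_two_state_closed_form_dt_over_p(self):
        net = two_state_network(p=0.5, dt=4.0)
        assert solve_mfpt(net, 0).mfpt[1] == pytest.approx(8.0, rel=1e-10)

    def test_random_chain_against_monte_carlo(self):
        """Linear-solve mfpt vs 20,000 simulated passages per node."""
        rng = np.random.default_rng(17)
        n = 6
        P = rng.random((n, n)) + 0.3 * np.eye(n)
        P /= P.sum(axis=1, keepdims=True)
        net = network_from_counts(P * 1000, dt=4.0)
        mfpt = solve_mfpt(net, 0).mfpt
        mc, se = simulate_fpt_mc(P, 0, 4.0, 20_000, rng)
        for i in range(1, n):
            assert abs(mfpt[i] - mc[i]) <= 3 * se[i], i

    def test_trapped_nodes_reported(self):
        C = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 5.0]])
        net = network_from_counts(C, dt=4.0)
        with pytest.raises(ValueError, match="cannot reach"):
            solve_mfpt(net, 0)


class TestCutProfile:
    def test_direct_arithmetic_barrier(self):
        """Z = 1000, cut crossed by 10 transitions -> y = -ln(0.01)."""
        C = np.array([[490.0, 10.0], [10.0, 490.0]])
        net = network_from_counts(C, dt=4.0)
        prof = cut_profile(net, np.array([0.0, 1.0]))
        assert prof.points.loc[0, "y_kT"] == pytest.approx(-np.log(0.01), rel=1e-12)

    def test_final_cut_reaches_x_one(self):
        net = two_state_network()
        prof = cut_profile(net, solve_mfpt(net, 0))
        assert prof.points["x"].iloc[-1] == pytest.approx(1.0)
        assert bool(prof.points["infinite"].iloc[-1])

    def test_matches_exhaustive_enumeration_on_random_chains(self):
        """Every cut value equals a brute-force double-loop computation."""
        rng = np.random.default_rng(23)
        for _ in range(5):
            n = rng.integers(4, 12)
            C = rng.random((n, n)) * 10
            C = 0.5 * (C + C.T)
            net = network_from_counts(C, dt=4.0)
            score = rng.permutation(n).astype(float)
            prof = cut_profile(net, score)
            Z = C.sum()
            order = np.argsort(score)
            for k, row in prof.points.iterrows():
                A = order[: k + 1]
                B = order[k + 1 :]
                z_a = C[A, :].sum()
                z_ab = C[np.ix_(A, B)].sum()
                assert row["x"] == pytest.approx(z_a / Z, rel=1e-12)
                if len(B):
                    assert row["y_kT"] == pytest.approx(-np.log(z_ab / Z), rel=1e-10)

    def test_invariance_under_monotone_transform_of_ordering(self):
        rng = np.random.default_rng(29)
        C = rng.random((9, 9)) * 5
        net = network_from_counts(C, dt=4.0)
        score = rng.random(9)
        a = cut_profile(net, score).points[["x", "y_kT"]]
        b = cut_profile(net, np.exp(3 * score) - 1).points[["x", "y_kT"]]
        pd.testing.assert_frame_equal(a, b)

    def test_profile_agrees_from_complement_side(self):
        """On a symmetrized network Z_AB is symmetric under A<->B."""
        rng = np.random.default_rng(31)
        C = symmetrize(network_from_counts(rng.random((7, 7)) * 8, dt=4.0))
        score = rng.random(7)
        fwd = cut_profile(C, score).points
        bwd = cut_profile(C, -score).points
        y_f = fwd["y_kT"].to_numpy()[:-1]
        y_b = bwd["y_kT"].to_numpy()[:-1][::-1]
        np.testing.assert_allclose(y_f, y_b, rtol=1e-10)

    def test_exact_profile_of_generating_chain(self, default_landscape):
        """cut_profile on the expected-count network reproduces the exhaustive
        ground-truth profile of the generating chain exactly."""
        _, chain, gt = default_landscape
        C = chain.expected_counts(1.0)
        net = network_from_counts(C, dt=chain.dt)
        ref = int(np.argmax(np.where(chain.bound_mask, gt.stationary, -1)))
        prof = cut_profile(net, solve_mfpt(net, ref))
        pts = prof.points
        np.testing.assert_allclose(pts["x"].to_numpy()[:-1], gt.true_profile_x, rtol=1e-9)
        np.testing.assert_allclose(
            pts["y_kT"].to_numpy()[:-1], gt.true_profile_y, rtol=1e-9
        )

    def test_symmetric_double_well_barrier_at_half(self):
        """Barrier cut of a symmetric two-basin chain sits at x = 0.5."""
        spec = LandscapeSpec(
            n_subbasins=2, basin_weights=(1, 1), n_micro=3, intra_hop=0.01,
            escape_prob=1e-4,
        )
        chain, _ = build_markov_landscape(spec)
        C = chain.expected_counts(1.0)
        bound = chain.bound_mask
        net = network_from_counts(
            C[np.ix_(bound, bound)], dt=4.0, node_com=chain.com[bound]
        )
        prof = cut_profile(net, solve_mfpt(net, 0))
        pts = prof.points[~prof.points["infinite"]]
        barrier_x = pts.loc[pts["y_kT"].idxmax(), "x"]
        w_node = net.Z_i.max() / net.Z
        assert abs(barrier_x - 0.5) <= w_node + 1e-9


class TestDetectSubbasins:
    def _bound_expected_network(self, spec, total=1e6):
        chain, _ = build_markov_landscape(spec)
        C = chain.expected_counts(total)
        bound = chain.bound_mask
        return chain, network_from_counts(
            C[np.ix_(bound, bound)], dt=4.0, node_com=chain.com[bound]
        )

    def test_single_basin_chain_gives_one_subbasin(self):
        spec = LandscapeSpec(n_subbasins=1, n_micro=4)
        _, net = self._bound_expected_network(spec)
        sb = detect_subbasins(net)
        assert sb.n_subbasins == 1
        assert (sb.labels == 0).all()

    def test_planted_three_subbasins_recovered(self):
        """Three binding modes with >=2 kT inter-mode barriers.

        Unequal weights keep the modes at distinct kinetic distances; with
        exactly equal weights two modes tie in mfpt and overlap on the
        profile (nodes at the same kinetic distance enter the cut together).
        """
        spec = LandscapeSpec(
            n_subbasins=3, basin_weights=(0.5, 0.3, 0.2), n_micro=4,
            micro_hop=0.2, intra_hop=0.004, escape_prob=1e-4, seed=12,
        )
        chain, net = self._bound_expected_network(spec)
        sb = detect_subbasins(net)
        assert sb.n_subbasins == 3
        # the recovered partition is exactly the planted basin structure
        basin_of = np.repeat(np.arange(3), 4)
        for k in range(3):
            members = np.unique(basin_of[sb.labels == k])
            assert len(members) == 1

    def test_tilted_two_basin_populations_match_weights(self):
        """Subbasin populations from sampled trajectories reproduce the
        planted stationary weights within multinomial error."""
        spec = LandscapeSpec(
            n_subbasins=2, basin_weights=(0.7, 0.3), n_micro=3, micro_hop=0.2,
            intra_hop=0.004, escape_prob=1e-4, seed=2,
        )
        chain, _ = build_markov_landscape(spec)
        from unbindnet.network import build_network

        ts = emit_trajectories(chain, 4, 25_000, stop_rule=None, seed=77,
                               initial="stationary_bound")
        df = ts.frames.rename(columns={"state_truth": "node"})
        df["com_distance"] = chain.com[df["node"].to_numpy()]
        net = symmetrize(build_network(df, dt=4.0, n_nodes=chain.n_states))
        net = restrict_nodes(net, chain.bound_mask & (net.Z_i > 0))
        sb = detect_subbasins(net)
        assert sb.n_subbasins == 2
        frac = np.sort(sb.populations / sb.populations.sum())[::-1]
        n_eff = 1000  # conservative for serially correlated sampling
        se = np.sqrt(0.7 * 0.3 / n_eff)
        assert abs(frac[0] - 0.7) < 4 * se


class TestDiffusivityCheck:
    def test_equal_lag_profiles_have_zero_offset(self):
        chain, _ = build_markov_landscape(LandscapeSpec(seed=6))
        ts = emit_trajectories(chain, 2, 4000, stop_rule=None, seed=15)
        df = ts.frames.rename(columns={"state_truth": "node"})
        rep1 = diffusivity_check(df, dt=4.0)
        rep2 = diffusivity_check(df, dt=4.0)
        assert rep1.offset_kT == rep2.offset_kT  # deterministic

    def test_two_state_jump_chain_fails_diffusive_expectation(self):
        """Instantaneous-jump dynamics: lag doubling shifts by ~ln 2, far from
        the diffusive (1/2) ln 2 (negative control)."""
        p = 0.05
        P = np.array([[1 - p, p], [p, 1 - p]])
        chain = MarkovChain(P, np.array([3.0, 20.0]), np.array([True, False]), 4.0)
        rng = np.random.default_rng(3)
        labels = chain.simulate(1, 200_000, rng, initial=np.array(0))[0]
        df = pd.DataFrame(
            {"run_id": 0, "frame": np.arange(len(labels)), "node": labels}
        )
        rep = diffusivity_check(df, dt=4.0)
        assert rep.relative_deviation > 0.2


def test_first_barrier_index_detects_peak_then_drop():
    pts = pd.DataFrame(
        {
            "x": np.linspace(0.1, 1.0, 6),
            "y_kT": [1.0, 3.0, 2.2, 4.0, 3.0, np.inf],
            "infinite": [False] * 5 + [True],
        }
    )
    from unbindnet.cfep import CutFEP

    prof = CutFEP(points=pts, temperature=310.0)
    assert first_barrier_index(prof, min_drop_kT=0.5) == 1
    assert first_barrier_index(prof, min_drop_kT=2.0) is None
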