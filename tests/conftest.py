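import numpy as np
import pandas as pd
import pytest

from unbindnet.synthetic import (
    LandscapeSpec,
    build_markov_landscape,
    embed_geometry,
    emit_trajectories,
)


@pytest.fixture(scope="session")
def default_landscape():
    """Default three-subbasin landscape with its exact ground truth."""
    spec = LandscapeSpec()
    chain, gt = build_markov_landscape(spec)
    return spec, chain, gt


@pytest.fixture(scope="session")
def small_trajectories(default_landscape):
    """A modest multi-run sample from the default landscape with geometry."""
    _, chain, _ = default_landscape
    ts = emit_trajectories(chain, n_runs=20, max_len=2000, seed=101)
    return embed_geometry(ts, chain, with_energies=True, seed=202)


def assignments_from_labels(ts, chain):
    """Assignment table using the generating states as nodes (exactly what a
    perfect clustering would recover)."""
    df = ts.frames[["run_id", "frame", "time"]].copy()
    df["node"] = ts.frames["state_truth"].to_numpy()
    df["com_distance"] = chain.com[df["node"].to_numpy()]
    return df


def simulate_fpt_mc(P, reference, dt, n_walkers, rng, max_steps=200_000):
    """Monte-Carlo first-passage oracle: mean and SE of the first passage time
    to ``reference`` from every state, fully independent of the linear solver."""
    n = P.shape[0]
    cum = np.cumsum(P, axis=1)
    means = np.zeros(n)
    ses = np.zeros(n)
    for start in range(n):
        if start == reference:
            continue
        cur = np.full(n_walkers, start)
        steps = np.zeros(n_walkers, dtype=np.int64)
        active = np.ones(n_walkers, dtype=bool)
        for _ in range(max_steps):
            u = rng.random(int(active.sum()))
            nxt = (cum[cur[active]] < u[:, None]).sum(axis=1)
            cur[active] = nxt
            steps[active] += 1
            active[active] = nxt != reference
            if not active.any():
                break
        assert not active.any(), "first-passage simulation hit the step cap"
        t = steps * dt
        means[start] = t.mean()
        ses[start] = t.std(ddof=1) / np.sqrt(n_walkers)
    return means, ses
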