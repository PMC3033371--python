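# unbindnet

Transition-network analysis of spontaneous ligand unbinding from multi-run
molecular-dynamics (or synthetic) trajectories: DRMS leader clustering,
cut-based free-energy profiles, unbinding kinetics, committor-based
transition-state identification, and linear-interaction-energy (LIE)
affinity estimation.

## The problem and the approach

Small, weakly binding ligands (fragment-like, mM–µM affinity) dissociate
spontaneously from a protein site within tens of nanoseconds, so an ensemble
of independent MD runs samples many unbinding (and some rebinding) events.
`unbindnet` turns such an ensemble into a quantitative picture of the
unbinding free-energy landscape:

* **Nodes**: snapshots are grouped by the *distance root mean square*
  DRMS(a,b) = √(1/N·Σ_k (a_k−b_k)²) over the N intermolecular heavy-atom
  distances (no structural superposition needed), using the single-pass
  leader algorithm at a 1 Å threshold.
* **Network**: direct transitions between consecutive frames (lag Δt = 4 ps,
  self-transitions included, none across run boundaries) give counts n_ij,
  node weights Z_i = Σ_j n_ij, and probabilities p_ij = n_ij/Z_i; detailed
  balance is imposed by n′_ij = (n_ij+n_ji)/2.
* **Profile**: mean first passage times to the most populated node solve
  mfpt_i = Δt + Σ_j p_ij·mfpt_j with mfpt_ref = 0; sweeping a cut through
  the mfpt ordering yields the cut-based free-energy profile
  (x, y) = (Z_A/Z, −kT·ln(Z_AB/Z)), which preserves barrier heights and is
  invariant under monotone reparameterization.  Iterative re-referencing
  decomposes the bound state into subbasins (binding modes).
* **Kinetics**: unbinding events (ligand–site COM separation > 15 Å) and
  rebinding events (< 10 Å) feed a single-exponential fit
  f(t) = 1 − e^(−t/τ) of the cumulative event fraction, with a split-half
  cross-validated error.
* **Transition state**: each node's unbinding probability p_u is the
  fraction of member snapshots that unbind within a 0.8 ns commitment time;
  nodes with p_u ∈ [0.45, 0.55] (≥ 20 snapshots, weight > 5) form the TSE.
  Comparing TSE positions across ligands quantifies Hammond behaviour:
  weaker binders have transition states closer to the bound pose.
* **Affinity**: ΔG ≈ 0.5·ΔE_elec + α·ΔE_vdw, averaging each ligand–
  surroundings term separately over bound and dissociated segments, with
  five-block errors and α fitted on neutral compounds (default 0.56).

A first-class synthetic-data module generates multi-run trajectories from
discrete-state landscapes (metastable subbasins, one dominant unbinding
barrier, rebinding, exponential unbinding times) whose mean first passage
times, cut profiles and committors are known *exactly* — every analysis
stage is validated against closed forms, exhaustive enumeration, or
Monte-Carlo oracles.  See `docs/methods.md` for the models and all numerical
choices.

## Worked example

```bash
python examples/03_unbinding_kinetics.py
```

prints (50 synthetic 20-ns runs on a landscape with true τ = 4 ns):

```
49 unbinding and 92 rebinding events in 50 runs
true tau      : 4.00 ns
fitted tau    : 4.01 ns
cross-validated: 3.86 ± 2.53 ns
```

The first line counts threshold crossings (15 Å out, 10 Å back in); the
fitted τ comes from the cumulative single-exponential fit; the ± value is
the mean absolute held-out error of the 100-fold split-half protocol (an
error estimate for a 25-run fit, hence large relative to τ).

The other examples each exercise one capability and print what the numbers
mean: `01` clustering recovery of planted states, `02` profile + subbasin
detection (recovers 3 planted binding modes with populations ≈ 0.5/0.3/0.2),
`04` committor vs exact commitment probabilities and TSE selection, `05` the
Hammond shift between a strong and a weak binder, `06` LIE totals and α
refitting, `07` the full pipeline from a YAML config with provenance
stamping.

A thin CLI mirrors the library (`unbindnet simulate | cluster | network |
cfep | kinetics | committor | lie | run`); `unbindnet run config.yaml`
executes every stage and writes TSV outputs plus a provenance manifest.

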