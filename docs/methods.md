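# Methods

`unbindnet` analyses time-ordered trajectories of a small ligand leaving a
protein binding site and reconstructs the free-energy landscape of unbinding:
the binding modes (subbasins) of the bound state, the height and position of
the dissociation barrier, the unbinding rate, the transition-state ensemble,
and a linear-interaction-energy estimate of the binding affinity.  This note
records the models, the parameters that matter, the numerical choices, and
what the synthetic benchmarks do and do not demonstrate.

## Transition networks from snapshots

Snapshots are compared by the distance root mean square (DRMS) over the N
intermolecular heavy-atom distances between the ligand and the site residues:

    DRMS(a, b) = sqrt( (1/N) Σ_k (a_k − b_k)² )      [Å]

No rigid-body superposition is required.  The 1/N (mean-square) normalization
makes a fixed threshold scale-free in N; whether 1/N or 1/(2N) was used by
earlier tooling is not recoverable, so the convention is stated in every
output header.  Clustering uses the classical single-pass leader algorithm:
in stream order (run-major), a snapshot joins the *first* leader within the
threshold, else founds a new cluster whose leader is its own feature vector,
never updated.  This is deterministic given the stream order; a
nearest-leader variant is available (`assign="nearest"`).  The operating
threshold is 1.0 Å; `threshold_sweep` exists because results should be (and
on the synthetic benchmarks are) stable over 0.8–1.0 Å.

Transitions are counted between consecutive frames of the same run at the
saving interval Δt = 4 ps (the lag), including self-transitions; nothing is
counted across run boundaries.  Node weight Z_i is the row sum (transitions
out of i), which makes the transition probabilities p_ij = n_ij / Z_i exactly
row-stochastic; Z_i equals the visit count up to at most one end-of-run frame
per run (tested).  Detailed balance is imposed by arithmetic averaging,
n′_ij = n′_ji = (n_ij + n_ji)/2; half-integer counts are kept, so the total Z
is conserved exactly.

## Cut-based free-energy profile

Mean first passage times to a reference node (by default the most populated
one) solve

    mfpt_i = Δt + Σ_j p_ij · mfpt_j ,   mfpt_ref = 0 ,

as a sparse (dense below ~600 nodes) linear system; the solve is rejected if
the residual exceeds 1e−8·Δt, and nodes with no path to the reference are
reported by name rather than silently producing a singular system.  Sweeping
a cut through the mfpt ordering, each prefix group A (always containing the
reference) contributes the point

    x = Z_A / Z ,   y = −kT ln(Z_AB / Z) ,

with Z_AB = Σ_{i∈A, j∉A} n_ij, the one-directional count of cut-crossing
transitions (on a symmetrized network the two directions are equal).  Nodes
with tied mfpt enter the cut together — they sit at the same kinetic distance
and would otherwise be split arbitrarily.  The profile is invariant under any
strictly increasing transform of the ordering variable (property-tested), and
barrier heights are preserved by construction.  Interior cuts with Z_AB = 0
flag disconnected sampling; the final cut (A = everything) is emitted with an
infinite-barrier flag.  Energies are kT internally, converted to kcal/mol at
the configured temperature (default 310 K) on output.

Subbasins (binding modes) are peeled iteratively: reference = most populated
unassigned node; compute the profile over the unassigned subnetwork; assign
everything at or left of the first barrier — the first local maximum of y
followed by a drop exceeding 0.5 kT (configurable; the visual procedure it
algorithmizes has no canonical depth) — and repeat.  A profile with no
interior barrier yields a single subbasin.  Two caveats discovered on exact
test chains: modes with *identical* statistical weight tie in mfpt and
overlap on the profile (as real networks' equal-weight nodes do), so the
planted-recovery fixtures use unequal weights; and a mode must contain
several nodes for within-mode flux to contrast with between-mode flux, which
is why the synthetic landscape supports micro-structured subbasins.

The diffusivity check rebuilds the network from every second frame (lag 2Δt)
and reports the median vertical offset between the two profiles over their
shared x-range.  For diffusive dynamics the crossing count of a cut scales as
sqrt(lag), so the lag-doubled profile sits lower by (1/2)·ln 2 ≈ 0.347 kT —
adopted from free-diffusion scaling as the reference value.  A two-state
jump process shifts by ~ln 2 instead and serves as the negative control.

## Unbinding kinetics

An unbinding event is the first up-crossing of the ligand–site COM separation
above 15 Å; a rebinding event is a subsequent down-crossing below 10 Å
(hysteresis between the two cuts), after which further unbinding events may
follow.  The unbinding time τ fits f(t) = 1 − exp(−t/τ) to the empirical
cumulative fraction of first-unbinding times by unweighted least squares
(log-parameterized to keep τ > 0), with the *total* number of runs as the
denominator so censored runs push the curve down without contributing an
event.  A censored-MLE alternative (`fit_mle`) agrees within 10 % on
model-consistent data.  The cross-validated error fits on a random half of
the runs and scores each held-out event against the fitted curve's quantile
at that event's within-held-out cumulative rank, repeated (default 100×) with
a seeded RNG; the reported τ and error are means over splits.  The rank-based
pairing is a documented choice — the split-half protocol does not itself
specify how held-out runs map to curve predictions.

## Committor and transition-state ensemble

Each node's unbinding probability p_u is the fraction of its member snapshots
whose own run reaches COM > 15 Å within the commitment time (default 0.8 ns
= 200 frames), under the assumption that structurally similar snapshots share
kinetic behaviour.  Scoring rules, both chosen to avoid censoring bias:
snapshots whose run ends within the horizon are excluded (outcome unknown),
and snapshots at or after a run's first unbinding are excluded until the
ligand has rebound below 10 Å (configurable; the committor describes the
bound process).  The TSE is the set of nodes with p_u ∈ [0.45, 0.55] and at
least 20 snapshots; ensemble statistics additionally drop nodes with weight
Z ≤ 5, which only add noise.  p_u is non-decreasing in the commitment time
(tested), and a sweep utility (0.4–1.2 ns) probes robustness.

One methodological point worth stating: when trajectories are terminated at a
large-separation stop distance (the 30 Å rule emulated by the generator),
the frames censored at the end of a stopped run are precisely those whose
pending outcome was "unbinds", so committor estimates from stopped runs are
biased low (≈ −0.02 near the band in our benchmarks).  Committor studies in
this package therefore run on non-terminated trajectories.

The Hammond comparison runs the TSE analysis per ligand and rank-correlates
the snapshot-weighted mean TSE COM distance against a bound-state stability
ordering: destabilizing the bound state (weaker binder) moves the
isocommittor surface toward it, i.e. shrinks the TSE distance.  With detailed
balance, depth influences the *finite-horizon* committor only through
re-escape within the commitment time, which is exactly why the effect is
probed at fixed commitment times rather than with splitting probabilities.

## LIE affinity

ΔG ≈ β·ΔE_elec + α·ΔE_vdw with β = 0.5 fixed (the ionic-hydration argument)
and α empirical (0.56 by default).  Each term is averaged separately over
bound (COM < 15 Å) and fully dissociated segments — dissociated segments of
all runs are pooled before averaging — and the Δ is bound minus unbound.
Errors are five-block averages: std of contiguous block means / sqrt(5),
remainder folded into the last block; the per-term error on Δ combines the
bound and unbound block errors in quadrature.  `fit_alpha` solves the
one-parameter least-squares problem over neutral ligands with ΔE_vdw ≠ 0
(degenerate ligands stay in the residual report).  Charged ligands trigger a
warning, not an algorithmic change: with fixed partial charges the model is
known to be a poor approximation for them.  Reference affinities may be given
directly or as dissociation constants via ΔG = RT ln K_d (molar standard
state, default 310 K).

## Synthetic landscapes (what they emulate, what they don't)

All benchmarks run on discrete-state Markov chains whose ground truth is
computed by linear algebra or exhaustive enumeration, never by sampling:

* **Default landscape** (`build_markov_landscape`): K bound subbasins
  (optionally micro-structured) with Metropolis hops targeting prescribed
  weights, uniform per-step escape probability into a "near-rim" unbound
  state at 16 Å, weight-proportional rebinding, and a "far" state at 32 Å
  that triggers the stop rule.  The chain is reversible, so the bound-
  conditional stationary distribution equals the prescribed weights exactly
  and expected transition counts are symmetric.  Exact references: mean
  unbinding time from the fundamental matrix (dt/escape_prob for one bound
  state), finite-horizon committors by backward recursion, and every
  mfpt-ordered cut of the expected-count network by brute force (≤ 20
  states).  Defaults: Δt = 4 ps, escape 1e−3/step (τ = 4 ns), runs of
  ≤ 5000 frames (20 ns) — fifty-run studies at these settings yield tens of
  unbinding events and a handful of rebindings per study.
* **Geometry embedding**: distance vectors are state centroids (pairwise
  DRMS ≥ 3 Å apart) plus isotropic Gaussian noise (σ = 0.25 Å), making DRMS
  between same-state snapshots ≈ σ√2 ≪ the 1 Å threshold; COM distances are
  state values plus noise; energies are state-conditional Gaussians with
  planted bound-minus-unbound deltas (−2, −5) kcal/mol, so the expected LIE
  total is −3.8 kcal/mol at α = 0.56.  Embedding refuses centroid separations
  below 3× the noise scale.
* **Funnel landscape** (`funnel_landscape`): layers of transit states with
  heterogeneous random forward/backward rates (fixed structure seed), giving
  a dense committor spectrum, multiple parallel pathways, and a COM
  coordinate assigned by splitting-probability rank — a landscape on which
  COM distance is an honest kinetic progress coordinate (Pearson r ≈ 0.98
  against mfpt).  Ligand families differing only in the well-escape
  probability probe the Hammond shift.
* **Diffusive fixture**: reflected Brownian motion binned at half the step
  scale, for the lag-doubling test.

Not emulated: explicit-solvent physics, force fields, rotational/translational
realism of coordinates, continuous unbound diffusion (the unbound region is
two states), or experimental affinities.  Passing benchmarks therefore
demonstrates the correctness of the network/profile/kinetics/committor/LIE
machinery on landscapes with the assumed structure — not force-field accuracy
on real complexes.

## Problem sizes and tolerances

The shipped tests use fifty-run studies of ≤ 5000 frames for kinetics (100
replicates for the τ-recovery distribution), 1e5-step equilibrium chains for
network statistics (20 replicates for barrier recovery), tens of thousands of
short independent-start runs for committor validation (so binomial standard
errors are exact), and up to ~7000 runs per ligand for the Hammond ensemble
— sizes at which the planted properties hold with comfortable statistical
margins.  Stochastic comparisons use 3-standard-error bands (or the stated
explicit tolerances); exact comparisons use machine-precision tolerances.
Linear solves check residuals at 1e−8·Δt; committor recursions are exact
matrix iterations.  All sampling is driven by explicit seeds, and every
pipeline output embeds the configuration hash that produced it.
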