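# Methods

This note documents the models, conventions and numerical choices behind
`gpcrmsm`, what the synthetic generators do and do not emulate, and the known
limitations.

## Geometric observables

**ECD tilt angle.** The orientation of the extracellular-domain (ECD)
N-terminal helix is summarized by the vector sum of backbone carbonyl (C=O)
bond vectors over the helical residues (default 30–47, inclusive, 1-based).
In an α-helix every C=O points roughly along the helix axis and the
perpendicular components rotate by ~100° per residue, so the sum is a robust
axis estimate that needs no line fitting. The tilt is measured against the
laboratory +Z axis taken as the membrane normal; no per-frame membrane
fitting is attempted, so trajectories must be prepared with the bilayer
normal along Z (the usual convention). Units are degrees in [0, 180]. A
vanishing summed vector raises a degenerate-geometry error rather than
returning an arbitrary angle.

**Centers of mass.** COM distances are geometric (unit-mass) by default,
with a mass-weighted option using standard atomic masses. Unit mass keeps
toy topologies element-agnostic; for backbone-only selections the difference
is well below other sources of variation.

**TM6 z-shift.** Defined as (z-COM of TM6 − z-COM of TM3) minus the same
quantity at a reference frame (default frame 0). Referencing TM3 removes
rigid-body drift; the value is signed, negative meaning TM6 moves toward the
intracellular side relative to TM3.

**Backbone RMSD.** Optimal rigid superposition (Kabsch, proper rotation
enforced via `scipy.spatial.transform.Rotation.align_vectors`) on an
alignment selection, RMSD measured on a possibly different selection. This
supports the usual pattern of aligning on a rigid core and measuring a
mobile region.

**Polar contacts.** A donor/acceptor pair is in contact when the minimum
donor–acceptor heavy-atom distance is ≤ 3.6 Å, *inclusive* — the common
polar-contact convention of structure viewers. A D−H···A angle criterion
(default threshold 120°, measured at the hydrogen) is applied only when
explicit hydrogens exist and the caller enables it; coarse backbone-only
models carry no hydrogens, and no angle criterion is invented for them.
Salt bridges are followed via the minimum N/O–N/O distance between two
residues.

**Water density.** Water oxygens are binned on a regular voxel grid
(half-open voxels `[lower, upper)` per axis, so boundary points bin
deterministically) after rigidly superposing each frame on a reference via a
protein selection. Counts are conserved exactly: in-grid plus out-of-grid
tallies equal waters × frames. Density is counts/(frames × voxel volume),
Å⁻³. A "water pathway" is a single 26-connected component of
above-threshold voxels reaching both ends of a z-layer range; 26-connectivity
is chosen so diagonal water chains count as connected, and because a
connected voxel path changes z by at most one layer per step, touching both
end layers implies presence at every intermediate layer. The density
threshold that defines a pathway is a user parameter — there is no canonical
value — and the detector is monotone in it by construction. The grid module
exposes a frame-range parameter so analyses can be restricted to the
equilibrated tail of a trajectory.

## State assignment

The threshold scheme maps tilt ∈ [20, 60]° to *open* (state 0),
[100, 150]° to *closed* (state 1), and everything else to a third
*intermediate* state, so the partition is complete — an MSM needs every
frame assigned. The interval bounds are inclusive. A seeded k-means
alternative (k-means++ initialization through scikit-learn) is provided for
multi-feature state definitions; the seed is a required part of the
configuration so clustering is reproducible.

## Markov state model

Transitions are counted at an integer lag (sliding window by default, which
uses all data; a strided mode subsamples for independence-sensitive error
estimates). The reversible estimator symmetrizes counts, S = (C + Cᵀ)/2,
then row-normalizes. This closed form satisfies detailed balance exactly and
is unbiased for equilibrium-sampled chains; it is *not* the reversible
maximum-likelihood estimator, which would be iterative — for the synthetic,
equilibrium-started chains this package targets, symmetrization is adequate
and keeps every invariant (row-stochasticity to 1e−10, πT = π to 1e−8,
detailed balance to 1e−10) checkable at machine precision. States outside
the largest connected component of the symmetrized count graph are dropped
(no pseudocounts) and the discarded frame fraction is reported on the model.

The Chapman–Kolmogorov test compares T(nτ) estimated directly against
T(τ)ⁿ, both by the plain row-normalized (maximum-likelihood) count
estimate. The MLE is used here rather than the reversible estimator so that
deterministic, irreversible test chains (e.g. a 3-cycle) validate exactly;
for reversible data the two differ only by sampling noise. Implied
timescales use eigenvalue moduli, report infinity for eigenvalues within
1e−12 of 1, and should be lag-independent for Markovian data.

The lag time is an abstract τ; conversion to physical time is the caller's
responsibility via the trajectory's frame interval. The default lag of 1
frame is appropriate for the synthetic two-basin process, which is Markovian
at the frame level by construction.

## Transition-path theory

The forward committor solves the interior linear system
(I − T<sub>II</sub>)q<sub>I</sub> = T<sub>IB</sub>·1 by direct solve; a
singular system (A and B not connected) yields q = 0 off B with a warning.
The backward committor is 1 − q⁺ for reversible models (guaranteed by our
estimator) and solved on the time-reversed chain T̃<sub>ij</sub> =
π<sub>j</sub>T<sub>ji</sub>/π<sub>i</sub> otherwise. Reactive flux, net
flux, total flux F (net flux across the A-cut, invariant across all
separating cuts to 1e−10) and the rate k<sub>AB</sub> = F/(τ Σ π<sub>i</sub>(1 − q⁺<sub>i</sub>))
follow the standard discrete TPT formulas. The rate is reported in 1/τ
units; no physical time unit is ever assumed.

"Shortest transition pathways" are computed by iterative bottleneck
decomposition: repeatedly extract the A→B path whose minimum-edge net flux
is maximal (Dijkstra-style widest-path search), record its capacity,
subtract it along the path. Ties are broken by fewer edges, then by
lexicographic state order, making the decomposition deterministic. Capacities
plus the residual equal F to 1e−8. Both the top-path bottleneck capacity and
the total flux F are exposed on the result, since either can be the quantity
of interest when ranking routes.

For a two-state model the TPT rate reduces to k<sub>AB</sub> =
T<sub>01</sub>/τ: with q⁺ = (0, 1), F = π₀T₀₁ and the denominator is π₀.
The simulation oracle — which counts completed A→B reactive events per unit
of time the chain is "last in A" — estimates exactly this quantity, and is
used throughout the tests as the independent check of the closed-form rates
(e.g. 1/(30τ) for the symmetric three-state reference chain, with agreement
within three standard errors of the event count).

## Synthetic data

The generators produce the *geometry and statistics* the analysis assumes,
not physical dynamics:

- **Ideal helices**: canonical α-helix backbone (100°/residue, 1.5 Å rise,
  2.3 Å radius — textbook values), with the C=O bond tilted 12° off the
  helix axis so the summed carbonyl vector is near-parallel (not trivially
  identical) to the axis, as in real helices.
- **Toy receptor**: seven TM helices on a 12 Å circle with axes along Z, an
  extended linker, and an ECD helix whose axis makes a prescribed angle with
  +Z. Residue numbering follows the PAC1R-style convention (ECD helix
  30–47, linker 126–149, TM6 351–371) so default selections resolve.
- **Two-basin trajectories**: a hidden two-state Markov chain (default stay
  probabilities 0.98/0.98, i.e. mean dwell 50 frames) emits per-frame tilts
  from truncated normals — open N(40°, 8°) on [20, 60], closed N(125°, 10°)
  on [100, 150] — and the receptor is rebuilt at each tilt. Rejection
  sampling gives exact support control, so the basins are disjoint by
  construction and threshold assignment can recover the hidden labels
  exactly; the stationary open fraction has the two-state closed form
  (1 − p<sub>cc</sub>)/((1 − p<sub>oo</sub>) + (1 − p<sub>cc</sub>)).
  One seeded generator stream drives both the chain and the emissions, so a
  trajectory regenerates bit-exactly from its spec.
- **Water ensembles**: uniform points in a box, a z-aligned cylinder (a
  water column), or a box minus a z-slab (a broken column), for density-grid
  and pathway tests.

What this does *not* emulate: force-field dynamics, membrane atoms,
side-chain packing, correlated emission noise, or overlapping basins.
Passing tests therefore demonstrate the correctness of the *analysis* —
estimators, solvers, bookkeeping — under known ground truth, not the
behaviour of the pipeline on noisy experimental-quality trajectories where
basins may overlap and the true dynamics need not be Markovian at any
tested lag.

## Problem sizes and numerical choices

Sampling-based checks use sizes chosen to make three-standard-error bounds
tight but cheap: 10⁶-step chains for parameter recovery and CK validation
(binomial SE ≈ 4×10⁻⁴ per matrix entry), 10⁶–10⁷-step chains for the
rate oracle, 5000-frame trajectories for the end-to-end analysis, 10³–2×10⁴
waters for grid statistics. All random draws flow from
`numpy.random.default_rng` seeds recorded in specs and manifests; the
acceptance script derives per-stage seeds from a single `--seed` via
`SeedSequence.spawn`.

Degenerate inputs fail loudly: non-stochastic matrices, reducible chains
(named components in the error), empty selections, all-zero count matrices,
vanishing tilt vectors, and rate denominators of zero all raise typed
exceptions rather than returning NaN.

## Design choices on genuinely open points

- The exact geometric criterion behind published H-bond counts is rarely
  stated; we adopt the inclusive 3.6 Å heavy-atom convention and make the
  angle criterion optional rather than guessing hydrogen positions.
- Whether published COM analyses are mass-weighted is typically unstated;
  geometric centers are the default with mass weighting available.
- Microstate clustering details (state count, features) vary between
  studies; both a transparent threshold scheme and seeded k-means are
  provided, with thresholds as the default because they are auditable.
- PDB I/O keeps the first altloc and rejects insertion codes — this is a
  toy/synthetic-scope reader, not a general crystallographic parser. The
  xyz dialect carries `repr` full precision for exact round-trips; PDB
  round-trips are exact to the format's three decimals.
- The intermediate tilt band (everything outside both named basins) is kept
  as its own state instead of being discarded, because an MSM requires a
  complete partition of frames; with the default disjoint supports the
  state is simply never populated.

## Known limitations

- The membrane normal is assumed to be +Z; tilted or curved membranes are
  out of scope.
- The reversible estimator assumes equilibrium sampling; strongly
  non-equilibrium data would need the reversible MLE.
- Water counting uses oxygen positions only.
- Pathway decomposition enumerates simple paths; for models with hundreds of
  states the `max_paths` cap bounds the work, with the undecomposed flux
  reported as a residual.
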