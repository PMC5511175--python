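# gpcrmsm

Conformational-transition analysis for class B GPCR-like receptor
trajectories: geometric featurization, discrete open/closed state assignment,
reversible Markov-state-model (MSM) estimation and transition-path-theory
(TPT) kinetics — with a synthetic-data module that generates every input the
pipeline needs.

## The problem

Class B GPCRs such as PAC1R carry a large extracellular domain (ECD) on top
of the canonical seven-transmembrane (7TM) bundle. The orientation of the ECD
relative to the membrane distinguishes two functional conformations: an
*open* state with the ECD tilted away from the bundle (tilt angle θ ≈ 20–60°)
and a *closed* state with the N-terminal helix angled down toward the 7TM
(θ ≈ 100–150°). Quantifying how a receptor interconverts between these states
requires (i) per-frame geometric observables, (ii) a discrete-state kinetic
model, and (iii) path-level statistics of the open↔closed transition.

This package implements that workflow for anyone analysing receptor
trajectories (or any trajectory with an equivalent two-basin orientation
coordinate). Since the microsecond simulations such analyses are usually run
on are too expensive to regenerate, a first-class synthetic module produces
receptor-like trajectories with a *known* hidden switching process, so every
stage of the pipeline can be validated against ground truth.

## The model

**Featurization.** The ECD tilt angle is θ = arccos(v·ẑ/|v|), where
v = Σ<sub>res</sub>(O − C) sums the backbone C=O bond vectors over the
N-terminal helix (residues 30–47 by default) and ẑ is the membrane normal.
Other observables: center-of-mass separations, TM6 z-shift relative to TM3,
Kabsch-aligned backbone RMSD, polar contacts (donor–acceptor heavy-atom
distance ≤ 3.6 Å), nearest-polar-atom salt-bridge distances, and
voxel-grid water densities on 7TM-aligned frames.

**MSM.** Frames are assigned to open / closed / intermediate states and
transitions counted at lag time τ. The reversible estimator symmetrizes the
count matrix, S = (C + Cᵀ)/2, giving T<sub>ij</sub> = S<sub>ij</sub>/Σ<sub>k</sub>S<sub>ik</sub>
and π<sub>i</sub> ∝ Σ<sub>k</sub>S<sub>ik</sub> with detailed balance
π<sub>i</sub>T<sub>ij</sub> = π<sub>j</sub>T<sub>ji</sub> exact by
construction. Probabilities propagate by the Chapman–Kolmogorov relation
p(nτ) = p(0)·T(τ)ⁿ, validated by the CK test and implied timescales
t<sub>k</sub> = −τ/ln λ<sub>k</sub>.

**TPT.** For reactant set A and product set B, the forward committor q⁺
solves q<sub>i</sub> = Σ<sub>j</sub>T<sub>ij</sub>q<sub>j</sub> with q = 0 on
A, 1 on B. Reactive flux f<sub>ij</sub> = π<sub>i</sub>q⁻<sub>i</sub>T<sub>ij</sub>q⁺<sub>j</sub>,
total flux F, and the rate

&nbsp;&nbsp;&nbsp;&nbsp;k<sub>AB</sub> = F / (τ Σ<sub>i</sub> π<sub>i</sub>(1 − q⁺<sub>i</sub>))

Transition pathways are ranked by iterative bottleneck decomposition of the
net flux network. A brute-force chain-simulation oracle independently checks
every rate the formulas produce.

## Worked example

```python
import numpy as np
from gpcrmsm import synthetic, features, msm, tpt

spec = synthetic.TwoBasinSpec(n_frames=5000, seed=42)
traj, hidden = synthetic.generate_two_basin_trajectory(spec)
tilt = features.ecd_tilt_angle(traj)            # degrees, residues 30-47
seq = features.assign_states(tilt)              # open=0 / closed=1 / intermediate=2
model = msm.estimate_reversible(msm.count_transitions(seq, lag=1))
result = tpt.analyze(model, A=[0], B=[1])

print(f"hidden-label agreement: {np.mean(seq.labels == hidden.labels):.4f}")
print(f"estimated T:\n{np.round(model.T, 4)}")
print(f"rate k_AB = {result.rate:.5f} per tau   (generator value 0.02)")
```

Output:

```
hidden-label agreement: 1.0000
estimated T:
[[0.9757 0.0243]
 [0.0176 0.9824]]
rate k_AB = 0.02430 per tau   (generator value 0.02)
```

The generator switches the hidden open/closed state with probability 0.02
per frame; the disjoint tilt supports (20–60° vs 100–150°) make threshold
assignment recover the hidden labels exactly, and the estimated transition
matrix and TPT rate match the generating process to within sampling error
(the binomial standard error on ~2100 open-state frames is ≈ 0.003).

The same pipeline runs from the shell:

```bash
gpcrmsm config-init > config.yaml        # inspect/edit all defaults
gpcrmsm simulate  --config config.yaml
gpcrmsm featurize --config config.yaml
gpcrmsm msm-tpt   --config config.yaml
gpcrmsm hydration --config config.yaml
gpcrmsm report    --config config.yaml
```

Each subcommand writes its numeric results plus a `manifest.json` (config
hash, seed, version) into the configured output directory.

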