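# Methods

## The model

Lipoxygenases (LOX) abstract the bis-allylic hydrogen at C11 of linoleic
acid and then add O2 to one carbon of the resulting pentadienyl radical
(C9, C11 or C13), on the face of the substrate opposite the catalytic iron
(antarafacial attack). For an enzyme with wild-type-like stereochemistry
this maps the three carbons one-to-one onto the 9R-, 11R- and
13S-hydroperoxide products. `loxshield` implements a purely steric model of
this choice: the product distribution is determined by how much room the
protein leaves for O2 at each carbon's pre-reactive position, frame by
frame over a structural ensemble.

Per snapshot:

1. **Mean plane.** A total-least-squares plane is fitted through the five
   pentadiene carbons C9..C13 (smallest principal direction of the centered
   coordinates). Using all five carbons, not just the reactive three,
   stabilizes the normal against local torsional noise.
2. **Antarafacial normal.** The normal sign is chosen so that
   n · (iron − centroid) < 0. An iron within 0.1 Å of the plane leaves the
   side undefined and is an error; the threshold guards against sign flips
   from numerical noise.
3. **Probe points.** For C9, C11 and C13 the probe is placed at
   `carbon + d_probe · n` with `d_probe = 3.0 Å`, the van der Waals optimum
   for an incoming O2 in a pre-reactive complex.
4. **Nearest blocker.** The minimum Euclidean distance from each probe to
   any atom that can shield it. Substrate atoms and the catalytic iron are
   always excluded; the remaining set is controlled by `blocker_policy`
   (`protein-only`, `protein+water`, or the default `all-non-substrate`)
   and `include_hydrogens` (default true — simulation snapshots are fully
   protonated, and a hydrogen is still excluded volume).
5. **Accessibility score.** Distance maps to a fraction in [0, 1]:
   1 at or beyond `r_open = 2.2 Å` (room for O2), 0 at or below
   `r_block = 1.8 Å` (no room), and in between the normalized exponential
   ramp

   g(d) = (e^{k·u} − 1) / (e^k − 1),  u = (d − r_block)/(r_open − r_block)

   with steepness `k = 2` by default. Only the qualitative shape of this
   damping — continuous, monotone, exponential — is constrained by the
   physics it stands in for (thermal breathing of near-threshold contacts),
   so the analytic form is a package choice and `k` is an exposed parameter
   for sensitivity analysis. Both boundaries are closed (score exactly 1 at
   `r_open`, exactly 0 at `r_block`), a measure-zero convention.

Per trajectory: each snapshot's score triple is normalized to weights
(snapshots with all three sites shielded are excluded rather than counted
as uniform — the ramp exists precisely to supply partial weights, so an
all-blocked frame carries no information about preference), weights are
averaged and renormalized. A **bis-allylic penalty** then moves
`c11_penalty = 10%` of the 11R fraction, half each, to 9R and 13S,
reflecting the higher activation barrier for oxygen attack at the central
carbon. The penalty is *relative* by default (10% of the C11 fraction, not
10 percentage points), because an absolute subtraction is ill-defined when
the C11 fraction is small; `mode="absolute"` (clamped at zero) is also
available. Replicate trajectories are averaged unweighted.

Agreement between predicted and experimental distributions is summarized
by MAXD (largest absolute deviation) and RMSD (root mean square of the
pooled deviations) over all (enzyme, product) pairs, in percentage points;
experimental tables are renormalized over the 9R/11R/13S trio first, since
the model only describes antarafacial products and is restricted to
enzymes that keep wild-type stereochemistry. MAXD ≥ RMSD always.

## Parameters

| name | default | unit | meaning |
|---|---|---|---|
| `d_probe` | 3.0 | Å | carbon-to-probe distance along the antarafacial normal |
| `r_open` | 2.2 | Å | nearest-blocker distance at/above which a site is fully accessible |
| `r_block` | 1.8 | Å | distance at/below which a site is fully shielded |
| `ramp_steepness` | 2.0 | — | `k` of the exponential ramp between the thresholds |
| `blocker_policy` | `all-non-substrate` | — | which atoms can shield a probe |
| `include_hydrogens` | true | — | whether H atoms count as blockers |
| `c11_penalty` | 0.10 | fraction | relative reduction of the 11R product |

## Synthetic scenes

The generator (`synthetic_scenes`) replaces molecular-dynamics ensembles
with a controlled stand-in so the entire pipeline is testable without
simulation data. A 7-carbon substrate chain (pentadiene plus two terminal
dummy carbons, 1.40 Å conjugated / 1.51 Å terminal bonds, 120° angles) is
built from internal coordinates; the iron sits `iron_offset = 3 Å` below
the pentadiene plane; one pseudo-atom blocker per reactive carbon is
placed on the antarafacial normal so its unjittered distance to that
carbon's probe equals a requested value. Because those distances are
chosen, every scene has an analytic accessibility triple and hence an
analytic product distribution (`ground_truth_distribution`).

Ensemble conditions default to 5000 snapshots per run with three replicate
runs per enzyme (mirroring one frame per 0.2 ps of a 1 ns production
trajectory), torsional jitter N(180°, 5°) on the two internal pentadiene
dihedrals, and isotropic Cartesian jitter of σ = 0.1 Å on every atom. A
jitter draw that breaks the bonded-geometry window of the pentadiene
(consecutive carbons outside 1.2–1.8 Å) is redrawn — free Cartesian noise
is unphysical for bonded atoms, and the redraw plays the role bond
constraints play in a real simulation. All randomness flows from a single
seed in `SceneSpec`; identical specs are bit-identical.

What the generator does *not* emulate: real side-chain packing and
correlated pocket motions, solvent structure, force-field energetics, and
any coupling between substrate conformation and pocket shape. Passing the
recovery tests therefore shows that the geometry→score→distribution
pipeline is correct and stable under thermal-scale noise — not that the
model's predictions for a real enzyme are accurate, which depends on the
quality of the input ensemble.

## Numerical behavior and known limitations

* **Zero-noise recovery is exact.** On a jitter-free scene the pipeline
  reproduces the analytic distribution to 1e-9 (it is the same arithmetic
  traversed through the full I/O and geometry stack).
* **Plateau scenes recover within noise.** With σ = 0.1 Å and 5000
  snapshots, scenes whose blocker distances sit on the plateaus (clearly
  open or clearly blocked) or symmetrically mid-ramp recover the analytic
  distribution to well within 3 percentage points per product.
* **Near-threshold distances are biased under noise.** The ramp is convex
  at one end and saturates at both, so the *mean score under noisy
  distances* differs from the *score at the mean distance* (a Jensen
  effect): a blocker just inside `r_block` leaks accessibility upward, one
  just inside `r_open` gains it. For asymmetric scenes with distances near
  the thresholds this produces systematic deviations of several percentage
  points from the jitter-free analytic value (`scripts/acceptance.py`
  reports the measured magnitude as `ramp_edge_bias_max_pp` and
  `wt_like_recovery_max_err_pp`). This is a property of the model applied
  to noisy ensembles, not an implementation error, and it is invisible in
  comparisons against *experiment* — the noisy-ensemble mean is the model's
  actual prediction — but it matters when treating the analytic zero-noise
  distribution as truth.
* **Degenerate inputs.** Collinear pentadiene carbons (plane undefined),
  iron within 0.1 Å of the plane (side undefined), all-shielded
  trajectories (no contributing snapshot) and non-rotation matrices all
  raise `ValueError` rather than returning garbage.
* **Structural comparison.** `kabsch_superpose` enforces a proper rotation
  (no mirror matching). The sequence-independent `align_structures` seeds
  from principal-axis alignment (all four proper sign combinations) and
  iterates mutual-nearest-Cα pairing (5 Å cutoff) with Kabsch refits; it
  is intended for homologous folds and will not find alignments between
  unrelated topologies. Same-sequence chains are paired by residue number
  instead, which is exact and deterministic.
* **Deposited crystal structures.** The structural targets on the
  deposited wild-type model (inter-chain RMSD and rotation angle, residue
  and iron counts, comparison with the coral 8R-LOX structure) run only
  when the PDB files are placed under `data/pdb/`; they are not bundled.

## Problem sizes

Tests and the acceptance script use 5000-snapshot ensembles (the default
production condition) for recovery checks, three replicates for the
replicate-averaging path, and 50–200 snapshots for exact zero-noise
checks; oracle-equivalence tests run 100–1000 random instances and 10^4
random distributions for the conservation laws.
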