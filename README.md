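# loxshield

Steric-shielding analysis of lipoxygenase regio- and stereospecificity.

Lipoxygenases (LOX) oxygenate polyunsaturated fatty acids with remarkable
positional and stereochemical control: after hydrogen abstraction at the
bis-allylic C11 of linoleic acid, O2 adds to C9, C11 or C13 of the
delocalized pentadienyl radical, always on the substrate face opposite the
catalytic iron. Which carbon wins — and hence whether the enzyme makes
9R-, 11R- or 13S-HPODE — is controlled by how much space the active-site
residues leave around each carbon. `loxshield` turns that idea into a
quantitative model for ensembles of active-site structures (simulation
snapshots or any multi-model PDB): it scores the steric accessibility of
each reactive carbon frame by frame and aggregates the scores into a
predicted product distribution.

For each snapshot the package

1. fits the least-squares mean plane through the pentadiene carbons
   C9..C13,
2. orients the plane normal **n** antarafacially (away from the iron),
3. places a probe point at `C + 3 Å · n` for C = C9, C11, C13 — where O2
   would sit in the pre-reactive complex,
4. finds the nearest non-substrate atom to each probe, and
5. maps that distance d to an accessibility score: 1 if d ≥ 2.2 Å, 0 if
   d ≤ 1.8 Å, and the exponential ramp
   g(d) = (e^{k·u} − 1)/(e^k − 1), u = (d − 1.8)/0.4, in between.

Snapshot scores become weights over {C9, C11, C13} → {9R, 11R, 13S}, a 10%
relative penalty moves part of the bis-allylic 11R product to 9R/13S
(higher barrier for central attack), replicates are averaged, and model vs.
experiment agreement is summarized as MAXD / RMSD in percentage points.

Also included: substrate dihedral-distribution analysis (C9-C10-C11-C12
and C10-C11-C12-C13 torsions), Kabsch superposition and rotation-angle
utilities for comparing deposited crystal structures, the active-site-clamp
residue correspondence table across LOX enzymes, and a seeded synthetic
scene generator that produces snapshot ensembles with *analytic* ground
truth for end-to-end validation. See `docs/methods.md` for the model's
assumptions and limitations.

## Worked example

```python
from loxshield import (
    SceneSpec, ShieldingConfig, build_scene,
    ground_truth_distribution, predict_product_distribution,
)

# a pocket that leaves C11 open and partially restricts C9/C13
spec = SceneSpec(
    blocker_distance={"C9": 2.0, "C11": "OPEN", "C13": 2.0},
    n_snapshots=5000, jitter_sigma=0.1, dihedral_sigma=5.0, seed=7,
)
ensemble, _ = build_scene(spec)
predicted = predict_product_distribution(ensemble)
analytic = ground_truth_distribution(spec)
for label in ("9R", "11R", "13S"):
    print(f"{label}: predicted {100 * predicted.fractions[label]:5.1f}%"
          f"  (zero-noise analytic {100 * analytic.fractions[label]:5.1f}%)")
```

prints

```
9R: predicted  26.7%  (zero-noise analytic  20.7%)
11R: predicted  47.4%  (zero-noise analytic  58.5%)
13S: predicted  25.9%  (zero-noise analytic  20.7%)
```

The 11R product dominates because its probe is unobstructed, while C9 and
C13 sit mid-ramp (nearest blocker 2.0 Å from the probe, score ≈ 0.27).
Under thermal jitter the predicted distribution deviates from the
zero-noise analytic value for such near-threshold pockets — the mean of
the nonlinear ramp over noisy distances is not the ramp at the mean
distance; `docs/methods.md` discusses this bias. With jitter off the
pipeline reproduces the analytic distribution to 1e-9.

Real ensembles enter the same way: `read_trajectory("snapshots.pdb")`
(multi-MODEL PDB), then `annotate_ensemble(...)` with atom selections such
as `"resname LNR and name C9 C10 C11 C12 C13"` and `"element Fe"`, then
`predict_product_distribution(...)`.

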