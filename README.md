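# stalkmech

Quantitative comparative structural analysis of rigid-body RNA domain
motion, built around the ribosomal L1 stalk — the mobile arm of the
large ribosomal subunit (23S rRNA helices H76–H78 plus protein L1)
that escorts deacylated tRNA out of the ribosome during translocation.
The stalk swings through four positions (open, two intermediates,
closed) correlated with the tRNA binding state; the package measures
that motion from coordinate files and localizes where in the RNA it
originates.

Intended users: structural biologists and RNA biophysicists comparing
conformers of large RNA machines (X-ray or cryo-EM models, PDB/mmCIF).

## What it computes

**Screw-axis (Euler–Rodrigues) decomposition.** After superposing two
conformers on a static core, the residual rigid transform *(R, T)* of a
mobile domain is expressed as a single rotation about one axis plus a
translation along it:

- angle Θ = arccos((tr *R* − 1)/2)
- axis direction **n** ∝ (R₃₂−R₂₃, R₁₃−R₃₁, R₂₁−R₁₂)
- pitch h = **T**·**n**
- axis origin **p** solving (I − R)**p** = **T**⊥ (minimum-norm solution)

For the L1 stalk, helix H75 (residues 2083–2090/2229–2236) is the
static domain and H76 (2093–2109/2181–2196) the mobile one; rotation is
measured against the most open conformer and classified into the four
states with boundaries at 9.2° / 17.4° / 23.5° (midpoints between the
group means 4.0°, 14.4°, 20.4°, 26.5°).

**Helical-axis deviation profiles.** A local helix axis is traced
through a base-pair list (per 3-pair window, the screw axis of the
dinucleotide-step transform); the per-residue deviation of a
conformer's axis from a reference axis localizes hinge points as
inflections — for the L1 stalk, at the H75/H76/H79 three-way junction
(around residue 2092) and in the G-U-rich zone of H76 (around 2098).

**Geometry and contacts.** Groove widths (e.g. P2093–P2189), closest
approaches between helices, heavy-atom contact maps with A-minor
(minor-groove face) classification, named interaction catalogs (the
transient stalk–30S bridge, bridge B7a, the H68 minor-groove network),
and base-stacking overlap as the intersection area of ring polygons
projected on a pair's mean plane.

**Synthetic ground truth.** Idealized A-form duplexes, hinged helices
with a known bend at a known step, and two-domain systems with an
imposed screw motion and optional Gaussian coordinate noise — every
pipeline stage is validated by parameter recovery without downloading
any structures.

## Worked example

```python
import numpy as np
from stalkmech import (
    HelixSpec, MotionSpec, make_two_domain_system, make_hinged_helix,
    make_aform_helix, domain_rotation, classify_state,
    trace_helical_axis, deviation_profile, find_inflections,
)

# a tethered mobile helix rotated 26.5 deg, with 0.2 A coordinate noise
system = make_two_domain_system(
    HelixSpec(n_bp=16), HelixSpec(n_bp=12),
    MotionSpec(angle=26.5, noise_sigma=0.2, seed=11),
)
screw = domain_rotation(system.moved, system.reference,
                        system.static_selection, system.mobile_selection)
print(f"rotation: {screw.angle:.2f} deg about {np.round(screw.direction, 3)}")
print(f"pitch: {screw.pitch:.3f} A, state: {classify_state(screw.angle)}")

# a 25-deg bend imposed between base-pair steps 8 and 9
straight = make_aform_helix(HelixSpec(n_bp=20))
bent = make_hinged_helix(HelixSpec(n_bp=20, seed=11), hinge_step=8,
                         bend_angle=25.0, noise_sigma=0.2)
profile = deviation_profile(
    trace_helical_axis(bent.model, bent.base_pairs),
    trace_helical_axis(straight.model, straight.base_pairs),
)
print("inflections:", find_inflections(profile))
```

Output:

```
rotation: 26.44 deg about [0.002 0.003 1.   ]
pitch: 0.059 A, state: closed
inflections: [9]
```

The imposed 26.5° rotation is recovered to 0.06° despite the noise and
classifies as the closed state; the hinge imposed between steps 8 and 9
is called at label 9, within one base-pair step.

A command-line interface wraps the same operations
(`stalkmech rotation/profile/summary/contacts/simulate/show-config`);
`stalkmech show-config` prints every packaged preset (static-core
residue lists, domain definitions, markers, catalogs, boundaries).

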