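# Methods

## Scope and model

The package quantifies rigid-body motion of a tethered RNA domain
between conformers of the same assembly, with the ribosomal L1 stalk as
the driving case. The underlying mechanical model is that of a screw
motion: any proper rigid displacement of a domain, measured after the
surrounding static structure has been superposed, is equivalent to a
single rotation about one axis in space plus a translation (pitch)
along that axis. The rotation magnitude is the primary order parameter;
its clustering over an ensemble of conformers defines discrete
functional states, and the location of the axis (together with
helical-axis deviation profiles) localizes the structural hinges that
produce the motion.

## Superposition

`superpose` is a plain Kabsch fit (SVD of the covariance matrix,
proper rotation enforced by sign correction of the smallest singular
vector). It performs no outlier rejection: rejection is a separate,
explicit step so that every fit is reproducible from its inputs.
Degenerate inputs (n < 3, collinear sets) are errors, not warnings.

`refine_static_core` identifies the conformationally static residue
core of an ensemble. All structures are superposed onto the first on
the current core (sugar-phosphate backbone atoms P, OP1, OP2, O5',
C5', C4', C3', O3'); the per-residue RMSD versus that anchor, pooled
over all structures and backbone atoms, is compared with a threshold
(default 0.8 Å); residues at or above threshold leave the core. Two
choices deserve comment:

- *Anchor-based, not all-pairs*: RMSD is measured against the first
  structure only. This is O(n) in ensemble size, deterministic, and
  makes the result invariant to permuting the other structures.
- *Re-evaluation each round*: every residue of the initial selection is
  re-scored against the current-core fit, so residues unfairly
  penalized by an early compromise fit (when a genuinely mobile region
  was still inside the core and dragged the superposition) re-enter
  once the core is clean. With one-way dropping, a 5 Å rigid
  displacement of one helix in half the members contaminates the first
  fit enough to discard static residues permanently; with
  re-evaluation the refinement converges to exactly the
  displaced-helix complement. Iteration is capped at 50 rounds;
  convergence is an unchanged residue set.

## Screw-axis decomposition

`er_decompose` uses the rotation-matrix route: angle from the trace,
direction from the antisymmetric part, pitch as the axial component of
the translation, and the axis origin as the minimum-norm solution of
the singular system (I − R)p = T⊥ via pseudo-inverse. The reported
origin is canonicalized to the axis point closest to the coordinate
origin (or, in `domain_rotation`, closest to the reference mobile
domain centroid — a physically interpretable point near the moving
helix).

Numerical edges:

- angles below 0.25° (configurable): the direction is numerically
  meaningless; the result is flagged `undefined` but the angle is still
  returned.
- angles within 0.25° of 180°: the antisymmetric part vanishes; the
  direction is taken from the dominant column of R + Rᵀ − 2cosΘ·I,
  which equals 2(1 − cosΘ)·nnᵀ exactly and is free of the sin Θ
  contamination that affects R + I. The sign follows the residual
  antisymmetric part when present, otherwise a deterministic
  largest-component-positive rule.

The decomposition is validated in the test suite against an
independently written quaternion implementation (angle/axis from the
unit quaternion, axis point from the closed-form planar inverse of
I − R), with 10⁻⁶ agreement over 1000 random screws.

`domain_rotation` reports the screw of the *reference → structure*
motion of the mobile domain expressed in the reference frame: the
structure is first superposed on the static-domain selection, then the
reference's mobile-domain atoms are fitted onto the structure's
static-aligned mobile atoms, and that transform is decomposed. With
this orientation convention an imposed synthetic rotation of +Θ about
axis **n** is recovered as (+Θ, **n**), not (+Θ, −**n**). Backbone
atoms only are used for both fits, since base atoms are frequently
unmodeled in medium-resolution entries.

## Helical-axis tracing and hinge localization

The axis tracer works on an ordered base-pair list, using backbone +
C1' atoms (plus ring atoms where two consecutive residues of a strand
share the same base, so that atom names map onto geometrically
equivalent positions). For each window of three consecutive pairs, the
rigid transform mapping the dinucleotide slab (pairs i, i+1) onto
(pairs i+1, i+2) is fitted and decomposed into its screw axis. Inside
a helically regular stretch this transform is exactly the local helix
screw, so its axis is the local helix axis; the C1'–C1' pair midpoints
are projected onto it to give one axis-point estimate per covered
pair. Each pair keeps the estimate from the lowest-RMSD window
covering it. The post-fit RMSD acts as a strain detector: a window
bridging a hinge cannot be mapped rigidly and shows an elevated RMSD,
so hinge-flanking pairs automatically take their estimate from the
regular side. On noiseless ideal helices the trace reproduces the
generating cylinder axis to < 10⁻³ Å; under 0.2 Å coordinate noise the
axis-point error is ≈ 0.17 Å RMS (the ~70-atom window fits average the
noise down).

Deviation profiles are per-pair Euclidean distances between two traces
on shared labels (5'-strand residue numbers), with the structures
already superposed on a common static core. Hinges are called by
`find_inflections`: moving-average smoothing (window 3), then a
discrete second difference on a 3-point half-width stencil
(p[i−3] − 2p[i] + p[i+3]), then prominence-filtered peak calling
(default 0.5 Å). The wide stencil integrates the slope change over
several steps — a piecewise-linear kink of slope change s gives a peak
of height 3s instead of s — tripling the signal-to-noise ratio without
moving the peak. Smoothing window, prominence and stencil are exposed
parameters; the defaults are calibrated so that hinge recovery on
noisy synthetic helices (below) succeeds.

Whether profiles are indexed per residue or per base-pair step is a
convention choice; per-pair labels on the 5' strand are used
throughout.

This tracer is deliberately not a full helicoidal-parameter engine
(no roll/tilt/twist decomposition, no groove geometry beyond explicit
atom–atom distances): only axis positions feed the hinge analysis, and
Å-scale hinging dominates sub-Å differences between axis definitions.

## Contacts and stacking

Contacts are heavy-atom pairs within a cutoff (default 4.0 Å — no
universal convention exists, so it is exposed everywhere). A contact is
classed `minor_groove` when either atom lies on a nucleotide's
minor-groove face: O2' and, for purines, N1/C2/N3, for pyrimidines O2
(the A-minor convention). Catalog evaluation (`bridge_report`) marks
entries whose chains or residues are missing as "absent residue"
instead of raising — unmodeled components (e.g. protein L1 in some
entries, or an absent tRNA chain) are an expected condition, not an
error.

Stacking overlap between two base pairs is the area of intersection of
the two pairs' ring-atom convex hulls, projected onto the mean plane
(SVD) of the first pair, together with the interplanar distance along
that plane's normal and the angle between the two pairs' plane
normals. Convex hulls of ring atoms, rather than van-der-Waals disks,
keep the measure deterministic and parameter-free; it is a proxy for
visual overlap in stacking diagrams and is meant for comparisons
(ordering of states), not absolute contact areas.

## Dataset pipeline and classification

`run_dataset` evaluates a manifest of conformers against a reference
(defaults to PDB 4GD2, with 4V9D accepted as an alias; the two ids
label the same open-state reference in different sources and the alias
use is logged). Per entry: static-core superposition → H76 screw angle
→ marker displacement (P2127 in bacteria, P2469 in yeast, at the top
of the stalk head) → optional 30S body/head rotations → state label.
Classification boundaries default to the midpoints between the group
means (9.2°, 17.4°, 23.5°) with left-closed intervals (a rotation
exactly on a boundary takes the higher state); they are configuration,
not code.

The 16S body/head domain selections needed for the optional 30S
rotation columns are not shipped: they are not derivable from the
information packaged here, so the config holds a documented placeholder
and the columns stay empty unless the user supplies selections.

Non-E.-coli numbering is handled by explicit per-structure,
per-chain residue-number offsets in the manifest; the package never
guesses a numbering map.

## Synthetic data: what it emulates, and what it does not

The generators produce the three geometries the analyses consume:

- `make_aform_helix` — a duplex with C1' atoms on a cylinder (radius
  9.4 Å, rise 2.81 Å, twist 32.7°/bp — standard A-form values), a
  simplified backbone built from fixed per-atom cylindrical offsets,
  and planar rings in the pair plane. The C1'–C1' span across a pair
  is 10.4 Å. The default sequence is uniform (G paired with C): the
  fully idealized lattice in which every base-pair step is
  geometrically identical, which is the point of an ideal fixture.
- `make_hinged_helix` — the same duplex with the distal segment rotated
  by a chosen angle about an in-plane axis between two chosen pairs;
  emulates localized helix bending (G-U-rich zones, junction hinges).
- `make_two_domain_system` — a static helix plus an orthogonally posed
  mobile helix displaced by an imposed screw motion; emulates the
  static-H75/mobile-H76 architecture. Noise is isotropic Gaussian per
  coordinate, applied after the motion, seeded independently per
  structure.

Noise sigma in the recovery tests is 0.2 Å, a coordinate-precision
scale typical of well-refined crystallographic models; the noiseless
variants verify exactness of the algebra.

What the generators do *not* emulate: sugar pucker, sequence-dependent
step geometry, non-canonical pairs, bulges, thermal anisotropy, or any
crystallographic artefact (alternate conformations, partial occupancy,
missing loops). Passing the synthetic recovery tests therefore
demonstrates the correctness of the algebra and the robustness of the
estimators to isotropic coordinate noise — not that real rRNA helices
meet the idealized assumptions. On real structures the axis tracer and
hinge caller additionally face irregular twist and non-canonical
pairing; the window-RMSD selection rule degrades gracefully there (a
strained window is simply never preferred), but hinge calls closer
than ~2 steps apart will merge.

## Problem sizes and determinism

The shipped test suite and the acceptance script run entirely on
synthetic structures: 1000 random screws for the decomposition
round-trip, 16–20 bp duplexes for tracing, 400 noisy replicates
(4 bend angles × 4 hinge positions × 25 seeds) for hinge localization,
and 100 replicates of 500-atom sets for the superposition noise floor.
These sizes give Monte-Carlo error comfortably below the tolerances
being checked while keeping the whole suite in seconds. All
randomness flows from explicit seeds (the acceptance script derives
every stream from `--seed` via `SeedSequence.spawn`); fixed seeds give
byte-identical generated files.

## Known limitations

- The static-core refinement measures deviation against a single
  anchor structure; a pathological anchor (e.g. itself an outlier)
  biases the core. Choosing the reference/open conformer as the first
  structure is the intended use.
- The axis tracer requires ≥ 4 pairs and loses discrimination at the
  two terminal pairs of a duplex (nearest-window estimates).
- Stacking overlap is a projected-polygon proxy; it is not an
  energy or a buried-surface area.
- `bridge_report` is distance-based only; it does not validate
  hydrogen-bond geometry or classify pair families.
- Published-value checks require the original PDB entries, which are
  not redistributable inside the package; without them those tests
  report failure with an explanatory message.
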