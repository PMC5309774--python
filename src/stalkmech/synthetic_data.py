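"""Synthetic coordinate generators with known ground truth.

Every downstream stage of the pipeline (superposition, screw-axis
decomposition, helical-axis tracing, hinge localization, contact and
stacking geometry) can be validated by parameter recovery on these
fixtures, without any external structure downloads.

Three generators are provided:

* :func:`make_aform_helix` — an idealized A-form-like duplex: C1'
  atoms on a cylinder (default radius 9.4 A, rise 2.81 A, twist 32.7
  deg/bp), a simplified sugar-phosphate backbone, and planar ring atoms
  in the base-pair plane.  The generating cylinder axis is the ground
  truth for axis tracing.
* :func:`make_hinged_helix` — the same duplex bent by a known angle at
  a chosen base-pair step, emulating hinge/bending zones of RNA helices
  (e.g. the G-U-rich region of ribosomal helix H76).
* :func:`make_two_domain_system` — a static helix plus a tethered
  mobile helix displaced by a known screw motion, emulating the
  H75 (static) / H76 (mobile) architecture at the base of the L1 stalk.

The geometry is deliberately simplified (no sugar pucker, no
sequence-dependent parameters): each residue carries the backbone heavy
atoms, C1', and a planar ring — exactly the atoms the analysis
operations require.  Generation is deterministic for a fixed seed (byte-identical output
files); written coordinates carry the PDB field precision of 0.001 A,
within which structures round-trip exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ConfigError
from .structure_io import StructureModel, ResidueSelection, write_structure

_COMPLEMENT = {"G": "C", "C": "G", "A": "U", "U": "A"}
_PURINES = {"A", "G"}

#: target C1'-C1' distance across a pair (A); sets the inter-strand phase
_PAIR_SPAN = 10.4

# simplified backbone template: atom -> (d_radius, d_angle_deg, d_z)
# relative to the C1' cylindrical position; mirrored for the 3'->5' strand
_BACKBONE_TEMPLATE = {
    "P": (0.9, 12.0, 1.8),
    "OP1": (1.9, 16.0, 2.3),
    "OP2": (0.2, 18.0, 1.2),
    "O5'": (0.6, 10.0, 1.0),
    "C5'": (0.5, 7.0, 0.6),
    "C4'": (0.3, 4.0, 0.3),
    "C3'": (0.6, 1.0, -0.2),
    "O3'": (0.8, -3.0, -0.7),
}


def _hexagon(center_x: float, radius: float, names, start_angle: float = 180.0):
    pts = {}
    for k, name in enumerate(names):
        a = math.radians(start_angle + 60.0 * k)
        pts[name] = (center_x + radius * math.cos(a), radius * math.sin(a))
    return pts


def _pyrimidine_template() -> dict:
    # hexagon with N1 attached toward C1' (local +x is the inward direction)
    return _hexagon(1.48 + 1.39, 1.39, ["N1", "C2", "N3", "C4", "C5", "C6"])


def _purine_template() -> dict:
    # fused 5-ring (N9 C4 C5 N7 C8) + 6-ring sharing the C4-C5 edge
    r5 = 1.17
    c5x = 1.48 + r5
    ring5_names = ["N9", "C4", "C5", "N7", "C8"]
    ring5 = {}
    for k, name in enumerate(ring5_names):
        a = math.radians(180.0 - 72.0 * k)
        ring5[name] = np.array([c5x + r5 * math.cos(a), r5 * math.sin(a)])
    c4, c5 = ring5["C4"], ring5["C5"]
    edge = c5 - c4
    e = float(np.linalg.norm(edge))
    mid = (c4 + c5) / 2.0
    pent_center = np.array([c5x, 0.0])
    normal = mid - pent_center
    normal /= np.linalg.norm(normal)
    hex_center = mid + normal * (e * math.sqrt(3.0) / 2.0)
    # walk the hexagon from C4 to C5 the long way round: C4,N3,C2,N1,C6,C5
    names = ["C4", "N3", "C2", "N1", "C6", "C5"]
    for sign in (1.0, -1.0):
        pts = {}
        v = c4 - hex_center
        for k, name in enumerate(names):
            ang = math.radians(sign * 60.0 * k)
            rot = np.array([[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]])
            pts[name] = hex_center + rot @ v
        if np.linalg.norm(pts["C5"] - c5) < 1e-6:
            break
    out = {k: tuple(v) for k, v in ring5.items()}
    out.update({k: tuple(v) for k, v in pts.items() if k not in out})
    return out


_RING_TEMPLATES = {
    True: _purine_template(),    # purines
    False: _pyrimidine_template(),  # pyrimidines
}

#: ring atom names per base class (used by interaction_analysis as well)
PURINE_RING_ATOMS = ("N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6")
PYRIMIDINE_RING_ATOMS = ("N1", "C2", "N3", "C4", "C5", "C6")


@dataclass(frozen=True)
class HelixSpec:
    """Parameters of an idealized A-form-like duplex."""

    n_bp: int = 20
    rise: float = 2.81
    twist: float = 32.7
    radius: float = 9.4
    sequence: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_bp < 4:
            raise ConfigError("n_bp must be >= 4")
        if self.rise <= 0:
            raise ConfigError("rise must be positive")
        if not 0 < self.twist < 60:
            raise ConfigError("twist must be in (0, 60) deg/bp")
        if self.radius <= _PAIR_SPAN / 2:
            raise ConfigError(f"radius must exceed {_PAIR_SPAN / 2} A")
        if self.sequence is not None:
            seq = self.sequence.upper()
            if len(seq) != self.n_bp or set(seq) - set("AUGC"):
                raise ConfigError("sequence must be AUGC of length n_bp")


@dataclass(frozen=True)
class MotionSpec:
    """A screw motion with optional isotropic Gaussian coordinate noise."""

    angle: float
    axis_direction: tuple = (0.0, 0.0, 1.0)
    axis_origin: tuple = (0.0, 0.0, 0.0)
    pitch: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        d = np.asarray(self.axis_direction, dtype=float)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise ConfigError("axis_direction must be non-zero")
        object.__setattr__(self, "axis_direction", tuple(d / n))
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        d = np.asarray(self.axis_direction)
        p0 = np.asarray(self.axis_origin, dtype=float)
        rot = Rotation.from_rotvec(np.radians(self.angle) * d)
        return rot.apply(coords - p0) + p0 + self.pitch * d


@dataclass(frozen=True)
class AformHelix:
    """Generated duplex plus its ground truth."""

    model: StructureModel
    base_pairs: tuple
    axis_origin: tuple = (0.0, 0.0, 0.0)
    axis_direction: tuple = (0.0, 0.0, 1.0)
    spec: HelixSpec = field(default_factory=HelixSpec)

    def ground_truth(self) -> dict:
        return {
            "axis_origin": list(self.axis_origin),
            "axis_direction": list(self.axis_direction),
            "rise": self.spec.rise,
            "twist": self.spec.twist,
            "n_bp": self.spec.n_bp,
        }


@dataclass(frozen=True)
class HingedHelix:
    model: StructureModel
    base_pairs: tuple
    hinge_step: int
    bend_angle: float
    noise_sigma: float
    spec: HelixSpec

    def ground_truth(self) -> dict:
        return {
            "hinge_step": self.hinge_step,
            "bend_angle": self.bend_angle,
            "noise_sigma": self.noise_sigma,
        }


@dataclass(frozen=True)
class TwoDomainSystem:
    reference: StructureModel
    moved: StructureModel
    motion: MotionSpec
    static_selection: ResidueSelection
    mobile_selection: ResidueSelection

    def ground_truth(self) -> dict:
        return {
            "angle": self.motion.angle,
            "axis_direction": list(self.motion.axis_direction),
            "axis_origin": list(self.motion.axis_origin),
            "pitch": self.motion.pitch,
            "noise_sigma": self.motion.noise_sigma,
        }


def _default_sequence(n_bp: int) -> str:
    # uniform G (paired C) strand: the fully idealized lattice, in which
    # every base-pair step is geometrically identical
    return "G" * n_bp


def _residue_atoms(base: str, c1_cyl: tuple, sense: float, pair_mid: np.ndarray):
    """Place backbone + C1' + ring atoms for one residue.

    c1_cyl: (radius, angle_rad, z) of the C1' atom on the cylinder;
    sense: +1 for the 5'->3' strand, -1 for the complementary strand;
    pair_mid: Cartesian midpoint of the two C1' atoms of the pair.
    """
    radius, angle, z = c1_cyl
    c1 = np.array([radius * math.cos(angle), radius * math.sin(angle), z])
    atoms = [("C1'", "C", c1)]
    for name, (dr, dang, dz) in _BACKBONE_TEMPLATE.items():
        a = angle + sense * math.radians(dang)
        r = radius + dr
        atoms.append(
            (name, _element_of(name), np.array([r * math.cos(a), r * math.sin(a), z + sense * dz]))
        )
    # ring in the base-pair plane, extending inward toward the partner
    xhat = pair_mid - c1
    xhat[2] = 0.0
    nx = np.linalg.norm(xhat)
    xhat = xhat / nx if nx > 1e-9 else np.array([1.0, 0.0, 0.0])
    yhat = np.cross([0.0, 0.0, 1.0], xhat)
    for name, (tx, ty) in _RING_TEMPLATES[base in _PURINES].items():
        atoms.append((name, name[0], c1 + tx * xhat + ty * yhat))
    return atoms


def _element_of(atom_name: str) -> str:
    return next(ch for ch in atom_name if ch.isalpha()).upper()


def make_aform_helix(
    spec: HelixSpec, chain_a: str = "A", chain_b: str = "B"
) -> AformHelix:
    """Generate an ideal straight duplex along the +z axis through the origin.

    Base pair ``k`` (1-based) sits at z = (k-1)*rise; the 5'->3' strand
    (chain_a) runs with increasing z, the complement (chain_b) is
    numbered antiparallel so pair k joins (chain_a, k) with
    (chain_b, n_bp - k + 1).  The per-strand P/OP1/OP2 atoms are omitted
    on each 5'-terminal residue.
    """
    seq = (spec.sequence or _default_sequence(spec.n_bp)).upper()
    half_span = math.asin(_PAIR_SPAN / (2.0 * spec.radius))
    twist = math.radians(spec.twist)

    chain_ids, res_nums, res_names, atom_names, elements, xyz = [], [], [], [], [], []
    pairs = []
    for k in range(spec.n_bp):
        z = k * spec.rise
        theta = k * twist
        ang_a = theta - half_span
        ang_b = theta + half_span
        c1a = np.array([spec.radius * math.cos(ang_a), spec.radius * math.sin(ang_a), z])
        c1b = np.array([spec.radius * math.cos(ang_b), spec.radius * math.sin(ang_b), z])
        mid = (c1a + c1b) / 2.0
        base_a = seq[k]
        base_b = _COMPLEMENT[base_a]
        num_a = k + 1
        num_b = spec.n_bp - k
        pairs.append(((chain_a, num_a), (chain_b, num_b)))
        for chain, num, base, cyl, sense in (
            (chain_a, num_a, base_a, (spec.radius, ang_a, z), 1.0),
            (chain_b, num_b, base_b, (spec.radius, ang_b, z), -1.0),
        ):
            is_5prime = (chain == chain_a and num == 1) or (chain == chain_b and num == 1)
            for name, element, pos in _residue_atoms(base, cyl, sense, mid):
                if is_5prime and name in ("P", "OP1", "OP2"):
                    continue
                chain_ids.append(chain)
                res_nums.append(num)
                res_names.append(base)
                atom_names.append(name)
                elements.append(element)
                xyz.append(pos)

    model = StructureModel(
        chain_ids,
        res_nums,
        res_names,
        atom_names,
        elements,
        np.array(xyz),
        source_id=f"aform-{spec.n_bp}bp-seed{spec.seed}",
        species_tag="synthetic",
    )
    return AformHelix(model, tuple(pairs), spec=spec)


def add_noise(model: StructureModel, sigma: float, seed: int) -> StructureModel:
    """Add isotropic Gaussian noise (std ``sigma`` per coordinate)."""
    if sigma < 0:
        raise ConfigError("sigma must be >= 0")
    if sigma == 0:
        return model
    rng = np.random.default_rng(seed)
    return model.with_coords(model.coords + rng.normal(0.0, sigma, model.coords.shape))


def make_hinged_helix(
    spec: HelixSpec,
    hinge_step: int,
    bend_angle: float,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> HingedHelix:
    """Bend the duplex by ``bend_angle`` degrees between base-pair steps
    ``hinge_step`` and ``hinge_step + 1`` (1-based pair indices).

    The distal segment (pairs > hinge_step) is rotated about an axis
    through the midpoint between the flanking pairs, perpendicular to
    the helix axis.
    """
    if not 2 <= hinge_step <= spec.n_bp - 2:
        raise ConfigError(f"hinge_step {hinge_step} out of range [2, {spec.n_bp - 2}]")
    helix = make_aform_helix(spec)
    model = helix.model

    z_h = (hinge_step - 0.5) * spec.rise
    pivot = np.array([0.0, 0.0, z_h])
    rot = Rotation.from_rotvec(np.radians(bend_angle) * np.array([1.0, 0.0, 0.0]))

    # pairs with 1-based index > hinge_step: chain A residues > hinge_step,
    # chain B residues < n_bp - hinge_step + 1
    distal = ((model.chain_ids == "A") & (model.residue_numbers > hinge_step)) | (
        (model.chain_ids == "B") & (model.residue_numbers <= spec.n_bp - hinge_step)
    )
    coords = model.coords.copy()
    coords[distal] = rot.apply(coords[distal] - pivot) + pivot
    out = model.with_coords(coords)
    out = add_noise(out, noise_sigma, spec.seed if seed is None else seed)
    return HingedHelix(out, helix.base_pairs, hinge_step, bend_angle, noise_sigma, spec)


def make_two_domain_system(
    static_spec: HelixSpec,
    mobile_spec: HelixSpec,
    motion: MotionSpec,
) -> TwoDomainSystem:
    """Static helix (chains A/B, along +z) plus a tethered mobile helix
    (chains C/D, along +x, anchored near the static helix top).

    ``reference`` holds both domains in the base pose; ``moved`` has the
    mobile domain additionally displaced by the screw ``motion``.
    Gaussian noise (``motion.noise_sigma``) is then applied to all atoms
    of both structures independently.
    """
    static = make_aform_helix(static_spec, chain_a="A", chain_b="B").model
    mobile0 = make_aform_helix(mobile_spec, chain_a="C", chain_b="D").model

    # pose the mobile helix roughly orthogonal to the static one, like a
    # helix emerging from a junction at the static helix top
    pose_rot = Rotation.from_rotvec(np.radians(90.0) * np.array([0.0, 1.0, 0.0]))
    offset = np.array([6.0, 0.0, (static_spec.n_bp - 1) * static_spec.rise + 6.0])
    mobile_coords = pose_rot.apply(mobile0.coords) + offset
    mobile = mobile0.with_coords(mobile_coords)

    def merge(a: StructureModel, b: StructureModel, tag: str) -> StructureModel:
        return StructureModel(
            np.concatenate([a.chain_ids, b.chain_ids]),
            np.concatenate([a.residue_numbers, b.residue_numbers]),
            np.concatenate([a.residue_names, b.residue_names]),
            np.concatenate([a.atom_names, b.atom_names]),
            np.concatenate([a.elements, b.elements]),
            np.vstack([a.coords, b.coords]),
            source_id=tag,
            species_tag="synthetic",
        )

    reference = merge(static, mobile, "two-domain-reference")
    mobile_moved = mobile.with_coords(motion.apply(mobile.coords))
    moved = merge(static, mobile_moved, "two-domain-moved")

    if motion.noise_sigma > 0:
        seeds = np.random.SeedSequence(motion.seed).generate_state(2)
        reference = add_noise(reference, motion.noise_sigma, int(seeds[0]))
        moved = add_noise(moved, motion.noise_sigma, int(seeds[1]))

    nb_s, nb_m = static_spec.n_bp, mobile_spec.n_bp
    static_sel = ResidueSelection((("A", 1, nb_s), ("B", 1, nb_s)))
    mobile_sel = ResidueSelection((("C", 1, nb_m), ("D", 1, nb_m)))
    return TwoDomainSystem(reference, moved, motion, static_sel, mobile_sel)


def write_fixture(result, directory: str | Path, name: str) -> dict:
    """Write generated model(s) as PDB plus a JSON ground-truth sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {}
    if isinstance(result, TwoDomainSystem):
        for tag, model in (("reference", result.reference), ("moved", result.moved)):
            p = directory / f"{name}_{tag}.pdb"
            write_structure(model, p, format="pdb")
            files[tag] = str(p)
    else:
        p = directory / f"{name}.pdb"
        write_structure(result.model, p, format="pdb")
        files["model"] = str(p)
    sidecar = directory / f"{name}.json"
    payload = {"files": {k: Path(v).name for k, v in files.items()},
               "ground_truth": result.ground_truth()}
    if hasattr(result, "base_pairs"):
        payload["base_pairs"] = [list(map(list, bp)) for bp in result.base_pairs]
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    files["sidecar"] = str(sidecar)
    return files
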