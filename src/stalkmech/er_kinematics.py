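"""Euler-Rodrigues screw-axis decomposition of rigid-body domain motion.

Any rigid transform (R, T) between two conformations of a tethered
domain can be expressed as a single rotation about one axis in space
(the screw axis) plus a translation (pitch) along it:

* angle     Theta = arccos((trace(R) - 1) / 2), degrees, in [0, 180]
* direction d  proportional to (R32 - R23, R13 - R31, R21 - R12)
* pitch     h = T . d
* origin    a point p on the axis solving (I - R) p = T_perp, where
  T_perp is T with its axial component removed; the linear system is
  singular along d and is solved by the minimum-norm (pseudo-inverse)
  solution, optionally shifted along the axis to the point closest to a
  reference centroid.

Near-degenerate cases: for angles below ``angle_floor`` (default 0.25
deg) the axis direction is numerically meaningless and the result is
flagged ``undefined``; within 0.25 deg of 180 deg the antisymmetric
part of R vanishes and the direction is recovered from the symmetric
part R + R^T - 2 cos(t) I, flagged ``near_degenerate``.

:func:`domain_rotation` applies the decomposition to domain motion
between two structures: superpose on the static domain, then fit the
mobile domain, then decompose the residual mobile-domain transform.
For the ribosomal L1 stalk the mobile domain is helix H76 and the
static domain helix H75 (selection presets in :mod:`stalkmech.presets`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import MissingAtomError
from .structure_io import (
    BACKBONE_ATOMS,
    ResidueSelection,
    StructureModel,
    select_atoms,
)
from .superposition import RigidTransform, pair_atoms, superpose, superpose_models

DEFAULT_ANGLE_FLOOR = 0.25  # degrees


@dataclass(frozen=True)
class ScrewAxis:
    """A screw motion: unit direction, a point on the axis, angle (deg), pitch (A)."""

    direction: np.ndarray
    origin: np.ndarray
    angle: float
    pitch: float
    undefined: bool = False
    near_degenerate: bool = False

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float).reshape(3)
        if not math.isclose(float(np.linalg.norm(d)), 1.0, abs_tol=1e-8):
            raise ValueError("direction must be a unit vector")
        object.__setattr__(self, "direction", d)
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float).reshape(3))

    def to_transform(self) -> RigidTransform:
        """Rebuild the rigid transform this screw axis describes."""
        R = Rotation.from_rotvec(np.radians(self.angle) * self.direction).as_matrix()
        t = (np.eye(3) - R) @ self.origin + self.pitch * self.direction
        return RigidTransform(R, t)

    def point_on_axis_closest_to(self, point: np.ndarray) -> np.ndarray:
        p = np.asarray(point, dtype=float)
        return self.origin + np.dot(p - self.origin, self.direction) * self.direction


def er_decompose(transform: RigidTransform, angle_floor: float = DEFAULT_ANGLE_FLOOR) -> ScrewAxis:
    """Decompose a rigid transform into its screw axis."""
    R = transform.rotation
    T = transform.translation
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    angle = math.degrees(math.acos(cos_theta))

    antisym = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    norm_as = float(np.linalg.norm(antisym))
    undefined = angle < angle_floor
    near_degenerate = (180.0 - angle) < angle_floor

    if undefined:
        # rotation too small for a meaningful axis; report a default
        direction = np.array([0.0, 0.0, 1.0]) if norm_as < 1e-12 else antisym / norm_as
    elif near_degenerate:
        # symmetric part: R + R^T = 2 cos(t) I + 2(1 - cos(t)) d d^T, so
        # M below equals 2(1 - cos(t)) d d^T exactly; its dominant column
        # is proportional to d without the sin(t) contamination of R + I
        M = R + R.T - 2.0 * cos_theta * np.eye(3)
        col = M[:, int(np.argmax(np.linalg.norm(M, axis=0)))]
        direction = col / np.linalg.norm(col)
        if norm_as > 1e-12 and np.dot(direction, antisym) < 0:
            direction = -direction
        elif norm_as <= 1e-12:
            # exactly 180 deg: sign is arbitrary; fix deterministically
            idx = int(np.argmax(np.abs(direction)))
            if direction[idx] < 0:
                direction = -direction
    else:
        direction = antisym / norm_as

    pitch = float(np.dot(T, direction))
    t_perp = T - pitch * direction
    if angle < 1e-7:
        # no meaningful axis at all: treat the motion as pure translation
        origin = np.zeros(3)
    else:
        origin = np.linalg.pinv(np.eye(3) - R, rcond=1e-10) @ t_perp
        # keep only the component perpendicular to the axis (canonical point)
        origin = origin - np.dot(origin, direction) * direction
    return ScrewAxis(direction, origin, float(angle), pitch, undefined, near_degenerate)


def domain_rotation(
    structure: StructureModel,
    reference: StructureModel,
    static_sel: ResidueSelection,
    mobile_sel: ResidueSelection,
    backbone_atoms: frozenset | set = BACKBONE_ATOMS,
    angle_floor: float = DEFAULT_ANGLE_FLOOR,
) -> ScrewAxis:
    """Screw axis of mobile-domain motion in the reference frame.

    Procedure: (1) superpose ``structure`` onto ``reference`` using the
    static-domain selection; (2) superpose the static-frame-aligned
    mobile-domain atoms onto the reference's mobile-domain atoms;
    (3) decompose that residual transform.  The axis origin is reported
    as the point on the axis closest to the reference mobile-domain
    centroid.
    """
    static_fit = superpose_models(structure, reference, static_sel, backbone_atoms)

    msel = mobile_sel.with_atom_filter(backbone_atoms)
    mob, ref, _ = pair_atoms(
        select_atoms(structure, msel).model, select_atoms(reference, msel).model
    )
    mob_aligned = static_fit.transform.apply(mob)
    # fit the reference mobile domain onto the static-aligned mobile domain:
    # the screw then describes the domain's motion reference -> structure,
    # expressed in the reference frame
    mobile_fit = superpose(ref, mob_aligned)
    screw = er_decompose(mobile_fit.transform, angle_floor)
    if not screw.undefined:
        centroid = ref.mean(axis=0)
        screw = ScrewAxis(
            screw.direction,
            screw.point_on_axis_closest_to(centroid),
            screw.angle,
            screw.pitch,
            screw.undefined,
            screw.near_degenerate,
        )
    return screw


def displacement_at(
    structure: StructureModel,
    reference: StructureModel,
    marker: tuple,
    core_sel: ResidueSelection | None = None,
    backbone_atoms: frozenset | set = BACKBONE_ATOMS,
) -> float:
    """Euclidean displacement (A) of a marker atom between two structures.

    ``marker`` is (chain_id, residue_number, atom_name).  If
    ``core_sel`` is given, ``structure`` is first superposed onto
    ``reference`` on that static core; otherwise the structures are
    assumed to be already superposed.
    """
    chain, resnum, atom = marker
    i = structure.get_atom_index(chain, resnum, atom)
    j = reference.get_atom_index(chain, resnum, atom)
    if i is None or j is None:
        where = "structure" if i is None else "reference"
        raise MissingAtomError(f"marker atom {marker} absent from {where}")
    pos = structure.coords[i]
    if core_sel is not None:
        fit = superpose_models(structure, reference, core_sel, backbone_atoms)
        pos = fit.transform.apply(pos[None, :])[0]
    return float(np.linalg.norm(pos - reference.coords[j]))
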