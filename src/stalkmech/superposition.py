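"""Least-squares rigid superposition and static-core refinement.

The superposition is the classic Kabsch fit: the optimal proper
rotation + translation minimizing the RMSD between paired coordinate
sets, computed via SVD of the covariance matrix.  No outlier rejection
happens inside :func:`superpose`; iterative rejection lives only in
:func:`refine_static_core`, which reproduces the data-driven
identification of the conformationally static rRNA core (residues whose
ensemble backbone RMSD stays below a threshold, 0.8 A by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ConvergenceError, DegenerateInputError
from .structure_io import (
    BACKBONE_ATOMS,
    ResidueSelection,
    Selection,
    StructureModel,
    select_atoms,
)


@dataclass(frozen=True)
class RigidTransform:
    """y = R x + t, rotation proper-orthonormal."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or not np.isclose(
            np.linalg.det(R), 1.0, atol=1e-8
        ):
            raise DegenerateInputError("rotation is not a proper orthonormal matrix")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass(frozen=True)
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_atoms: int
    per_residue_rmsd: Mapping[tuple, float]


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    residue_labels: Sequence[tuple] | None = None,
) -> SuperpositionResult:
    """Optimal least-squares rigid fit of ``mobile`` onto ``reference``.

    The two coordinate sets must be correspondence-paired and of equal
    length (n >= 3, not all collinear).  If ``residue_labels`` (one
    hashable label per atom) is given, a per-residue RMSD map is
    computed from the post-fit paired distances.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.ndim != 2 or mob.shape[1] != 3 or mob.shape != ref.shape:
        raise DegenerateInputError(f"paired (n,3) sets required, got {mob.shape} vs {ref.shape}")
    n = mob.shape[0]
    if n < 3:
        raise DegenerateInputError(f"need >= 3 paired atoms, got {n}")

    mob_mean = mob.mean(axis=0)
    ref_mean = ref.mean(axis=0)
    mob_c = mob - mob_mean
    ref_c = ref - ref_mean
    if min(np.linalg.matrix_rank(mob_c, tol=1e-8), np.linalg.matrix_rank(ref_c, tol=1e-8)) < 2:
        raise DegenerateInputError("degenerate (collinear or coincident) coordinate set")

    H = mob_c.T @ ref_c
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = ref_mean - R @ mob_mean
    transform = RigidTransform(R, t)

    diff = transform.apply(mob) - ref
    sq = np.einsum("ij,ij->i", diff, diff)
    rmsd = float(np.sqrt(sq.mean()))

    per_residue: dict = {}
    if residue_labels is not None:
        if len(residue_labels) != n:
            raise DegenerateInputError("residue_labels length mismatch")
        acc: dict = {}
        for label, s in zip(residue_labels, sq):
            acc.setdefault(label, []).append(s)
        per_residue = {k: float(np.sqrt(np.mean(v))) for k, v in acc.items()}
    return SuperpositionResult(transform, rmsd, n, per_residue)


def pair_atoms(
    a: StructureModel, b: StructureModel
) -> tuple[np.ndarray, np.ndarray, list]:
    """Match atoms of two models on (chain, residue number, atom name).

    Returns paired coordinate arrays in ``a``'s order plus the matched
    identity keys.
    """
    idx_b = b.key_index
    ia, ib, keys = [], [], []
    for i in range(len(a)):
        k = (a.chain_ids[i], int(a.residue_numbers[i]), a.atom_names[i])
        j = idx_b.get(k)
        if j is not None:
            ia.append(i)
            ib.append(j)
            keys.append(k)
    if not ia:
        raise DegenerateInputError("no common atoms between structures")
    return a.coords[ia], b.coords[ib], keys


def superpose_models(
    mobile: StructureModel,
    reference: StructureModel,
    selection: ResidueSelection,
    atom_filter: frozenset | set | None = BACKBONE_ATOMS,
) -> SuperpositionResult:
    """Superpose ``mobile`` onto ``reference`` on the atoms of ``selection``."""
    sel = selection if atom_filter is None else selection.with_atom_filter(atom_filter)
    ca, cb, keys = pair_atoms(select_atoms(mobile, sel).model, select_atoms(reference, sel).model)
    labels = [(k[0], k[1]) for k in keys]
    return superpose(ca, cb, residue_labels=labels)


def refine_static_core(
    structures: Sequence[StructureModel],
    initial: ResidueSelection,
    threshold: float = 0.8,
    backbone_atoms: frozenset | set = BACKBONE_ATOMS,
    max_iter: int = 50,
) -> ResidueSelection:
    """Iteratively identify the conformationally static residue core.

    All structures are superposed onto the first on the current core;
    residues whose ensemble backbone RMSD (RMS over all backbone atoms
    of the residue, over all structures, versus the first structure) is
    >= ``threshold`` are dropped; this repeats until the residue set is
    stable.  Residues of the initial selection absent from any structure
    are dropped up front with a warning.
    """
    if len(structures) < 2:
        raise DegenerateInputError("need at least 2 structures")
    sel = initial.with_atom_filter(backbone_atoms)
    anchor = structures[0]

    # residues present (with >= 1 backbone atom) in every structure
    selections: list[Selection] = [select_atoms(s, sel) for s in structures]
    present_sets = []
    for picked in selections:
        m = picked.model
        present_sets.append({(m.chain_ids[i], int(m.residue_numbers[i])) for i in range(len(m))})
    current = set.intersection(*present_sets)
    requested = set(sel.residues())
    dropped = requested - current
    if dropped:
        warnings.warn(
            f"{len(dropped)} residue(s) of the initial core are absent from at "
            "least one structure and were dropped",
            stacklevel=2,
        )

    candidates = set(current)
    all_sel = ResidueSelection.from_residues(sorted(candidates), backbone_atoms)
    for _ in range(max_iter):
        if len(current) < 3:
            raise ConvergenceError("static core shrank below 3 residues")
        core_sel = ResidueSelection.from_residues(sorted(current), backbone_atoms)
        # superpose on the current core, but evaluate every candidate
        # residue, so residues unfairly penalized by an earlier
        # compromise fit can re-enter once the core is clean
        acc: dict[tuple, list] = {r: [] for r in candidates}
        for s in structures[1:]:
            core_a, core_b, _ = pair_atoms(
                select_atoms(s, core_sel).model, select_atoms(anchor, core_sel).model
            )
            fit = superpose(core_a, core_b)
            ca, cb, keys = pair_atoms(
                select_atoms(s, all_sel).model, select_atoms(anchor, all_sel).model
            )
            diff = fit.transform.apply(ca) - cb
            sq = np.einsum("ij,ij->i", diff, diff)
            for k, v in zip(keys, sq):
                acc[(k[0], k[1])].append(v)
        rmsd_by_res = {r: float(np.sqrt(np.mean(v))) for r, v in acc.items() if v}
        new = {r for r in candidates if rmsd_by_res.get(r, np.inf) < threshold}
        if new == current:
            return ResidueSelection.from_residues(sorted(current), initial.atom_filter)
        current = new
    raise ConvergenceError(f"core refinement did not converge in {max_iter} iterations")
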