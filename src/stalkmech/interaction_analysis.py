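"""Contact networks and base-stacking overlap geometry.

Contacts are heavy-atom pairs within a distance cutoff (4.0 A default;
no universal convention exists, so the cutoff is exposed everywhere).
A contact is classed ``minor_groove`` when either atom is on a
nucleotide's minor-groove face (O2'; purine N1/C2/N3; pyrimidine O2),
the A-minor convention.  Named catalogs of expected interactions (the
transient 50S-30S bridge formed by the closed L1 stalk head, the B7a
bridge, and the helix-68 minor-groove network) are evaluated by
:func:`bridge_report`, which marks unresolvable entries "absent
residue" rather than raising.

Stacking between two base pairs is quantified by projecting the ring
atoms of both pairs onto the mean plane of the first pair and
intersecting the convex hulls of the projected rings: a deterministic,
parameter-free proxy for visual stacking-overlap panels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint

from .errors import EmptySelectionError, MissingAtomError
from .structure_io import ResidueSelection, StructureModel, select_atoms

DEFAULT_CONTACT_CUTOFF = 4.0  # Angstrom, heavy-atom

PURINE_RING_ATOMS = frozenset({"N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9"})
PYRIMIDINE_RING_ATOMS = frozenset({"N1", "C2", "N3", "C4", "C5", "C6"})
_PURINES = {"A", "G", "DA", "DG"}
_PYRIMIDINES = {"C", "U", "T", "DC", "DT"}

#: nucleotide atoms on the minor-groove (A-minor) face
_MINOR_GROOVE_FACE = {
    "purine": {"O2'", "N3", "C2", "N1"},
    "pyrimidine": {"O2'", "O2"},
}


@dataclass(frozen=True)
class Contact:
    atom_a: tuple
    atom_b: tuple
    distance: float
    contact_class: str  # "minor_groove" | "other"


@dataclass(frozen=True)
class StackingOverlap:
    pair_a: tuple
    pair_b: tuple
    overlap_area: float
    interplanar_distance: float
    planarity_angle: float


def _is_minor_groove_atom(residue_name: str, atom_name: str) -> bool:
    if residue_name in _PURINES:
        return atom_name in _MINOR_GROOVE_FACE["purine"]
    if residue_name in _PYRIMIDINES:
        return atom_name in _MINOR_GROOVE_FACE["pyrimidine"]
    return False


def _heavy(model: StructureModel) -> StructureModel:
    mask = np.array([e.upper() not in ("H", "D") for e in model.elements])
    if not mask.any():
        raise EmptySelectionError("no heavy atoms in selection")
    return model.subset(mask)


def contact_map(
    structure: StructureModel,
    sel_a: ResidueSelection,
    sel_b: ResidueSelection,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> list:
    """All inter-selection heavy-atom pairs within ``cutoff`` Angstrom."""
    ma = _heavy(select_atoms(structure, sel_a).model)
    mb = _heavy(select_atoms(structure, sel_b).model)
    pairs = cKDTree(ma.coords).query_ball_tree(cKDTree(mb.coords), r=cutoff)
    out = []
    for i, js in enumerate(pairs):
        key_a = (ma.chain_ids[i], int(ma.residue_numbers[i]), ma.atom_names[i])
        for j in js:
            key_b = (mb.chain_ids[j], int(mb.residue_numbers[j]), mb.atom_names[j])
            if key_a == key_b:
                continue
            d = float(np.linalg.norm(ma.coords[i] - mb.coords[j]))
            minor = _is_minor_groove_atom(ma.residue_names[i], ma.atom_names[i]) or (
                _is_minor_groove_atom(mb.residue_names[j], mb.atom_names[j])
            )
            out.append(Contact(key_a, key_b, d, "minor_groove" if minor else "other"))
    out.sort(key=lambda c: (c.atom_a, c.atom_b))
    return out


def bridge_report(
    structure: StructureModel,
    catalog: Sequence[Mapping],
    chain_map: Mapping[str, str],
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> pd.DataFrame:
    """Evaluate a named catalog of expected interactions.

    ``catalog`` entries are mappings with keys ``name``, ``a`` and
    ``b``; each side has a ``role`` (resolved to a chain id through
    ``chain_map``) and optional ``residues`` (list of residue numbers
    or [start, end] ranges; whole chain if omitted).  Returns one row
    per entry with columns name, found, min_distance, status.  Entries
    whose chains or residues are missing from the structure get status
    "absent residue" instead of raising.
    """
    rows = []
    for entry in catalog:
        name = entry["name"]
        sels = []
        status = "ok"
        for side in ("a", "b"):
            role = entry[side]["role"]
            chain = chain_map.get(role)
            if chain is None or chain not in structure.chains():
                status = "absent residue"
                break
            residues = entry[side].get("residues")
            if residues is None:
                nums = structure.residue_numbers[structure.chain_ids == chain]
                ranges = [(chain, int(nums.min()), int(nums.max()))]
            else:
                ranges = []
                for r in residues:
                    if isinstance(r, (list, tuple)):
                        ranges.append((chain, int(r[0]), int(r[1])))
                    else:
                        ranges.append((chain, int(r), int(r)))
            sel = ResidueSelection(tuple(ranges))
            try:
                sels.append(select_atoms(structure, sel).model)
            except EmptySelectionError:
                status = "absent residue"
                break
        if status != "ok":
            rows.append({"name": name, "found": False, "min_distance": np.nan, "status": status})
            continue
        ma, mb = _heavy(sels[0]), _heavy(sels[1])
        d, _ = cKDTree(mb.coords).query(ma.coords, k=1)
        min_d = float(np.min(d))
        rows.append(
            {"name": name, "found": bool(min_d <= cutoff), "min_distance": min_d, "status": "ok"}
        )
    return pd.DataFrame(rows, columns=["name", "found", "min_distance", "status"])


def _ring_atoms(structure: StructureModel, chain: str, resnum: int) -> np.ndarray:
    idx = [
        i
        for i in range(len(structure))
        if structure.chain_ids[i] == chain and structure.residue_numbers[i] == resnum
    ]
    if not idx:
        raise MissingAtomError(f"residue {chain}:{resnum} not found")
    resname = structure.residue_names[idx[0]]
    wanted = PURINE_RING_ATOMS if resname in _PURINES else PYRIMIDINE_RING_ATOMS
    got = {structure.atom_names[i]: structure.coords[i] for i in idx if structure.atom_names[i] in wanted}
    missing = sorted(wanted - set(got))
    if missing:
        raise MissingAtomError(f"residue {chain}:{resnum} ({resname}) lacks ring atoms {missing}")
    return np.array([got[n] for n in sorted(got)])


def _pair_ring_coords(structure: StructureModel, pair: Sequence) -> np.ndarray:
    (c1, r1), (c2, r2) = pair
    return np.vstack([_ring_atoms(structure, c1, int(r1)), _ring_atoms(structure, c2, int(r2))])


def _mean_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    return centroid, vt[2]


def stacking_overlap(
    structure: StructureModel, pair_a: Sequence, pair_b: Sequence
) -> StackingOverlap:
    """Projected ring-polygon overlap between two (stacked) base pairs.

    Each pair is ((chain, residue), (chain, residue)).  The mean plane
    of ``pair_a``'s ring atoms defines the projection plane; the
    overlap area is the intersection of the two pairs' projected
    convex hulls (A^2).
    """
    ra = _pair_ring_coords(structure, pair_a)
    rb = _pair_ring_coords(structure, pair_b)
    centroid_a, normal = _mean_plane(ra)
    centroid_b = rb.mean(axis=0)
    _, normal_b = _mean_plane(rb)

    # in-plane basis
    e1 = np.cross(normal, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(normal, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)

    def project(coords):
        rel = coords - centroid_a
        return np.column_stack([rel @ e1, rel @ e2])

    hull_a = MultiPoint(project(ra)).convex_hull
    hull_b = MultiPoint(project(rb)).convex_hull
    area = float(hull_a.intersection(hull_b).area)

    cosang = abs(float(np.dot(normal, normal_b)))
    angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    dist = abs(float(np.dot(centroid_b - centroid_a, normal)))
    return StackingOverlap(
        tuple(map(tuple, pair_a)), tuple(map(tuple, pair_b)), area, dist, angle
    )


def hull_area(structure: StructureModel, pair: Sequence) -> float:
    """In-plane convex-hull area of one base pair's projected ring atoms."""
    ra = _pair_ring_coords(structure, pair)
    centroid, normal = _mean_plane(ra)
    e1 = np.cross(normal, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(normal, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    rel = ra - centroid
    return float(MultiPoint(np.column_stack([rel @ e1, rel @ e2])).convex_hull.area)
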