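"""Coordinate I/O and residue selections.

Structures are held in a light array-backed container
(:class:`StructureModel`) with author (PDB) residue numbering, 1-based,
inclusive ranges throughout.  Reading and writing of PDB/mmCIF goes
through :mod:`gemmi`; alternate locations are resolved to the highest
occupancy conformer (ties broken alphabetically by altloc id).

Selections are lists of inclusive residue ranges per chain, optionally
restricted to a set of atom names (e.g. the sugar-phosphate backbone).
Curated presets — the rRNA static-core residue lists, the mobile/static
helix definitions of the L1 stalk and the named displacement markers —
are shipped as YAML package data and loaded via :mod:`stalkmech.presets`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gemmi
import numpy as np

from .errors import ConfigError, EmptySelectionError, EmptyStructureError, FormatError

#: Sugar-phosphate backbone atom names used for core refinement and
#: domain superpositions (heavy atoms of the phosphodiester backbone).
BACKBONE_ATOMS = frozenset({"P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'"})

SPECIES_TAGS = ("bacterial", "eukaryotic", "synthetic")


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity plus Cartesian position in Angstrom."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray
    altloc: str = ""
    model_index: int = 1


class StructureModel:
    """Array-backed collection of atoms for one conformer.

    Atoms are stored sorted by (chain_id, residue_number), stable within
    a residue.  The identity key (chain, residue_number, atom_name,
    altloc, model_index) is unique.
    """

    __slots__ = (
        "chain_ids",
        "residue_numbers",
        "residue_names",
        "atom_names",
        "elements",
        "altlocs",
        "coords",
        "model_index",
        "source_id",
        "species_tag",
        "_key_index",
    )

    def __init__(
        self,
        chain_ids: Sequence[str],
        residue_numbers: Sequence[int],
        residue_names: Sequence[str],
        atom_names: Sequence[str],
        elements: Sequence[str],
        coords: np.ndarray,
        altlocs: Sequence[str] | None = None,
        model_index: int = 1,
        source_id: str = "",
        species_tag: str = "synthetic",
    ):
        n = len(chain_ids)
        if n == 0:
            raise EmptyStructureError(f"structure {source_id!r} has no atoms")
        if species_tag not in SPECIES_TAGS:
            raise ConfigError(f"unknown species_tag {species_tag!r}")
        coords = np.asarray(coords, dtype=float).reshape(n, 3)
        if not np.all(np.isfinite(coords)):
            raise ConfigError("non-finite coordinates")
        chain_ids = np.asarray(chain_ids, dtype=object)
        residue_numbers = np.asarray(residue_numbers, dtype=np.int64)
        residue_names = np.asarray(residue_names, dtype=object)
        atom_names = np.asarray(atom_names, dtype=object)
        elements = np.asarray(elements, dtype=object)
        if altlocs is None:
            altlocs = np.full(n, "", dtype=object)
        else:
            altlocs = np.asarray(altlocs, dtype=object)

        # stable sort by (chain, residue number); atom order within a
        # residue is preserved from the input
        order = np.lexsort((np.arange(n), residue_numbers, chain_ids.astype(str)))
        self.chain_ids = chain_ids[order]
        self.residue_numbers = residue_numbers[order]
        self.residue_names = residue_names[order]
        self.atom_names = atom_names[order]
        self.elements = elements[order]
        self.altlocs = altlocs[order]
        self.coords = coords[order]
        self.model_index = int(model_index)
        self.source_id = source_id
        self.species_tag = species_tag
        self._key_index = None

        keys = set()
        for i in range(n):
            k = (self.chain_ids[i], int(self.residue_numbers[i]), self.atom_names[i], self.altlocs[i])
            if k in keys:
                raise ConfigError(f"duplicate atom identity {k} in {source_id!r}")
            keys.add(k)

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_atoms(
        cls,
        atoms: Iterable[AtomRecord],
        source_id: str = "",
        species_tag: str = "synthetic",
    ) -> "StructureModel":
        atoms = list(atoms)
        return cls(
            [a.chain_id for a in atoms],
            [a.residue_number for a in atoms],
            [a.residue_name for a in atoms],
            [a.atom_name for a in atoms],
            [a.element for a in atoms],
            np.array([a.position for a in atoms], dtype=float).reshape(len(atoms), 3),
            [a.altloc for a in atoms],
            atoms[0].model_index if atoms else 1,
            source_id,
            species_tag,
        )

    # -- basic protocol -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.chain_ids)

    def iter_atoms(self) -> Iterator[AtomRecord]:
        for i in range(len(self)):
            yield AtomRecord(
                self.chain_ids[i],
                int(self.residue_numbers[i]),
                self.residue_names[i],
                self.atom_names[i],
                self.elements[i],
                self.coords[i].copy(),
                self.altlocs[i],
                self.model_index,
            )

    @property
    def key_index(self) -> Mapping[tuple, int]:
        """Map (chain_id, residue_number, atom_name) -> row index."""
        if self._key_index is None:
            self._key_index = {
                (self.chain_ids[i], int(self.residue_numbers[i]), self.atom_names[i]): i
                for i in range(len(self))
            }
        return self._key_index

    def get_atom_index(self, chain_id: str, residue_number: int, atom_name: str) -> int | None:
        return self.key_index.get((chain_id, residue_number, atom_name))

    def subset(self, mask: np.ndarray, source_id: str | None = None) -> "StructureModel":
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise EmptyStructureError("subset selects no atoms")
        return StructureModel(
            self.chain_ids[mask],
            self.residue_numbers[mask],
            self.residue_names[mask],
            self.atom_names[mask],
            self.elements[mask],
            self.coords[mask],
            self.altlocs[mask],
            self.model_index,
            self.source_id if source_id is None else source_id,
            self.species_tag,
        )

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        out = self.subset(np.ones(len(self), dtype=bool))
        out.coords = np.asarray(coords, dtype=float).reshape(len(self), 3)
        return out

    def present_residues(self, chain_id: str) -> set:
        return set(self.residue_numbers[self.chain_ids == chain_id].tolist())

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(c)
        return list(seen)


# -- residue selections -------------------------------------------------------


def _normalize_ranges(ranges: Iterable[tuple]) -> tuple:
    """Sort ranges and merge overlapping/adjacent ones per chain."""
    by_chain: dict[str, list[list[int]]] = {}
    for chain, start, end in ranges:
        start, end = int(start), int(end)
        if start > end:
            raise ConfigError(f"selection range start {start} > end {end}")
        by_chain.setdefault(str(chain), []).append([start, end])
    out = []
    for chain in sorted(by_chain):
        merged: list[list[int]] = []
        for start, end in sorted(by_chain[chain]):
            if merged and start <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        out.extend((chain, a, b) for a, b in merged)
    return tuple(out)


@dataclass(frozen=True)
class ResidueSelection:
    """Inclusive residue ranges per chain, with an optional atom-name filter."""

    ranges: tuple
    atom_filter: frozenset | None = None

    def __post_init__(self):
        object.__setattr__(self, "ranges", _normalize_ranges(self.ranges))
        if self.atom_filter is not None:
            object.__setattr__(self, "atom_filter", frozenset(self.atom_filter))

    @classmethod
    def from_ranges(
        cls,
        chain_id: str,
        pairs: Iterable[tuple],
        atom_filter: Iterable[str] | None = None,
    ) -> "ResidueSelection":
        return cls(
            tuple((chain_id, a, b) for a, b in pairs),
            None if atom_filter is None else frozenset(atom_filter),
        )

    @classmethod
    def from_residues(
        cls, residues: Iterable[tuple], atom_filter: Iterable[str] | None = None
    ) -> "ResidueSelection":
        return cls(
            tuple((c, r, r) for c, r in residues),
            None if atom_filter is None else frozenset(atom_filter),
        )

    def residues(self) -> Iterator[tuple]:
        for chain, start, end in self.ranges:
            for r in range(start, end + 1):
                yield (chain, r)

    def with_atom_filter(self, atom_filter: Iterable[str] | None) -> "ResidueSelection":
        return ResidueSelection(self.ranges, None if atom_filter is None else frozenset(atom_filter))

    def with_chain(self, chain_id: str) -> "ResidueSelection":
        """Rebind every range to a single chain (used for chain-agnostic presets)."""
        return ResidueSelection(
            tuple((chain_id, a, b) for _, a, b in self.ranges), self.atom_filter
        )

    def shifted(self, offsets: Mapping[str, int]) -> "ResidueSelection":
        """Apply per-chain residue-numbering offsets (user-supplied maps)."""
        return ResidueSelection(
            tuple((c, a + offsets.get(c, 0), b + offsets.get(c, 0)) for c, a, b in self.ranges),
            self.atom_filter,
        )


@dataclass(frozen=True)
class Selection:
    """Result of :func:`select_atoms`: the atoms plus the absent residues."""

    model: StructureModel
    absent_residues: tuple


def select_atoms(structure: StructureModel, selection: ResidueSelection) -> Selection:
    """Resolve a :class:`ResidueSelection` against a structure.

    Returns atoms in residue order and records which requested residues
    had no matching atoms.  Raises :class:`EmptySelectionError` if the
    selection resolves to zero atoms.
    """
    mask = np.zeros(len(structure), dtype=bool)
    for chain, start, end in selection.ranges:
        mask |= (
            (structure.chain_ids == chain)
            & (structure.residue_numbers >= start)
            & (structure.residue_numbers <= end)
        )
    if selection.atom_filter is not None:
        mask &= np.isin(structure.atom_names, list(selection.atom_filter))
    if not mask.any():
        raise EmptySelectionError(f"selection {selection.ranges} matched no atoms")
    sub = structure.subset(mask)
    present = {
        (sub.chain_ids[i], int(sub.residue_numbers[i])) for i in range(len(sub))
    }
    absent = tuple(r for r in selection.residues() if r not in present)
    return Selection(sub, absent)


# -- file I/O -----------------------------------------------------------------

_FORMATS = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif, "auto": gemmi.CoorFormat.Detect}


def read_structure(
    path: str | Path,
    format: str = "auto",
    model_index: int = 1,
    source_id: str | None = None,
    species_tag: str = "bacterial",
) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Model ``model_index`` (1-based, default first) is used.  Alternate
    locations are resolved to the highest-occupancy conformer, ties
    broken alphabetically by altloc identifier.
    """
    path = Path(path)
    if format not in _FORMATS:
        raise ConfigError(f"unknown format {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError, IndexError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path} contains no models")
    if model_index > len(st):
        raise ConfigError(f"model {model_index} requested but file has {len(st)}")
    model = st[model_index - 1]

    chain_ids, res_nums, res_names, atom_names, elements, altlocs, xyz = (
        [], [], [], [], [], [], []
    )
    for chain in model:
        for residue in chain:
            # altloc resolution: per atom name keep max occupancy,
            # ties -> alphabetically first altloc id
            best: dict[str, tuple] = {}
            for i_at, atom in enumerate(residue):
                alt = atom.altloc if atom.altloc not in ("\x00", " ", "") else ""
                occ = atom.occ if atom.occ else 1.0
                prev = best.get(atom.name)
                if prev is None or occ > prev[0] or (occ == prev[0] and (alt or "~") < (prev[1] or "~")):
                    best[atom.name] = (occ, alt, i_at)
            for i_at, atom in enumerate(residue):
                sel = best[atom.name]
                if sel[2] != i_at:
                    continue
                chain_ids.append(chain.name)
                res_nums.append(residue.seqid.num)
                res_names.append(residue.name.strip())
                atom_names.append(atom.name)
                elements.append(atom.element.name)
                altlocs.append(sel[1])
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not chain_ids:
        raise EmptyStructureError(f"{path} has no atoms in model {model_index}")
    return StructureModel(
        chain_ids,
        res_nums,
        res_names,
        atom_names,
        elements,
        np.array(xyz, dtype=float),
        altlocs,
        model_index,
        source_id if source_id is not None else path.stem,
        species_tag,
    )


def _guess_element(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def write_structure(structure: StructureModel, path: str | Path, format: str = "auto") -> None:
    """Write a structure as PDB or mmCIF (format inferred from suffix if auto)."""
    path = Path(path)
    if format == "auto":
        format = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    if format not in ("pdb", "mmcif"):
        raise ConfigError(f"unknown format {format!r}")

    st = gemmi.Structure()
    st.name = structure.source_id or "stalkmech"
    model = gemmi.Model("1")
    chain = None
    residue = None
    for a in structure.iter_atoms():
        if chain is None or chain.name != a.chain_id:
            chain = model.add_chain(gemmi.Chain(a.chain_id))
            residue = None
        if residue is None or residue.seqid.num != a.residue_number:
            new_res = gemmi.Residue()
            new_res.name = a.residue_name
            new_res.seqid = gemmi.SeqId(a.residue_number, " ")
            residue = chain.add_residue(new_res)
        atom = gemmi.Atom()
        atom.name = a.atom_name
        atom.element = gemmi.Element(a.element or _guess_element(a.atom_name))
        atom.pos = gemmi.Position(*a.position)
        atom.occ = 1.0
        atom.b_iso = 0.0
        if a.altloc:
            atom.altloc = a.altloc
        residue.add_atom(atom)
    st.add_model(model)
    st.setup_entities()
    if format == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))
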