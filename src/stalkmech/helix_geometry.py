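"""Helical-axis tracing, deviation profiles and hinge localization.

The local axis of an (approximately) A-form duplex is traced from the
backbone + C1' (+ ring, where consecutive residues share a base) atoms
of both strands, in windows of three consecutive base pairs.  For each
window the rigid transform carrying the dinucleotide slab (pairs i,
i+1) onto (pairs i+1, i+2), matched by atom name within each strand,
is fitted by least squares and decomposed into its screw axis.  Within
a helically regular segment that screw axis coincides exactly with the
helix axis, so projecting the C1'-C1' pair midpoints onto the window
axis yields one axis-point estimate per covered pair; each pair keeps
the estimate from the best-fitting (lowest post-fit RMSD) of its
covering windows, so windows internally strained by a hinge are used
only where no regular window covers a pair.  The construction is local
— a hinge perturbs only the windows that bridge it — and averages tens
of atoms per fit, which keeps the axis trace stable under coordinate
noise.  This is a deliberately minimal replacement for full
helicoidal-parameter machinery (Curves+-style): only axis positions are
needed, because hinge localization rides on Angstrom-scale deviations
that dominate sub-Angstrom axis-definition differences.

Deviation profiles are per-pair distances between a trace and a
reference trace (structures already superposed on a common static
core); hinge points appear as local maxima of the second difference of
the smoothed profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks
from scipy.spatial import cKDTree

from .errors import (
    EmptySelectionError,
    IncompatibleTracesError,
    MissingAtomError,
    TooShortError,
)
from .structure_io import ResidueSelection, StructureModel, select_atoms

ANCHOR_ATOM = "C1'"


@dataclass(frozen=True)
class HelicalAxisTrace:
    """Ordered (residue_label, axis_point) samples of a helical axis."""

    labels: tuple
    points: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(int(x) for x in self.labels))
        pts = np.asarray(self.points, dtype=float).reshape(len(self.labels), 3)
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.labels)

    def tangents(self) -> np.ndarray:
        """Unit tangent per segment between consecutive axis points."""
        d = np.diff(self.points, axis=0)
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    def transformed(self, transform) -> "HelicalAxisTrace":
        return HelicalAxisTrace(self.labels, transform.apply(self.points))


@dataclass(frozen=True)
class DeviationProfile:
    """Per-residue-position displacement (A) of an axis trace vs a reference."""

    labels: tuple
    deviations: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(int(x) for x in self.labels))
        dev = np.asarray(self.deviations, dtype=float).reshape(len(self.labels))
        object.__setattr__(self, "deviations", dev)

    def __len__(self) -> int:
        return len(self.labels)


#: atoms used for the per-window rigid fits (conformation-stable backbone set)
_STEP_FIT_ATOMS = ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'", "C1'")
#: ring atoms, included in a fit only across same-name residues
_RING_FIT_ATOMS = ("N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6")


def _pair_frames(structure: StructureModel, pairing: Sequence, anchor_atom: str):
    """Per usable pair: backbone/C1'/ring atom coordinates of both residues
    keyed by (strand, atom name), residue names per strand, label and the
    C1'-C1' midpoint.  Pairs with missing anchors are skipped (error if
    more than 20% are skipped)."""
    frames, labels, mids, skipped = [], [], [], []
    for (ch1, r1), (ch2, r2) in pairing:
        i = structure.get_atom_index(ch1, int(r1), anchor_atom)
        j = structure.get_atom_index(ch2, int(r2), anchor_atom)
        if i is None or j is None:
            skipped.append(((ch1, r1), (ch2, r2)))
            continue
        atoms = {}
        resnames = {}
        for strand, (ch, rn) in enumerate(((ch1, int(r1)), (ch2, int(r2)))):
            for name in _STEP_FIT_ATOMS + _RING_FIT_ATOMS:
                k = structure.get_atom_index(ch, rn, name)
                if k is not None:
                    atoms[(strand, name)] = structure.coords[k]
                    resnames[strand] = structure.residue_names[k]
        frames.append((atoms, resnames))
        labels.append(int(r1))
        mids.append((structure.coords[i] + structure.coords[j]) / 2.0)
    if len(pairing) and len(skipped) / len(pairing) > 0.2:
        raise MissingAtomError(
            f"{len(skipped)}/{len(pairing)} base pairs lack {anchor_atom} anchors: {skipped}"
        )
    return frames, labels, np.array(mids)


def trace_helical_axis(
    structure: StructureModel,
    pairing: Sequence,
    anchor_atom: str = ANCHOR_ATOM,
) -> HelicalAxisTrace:
    """Trace the local helical axis through an ordered base-pair list.

    ``pairing`` is an ordered sequence of ((chain, residue), (chain,
    residue)) tuples, 5' strand first; the trace is labelled by the
    first strand's residue numbers.  At least 4 pairs are required.

    For each 3-pair window the rigid transform carrying the dinucleotide
    slab (pairs i, i+1) onto (pairs i+1, i+2) is fitted and decomposed
    into its screw axis — within a regular helical stretch this is the
    local helix axis.  Pair midpoints are projected onto the window
    axis; each pair takes the estimate from the best-fitting (lowest
    post-fit RMSD) of its covering windows, so a window bridging a
    hinge, whose slab is internally strained, is not used where a
    regular window is available.
    """
    # local import avoids a cycle (superposition does not import this module)
    from .superposition import superpose
    from .er_kinematics import er_decompose

    if len(pairing) < 4:
        raise TooShortError(f"need >= 4 base pairs, got {len(pairing)}")
    frames, labels, mid = _pair_frames(structure, pairing, anchor_atom)
    n = len(labels)
    if n < 4:
        raise TooShortError(f"only {n} usable base pairs after skipping missing anchors")

    estimates: list[list] = [[] for _ in range(n)]
    for i in range(n - 2):
        src, dst = [], []
        for off in (0, 1):
            a_atoms, a_res = frames[i + off]
            b_atoms, b_res = frames[i + off + 1]
            for key in set(a_atoms) & set(b_atoms):
                strand, name = key
                if name in _RING_FIT_ATOMS and a_res.get(strand) != b_res.get(strand):
                    continue
                src.append(a_atoms[key])
                dst.append(b_atoms[key])
        if len(src) < 3:
            continue
        fit = superpose(np.array(src), np.array(dst))
        screw = er_decompose(fit.transform, angle_floor=1e-6)
        if screw.undefined:
            # locally untwisted: fall back to the pair midpoints themselves
            for j in (i, i + 1, i + 2):
                estimates[j].append((np.inf, mid[j]))
            continue
        for j in (i, i + 1, i + 2):
            estimates[j].append((fit.rmsd, screw.point_on_axis_closest_to(mid[j])))

    if any(not e for e in estimates):
        raise TooShortError("too many unusable windows to trace the axis")
    axis_points = np.array([min(e, key=lambda t: t[0])[1] for e in estimates])
    return HelicalAxisTrace(tuple(labels), axis_points)


def deviation_profile(trace: HelicalAxisTrace, reference: HelicalAxisTrace) -> DeviationProfile:
    """Pointwise distance between two traces on their shared labels."""
    ref_map = {lab: reference.points[i] for i, lab in enumerate(reference.labels)}
    labels, devs = [], []
    for i, lab in enumerate(trace.labels):
        if lab in ref_map:
            labels.append(lab)
            devs.append(float(np.linalg.norm(trace.points[i] - ref_map[lab])))
    if not labels:
        raise IncompatibleTracesError("traces share no residue labels")
    return DeviationProfile(tuple(labels), np.array(devs))


def average_trace(traces: Sequence[HelicalAxisTrace]) -> HelicalAxisTrace:
    """Pointwise mean trace over the labels shared by all input traces."""
    if not traces:
        raise IncompatibleTracesError("no traces given")
    shared = set(traces[0].labels)
    for t in traces[1:]:
        shared &= set(t.labels)
    if not shared:
        raise IncompatibleTracesError("traces share no residue labels")
    labels = [lab for lab in traces[0].labels if lab in shared]
    maps = [{lab: t.points[i] for i, lab in enumerate(t.labels)} for t in traces]
    pts = np.array([np.mean([m[lab] for m in maps], axis=0) for lab in labels])
    return HelicalAxisTrace(tuple(labels), pts)


def trace_spread(traces: Sequence[HelicalAxisTrace]) -> DeviationProfile:
    """Per-point spread (max pairwise distance) across traces, on shared labels."""
    avg = average_trace(traces)
    maps = [{lab: t.points[i] for i, lab in enumerate(t.labels)} for t in traces]
    spread = []
    for lab in avg.labels:
        pts = np.array([m[lab] for m in maps])
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        spread.append(float(d.max()))
    return DeviationProfile(avg.labels, np.array(spread))


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    kernel = np.ones(window) / window
    padded = np.pad(values, window // 2, mode="edge")
    out = np.convolve(padded, kernel, mode="valid")
    return out[: len(values)]


def find_inflections(
    profile: DeviationProfile,
    smoothing_window: int = 3,
    min_prominence: float = 0.5,
    stencil: int = 3,
) -> list:
    """Residue labels at inflection (hinge) points of a deviation profile.

    The profile is moving-average smoothed, the discrete second
    difference taken on a stencil of half-width ``stencil`` points
    (``p[i-s] - 2 p[i] + p[i+s]``; the wider stencil integrates the
    slope change over several steps, which stabilizes hinge calling on
    noisy profiles without shifting the peak), and prominence-filtered
    local maxima are returned sorted by position.  A straight-line
    profile yields no inflections.
    """
    if len(profile) < 2 * smoothing_window + 3:
        raise TooShortError(
            f"profile of {len(profile)} points too short for window {smoothing_window}"
        )
    labels, _ = _inflections_with_prominence(profile, smoothing_window, min_prominence, stencil)
    return labels


def _inflections_with_prominence(
    profile: DeviationProfile,
    smoothing_window: int,
    min_prominence: float,
    stencil: int = 3,
) -> tuple[list, list]:
    smoothed = _smooth(profile.deviations, smoothing_window)
    s = max(1, min(int(stencil), (len(smoothed) - 1) // 2))
    d2 = np.zeros_like(smoothed)
    d2[s:-s] = smoothed[: -2 * s] - 2.0 * smoothed[s:-s] + smoothed[2 * s:]
    peaks, props = find_peaks(d2, prominence=min_prominence)
    labels = [profile.labels[i] for i in peaks]
    return labels, list(props["prominences"])


def strongest_inflection(
    profile: DeviationProfile,
    smoothing_window: int = 3,
    min_prominence: float = 0.0,
    stencil: int = 3,
) -> int | None:
    """Label of the most prominent inflection, or None if there is none."""
    labels, proms = _inflections_with_prominence(
        profile, smoothing_window, min_prominence, stencil
    )
    if not labels:
        return None
    return labels[int(np.argmax(proms))]


def groove_width(structure: StructureModel, atom_a: tuple, atom_b: tuple) -> float:
    """Distance (A) between two named atoms, e.g. the P2093-P2189 groove width."""
    out = []
    for chain, resnum, name in (atom_a, atom_b):
        i = structure.get_atom_index(chain, int(resnum), name)
        if i is None:
            raise MissingAtomError(f"atom {(chain, resnum, name)} not found")
        out.append(structure.coords[i])
    return float(np.linalg.norm(out[0] - out[1]))


def closest_approach(
    structure: StructureModel,
    sel_a: ResidueSelection,
    sel_b: ResidueSelection,
) -> tuple[float, tuple]:
    """Minimum heavy-atom distance between two selections and the atom pair.

    Identical atoms (same identity in overlapping selections) are
    excluded; ties are broken by atom identity ordering.
    """
    ma = _heavy(select_atoms(structure, sel_a).model)
    mb = _heavy(select_atoms(structure, sel_b).model)
    tree = cKDTree(mb.coords)
    k = min(2, len(mb)) if _may_overlap(ma, mb) else 1
    dists, idx = tree.query(ma.coords, k=k)
    dists = np.atleast_2d(dists.T).T
    idx = np.atleast_2d(idx.T).T

    best = (np.inf, None)
    for i in range(len(ma)):
        key_a = (ma.chain_ids[i], int(ma.residue_numbers[i]), ma.atom_names[i])
        for d, j in zip(dists[i], idx[i]):
            j = int(j)
            key_b = (mb.chain_ids[j], int(mb.residue_numbers[j]), mb.atom_names[j])
            if key_a == key_b:
                continue
            cand = (float(d), (key_a, key_b))
            if cand[0] < best[0] - 1e-9 or (
                abs(cand[0] - best[0]) <= 1e-9 and best[1] is not None and cand[1] < best[1]
            ):
                best = cand
            break
    if best[1] is None:
        raise EmptySelectionError("no valid atom pairs between selections")
    return best


def _heavy(model: StructureModel) -> StructureModel:
    mask = np.array([e.upper() not in ("H", "D") for e in model.elements])
    if not mask.any():
        raise EmptySelectionError("selection contains no heavy atoms")
    return model.subset(mask)


def _may_overlap(a: StructureModel, b: StructureModel) -> bool:
    ka = {(a.chain_ids[i], int(a.residue_numbers[i])) for i in range(len(a))}
    kb = {(b.chain_ids[i], int(b.residue_numbers[i])) for i in range(len(b))}
    return bool(ka & kb)
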