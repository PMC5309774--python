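"""Contact maps, interaction catalogs and stacking-overlap geometry."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from stalkmech.errors import MissingAtomError
from stalkmech.interaction_analysis import (
    bridge_report,
    contact_map,
    hull_area,
    stacking_overlap,
)
from stalkmech.presets import get_catalog
from stalkmech.structure_io import ResidueSelection, StructureModel
from stalkmech.superposition import RigidTransform
from stalkmech.synthetic_data import HelixSpec, make_aform_helix


def _pair_model(distance, atom_b="N3", res_b="A"):
    """Two single-atom residues on different chains, `distance` apart."""
    return StructureModel(
        ["A", "B"], [1, 1], ["G", res_b], ["C8", atom_b], ["C", "N"],
        np.array([[0.0, 0.0, 0.0], [distance, 0.0, 0.0]]),
    )


SEL_A = ResidueSelection((("A", 1, 1),))
SEL_B = ResidueSelection((("B", 1, 1),))


def test_contact_within_cutoff_found():
    contacts = contact_map(_pair_model(3.9), SEL_A, SEL_B, cutoff=4.0)
    assert len(contacts) == 1
    assert contacts[0].distance == pytest.approx(3.9)


def test_contact_beyond_cutoff_empty():
    assert contact_map(_pair_model(3.9), SEL_A, SEL_B, cutoff=3.5) == []


def test_minor_groove_face_classification():
    # purine N3 is on the minor-groove (A-minor) face; C8 is not
    minor = contact_map(_pair_model(3.0, atom_b="N3"), SEL_A, SEL_B)
    other = contact_map(_pair_model(3.0, atom_b="C8"), SEL_A, SEL_B)
    assert minor[0].contact_class == "minor_groove"
    assert other[0].contact_class == "other"


def test_contact_map_symmetric_under_selection_swap(straight_helix):
    # A 1-10 pairs with B 11-20 (antiparallel numbering)
    sa = ResidueSelection((("A", 1, 10),))
    sb = ResidueSelection((("B", 11, 20),))
    ab = contact_map(straight_helix.model, sa, sb, cutoff=5.0)
    ba = contact_map(straight_helix.model, sb, sa, cutoff=5.0)
    assert {frozenset((c.atom_a, c.atom_b)) for c in ab} == {
        frozenset((c.atom_a, c.atom_b)) for c in ba
    }
    assert len(ab) > 0


# -- catalogs -----------------------------------------------------------------


def test_bridge_report_marks_missing_chains_absent(straight_helix):
    catalog = [
        {"name": "present", "a": {"role": "x", "residues": [1]}, "b": {"role": "y", "residues": [20]}},
        {"name": "gone", "a": {"role": "x", "residues": [1]}, "b": {"role": "trna", "residues": [1]}},
    ]
    table = bridge_report(
        straight_helix.model, catalog, chain_map={"x": "A", "y": "B"}, cutoff=15.0
    )
    present = table[table["name"] == "present"].iloc[0]
    gone = table[table["name"] == "gone"].iloc[0]
    assert present["status"] == "ok" and bool(present["found"])
    assert gone["status"] == "absent residue" and not bool(gone["found"])


def test_packaged_b9_catalog_runs_with_role_map(straight_helix):
    # roles resolved onto the synthetic chains; far-apart residues -> not found
    table = bridge_report(
        straight_helix.model,
        get_catalog("b9"),
        chain_map={"23S": "A", "S11": "B", "S7": "B", "S13": "B", "L1": "A"},
        cutoff=4.0,
    )
    assert len(table) == 4
    # rows naming 23S residues (2100s) cannot resolve in a 20-mer helix;
    # the whole-chain L1-S13 row resolves onto the two strands
    by_name = table.set_index("name")["status"].to_dict()
    assert by_name["G2141-S11"] == "absent residue"
    assert by_name["G2116-S7"] == "absent residue"
    assert by_name["G2148-S7"] == "absent residue"
    assert by_name["L1-S13"] == "ok"


# -- stacking overlap ---------------------------------------------------------


@pytest.fixture(scope="module")
def helix_pairs(straight_helix):
    return straight_helix.model, straight_helix.base_pairs


def _translated_copy_model(model, pair, offset):
    """The two pair residues duplicated on new chains, shifted by offset."""
    (c1, r1), (c2, r2) = pair
    mask = ((model.chain_ids == c1) & (model.residue_numbers == r1)) | (
        (model.chain_ids == c2) & (model.residue_numbers == r2)
    )
    sub = model.subset(mask)
    dup = StructureModel(
        [{"A": "X", "B": "Y"}[c] for c in sub.chain_ids],
        sub.residue_numbers,
        sub.residue_names,
        sub.atom_names,
        sub.elements,
        sub.coords + np.asarray(offset),
    )
    return StructureModel(
        np.concatenate([model.chain_ids, dup.chain_ids]),
        np.concatenate([model.residue_numbers, dup.residue_numbers]),
        np.concatenate([model.residue_names, dup.residue_names]),
        np.concatenate([model.atom_names, dup.atom_names]),
        np.concatenate([model.elements, dup.elements]),
        np.vstack([model.coords, dup.coords]),
    )


def test_pair_stacked_on_its_translated_copy(helix_pairs):
    model, pairs = helix_pairs
    pair = pairs[5]
    merged = _translated_copy_model(model, pair, (0.0, 0.0, 3.4))
    copy_pair = (("X", pair[0][1]), ("Y", pair[1][1]))
    result = stacking_overlap(merged, pair, copy_pair)
    assert result.overlap_area == pytest.approx(hull_area(model, pair), rel=1e-6)
    assert result.planarity_angle == pytest.approx(0.0, abs=1e-6)
    assert result.interplanar_distance == pytest.approx(3.4, abs=1e-6)


def test_laterally_displaced_pair_has_zero_overlap(helix_pairs):
    model, pairs = helix_pairs
    pair = pairs[5]
    merged = _translated_copy_model(model, pair, (15.0, 0.0, 3.4))
    copy_pair = (("X", pair[0][1]), ("Y", pair[1][1]))
    assert stacking_overlap(merged, pair, copy_pair).overlap_area == pytest.approx(0.0)


def test_consecutive_helix_pairs_overlap_positively(helix_pairs):
    model, pairs = helix_pairs
    result = stacking_overlap(model, pairs[5], pairs[6])
    assert result.overlap_area > 0.0
    assert result.interplanar_distance == pytest.approx(2.81, abs=0.05)


def test_overlap_bounded_by_smaller_hull(helix_pairs):
    model, pairs = helix_pairs
    for i in range(4, 8):
        result = stacking_overlap(model, pairs[i], pairs[i + 1])
        bound = min(hull_area(model, pairs[i]), hull_area(model, pairs[i + 1]))
        assert result.overlap_area <= bound + 1e-9


def test_overlap_invariant_under_rigid_transform(helix_pairs):
    model, pairs = helix_pairs
    g = RigidTransform(
        Rotation.from_euler("xyz", [25, -140, 67], degrees=True).as_matrix(),
        np.array([11.0, 3.0, -9.0]),
    )
    moved = model.with_coords(g.apply(model.coords))
    a = stacking_overlap(model, pairs[5], pairs[6])
    b = stacking_overlap(moved, pairs[5], pairs[6])
    assert a.overlap_area == pytest.approx(b.overlap_area, abs=1e-3)
    assert a.planarity_angle == pytest.approx(b.planarity_angle, abs=1e-6)


def test_missing_ring_atoms_are_listed(helix_pairs):
    model, pairs = helix_pairs
    mask = ~(
        (model.chain_ids == "A") & (model.residue_numbers == 6) & (model.atom_names == "N7")
    )
    broken = model.subset(mask)
    with pytest.raises(MissingAtomError, match="N7"):
        stacking_overlap(broken, pairs[5], pairs[6])
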