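"""Helical-axis tracing, deviation profiles, hinges, grooves, approaches."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from stalkmech.errors import (
    EmptySelectionError,
    IncompatibleTracesError,
    MissingAtomError,
    TooShortError,
)
from stalkmech.helix_geometry import (
    DeviationProfile,
    HelicalAxisTrace,
    average_trace,
    closest_approach,
    deviation_profile,
    find_inflections,
    groove_width,
    strongest_inflection,
    trace_helical_axis,
    trace_spread,
)
from stalkmech.structure_io import ResidueSelection, StructureModel
from stalkmech.superposition import RigidTransform
from stalkmech.synthetic_data import HelixSpec, make_aform_helix, make_hinged_helix


@pytest.fixture(scope="module")
def ref_trace(straight_helix):
    return trace_helical_axis(straight_helix.model, straight_helix.base_pairs)


def test_straight_helix_axis_on_generating_cylinder_axis(ref_trace):
    off_axis = np.linalg.norm(ref_trace.points[:, :2], axis=1)
    assert off_axis.max() < 0.5


def test_axis_point_spacing_matches_rise(ref_trace):
    spacing = np.linalg.norm(np.diff(ref_trace.points, axis=0), axis=1)
    assert np.all(np.abs(spacing - 2.81) < 0.3)


def test_bent_helix_tangent_change_matches_imposed_bend():
    bent = make_hinged_helix(HelixSpec(n_bp=20), hinge_step=10, bend_angle=30.0)
    trace = trace_helical_axis(bent.model, bent.base_pairs)
    tangents = trace.tangents()
    a = tangents[1:8].mean(axis=0)
    b = tangents[11:18].mean(axis=0)
    a /= np.linalg.norm(a)
    b /= np.linalg.norm(b)
    angle = np.degrees(np.arccos(np.clip(np.dot(a, b), -1, 1)))
    assert angle == pytest.approx(30.0, abs=2.0)


def test_trace_equivariant_under_rigid_transform(straight_helix, ref_trace):
    g = RigidTransform(
        Rotation.from_euler("zyx", [12, 133, -76], degrees=True).as_matrix(),
        np.array([4.0, -17.0, 2.5]),
    )
    moved = straight_helix.model.with_coords(g.apply(straight_helix.model.coords))
    moved_trace = trace_helical_axis(moved, straight_helix.base_pairs)
    np.testing.assert_allclose(moved_trace.points, g.apply(ref_trace.points), atol=1e-6)


def test_too_few_pairs_rejected(straight_helix):
    with pytest.raises(TooShortError):
        trace_helical_axis(straight_helix.model, straight_helix.base_pairs[:3])


def test_missing_anchor_pairs_skipped_or_rejected(straight_helix):
    pairs = list(straight_helix.base_pairs)
    bogus = [(("A", 900 + i), ("B", 950 + i)) for i in range(len(pairs))]
    with pytest.raises(MissingAtomError):
        trace_helical_axis(straight_helix.model, pairs + bogus)


# -- deviation profiles -------------------------------------------------------


def test_profile_of_trace_vs_itself_is_zero(ref_trace):
    prof = deviation_profile(ref_trace, ref_trace)
    np.testing.assert_allclose(prof.deviations, 0.0, atol=1e-12)


def test_rigidly_translated_reference_gives_constant_profile(ref_trace):
    shifted = HelicalAxisTrace(ref_trace.labels, ref_trace.points + np.array([7.0, 0.0, 0.0]))
    prof = deviation_profile(ref_trace, shifted)
    np.testing.assert_allclose(prof.deviations, 7.0, atol=1e-12)


def test_profile_symmetric(ref_trace):
    other = HelicalAxisTrace(ref_trace.labels, ref_trace.points + np.array([1.0, -2.0, 0.5]))
    a = deviation_profile(ref_trace, other)
    b = deviation_profile(other, ref_trace)
    np.testing.assert_allclose(a.deviations, b.deviations, atol=1e-12)


def test_disjoint_labels_raise(ref_trace):
    other = HelicalAxisTrace(tuple(l + 1000 for l in ref_trace.labels), ref_trace.points)
    with pytest.raises(IncompatibleTracesError):
        deviation_profile(ref_trace, other)


def test_average_of_single_trace_is_itself(ref_trace):
    avg = average_trace([ref_trace])
    np.testing.assert_allclose(avg.points, ref_trace.points, atol=1e-12)


def test_average_of_symmetric_offsets_is_midline(ref_trace):
    d = np.array([0.0, 3.0, 0.0])
    up = HelicalAxisTrace(ref_trace.labels, ref_trace.points + d)
    down = HelicalAxisTrace(ref_trace.labels, ref_trace.points - d)
    avg = average_trace([up, down])
    np.testing.assert_allclose(avg.points, ref_trace.points, atol=1e-12)
    spread = trace_spread([up, down])
    np.testing.assert_allclose(spread.deviations, 6.0, atol=1e-12)


# -- inflection calling -------------------------------------------------------


def test_linear_profile_has_no_inflections():
    prof = DeviationProfile(tuple(range(1, 21)), np.linspace(0.0, 10.0, 20))
    assert find_inflections(prof) == []


def test_hinge_localized_on_noiseless_bend(ref_trace):
    bent = make_hinged_helix(HelixSpec(n_bp=20), hinge_step=12, bend_angle=25.0)
    trace = trace_helical_axis(bent.model, bent.base_pairs)
    prof = deviation_profile(trace, ref_trace)
    labels = find_inflections(prof)
    assert any(abs(lab - 12) <= 1 for lab in labels)
    assert abs(strongest_inflection(prof) - 12) <= 1


def test_short_profile_rejected():
    prof = DeviationProfile((1, 2, 3, 4), np.zeros(4))
    with pytest.raises(TooShortError):
        find_inflections(prof)


# -- distances ----------------------------------------------------------------


def _two_atom_model(distance):
    return StructureModel(
        ["A", "B"], [1, 1], ["G", "G"], ["P", "P"], ["P", "P"],
        np.array([[0.0, 0.0, 0.0], [distance, 0.0, 0.0]]),
    )


def test_groove_width_is_plain_distance():
    model = _two_atom_model(11.0)
    assert groove_width(model, ("A", 1, "P"), ("B", 1, "P")) == pytest.approx(11.0)
    with pytest.raises(MissingAtomError):
        groove_width(model, ("A", 1, "P"), ("B", 2, "OP1"))


def test_closest_approach_two_atoms():
    model = _two_atom_model(2.0)
    dist, pair = closest_approach(
        model, ResidueSelection((("A", 1, 1),)), ResidueSelection((("B", 1, 1),))
    )
    assert dist == pytest.approx(2.0)
    assert pair == (("A", 1, "P"), ("B", 1, "P"))


def test_closest_approach_excludes_self_pairs(straight_helix):
    sel = ResidueSelection((("A", 5, 8),))
    dist, pair = closest_approach(straight_helix.model, sel, sel)
    assert dist > 0.5  # smallest intra-selection distance, never a self-pair
    assert pair[0] != pair[1]


def test_closest_approach_empty_selection(straight_helix):
    with pytest.raises(EmptySelectionError):
        closest_approach(
            straight_helix.model,
            ResidueSelection((("A", 1, 3),)),
            ResidueSelection((("Q", 1, 3),)),
        )


def test_closest_approach_between_strands_is_symmetric(straight_helix):
    sa = ResidueSelection((("A", 1, 10),))
    sb = ResidueSelection((("B", 1, 10),))
    d_ab, pair_ab = closest_approach(straight_helix.model, sa, sb)
    d_ba, pair_ba = closest_approach(straight_helix.model, sb, sa)
    assert d_ab == pytest.approx(d_ba, abs=1e-12)
    assert pair_ab == (pair_ba[1], pair_ba[0])
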