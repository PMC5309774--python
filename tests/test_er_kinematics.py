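"""Screw-axis decomposition and domain-motion metrics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from oracles import point_line_distance, quaternion_screw, random_screw_transform

from stalkmech.er_kinematics import displacement_at, domain_rotation, er_decompose
from stalkmech.errors import MissingAtomError
from stalkmech.superposition import RigidTransform
from stalkmech.synthetic_data import HelixSpec, MotionSpec, make_two_domain_system


def test_identity_transform_flagged_undefined():
    screw = er_decompose(RigidTransform.identity())
    assert screw.angle == pytest.approx(0.0, abs=1e-12)
    assert screw.undefined


def test_quarter_turn_about_z():
    R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    screw = er_decompose(RigidTransform(R, np.zeros(3)))
    assert screw.angle == pytest.approx(90.0, abs=1e-10)
    np.testing.assert_allclose(screw.direction, [0, 0, 1], atol=1e-10)
    assert screw.pitch == pytest.approx(0.0, abs=1e-10)
    assert point_line_distance(screw.origin, np.zeros(3), np.array([0, 0, 1.0])) < 1e-10


def test_random_screws_match_quaternion_oracle(rng):
    """200 random screw motions: angle/direction/pitch/axis agree with the
    independently derived quaternion route to 1e-6."""
    for _ in range(200):
        R, T, _ = random_screw_transform(rng)
        screw = er_decompose(RigidTransform(R, T))
        o_angle, o_dir, o_pitch, o_point = quaternion_screw(R, T)
        assert screw.angle == pytest.approx(o_angle, abs=1e-6)
        np.testing.assert_allclose(screw.direction, o_dir, atol=1e-6)
        assert screw.pitch == pytest.approx(o_pitch, abs=1e-6)
        assert point_line_distance(screw.origin, o_point, o_dir) < 1e-6
        assert point_line_distance(o_point, screw.origin, screw.direction) < 1e-6


def test_rebuild_roundtrip(rng):
    for _ in range(100):
        R, T, _ = random_screw_transform(rng)
        screw = er_decompose(RigidTransform(R, T))
        rebuilt = screw.to_transform()
        np.testing.assert_allclose(rebuilt.rotation, R, atol=1e-6)
        np.testing.assert_allclose(rebuilt.translation, T, atol=1e-6)


def test_near_180_degrees_uses_symmetric_route():
    axis = np.array([1.0, 2.0, -0.5])
    axis /= np.linalg.norm(axis)
    R = Rotation.from_rotvec(np.radians(179.9) * axis).as_matrix()
    screw = er_decompose(RigidTransform(R, np.zeros(3)))
    assert screw.near_degenerate
    assert screw.angle == pytest.approx(179.9, abs=1e-6)
    assert abs(np.dot(screw.direction, axis)) > 1.0 - 1e-8


def test_small_angle_flagged_but_angle_returned():
    axis = np.array([0.0, 1.0, 0.0])
    R = Rotation.from_rotvec(np.radians(0.1) * axis).as_matrix()
    screw = er_decompose(RigidTransform(R, np.zeros(3)))
    assert screw.undefined
    assert screw.angle == pytest.approx(0.1, abs=1e-9)


# -- domain rotation ----------------------------------------------------------


def test_structure_equal_to_reference_gives_zero(two_domain_26):
    screw = domain_rotation(
        two_domain_26.reference,
        two_domain_26.reference,
        two_domain_26.static_selection,
        two_domain_26.mobile_selection,
    )
    assert screw.angle == pytest.approx(0.0, abs=1e-9)


def test_imposed_rotation_recovered_exactly(two_domain_26):
    screw = domain_rotation(
        two_domain_26.moved,
        two_domain_26.reference,
        two_domain_26.static_selection,
        two_domain_26.mobile_selection,
    )
    assert screw.angle == pytest.approx(26.5, abs=1e-6)
    assert np.dot(screw.direction, two_domain_26.motion.axis_direction) > 0.999999


def test_noisy_rotation_recovered_within_half_degree():
    system = make_two_domain_system(
        HelixSpec(n_bp=16), HelixSpec(n_bp=12), MotionSpec(angle=26.5, noise_sigma=0.2, seed=5)
    )
    screw = domain_rotation(
        system.moved, system.reference, system.static_selection, system.mobile_selection
    )
    assert screw.angle == pytest.approx(26.5, abs=0.5)


def test_frame_independence(two_domain_26):
    """A global rigid transform of the input structure leaves the domain
    rotation unchanged (motion is measured in the reference frame)."""
    R = Rotation.from_euler("xyz", [31, -47, 110], degrees=True).as_matrix()
    g = RigidTransform(R, np.array([12.0, -8.0, 3.0]))
    moved = two_domain_26.moved.with_coords(g.apply(two_domain_26.moved.coords))
    a = domain_rotation(
        two_domain_26.moved, two_domain_26.reference,
        two_domain_26.static_selection, two_domain_26.mobile_selection,
    )
    b = domain_rotation(
        moved, two_domain_26.reference,
        two_domain_26.static_selection, two_domain_26.mobile_selection,
    )
    assert a.angle == pytest.approx(b.angle, abs=1e-6)
    np.testing.assert_allclose(a.direction, b.direction, atol=1e-6)


def test_angle_symmetric_under_swap(two_domain_26):
    forward = domain_rotation(
        two_domain_26.moved, two_domain_26.reference,
        two_domain_26.static_selection, two_domain_26.mobile_selection,
    )
    backward = domain_rotation(
        two_domain_26.reference, two_domain_26.moved,
        two_domain_26.static_selection, two_domain_26.mobile_selection,
    )
    assert forward.angle == pytest.approx(backward.angle, abs=1e-6)


def test_monotone_recovery_of_graded_angles():
    """Imposed angles 5..30 deg recovered in order, each within 0.5 deg,
    at coordinate noise sigma = 0.2 A."""
    recovered = []
    for k, angle in enumerate((5.0, 10.0, 15.0, 20.0, 25.0, 30.0)):
        system = make_two_domain_system(
            HelixSpec(n_bp=16),
            HelixSpec(n_bp=12),
            MotionSpec(angle=angle, noise_sigma=0.2, seed=50 + k),
        )
        screw = domain_rotation(
            system.moved, system.reference, system.static_selection, system.mobile_selection
        )
        assert screw.angle == pytest.approx(angle, abs=0.5)
        recovered.append(screw.angle)
    assert recovered == sorted(recovered)


# -- marker displacement ------------------------------------------------------


def test_displacement_zero_for_identical(two_domain_26):
    d = displacement_at(
        two_domain_26.reference, two_domain_26.reference, ("C", 6, "C1'"),
        core_sel=two_domain_26.static_selection,
    )
    assert d == pytest.approx(0.0, abs=1e-9)


def test_displacement_three_four_five(two_domain_26):
    ref = two_domain_26.reference
    coords = ref.coords.copy()
    marker = ("C", 6, "C1'")
    idx = ref.get_atom_index(*marker)
    coords[idx] += np.array([3.0, 4.0, 0.0])
    shifted = ref.with_coords(coords)
    assert displacement_at(shifted, ref, marker) == pytest.approx(5.0, abs=1e-9)


def test_missing_marker_is_named_in_error(two_domain_26):
    with pytest.raises(MissingAtomError, match="Z.*999"):
        displacement_at(two_domain_26.reference, two_domain_26.reference, ("Z", 999, "P"))
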