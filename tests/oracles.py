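"""Independent reference implementations used only to check stalkmech.

The screw-axis oracle goes through unit quaternions (scipy Rotation)
instead of the rotation-matrix trace/antisymmetric-part route the
package uses, and derives the axis point from the closed-form planar
inverse of (I - R) instead of a pseudo-inverse.
"""

import numpy as np
from scipy.spatial.transform import Rotation


def quaternion_screw(rotation: np.ndarray, translation: np.ndarray):
    """Screw parameters (angle_deg, direction, pitch, axis_point) via quaternions.

    For a rotation by theta about unit axis n the quaternion is
    (v, w) = (n sin(theta/2), cos(theta/2)); with w >= 0 the angle lies
    in [0, 180] and the axis sign is fixed.  The axis point solves
    (I - R) p = T_perp, whose in-plane inverse has the closed form
    p = T_perp / 2 + cot(theta/2) (n x T_perp) / 2.
    """
    q = Rotation.from_matrix(rotation).as_quat()  # (x, y, z, w)
    if q[3] < 0:
        q = -q
    v, w = q[:3], q[3]
    sin_half = np.linalg.norm(v)
    angle = 2.0 * np.arctan2(sin_half, w)
    if sin_half < 1e-12:
        return np.degrees(angle), None, None, None
    direction = v / sin_half
    pitch = float(np.dot(translation, direction))
    t_perp = translation - pitch * direction
    half = angle / 2.0
    point = 0.5 * t_perp + 0.5 * (np.cos(half) / np.sin(half)) * np.cross(direction, t_perp)
    return np.degrees(angle), direction, pitch, point


def point_line_distance(point: np.ndarray, line_point: np.ndarray, line_dir: np.ndarray) -> float:
    """Distance from a point to the line through line_point along line_dir."""
    rel = np.asarray(point) - np.asarray(line_point)
    rel = rel - np.dot(rel, line_dir) * np.asarray(line_dir)
    return float(np.linalg.norm(rel))


def random_screw_transform(rng: np.random.Generator):
    """A random screw motion (angle U(1,179) deg, random axis/origin/pitch)
    built directly from scipy primitives, plus its ground truth."""
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    angle = rng.uniform(1.0, 179.0)
    origin = rng.uniform(-50.0, 50.0, size=3)
    pitch = rng.uniform(-10.0, 10.0)
    R = Rotation.from_rotvec(np.radians(angle) * direction).as_matrix()
    T = (np.eye(3) - R) @ origin + pitch * direction
    return R, T, {"angle": angle, "direction": direction, "origin": origin, "pitch": pitch}
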