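"""Utilities on the rotation group SO(3) (and O(3) for handedness).

Rotations are plain 3x3 ``numpy`` arrays throughout the package; this module
provides Haar-uniform sampling, the geodesic (relative-angle) metric, the
axis-angle parametrization used by the local refinement step, projection back
onto the group after numerical drift, and composition with a reflection.

Conventions
-----------
A rotation ``R`` acts on a density map ``f`` as ``f_R(x) = f(R^T x)``
(see :mod:`wemdalign.volumes`).  Axis-angle vectors ("rotation vectors")
encode an axis scaled by the angle in radians; the canonical branch has
angle in ``[0, pi]``.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation as _ScipyRotation

__all__ = [
    "random_rotation",
    "is_rotation",
    "check_rotation",
    "relative_angle_deg",
    "exp_rotvec",
    "log_rotvec",
    "project_to_rotation",
    "reflect",
]

_ORTH_TOL = 1e-10


def is_rotation(matrix: np.ndarray, *, allow_reflection: bool = False, tol: float = _ORTH_TOL) -> bool:
    """Return True if ``matrix`` is orthogonal with det +1 (or ±1 if reflections allowed)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (3, 3):
        return False
    if np.max(np.abs(matrix.T @ matrix - np.eye(3))) > tol:
        return False
    det = np.linalg.det(matrix)
    if allow_reflection:
        return abs(abs(det) - 1.0) <= tol
    return abs(det - 1.0) <= tol


def check_rotation(matrix: np.ndarray, *, allow_reflection: bool = False) -> np.ndarray:
    """Validate and return ``matrix`` as a float array, raising ``ValueError`` otherwise.

    The orthogonality check uses a slightly relaxed tolerance (1e-8) so that
    matrices produced by chains of float operations still pass; exact group
    membership at 1e-10 is restored with :func:`project_to_rotation`.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (3, 3):
        raise ValueError(f"expected a 3x3 matrix, got shape {matrix.shape}")
    if not is_rotation(matrix, allow_reflection=allow_reflection, tol=1e-8):
        raise ValueError("matrix is not a valid rotation (orthogonality or determinant check failed)")
    return matrix


def random_rotation(rng: int | np.random.Generator) -> np.ndarray:
    """Draw a Haar-uniform rotation matrix.

    Implemented by normalizing a 4D standard-Gaussian draw to a unit
    quaternion, which is exactly uniform on SO(3) and reproducible given an
    integer seed or a ``numpy`` Generator.
    """
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    q = gen.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def relative_angle_deg(r1: np.ndarray, r2: np.ndarray) -> float:
    """Geodesic distance between two rotations, in degrees in [0, 180].

    This is the angle of the rotation ``r1^T r2``, i.e.
    ``arccos((trace(r1^T r2) - 1) / 2)``.  The arccos argument is clamped to
    [-1, 1] so float drift near 0 and 180 degrees cannot produce NaN.
    """
    r1 = check_rotation(r1)
    r2 = check_rotation(r2)
    cos_theta = (np.trace(r1.T @ r2) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(cos_theta, -1.0, 1.0))))


def exp_rotvec(v: np.ndarray) -> np.ndarray:
    """Rodrigues exponential: axis-angle vector -> rotation matrix."""
    v = np.asarray(v, dtype=float).reshape(3)
    return _ScipyRotation.from_rotvec(v).as_matrix()


def log_rotvec(r: np.ndarray) -> np.ndarray:
    """Matrix logarithm as an axis-angle vector, canonical branch (angle <= pi).

    At angle exactly pi the two antipodal vectors represent the same rotation;
    the one returned by scipy's quaternion conversion is used (its sign is an
    implementation detail, but ``exp_rotvec(log_rotvec(R)) == R`` regardless).
    """
    r = check_rotation(r)
    return _ScipyRotation.from_matrix(r).as_rotvec()


def project_to_rotation(m: np.ndarray) -> np.ndarray:
    """Nearest rotation matrix in Frobenius norm, via SVD polar decomposition.

    The determinant sign is corrected so the result lands on SO(3) even if the
    input has negative determinant.  Raises on singular input, where the
    nearest rotation is not unique.
    """
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3):
        raise ValueError(f"expected a 3x3 matrix, got shape {m.shape}")
    u, s, vt = np.linalg.svd(m)
    if s[-1] <= 1e-12 * max(s[0], 1.0):
        raise np.linalg.LinAlgError("matrix is singular; nearest rotation undefined")
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


def reflect(r: np.ndarray) -> np.ndarray:
    """Compose ``r`` with the reflection diag(-1, 1, 1); the result has det -1.

    Applying it twice returns the original rotation, so it also maps a
    reflection-composed element back to SO(3).
    """
    r = check_rotation(r, allow_reflection=True)
    return np.diag([-1.0, 1.0, 1.0]) @ r
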