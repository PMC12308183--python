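"""Canonical re-orientation, superposition, and Tait-Bryan decomposition.

Twist and pitch between two consecutive repeat units are measured by first
expressing each unit in its own circle-attached local frame (which cancels
the in-plane heading change already measured as curvature), then finding the
least-squares rigid superposition of the consecutive units, and decomposing
the inter-unit rotation into intrinsic z-y'-x'' Tait-Bryan angles:

    R = Rz(yaw) @ Ry(pitch) @ Rx(roll)

Yaw (about the curvature axis) is discarded — curvature comes from the
circle fit — leaving pitch (about the radial axis) and roll (about the
travel axis, reported as twist).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError
from .geometry import LocalFrame

#: |pitch - pi/2| below which the decomposition is treated as gimbal-locked.
GIMBAL_TOL = 1e-7

#: Rotation-matrix orthogonality / determinant tolerance.
ROT_TOL = 1e-9


@dataclass(frozen=True)
class TaitBryan:
    """Intrinsic z-y'-x'' angles of a rotation (radians).

    ``yaw`` about z (curvature axis), ``pitch`` about y (radial axis) in
    ``[-pi/2, pi/2]``, ``roll`` about x (travel axis).  ``gimbal`` marks a
    decomposition at ``|pitch| = pi/2`` where yaw and roll are not separable
    (yaw is set to 0 and the remainder absorbed into roll).
    """

    yaw: float
    pitch: float
    roll: float
    gimbal: bool = False


@dataclass(frozen=True)
class SuperpositionResult:
    """Least-squares rigid superposition of one unit onto another.

    ``rotation @ moving + translation ≈ fixed`` for the corresponded
    Calpha coordinates; ``rmsd`` is over that correspondence.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    aligned_length: int


@dataclass(frozen=True)
class PairDescriptor:
    """Geometrical descriptors for one consecutive unit pair.

    ``curvature`` comes from the circle fit (radians, unsigned); ``twist``
    and ``pitch`` from the superposition rotation (radians, signed, sign
    conventions applied upstream); ``yaw_residual`` is the discarded yaw
    component, kept for diagnostics only.
    """

    curvature: float
    twist: float
    pitch: float
    twist_handedness: int
    pitch_handedness: int
    rmsd: float
    aligned_length: int
    yaw_residual: float = 0.0


def _check_rotation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
        raise ValueError("matrix is not orthogonal")
    if np.linalg.det(R) < 0:
        raise ValueError("matrix is a reflection, not a rotation")
    return R


def rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def recompose(angles: TaitBryan) -> np.ndarray:
    """Rebuild the rotation matrix ``Rz(yaw) @ Ry(pitch) @ Rx(roll)``."""
    return rot_z(angles.yaw) @ rot_y(angles.pitch) @ rot_x(angles.roll)


def decompose_tait_bryan(R: np.ndarray) -> TaitBryan:
    """Factor a rotation as intrinsic z-y'-x'' Tait-Bryan angles.

    At gimbal lock (``|pitch|`` within :data:`GIMBAL_TOL` of ``pi/2``) only
    the sum/difference of yaw and roll is defined; yaw is set to 0, the
    remaining rotation absorbed into roll, and the result flagged.
    """
    R = _check_rotation(R)
    sp = -R[2, 0]
    if abs(abs(sp) - 1.0) <= GIMBAL_TOL:
        pitch = np.pi / 2 if sp > 0 else -np.pi / 2
        # With yaw := 0 the remaining rotation is about x; for either pitch
        # sign R[1,1] = cos(roll') and R[1,2] = -sin(roll').
        roll = float(np.arctan2(-R[1, 2], R[1, 1]))
        return TaitBryan(0.0, float(pitch), roll, gimbal=True)
    pitch = float(np.arcsin(np.clip(sp, -1.0, 1.0)))
    yaw = float(np.arctan2(R[1, 0], R[0, 0]))
    roll = float(np.arctan2(R[2, 1], R[2, 2]))
    return TaitBryan(yaw, pitch, roll)


def canonicalize_unit(coords: np.ndarray, frame: LocalFrame) -> np.ndarray:
    """Express unit coordinates in the unit's local frame.

    ``p -> F^T (p - anchor)`` where F has columns (x, y, z): a unit whose
    axes coincide with the global ones is merely translated to its local
    origin.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    return (coords - frame.anchor) @ frame.matrix


def _trim_to_match(longer: np.ndarray, target_len: int) -> np.ndarray:
    """Trim termini of the longer unit equally to ``target_len`` residues.

    The extra residue on an odd difference is trimmed from the C-terminus.
    """
    diff = len(longer) - target_len
    front = diff // 2
    back = diff - front
    return longer[front:len(longer) - back]


def _superpose_kabsch(moving: np.ndarray, fixed: np.ndarray
                      ) -> SuperpositionResult:
    mov_mean = moving.mean(axis=0)
    fix_mean = fixed.mean(axis=0)
    rot, _ = Rotation.align_vectors(fixed - fix_mean, moving - mov_mean)
    R = rot.as_matrix()
    t = fix_mean - R @ mov_mean
    # RMSD from the actual residuals (more accurate near zero than the
    # solver's reported rssd).
    resid = moving @ R.T + t - fixed
    rmsd = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return SuperpositionResult(R, t, rmsd, len(moving))


def _superpose_tmalign(moving: np.ndarray, fixed: np.ndarray
                       ) -> SuperpositionResult:
    """Superpose via the external TM-align wrapper, when installed."""
    try:
        from tmtools import tm_align
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise RuntimeError(
            "the 'tmalign' backend needs the optional tmtools package; "
            "use the default internal backend instead") from exc
    # TM-align wants sequences; Calpha-only traces get a poly-alanine one.
    res = tm_align(np.asarray(moving, float), np.asarray(fixed, float),
                   "A" * len(moving), "A" * len(fixed))
    R = np.asarray(res.u)
    t = np.asarray(res.t)
    aligned = R @ np.asarray(moving, float).T + t[:, None]
    n = min(len(moving), len(fixed))
    rmsd = float(np.sqrt(np.mean(np.sum(
        (aligned.T[:n] - np.asarray(fixed, float)[:n]) ** 2, axis=1))))
    return SuperpositionResult(R, t, rmsd, n)


def superpose_units(moving: np.ndarray, fixed: np.ndarray,
                    backend: str = "internal") -> SuperpositionResult:
    """Least-squares rigid superposition of ``moving`` onto ``fixed``.

    The default internal backend uses a 1:1 sequence-order correspondence
    (the longer unit's termini trimmed equally, extra residue trimmed
    C-terminally) and the Kabsch solution; the returned rotation is always
    proper (det +1).  The ``"tmalign"`` backend delegates the correspondence
    to TM-align when the optional wrapper is installed.
    """
    moving = np.atleast_2d(np.asarray(moving, dtype=float))
    fixed = np.atleast_2d(np.asarray(fixed, dtype=float))
    if len(moving) < 3 or len(fixed) < 3:
        raise DegenerateGeometryError(
            "superposition needs at least 3 Calpha per unit")
    if backend == "tmalign":
        return _superpose_tmalign(moving, fixed)
    if backend != "internal":
        raise ValueError(f"unknown superposition backend: {backend!r}")
    n = min(len(moving), len(fixed))
    if n < 3:
        raise DegenerateGeometryError("fewer than 3 correspondences")
    return _superpose_kabsch(_trim_to_match(moving, n),
                             _trim_to_match(fixed, n))


def _sign(x: float) -> int:
    """Handedness sign with the zero-maps-to-+1 convention."""
    return -1 if x < 0 else 1


def pair_descriptor(curvature: float, angles: TaitBryan, rmsd: float,
                    aligned_length: int) -> PairDescriptor:
    """Assemble the per-pair descriptor from its parts.

    A pure field mapping: ``twist`` is the roll component and ``pitch`` the
    pitch component of ``angles`` (sign conventions are applied by the
    caller before this point); the yaw component is recorded as a diagnostic
    but never reported as curvature, which comes from the circle fit.
    """
    return PairDescriptor(
        curvature=float(curvature),
        twist=float(angles.roll),
        pitch=float(angles.pitch),
        twist_handedness=_sign(angles.roll),
        pitch_handedness=_sign(angles.pitch),
        rmsd=float(rmsd),
        aligned_length=int(aligned_length),
        yaw_residual=float(angles.yaw),
    )
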