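"""Sliding-window circle fitting and per-unit local frames.

The geometric model: repeat-unit centroids within a sliding window (default
six units) are assumed to lie near a circular arc.  A reference plane is
fitted through the window centroids by principal component analysis, the
centroids are projected onto it, and an algebraic least-squares circle is
fitted.  The circle is then refined with a "widest crown" rule: every Calpha
of the window is projected onto the plane, labelled inner/outer against the
initial circle, and the refined radius is placed in the widest empty annulus
separating the two walls.  Curvature between two consecutive units is the
angle subtended at the circle centre by their centroids.

Each unit also receives a right-handed local frame:

* ``y`` (pitch axis) — from the circle centre to the unit centroid,
* ``x`` (twist axis) — the travel vector to the next centroid,
  orthogonalized against ``y`` (the tangent),
* ``z`` (curvature axis) — ``x × y``.

These frames are what the angle-decomposition stage uses to cancel the
in-plane heading change (yaw) before superposing consecutive units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError

logger = logging.getLogger(__name__)

#: Sliding-window length in repeat units.
WINDOW = 6

#: Orthonormality tolerance for planes and frames.
ORTHO_TOL = 1e-9

#: Default ratio of 2nd/1st principal singular value below which the window
#: is treated as (near-)linear.
LINEAR_RATIO = 1e-4

#: Default fitted-radius cap (Å) above which the window is treated as linear.
RADIUS_CAP = 1e4


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Plane:
    """Least-squares plane through a small centroid cloud.

    ``u``/``v`` span the plane (first two principal directions); ``normal``
    is ``u × v``.  ``singular_values`` are the three singular values of the
    centered cloud, used downstream to detect near-linear windows.
    """

    origin: np.ndarray
    u: np.ndarray
    v: np.ndarray
    normal: np.ndarray
    singular_values: tuple[float, float, float]

    def __post_init__(self) -> None:
        for a, b in ((self.u, self.v), (self.u, self.normal), (self.v, self.normal)):
            if abs(float(np.dot(a, b))) > 1e-8:
                raise ValueError("plane basis is not orthogonal")

    def project(self, points: np.ndarray) -> np.ndarray:
        """Project Nx3 points to Nx2 in-plane coordinates."""
        rel = np.atleast_2d(points) - self.origin
        return np.column_stack([rel @ self.u, rel @ self.v])

    def lift(self, point2d: np.ndarray) -> np.ndarray:
        """Map in-plane 2D coordinates back to 3D."""
        return self.origin + point2d[0] * self.u + point2d[1] * self.v

    def flipped(self) -> "Plane":
        """Same plane with the normal reversed (v negated, right-handed)."""
        return Plane(self.origin, self.u, -self.v, -self.normal,
                     self.singular_values)


@dataclass(frozen=True)
class FittedCircle:
    """Circle fitted to one sliding window.

    ``flag`` records how the radius was obtained: ``"crown"`` (regular widest
    crown), ``"gap_fallback"`` (inner/outer walls interleaved; widest empty
    gap used), ``"initial"`` (crown precondition failed; algebraic circle
    kept), or ``"linear"`` (no meaningful circle; radius is infinite).
    """

    plane: Plane
    center2d: np.ndarray
    center3d: np.ndarray
    radius: float
    crown_inner: float
    crown_outer: float
    window_units: range
    flag: str = "crown"

    def __post_init__(self) -> None:
        if self.flag != "linear":
            if not (self.crown_inner <= self.radius + 1e-9
                    and self.radius <= self.crown_outer + 1e-9):
                raise ValueError(
                    f"crown bounds violated: {self.crown_inner} <= "
                    f"{self.radius} <= {self.crown_outer}")


@dataclass(frozen=True)
class LocalFrame:
    """Right-handed orthonormal triad attached to one repeat unit.

    ``x`` twist axis (tangent, direction of travel), ``y`` pitch axis
    (radially outward from the circle centre), ``z = x × y`` curvature axis;
    anchored at the unit centroid.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    anchor: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if not np.allclose(m.T @ m, np.eye(3), atol=1e-8):
            raise ValueError("frame is not orthonormal")
        if np.linalg.det(m) < 0:
            raise ValueError("frame is left-handed")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 matrix with columns (x, y, z)."""
        return np.column_stack([self.x, self.y, self.z])


# ---------------------------------------------------------------------------
# operations


def unit_centroid(coords: np.ndarray) -> np.ndarray:
    """Arithmetic mean of a unit's Calpha coordinates."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.size == 0:
        raise DegenerateGeometryError("cannot take centroid of an empty unit")
    return coords.mean(axis=0)


def select_window(pair_index: int, n_units: int, window: int = WINDOW) -> range:
    """Unit indices of the sliding window for pair ``(i, i+1)``.

    The window is centred on the pair (two units before, three after for the
    default six-unit window) and clamped at the region ends, extending toward
    the other side so that ``min(window, n_units)`` units are always covered.
    """
    if n_units < 3:
        raise ValueError("a region needs at least 3 units")
    if not 0 <= pair_index <= n_units - 2:
        raise ValueError(f"pair index {pair_index} out of range for "
                         f"{n_units} units")
    size = min(window, n_units)
    before = (window - 2) // 2          # 2 for the default window of 6
    lo = max(0, pair_index - before)
    hi = min(n_units - 1, lo + size - 1)
    lo = max(0, hi - size + 1)
    return range(lo, hi + 1)


def fit_plane(centroids: np.ndarray) -> Plane:
    """PCA plane through ≥3 centroids.

    ``u`` and ``v`` are the first two principal directions of the centered
    cloud; the normal is ``u × v``.  Raises for fewer than three points or a
    cloud with no spatial extent; collinearity is *not* an error here — the
    caller inspects ``singular_values`` to decide on the linear fallback.
    """
    pts = np.atleast_2d(np.asarray(centroids, dtype=float))
    if pts.shape[0] < 3:
        raise DegenerateGeometryError("plane fit needs at least 3 centroids")
    origin = pts.mean(axis=0)
    centered = pts - origin
    # SVD of the centered cloud: rows of vt are principal directions.
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[0] <= ORTHO_TOL:
        raise DegenerateGeometryError("all centroids coincide; no plane")
    u, v = vt[0], vt[1]
    normal = np.cross(u, v)
    normal /= np.linalg.norm(normal)
    return Plane(origin, u, v, normal,
                 (float(svals[0]), float(svals[1]), float(svals[2])))


def fit_initial_circle(points2d: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic (Kåsa) least-squares circle through 2D points.

    Minimises the linearized objective ``sum((|p - c|^2 - r^2)^2)``, which is
    a linear least-squares problem and exact on exact-circle input.  Returns
    ``(center2d, radius)``.  Near-collinear input yields an ill-conditioned
    system; this raises so the caller can take the straight-line fallback.
    """
    pts = np.atleast_2d(np.asarray(points2d, dtype=float))
    if pts.shape[0] < 3:
        raise DegenerateGeometryError("circle fit needs at least 3 points")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2.0 * x, 2.0 * y, np.ones_like(x)])
    b = x * x + y * y
    sol, _, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3 or sv[-1] < 1e-12 * sv[0]:
        raise DegenerateGeometryError("points are collinear; circle undefined")
    cx, cy, c = sol
    r2 = c + cx * cx + cy * cy
    if r2 <= 0 or not np.isfinite(r2):
        raise DegenerateGeometryError("degenerate circle fit")
    return np.array([cx, cy]), float(np.sqrt(r2))


def _widest_gap(radii: np.ndarray, r0: float) -> tuple[float, float]:
    """Widest empty interval between consecutive sorted radial distances.

    Ties are broken by the interval midpoint closest to ``r0``.  Returns
    ``(low, high)`` of the chosen gap.
    """
    rs = np.unique(radii)
    if rs.size < 2:
        raise DegenerateGeometryError("no gap between projected radii")
    widths = np.diff(rs)
    best = None
    for lo, hi, w in zip(rs[:-1], rs[1:], widths):
        mid_dist = abs((lo + hi) / 2.0 - r0)
        key = (-w, mid_dist)
        if best is None or key < best[0]:
            best = (key, (float(lo), float(hi)))
    return best[1]


def widest_crown_refine(all_ca_2d: np.ndarray, center2d: np.ndarray,
                        radius: float, *, plane: Plane,
                        window_units: range) -> FittedCircle:
    """Refine the circle radius with the widest-crown rule.

    Projected Calpha points are labelled "in" when closer to the initial
    centre than the initial radius, "out" otherwise.  The crown is the
    annulus between the outermost "in" point and the innermost "out" point;
    when it is non-empty the refined radius is its midpoint.  When the two
    walls interleave, the refined radius falls back to the midpoint of the
    widest empty gap in the sorted radial distances (ties resolved toward
    the initial radius).  The centre is kept fixed: curvature depends only
    on the centre, so refinement is deliberately conservative.
    """
    pts = np.atleast_2d(np.asarray(all_ca_2d, dtype=float))
    center2d = np.asarray(center2d, dtype=float)
    dists = np.linalg.norm(pts - center2d, axis=1)
    inner = dists[dists < radius]
    outer = dists[dists >= radius]
    center3d = plane.lift(center2d)

    if inner.size == 0 or (dists > radius).sum() == 0:
        logger.debug("crown precondition failed (no points on one side); "
                     "keeping the initial circle")
        return FittedCircle(plane, center2d, center3d, radius,
                            radius, radius, window_units, flag="initial")

    crown_inner = float(inner.max())
    crown_outer = float(outer.min())
    if crown_outer > crown_inner:
        refined = (crown_inner + crown_outer) / 2.0
        return FittedCircle(plane, center2d, center3d, refined,
                            crown_inner, crown_outer, window_units,
                            flag="crown")

    lo, hi = _widest_gap(dists, radius)
    return FittedCircle(plane, center2d, center3d, (lo + hi) / 2.0,
                        lo, hi, window_units, flag="gap_fallback")


def curvature_angle(center3d: np.ndarray, centroid_a: np.ndarray,
                    centroid_b: np.ndarray) -> float:
    """Angle at the circle centre subtended by two unit centroids (radians).

    Unsigned, in ``[0, pi]``.
    """
    ra = np.asarray(centroid_a, dtype=float) - np.asarray(center3d, dtype=float)
    rb = np.asarray(centroid_b, dtype=float) - np.asarray(center3d, dtype=float)
    na, nb = np.linalg.norm(ra), np.linalg.norm(rb)
    if na <= ORTHO_TOL or nb <= ORTHO_TOL:
        raise DegenerateGeometryError("centroid coincides with circle centre")
    cosang = np.clip(np.dot(ra, rb) / (na * nb), -1.0, 1.0)
    return float(np.arccos(cosang))


def frame_from_axes(y_dir: np.ndarray, travel: np.ndarray,
                    anchor: np.ndarray) -> LocalFrame:
    """Build the unit frame from a pitch direction and a travel vector.

    ``y`` is the normalized pitch direction; ``x`` is the travel vector
    orthogonalized against ``y`` (Gram-Schmidt); ``z = x × y``.
    """
    y_dir = np.asarray(y_dir, dtype=float)
    travel = np.asarray(travel, dtype=float)
    ny = np.linalg.norm(y_dir)
    if ny <= ORTHO_TOL:
        raise DegenerateGeometryError("zero-length pitch axis")
    y = y_dir / ny
    t = travel - np.dot(travel, y) * y
    nt = np.linalg.norm(t)
    if nt <= 1e-9 * max(1.0, np.linalg.norm(travel)):
        raise DegenerateGeometryError(
            "travel vector is parallel to the pitch axis")
    x = t / nt
    z = np.cross(x, y)
    z /= np.linalg.norm(z)
    return LocalFrame(x, y, z, np.asarray(anchor, dtype=float))


def build_local_frame(circle: FittedCircle, centroid_i: np.ndarray,
                      centroid_next: np.ndarray) -> LocalFrame:
    """Local frame of a unit from the fitted circle and the next centroid."""
    centroid_i = np.asarray(centroid_i, dtype=float)
    centroid_next = np.asarray(centroid_next, dtype=float)
    return frame_from_axes(centroid_i - circle.center3d,
                           centroid_next - centroid_i, centroid_i)


def orient_plane(plane: Plane, *, prev_normal: np.ndarray | None,
                 travel0: np.ndarray | None = None,
                 y0: np.ndarray | None = None) -> Plane:
    """Fix the sign of a window normal for continuity along the region.

    The first window's normal is oriented so the first pair's travel
    satisfies ``travel · (n × y0) > 0`` (the frame tangent and the travel
    agree); every later window keeps its normal aligned with the previous
    window's.  This makes the "upward" direction — hence pitch handedness —
    comparable across windows.
    """
    if prev_normal is not None:
        if float(np.dot(plane.normal, prev_normal)) < 0:
            return plane.flipped()
        return plane
    if travel0 is None or y0 is None:
        return plane
    if float(np.dot(travel0, np.cross(plane.normal, y0))) < 0:
        return plane.flipped()
    return plane
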