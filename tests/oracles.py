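"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they validate: superposition is
solved with Horn's quaternion method (the package uses SVD-based Kabsch via
scipy), and the circumscribed circle of a triangle is computed from the
perpendicular-bisector closed form (the package uses an algebraic
least-squares fit).
"""

import numpy as np


def horn_superpose(moving: np.ndarray, fixed: np.ndarray):
    """Optimal rigid superposition via Horn's quaternion eigenvalue method.

    Returns ``(R, t, rmsd)`` with ``R @ moving + t ~= fixed`` in the
    least-squares sense; R is always a proper rotation.
    """
    moving = np.asarray(moving, float)
    fixed = np.asarray(fixed, float)
    mm, fm = moving.mean(axis=0), fixed.mean(axis=0)
    a, b = moving - mm, fixed - fm
    S = a.T @ b
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    N = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    vals, vecs = np.linalg.eigh(N)
    w, x, y, z = vecs[:, np.argmax(vals)]
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    t = fm - R @ mm
    rmsd = float(np.sqrt(np.mean(np.sum((a @ R.T - b) ** 2, axis=1))))
    return R, t, rmsd


def circumcircle(p1, p2, p3):
    """Circumscribed circle of a 2D triangle from perpendicular bisectors."""
    ax, ay = p1
    bx, by = p2
    cx, cy = p3
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    ux = ((ax ** 2 + ay ** 2) * (by - cy) + (bx ** 2 + by ** 2) * (cy - ay)
          + (cx ** 2 + cy ** 2) * (ay - by)) / d
    uy = ((ax ** 2 + ay ** 2) * (cx - bx) + (bx ** 2 + by ** 2) * (ax - cx)
          + (cx ** 2 + cy ** 2) * (bx - ax)) / d
    center = np.array([ux, uy])
    return center, float(np.linalg.norm(center - np.asarray(p1, float)))


def random_rotation(rng) -> np.ndarray:
    """Uniform-ish random rotation from a QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
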