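"""Idealized repeat-protein backbones with known ground-truth angles.

The generator is the oracle for the rest of the package: it builds a
Calpha-only solenoid whose unit centroids lie exactly on a circle of the
requested radius, with each unit's orientation advanced per pair by a
prescribed pitch (rotation about the radial axis) and twist/roll (rotation
about the travel axis), expressed in the same circle-attached local frame
the measurement pipeline reconstructs.  Because generation and measurement
share that frame convention, a noiseless solenoid's per-pair descriptors are
recovered to numerical precision: curvature equals the yaw step, twist the
roll step, pitch the pitch step.

The default unit template is a 10-residue Calpha trace of an ideal
alpha-helix (1.5 Å rise, 100° per residue, 2.3 Å helix radius), mimicking
one alpha-solenoid unit and giving well-conditioned superpositions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decomposition import rot_x, rot_y
from .errors import RegionValidationError
from .geometry import frame_from_axes
from .structure_io import RegionSpec, ResidueKey, Structure, UnitSpan

__all__ = [
    "SolenoidParams", "SolenoidResult", "ideal_helix_template",
    "generate_solenoid", "generate_linear_rod",
]


def ideal_helix_template(n_residues: int = 10, rise: float = 1.5,
                         turn_deg: float = 100.0,
                         helix_radius: float = 2.3) -> np.ndarray:
    """Calpha trace of an ideal alpha-helix, centered at its centroid."""
    if n_residues < 3:
        raise ValueError("template needs at least 3 residues")
    k = np.arange(n_residues)
    theta = np.deg2rad(turn_deg) * k
    pts = np.column_stack([helix_radius * np.cos(theta),
                           helix_radius * np.sin(theta),
                           rise * k])
    return pts - pts.mean(axis=0)


@dataclass
class SolenoidParams:
    """Parameters of an idealized solenoid.

    ``yaw0``/``pitch0``/``roll0`` are the per-pair curvature, pitch and
    twist steps in radians; ``radius`` the circle radius in Å; ``noise_sd``
    the isotropic Gaussian coordinate noise in Å.  ``closed=True`` forces
    ``yaw0 = 2*pi/n_units`` so the ring closes, and requires ``pitch0 = 0``
    (a pitched ring cannot close on itself).
    """

    n_units: int = 8
    yaw0: float = 0.4
    pitch0: float = 0.0
    roll0: float = 0.0
    radius: float = 20.0
    unit_template: np.ndarray | None = None
    noise_sd: float = 0.0
    seed: int = 0
    closed: bool = False

    def __post_init__(self) -> None:
        if self.n_units < 3:
            raise RegionValidationError("a solenoid needs at least 3 units")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.closed and abs(self.pitch0) > 1e-12:
            raise RegionValidationError(
                "a closed ring cannot have a pitch step (pitch0 != 0)")
        if not self.closed and abs(self.yaw0) < 1e-6:
            raise ValueError("yaw0 must be non-zero (use generate_linear_rod "
                             "for straight structures)")

    @property
    def effective_yaw(self) -> float:
        """The yaw step actually used (forced to 2*pi/n for closed rings)."""
        return 2.0 * np.pi / self.n_units if self.closed else self.yaw0

    def template(self) -> np.ndarray:
        tpl = (ideal_helix_template() if self.unit_template is None
               else np.asarray(self.unit_template, dtype=float))
        return tpl - tpl.mean(axis=0)


@dataclass
class SolenoidResult:
    """Generated structure, its region annotation, and the ground truth."""

    structure: Structure
    region: RegionSpec
    ground_truth: pd.DataFrame
    params: SolenoidParams = field(repr=False, default=None)


def _circle_frames(centroids: np.ndarray) -> list[np.ndarray]:
    """Circle-attached frame matrix per unit (same rule as the pipeline).

    y is radially outward from the circle centre (the origin here), x the
    travel to the next centroid orthogonalized against y (the previous
    travel for the last unit), z = x cross y.
    """
    n = len(centroids)
    mats = []
    for k in range(n):
        travel = (centroids[k + 1] - centroids[k] if k < n - 1
                  else centroids[k] - centroids[k - 1])
        mats.append(frame_from_axes(centroids[k], travel,
                                    centroids[k]).matrix)
    return mats


def _assemble(units: list[np.ndarray], noise_sd: float, seed: int,
              region_id: str) -> tuple[Structure, RegionSpec]:
    m = len(units[0])
    atoms = np.vstack(units)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        atoms = atoms + rng.normal(0.0, noise_sd, size=atoms.shape)
    coords: dict[ResidueKey, np.ndarray] = {}
    for i, xyz in enumerate(atoms):
        coords[ResidueKey("A", i + 1, "")] = xyz
    spans = [UnitSpan("A", k * m + 1, (k + 1) * m)
             for k in range(len(units))]
    region = RegionSpec(region_id, spans).validate()
    return Structure(coords, source="synthetic"), region


def generate_solenoid(params: SolenoidParams) -> SolenoidResult:
    """Build a solenoid with prescribed per-pair yaw/pitch/roll steps.

    Unit centroids are placed exactly on a circle of ``params.radius`` in
    the xy-plane, ``effective_yaw`` radians apart (chord length
    ``2 R sin(yaw0/2)``).  Unit ``k``'s orientation is the circle-attached
    frame at its centroid composed with ``Q^k`` where
    ``Q = Ry(pitch0) @ Rx(-roll0)`` — the per-pair orientation step in local
    coordinates, with the roll sign matching the clockwise-positive twist
    convention.  Gaussian noise of ``noise_sd`` is then added per coordinate
    with the given seed.

    Returns the structure, a matching region annotation, and a ground-truth
    table with one row per consecutive pair (columns ``yaw, pitch, roll``).
    """
    alpha = params.effective_yaw
    n = params.n_units
    tpl = params.template()

    k = np.arange(n)
    centroids = params.radius * np.column_stack(
        [np.cos(k * alpha), np.sin(k * alpha), np.zeros(n)])
    frames = _circle_frames(centroids)
    step = rot_y(params.pitch0) @ rot_x(-params.roll0)

    units = []
    orient_rel = np.eye(3)          # Q^k, orientation relative to the frame
    for i in range(n):
        orientation = frames[i] @ orient_rel
        units.append(centroids[i] + tpl @ orientation.T)
        orient_rel = orient_rel @ step

    structure, region = _assemble(units, params.noise_sd, params.seed,
                                  region_id="solenoid")
    truth = pd.DataFrame({
        "pair_index": np.arange(n - 1),
        "yaw": alpha,
        "pitch": params.pitch0,
        "roll": params.roll0,
    })
    return SolenoidResult(structure, region, truth, params)


def generate_linear_rod(n_units: int = 6, spacing: float = 10.0,
                        template: np.ndarray | None = None,
                        noise_sd: float = 0.0,
                        seed: int = 0) -> tuple[Structure, RegionSpec]:
    """Units translated along one axis with zero inter-unit rotation.

    The measurement pipeline must report zero curvature (flagged linear) and
    zero twist/pitch for the noiseless rod.
    """
    if n_units < 3:
        raise RegionValidationError("a rod needs at least 3 units")
    tpl = (ideal_helix_template() if template is None
           else np.asarray(template, dtype=float))
    tpl = tpl - tpl.mean(axis=0)
    units = [tpl + np.array([k * spacing, 0.0, 0.0]) for k in range(n_units)]
    return _assemble(units, noise_sd, seed, region_id="rod")
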