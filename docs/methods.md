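# Methods

## Model

A repeat region is an ordered list of units; each unit is reduced to its
Cα trace and represented by its centroid.  The local arrangement of
consecutive units is modelled as motion along a circular arc with
superimposed rotation of the moving unit about its own axes.  Three angles
per consecutive pair describe that motion completely:

* **curvature (yaw)**, the central angle between the two centroids on a
  circle fitted to the local window — a positional quantity, measured from
  the circle geometry alone;
* **twist (roll)** and **pitch**, orientational quantities, measured from
  the rotation that superposes one unit onto its predecessor after both
  have been expressed in their own circle-attached frames.

Expressing each unit in its own frame before superposition is what makes
the decomposition well-posed: the frame rotates with the circle, so the
in-plane heading change (the yaw already measured as curvature) cancels,
and the residual rotation carries only twist and pitch.  The residual yaw
is kept as a per-row diagnostic (`yaw_residual`); values far from zero
indicate that the circle model fits that window poorly.

Assumptions: units are given (no repeat detection is performed); the Cα
trace suffices (side chains carry no geometric signal at unit scale);
within a six-unit window the centroid path is approximately circular.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| `window` | 6 units | sliding-window length for plane/circle fitting. Long enough to stabilize the fit, short enough to track local curvature changes. |
| `linear_ratio` | 1e-4 | threshold on s2/s1 of the window-centroid singular values below which the window is treated as straight. |
| `radius_cap` | 1e4 Å | fitted radius above which the window is treated as straight (a 10 km circle is a line at protein scale). |
| `clockwise_positive` | on | twist sign convention: positive = clockwise looking along the travel direction (right-handed coiling). Equals the negated mathematical rotation about +x; a single switch flips it. |
| `pitch_disp_ratio` | 0.05 | minimum out-of-plane displacement, as a fraction of the inter-centroid chord, before the pitch sign is reconciled with the observed up/down movement (below it, the decomposition's own sign is kept — an absolute rule would flip signs randomly on planar structures under coordinate noise). |
| `refine_center` | off | fit the initial circle to all projected Cα instead of centroids only. Off because curvature depends only on the centre, and the centroid-based centre is the more stable estimator. |
| `wrap` | off | add the closing pair (last, first) for ring topologies; regions are otherwise traversed open, N→C. |
| `backend` | internal | superposition backend. The internal Kabsch path trims the longer unit's termini equally (extra residue C-terminally) to get a 1:1 sequence-order correspondence; an external TM-align wrapper can be plugged in when installed. |

## Numerical choices

* **Plane fit** — SVD of the centered window centroids; the first two
  principal directions span the plane.  The normal's sign is fixed for
  continuity: the first window is oriented so the first pair travels along
  the frame tangent, each later window keeps its normal aligned with the
  previous one.  This makes "up" (hence pitch handedness) comparable along
  a region.
* **Initial circle** — algebraic (Kåsa) least-squares fit: linear, exact
  on exact-circle input, deterministic.  Rank-deficient systems (collinear
  centroids) divert to the linear fallback.
* **Widest crown** — points at distance < r₀ from the initial centre are
  "inner", the rest "outer"; the crown is (max inner, min outer) and the
  refined radius its midpoint.  If the walls interleave, the refined radius
  is the midpoint of the widest empty gap among the sorted radial
  distances, ties resolved toward r₀.  If no point lies strictly on one
  side, the initial circle is kept (flagged `initial`).  The centre is
  never moved by refinement.
* **Tait–Bryan decomposition** — closed-form intrinsic z–y′–x″
  factorization with pitch ∈ [−π/2, π/2].  At gimbal lock
  (|pitch| within 1e-7 of π/2) yaw and roll are inseparable; yaw is set to
  0, the remainder absorbed into roll, and the result flagged.  Verified
  against an independent factorization in the tests.
* **Degenerate pairs** — coincident centroids, travel parallel to the
  pitch axis, units shorter than 3 Cα, unresolvable spans: the row is
  emitted with null angles and a reason flag, and the region continues.
  A region-level failure occurs only when every pair fails.
* **Summary statistics** — arithmetic mean and sample standard deviation
  (ddof = 1) of the signed per-pair values.  Circular statistics were
  rejected: observed angles live well inside (−π, π), far from wraparound.
  This is a documented limitation for hypothetical near-π regions.

## Synthetic generator

`generate_solenoid` places unit centroids *exactly* on a circle of the
requested radius, `yaw0` radians apart (the inter-centroid chord is then
2R·sin(yaw0/2) automatically), and assigns unit *k* the orientation
F_k·Qᵏ, where F_k is the same circle-attached frame the pipeline
reconstructs and Q = R_y(pitch0)·R_x(−roll0) is the per-pair orientation
step in local coordinates (the roll sign matching the clockwise-positive
twist convention).  Composing the orientation step in the frame rather
than integrating a free screw was a deliberate design choice: it keeps the
centroid path exactly circular for all parameter values, so every
generated structure has exact, closed-form ground truth (curvature = yaw0,
twist = roll0, pitch = pitch0 per pair) against which the pipeline can be
checked to numerical precision.  A consequence is that `pitch0` reorients
units without making the path climb — pitch is an orientational
descriptor here, matching what the rotation decomposition measures
(superposition rotations are translation-blind).  Closed rings force
yaw0 = 2π/n and reject pitch0 ≠ 0 (a pitched ring has a seam).

Gaussian coordinate noise (default 0 Å; 0.3 Å mimics typical experimental
uncertainty) is isotropic per atom and seeded.  The default unit template
is a 10-residue ideal α-helix Cα trace (1.5 Å rise, 100°/residue, 2.3 Å
helix radius), mimicking one alpha-solenoid unit and giving
well-conditioned superpositions.

What the generator does **not** emulate: realistic bond geometry beyond
the Cα trace, unit-to-unit structural variability (beyond isotropic
noise), insertions/deletions, chain breaks, alternate conformations.
Passing tests therefore demonstrate correctness of the geometry and of the
conventions, not robustness to every pathology of experimental structures
— though insertions, missing residues and unresolvable units are exercised
separately through the I/O layer.

## Validation problem sizes

The test suite and acceptance script use desk-scale inputs chosen as the
smallest sizes that exercise every code path: 8–12-unit rings and 10-unit
open solenoids (10 residues/unit) for recovery checks; a 4×3×3 grid over
(yaw, pitch, roll) ∈ [0.05, 1.0] × [−0.3, 0.3] × [−0.5, 0.5] for noiseless
recovery (tolerance 1e-3 rad); 50 seeds at 0.3 Å noise for the bias check
(tolerance 0.02 rad); 6-job batches for serial/parallel equivalence.

## Known limitations

* Sequence-order 1:1 correspondence in the internal backend: units related
  by circular permutation or with large indels are corresponded naively
  (termini trimmed); an external structure aligner backend is the intended
  remedy.
* Curvature is unsigned ([0, π]); direction reversals along a region show
  up in the frames/normal continuity, not in the curvature sign.
* Per-unit rows are indexed by the left unit of each pair; region-level
  values are plain means, so a single distorted pair moves the summary.
* The widest-crown refinement adjusts only the radius.  The circle centre
  — the only quantity curvature depends on — always comes from the
  centroid fit (`refine_center` switches the point set, not the rule).
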