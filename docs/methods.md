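# Methods

## Scope and model

`morphomap` quantifies whole-embryo morphogenesis from a temporal sequence
of closed, genus-0 triangle meshes of the embryo surface. The method makes
two physical assumptions:

* **Small deformations between frames.** Markers behave as material
  (Lagrangian) particles only when the per-frame surface displacement is
  small compared with the mesh edge length; this is the high-frequency
  sampling regime of modern light-sheet time-lapse data.
* **Surface kinematics only.** All rates are computed from the motion of
  the surface; no volumetric information is used and no forces or stresses
  are inferred.

## Reference sphere and parametrization

The marker mesh is an icosahedron subdivided *k* times with the
interpolating butterfly scheme (8-point stencil, wing weight −1/16, with
the standard extraordinary-vertex rules at the twelve valence-5 vertices),
each new vertex re-projected to the unit sphere. Interpolating subdivision
plus re-projection keeps the sphere exact at every level, so the (θ, φ)
coordinates of a vertex are exact, not approximate. The default is k = 4
(2 562 vertices, 5 120 faces): marker quality is insensitive to the count
well before this level, while the spherical-harmonic quadrature error at
l ≤ 12 is already below 1%. θ is the polar angle from +z; data whose
animal–vegetal axis is not +z are permuted once at read time
(`axis_map`), never inside the math.

Vertex quadrature weights are barycentric (one-third) area lumping. In the
harmonic transform the weights are rescaled to sum to exactly 4π,
removing the flat-triangle area deficit of the discretization (0.1% at
level 4) that would otherwise bias every diagonal Gram entry low.

## Surface registration and Lagrangian markers

Frame fitting descends the unsigned distance to the target: each vertex
moves toward its exact closest point on the target triangle mesh (k-d tree
over triangle centroids, exact point–triangle distances) by at most
0.3 × median target edge length per iteration, followed by a tangential
umbrella-Laplacian smoothing step (weight 0.1) that keeps the vertex
distribution even. A fit converges when the maximum vertex–surface
distance is below tol = 0.05 × median target edge length *and* the mesh
has stopped moving (last update < tol/2); the second condition lets the
smoothing equilibrate after the vertices reach the surface. A much looser
tolerance (a large fraction of an edge length) would be cheaper but makes
warm-started fits no-ops whenever the per-frame deformation is below it,
freezing the markers; the chosen tolerance sits well below the per-frame
displacements the method is designed for. Frame 0 starts from a sphere
enclosing the embryo (margin 1.05); frame k > 0 starts from the previous
fit, optionally blended with a re-centered sphere (`alpha`, default 0).

**What the markers can and cannot track.** An unsigned-distance descent
observes only the component of surface motion along the surface normal.
Normal motion (pulsation, invagination, local bulging) is tracked
accurately; the tangential component of a motion is invisible to the
distance functional, so under a rigid translation markers track the
*surface* exactly but slip tangentially by most of the per-frame
tangential shift. This is an intrinsic property of distance-based
registration, shared by any scheme without texture or feature
correspondence. The operative quality metric is therefore the
junction-displacement validation below, which measures exactly the
frame-to-frame marker consistency the downstream strain rates depend on.

**Junction validation.** Junctions — points where ≥ 3 cells meet — are
detected from per-cell meshes: cells whose triangle barycenters come
mutually within `contact_tol` (default 1.5 × median cell edge length) form
a contact clique, and the junction is placed at the mean of the
participating barycenters, restricted to the outermost (apical) band
because extruded 3D cells meet along radial contact lines while junctions
are apical structures. The per-frame error is the change of the
junction-to-marker distance between consecutive frames, normalized by the
mean apical edge length. On the default synthetic pulsation with a 40-cell
tessellation this error is ~0.2% (per-frame mean), far below the 8%
working bound for usable marker quality; the junction detector recovers
~95% of the ground-truth junctions within `contact_tol`.

## Strain-rate field

Velocities are centered differences of marker positions in time (one-sided
at the sequence ends), in length/hour. The per-triangle gradient of each
velocity component is the exact gradient of the linear interpolant; the
assembled gradient G (rows = component gradients) is symmetrized and
projected onto the triangle plane,

    D = P sym(G) P,   P = I − n nᵀ,

then area-averaged onto vertices. The projection matters: the intrinsic
gradient of a rigid rotation field is not antisymmetric (its normal-column
block is unobservable from surface data), and without the projection a
rotation would leave a spurious strain of the same order as a genuine
expansion. With it, rigid translations and rotations produce strain rates
at machine precision, and a uniform expansion v = c·x gives the expected
tangential signature: eigenvalues {c, c, 0} and scalar c√2 (within 0.1%
at subdivision level 4; the normal direction carries no observable
stretch, so the third eigenvalue is 0, not c).

The scalar activity field is f = √(λ₁² + λ₂² + λ₃²), identically the
Frobenius norm of D. Smoothing is applied to the *tensor* field before the
eigen-decomposition: a Gaussian over the ring-1/ring-2 mesh neighbourhood
(σ = 1 ring, truncated at ring 2) and a discrete Gaussian over frames
(σ = 1 frame, reflecting boundaries). Ring-index weights are used instead
of geodesic distances because the marker mesh is quasi-uniform; the kernel
is row-normalized, hence exactly constant-preserving, and componentwise,
hence symmetry-preserving and linear. Eigenvalues are sorted descending;
eigenvector signs are fixed (largest-magnitude component positive) so
output files are reproducible.

## Spherical-harmonic decomposition

The transform uses complex orthonormal harmonics evaluated at the marker
rest coordinates; dA is the area element of the *unit-sphere
parametrization* (the rest mesh), not of the deformed embryo, which keeps
the basis orthonormal and the coefficients comparable across time even as
the embryo deforms. On the level-4 icosphere the discrete Gram matrix for
l ≤ 8 deviates from identity by < 2 × 10⁻³ entrywise and a band-limited
round-trip errs by ~0.1%. L_max defaults to 12; an aliasing guard warns
when (L_max + 1)² exceeds half the vertex count. Variance ratios
vr_lm(t) = |f_lm(t)| / Σ|f_l'm'(t)| are reported per frame and
time-averaged; the denominator includes every computed mode so the ratios
sum to one per frame (frames with all-zero coefficients yield missing
values).

## Wavelet scalograms

Coefficient series are z-scored (population statistics) over an analysis
window, then correlated with L2-normalized Ricker wavelets
ψ_s(x) = (2/(√(3s) π^¼))(1 − (x/s)²) e^(−x²/2s²) on a geometric grid of
32 scales from 1 frame to N/4 frames. Boundaries are zero-padded; kernels
are truncated at 8 s, keeping the truncation error at the 10⁻¹³ level, and
a cone-of-influence mask flags pad-contaminated entries. Signed
coefficients are stored; heatmap export shows |C|. Event extraction takes
local maxima of |C| on the (scale, time) grid with non-maximum suppression
in time and deterministic tie-breaks (earlier time, then smaller scale).
Phase-structure tests read the *signed* coefficients: two activity phases
appear as two positive coarse-scale maxima with a negative band between
them, which is how a quiet transition between two deformation phases
manifests in a Mexican-hat transform.

## Synthetic embryos (what they emulate, what they do not)

All generators produce radial graphs r = R(θ, φ, t) > 0 over the sphere,
which guarantees embedded genus-0 surfaces at every frame and closed-form
particle trajectories and velocities (the "analytic" velocity uses a
centered difference with step 10⁻⁶ h, exact to ~10⁻¹² for these smooth
scripts). Defaults mimic the real data regime: rest radius 60 length
units, 60 frames at dt = 2 min, pulsation amplitude 3% (per-frame radial
displacement ≈ 0.1 edge length).

* The **pulsation script** (global R(t) = R₀(1 + 0.03 sin 2πt)) emulates
  embryo-wide activity cycles and is the default small-deformation
  sequence for marker validation.
* The **mode-recovery script** superposes a polar Y₁₀ radial modulation on
  a global carrier strong enough to keep the radial rate single-signed.
  The carrier is essential, not cosmetic: the scalar field is a magnitude,
  so a *pure* Y₁₀ drive folds into even harmonics (|cos θ|) and the
  recovered spectrum would peak at (2, 0). With the carrier — which also
  mirrors the real system, where division waves ride on top of localized
  invagination — the (1, 0) mode is genuinely the dominant l ≥ 1 mode of
  the activity field, and the pipeline recovers exactly that.
* The **invagination script** indents a polar cap (raised-cosine profile,
  C¹ at the rim) by a depth schedule; two logistic ramps separated by a
  plateau create two deformation phases with known centers for
  event-timing tests.
* The **cell tessellation** Lloyd-relaxes seeds on the direction sphere,
  assigns faces to the nearest seed, and extrudes each patch inward into a
  closed shell (default thickness ≈ half a cell diameter). Ground-truth
  junctions are the surface vertices whose incident faces span ≥ 3 cells,
  clustered by mesh adjacency (the same cell triple can meet at several
  distinct points).

The generators do **not** emulate: cell divisions that change topology,
tangential tissue flows (all scripts are radial), image segmentation
noise beyond isotropic vertex jitter, or non-star-shaped embryo
geometries. Passing tests therefore demonstrate the correctness of the
numerics and the recoverability of radial deformation modes, not
robustness to arbitrary real-data pathologies.

## Numerical choices and degenerate inputs

* Closest-point queries pre-select k = 12 candidate triangles by centroid
  distance, then use exact point-triangle distances; ties and degenerate
  (zero-area) triangles resolve to barycenter fallbacks.
* Zero-area triangles contribute nothing to area weights (warning) and
  flagged vertices inherit the mean tensor of their ring neighbours.
* Fits that reach the iteration cap (500) are flagged, never raised;
  marker propagation stops at a failed frame and returns the partial
  result with residual statistics per frame.
* Windows with fewer than 3 samples or zero variance are rejected before
  the wavelet transform (a constant series has no events by definition).
* All randomness (tessellation seeds, jitter) flows through
  `numpy.random.default_rng(seed)`; identical scripts and seeds give
  bitwise-identical surfaces.

## Problem sizes

Tests and the acceptance script run the full pipeline at the default
study conditions: subdivision level 4 (2 562 markers), 40–60 frames,
40-cell tessellations, L_max = 12, 32 wavelet scales. These sizes were
chosen to match the data regime the simulator emulates while keeping a
complete run in the tens of seconds on a single CPU; every quantity
reported by `scripts/acceptance.py` is recomputed from scratch at these
sizes.

## Known limitations

* Tangential motion is invisible to distance-based registration (see
  above); strain rates inherit only the normal-motion part of tangential
  flows.
* The harmonic transform is a quadrature, not a least-squares inversion;
  at L_max close to the aliasing limit coefficients blur into each other.
* Junction detection assumes cells meet along reasonably tight contact
  bands; very irregular or gappy segmentations will fragment cliques.
* Scalogram event times within ~5 scales of the window ends sit inside
  the cone of influence and are attenuated by the zero padding.
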