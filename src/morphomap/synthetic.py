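"""Ground-truthed synthetic embryos: deforming genus-0 surfaces.

The generators emulate the data regime the pipeline is built for: a closed
embryo surface sampled at high temporal frequency, so deformations between
consecutive frames are small.  All deformations are radial graphs over the
sphere, r = R(theta, phi, t) > 0, which guarantees an embedded genus-0
surface at every frame and makes particle trajectories, velocities and
dominant modes available in closed form:

* global pulses (an l=0 modulation) mimic rounds of synchronized division;
* low-degree real-harmonic radial modes create pole-localized activity;
* a smoothly blended polar-cap indentation mimics endoderm invagination;
* a centroidal Voronoi tessellation cuts the surface into cell patches and
  extrudes them into closed per-cell meshes with known 3-cell junctions.

Default geometry: rest radius 60 length units, 60 frames at dt = 2 minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .harmonics import real_sph_harm
from .registration import EvolvingSurface, Junction
from .sphere import SphereMesh

__all__ = [
    "DeformationScript",
    "GroundTruth",
    "make_deforming_sphere",
    "make_invagination_embryo",
    "make_cell_tessellation",
    "default_pulsation_script",
    "mode_recovery_script",
    "two_phase_depth",
]

_DERIV_H = 1e-6  # step for the quasi-exact time derivative of R


@dataclass
class DeformationScript:
    """Radial deformation R(theta, phi, t) = r0 (1 + modes + pulses).

    ``radial_modes`` is a list of ``(l, m, a)`` with ``a(t)`` the amplitude
    of the real harmonic Y_lm; ``pulse_schedule`` lists global
    ``(t_center, width, amplitude)`` Gaussian pulses (an l=0 term).
    Amplitudes must keep R positive everywhere.  ``noise_sigma`` adds
    isotropic Gaussian vertex jitter (in length units) to the emitted
    frames; the ground truth stays noise-free.
    """

    n_frames: int = 60
    dt: float = 2.0 / 60.0  # hours
    r0: float = 60.0
    radial_modes: Sequence[tuple[int, int, Callable[[float], float]]] = ()
    pulse_schedule: Sequence[tuple[float, float, float]] = ()
    noise_sigma: float = 0.0
    seed: int = 0

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    def relative_radius(self, theta: np.ndarray, phi: np.ndarray, t: float) -> np.ndarray:
        """R / r0 at one instant."""
        r = np.ones_like(theta)
        for l, m, a in self.radial_modes:
            r = r + a(t) * real_sph_harm(l, m, theta, phi)
        for tc, w, amp in self.pulse_schedule:
            r = r + amp * np.exp(-((t - tc) ** 2) / (2.0 * w**2))
        return r


@dataclass
class GroundTruth:
    """Exact particle paths and velocities consistent with the script."""

    trajectories: np.ndarray  # (T, V, 3), noise-free vertex paths
    velocities: np.ndarray  # (T, V, 3), analytic, length/hour
    mode_labels: list[tuple[int, int]] = dataclass_field(default_factory=list)
    event_times: list[float] = dataclass_field(default_factory=list)


def _radial_frames(
    radius_fn: Callable[[float], np.ndarray],
    directions: np.ndarray,
    times: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Positions and quasi-exact velocities for a radial deformation.

    ``radius_fn(t)`` returns the per-vertex radius; the velocity is radial,
    dR/dt * direction, evaluated by a centered difference with step 1e-6 h
    (exact to ~1e-12 for the smooth scripts used here).
    """
    pos = np.empty((len(times), len(directions), 3))
    vel = np.empty_like(pos)
    for k, t in enumerate(times):
        r = radius_fn(t)
        if np.any(r <= 0):
            raise ValueError("script error: non-positive radius (amplitudes too large)")
        pos[k] = directions * r[:, None]
        drdt = (radius_fn(t + _DERIV_H) - radius_fn(t - _DERIV_H)) / (2.0 * _DERIV_H)
        vel[k] = directions * drdt[:, None]
    return pos, vel


def make_deforming_sphere(
    script: DeformationScript, base: SphereMesh
) -> tuple[EvolvingSurface, GroundTruth]:
    """Sample the script on the base sphere mesh.

    Frame k places vertex v at R(theta_v, phi_v, t_k) times its unit
    direction.  Deterministic given the script (the seed only drives the
    optional jitter).
    """
    times = script.times
    theta, phi = base.theta, base.phi

    def radius(t: float) -> np.ndarray:
        return script.r0 * script.relative_radius(theta, phi, t)

    pos, vel = _radial_frames(radius, base.vertices, times)
    emitted = pos
    if script.noise_sigma > 0:
        rng = np.random.default_rng(script.seed)
        emitted = pos + rng.normal(0.0, script.noise_sigma, size=pos.shape)
    surface = EvolvingSurface(times, emitted, base.faces, "raw_input")
    truth = GroundTruth(
        trajectories=pos,
        velocities=vel,
        mode_labels=[(l, m) for l, m, _ in script.radial_modes],
        event_times=[tc for tc, _, _ in script.pulse_schedule],
    )
    return surface, truth


def default_pulsation_script(
    n_frames: int = 60,
    dt: float = 2.0 / 60.0,
    r0: float = 60.0,
    epsilon: float = 0.03,
    period: float = 1.0,
    seed: int = 0,
) -> DeformationScript:
    """Slow global radial pulsation R(t) = r0 (1 + eps sin(2 pi t / period)).

    The default small-deformation sequence: per-frame radial displacement is
    about a tenth of a mesh edge at subdivision level 4.
    """
    omega = 2.0 * np.pi / period
    y00 = 1.0 / np.sqrt(4.0 * np.pi)

    def a00(t: float) -> float:
        return epsilon * np.sin(omega * t) / y00

    return DeformationScript(
        n_frames=n_frames, dt=dt, r0=r0, radial_modes=[(0, 0, a00)], seed=seed
    )


def mode_recovery_script(
    n_frames: int = 60,
    dt: float = 2.0 / 60.0,
    r0: float = 60.0,
    a_global: float = 0.04,
    a_polar: float = 0.05,
    period: float = 1.0,
    seed: int = 0,
) -> DeformationScript:
    """Polar (1,0)-driven deformation riding on a global carrier.

    R = r0 (1 + s(t) (a_global + a_polar Y_10(theta))), s(t) = sin(2 pi t /
    period).  The global term keeps the radial rate positive everywhere, so
    the magnitude of the strain-rate field inherits the Y_10 asymmetry
    instead of folding it into even harmonics; (1, 0) is then the dominant
    l >= 1 mode of the scalar field by construction.
    """
    if a_polar * np.sqrt(3.0 / (4.0 * np.pi)) >= a_global:
        raise ValueError("carrier too weak: |a_polar * max Y10| must stay below a_global")
    omega = 2.0 * np.pi / period
    y00 = 1.0 / np.sqrt(4.0 * np.pi)

    def a00(t: float) -> float:
        return a_global * np.sin(omega * t) / y00

    def a10(t: float) -> float:
        return a_polar * np.sin(omega * t)

    return DeformationScript(
        n_frames=n_frames,
        dt=dt,
        r0=r0,
        radial_modes=[(0, 0, a00), (1, 0, a10)],
        seed=seed,
    )


def two_phase_depth(
    centers: tuple[float, float],
    widths: tuple[float, float] = (0.1, 0.1),
    amplitudes: tuple[float, float] = (6.0, 6.0),
) -> Callable[[float], float]:
    """Depth schedule with two logistic ramps: ramp, plateau, second ramp.

    The indentation deepens fastest at the two ramp centers, which are the
    ground-truth event times for scalogram tests.
    """

    def depth(t: float) -> float:
        d = 0.0
        for c, w, a in zip(centers, widths, amplitudes):
            d += a / (1.0 + np.exp(-(t - c) / w))
        return d

    return depth


def make_invagination_embryo(
    depth: Callable[[float], float],
    cap_angle: float,
    n_frames: int,
    dt: float,
    base: SphereMesh,
    r0: float = 60.0,
) -> tuple[EvolvingSurface, GroundTruth]:
    """Polar-cap indentation: a localized invagination-like deformation.

    Vertices within ``cap_angle`` of the +z pole move radially inward by
    ``depth(t)`` times a C1 raised-cosine profile that vanishes (with zero
    slope) at the cap rim; the rest of the surface is static.  The surface
    stays an embedded radial graph as long as the depth keeps r positive.
    """
    if not 0.0 < cap_angle < np.pi / 2.0:
        raise ValueError("cap_angle must lie in (0, pi/2)")
    times = np.arange(n_frames) * dt
    theta = base.theta
    profile = np.where(
        theta < cap_angle, 0.5 * (1.0 + np.cos(np.pi * theta / cap_angle)), 0.0
    )

    def radius(t: float) -> np.ndarray:
        return r0 - depth(t) * profile

    pos, vel = _radial_frames(radius, base.vertices, times)
    surface = EvolvingSurface(times, pos, base.faces, "raw_input")
    return surface, GroundTruth(trajectories=pos, velocities=vel)


# ---------------------------------------------------------------------------
# cell tessellation


def _lloyd_on_sphere(
    directions: np.ndarray, areas: np.ndarray, n_cells: int, rng: np.random.Generator, iters: int = 30
) -> tuple[np.ndarray, np.ndarray]:
    """Area-weighted spherical Lloyd relaxation; returns (seeds, assignment)."""
    seeds = rng.normal(size=(n_cells, 3))
    seeds /= np.linalg.norm(seeds, axis=1, keepdims=True)
    assign = np.zeros(len(directions), dtype=np.int64)
    for _ in range(iters):
        assign = np.argmax(directions @ seeds.T, axis=1)
        for c in range(n_cells):
            sel = assign == c
            if not sel.any():  # dead seed: restart on a random direction
                seeds[c] = directions[rng.integers(len(directions))]
                continue
            mean = (directions[sel] * areas[sel, None]).sum(axis=0)
            norm = np.linalg.norm(mean)
            if norm > 0:
                seeds[c] = mean / norm
        assign = np.argmax(directions @ seeds.T, axis=1)
    return seeds, assign


def _extrude_patch(
    vertices: np.ndarray, faces: np.ndarray, center: np.ndarray, thickness: float
) -> tuple[np.ndarray, np.ndarray]:
    """Close a surface patch into a solid cell shell of given thickness.

    The patch is the apical (outer) face set; basal faces are a copy pulled
    radially toward ``center`` and flipped; lateral walls seal the boundary.
    """
    used = np.unique(faces)
    local = {int(v): i for i, v in enumerate(used)}
    outer = vertices[used]
    radial = outer - center
    rn = np.linalg.norm(radial, axis=1, keepdims=True)
    inner = outer - radial / rn * min(thickness, 0.9 * rn.min())
    n_loc = len(used)
    verts = np.vstack([outer, inner])
    fl = np.vectorize(local.__getitem__)(faces)
    apical = fl
    basal = fl[:, ::-1] + n_loc
    # boundary edges: directed edges whose reverse is absent
    directed = set()
    for a, b, c in fl:
        directed.update(((a, b), (b, c), (c, a)))
    walls = []
    for a, b in list(directed):
        if (b, a) not in directed:  # boundary edge, interior on the left
            walls.append((b, a, a + n_loc))
            walls.append((b, a + n_loc, b + n_loc))
    return verts, np.vstack([apical, basal, np.asarray(walls, dtype=np.int64)])


def make_cell_tessellation(
    vertices: np.ndarray,
    faces: np.ndarray,
    n_cells: int,
    seed: int = 0,
    thickness: float | None = None,
) -> tuple[dict[int, tuple[np.ndarray, np.ndarray]], list[Junction]]:
    """Cut a closed surface into cells and extrude them into closed meshes.

    Faces are assigned to the nearest of ``n_cells`` centroidal-Voronoi
    seeds (Lloyd-relaxed on the unit sphere of directions from the surface
    centroid).  Each patch becomes a closed cell mesh of the given
    ``thickness`` (default: half the expected cell diameter).  The true
    3-cell junctions are the surface vertices whose incident faces span at
    least three cells, labelled with their member-cell sets.
    """
    vertices = np.asarray(vertices, float)
    faces = np.asarray(faces, np.int64)
    if n_cells < 3:
        raise ValueError("n_cells must be >= 3")
    if n_cells > len(vertices) / 10:
        raise ValueError("n_cells > V/10: patches would be under-resolved")
    rng = np.random.default_rng(seed)
    center = vertices.mean(axis=0)
    fc = vertices[faces].mean(axis=1)
    fdir = fc - center
    fdir /= np.linalg.norm(fdir, axis=1, keepdims=True)
    cross = np.cross(
        vertices[faces[:, 1]] - vertices[faces[:, 0]],
        vertices[faces[:, 2]] - vertices[faces[:, 0]],
    )
    farea = 0.5 * np.linalg.norm(cross, axis=1)
    _, assign = _lloyd_on_sphere(fdir, farea, n_cells, rng)

    mean_r = np.linalg.norm(vertices - center, axis=1).mean()
    if thickness is None:
        thickness = mean_r * np.sqrt(4.0 / n_cells)  # ~half a cell diameter

    cells = {}
    for c in range(n_cells):
        sel = faces[assign == c]
        if len(sel) == 0:
            continue
        cells[c] = _extrude_patch(vertices, sel, center, thickness)

    # true junctions: vertices whose incident faces span >= 3 cells,
    # clustered by mesh adjacency (the same cell triple can meet at several
    # distinct points, e.g. two antipodal triple points for 3 cells)
    incident: list[set[int]] = [set() for _ in range(len(vertices))]
    for f, c in zip(faces, assign):
        for v in f:
            incident[v].add(int(c))
    jverts = [v for v, cs in enumerate(incident) if len(cs) >= 3]
    import networkx as nx

    from .sphere import edges_from_faces

    g = nx.Graph()
    g.add_nodes_from(jverts)
    jset = set(jverts)
    for a, b in edges_from_faces(faces):
        if a in jset and b in jset and incident[a] == incident[b]:
            g.add_edge(int(a), int(b))
    junctions = []
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        members = frozenset().union(*(incident[v] for v in comp))
        junctions.append(Junction(members, vertices[comp].mean(axis=0)))
    junctions.sort(key=lambda j: (sorted(j.members), tuple(j.position)))
    return cells, junctions
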