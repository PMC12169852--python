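"""Reference sphere mesh: subdivided icosahedron with spherical parametrization.

The whole pipeline shares a single fixed-topology sphere mesh.  Its vertices
are the Lagrangian markers; their (theta, phi) coordinates on the undeformed
sphere are the arguments of every spherical-harmonic transform downstream.
Subdivision uses the interpolating butterfly scheme (8-point stencil, with
the extraordinary-vertex rules for the twelve valence-5 icosahedron
vertices), followed by re-projection onto the unit sphere so the sphere
stays exact at every level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SphereMesh",
    "build_icosphere",
    "spherical_coords",
    "vertex_area_weights",
    "edges_from_faces",
    "ordered_vertex_rings",
]

# Golden-ratio icosahedron, outward CCW orientation.
_T = (1.0 + np.sqrt(5.0)) / 2.0
_ICO_VERTICES = np.array(
    [
        (-1, _T, 0), (1, _T, 0), (-1, -_T, 0), (1, -_T, 0),
        (0, -1, _T), (0, 1, _T), (0, -1, -_T), (0, 1, -_T),
        (_T, 0, -1), (_T, 0, 1), (-_T, 0, -1), (-_T, 0, 1),
    ],
    dtype=float,
)
_ICO_FACES = np.array(
    [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ],
    dtype=np.int64,
)


def edges_from_faces(faces: np.ndarray) -> np.ndarray:
    """Unique undirected edges (sorted pairs, lexicographic order)."""
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e = np.sort(e, axis=1)
    return np.unique(e, axis=0)


@dataclass
class SphereMesh:
    """Fixed-topology sphere mesh (successively subdivided icosahedron).

    vertices lie on the unit sphere; ``theta`` is the polar angle from +z in
    [0, pi], ``phi`` the azimuth in [0, 2*pi).
    """

    vertices: np.ndarray
    faces: np.ndarray
    subdivision_level: int
    theta: np.ndarray = field(init=False)
    phi: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        r = np.linalg.norm(self.vertices, axis=1)
        if np.any(np.abs(r - 1.0) > 1e-12):
            raise ValueError("SphereMesh vertices must lie on the unit sphere")
        self.theta, self.phi = spherical_coords(self.vertices)

    @property
    def edges(self) -> np.ndarray:
        return edges_from_faces(self.faces)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges) + self.n_faces

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    def export(self, path: str) -> None:
        """Write as PLY (binary little-endian) or OBJ, by extension."""
        self.to_trimesh().export(path)


def spherical_coords(vertices: np.ndarray, tol: float = 1e-9):
    """Polar/azimuthal angles of unit vectors.

    theta = arccos(z) in [0, pi]; phi = atan2(y, x) wrapped into [0, 2*pi).
    """
    v = np.asarray(vertices, dtype=float)
    r = np.linalg.norm(v, axis=-1)
    if np.any(np.abs(r - 1.0) > tol):
        raise ValueError("vertices are not on the unit sphere")
    theta = np.arccos(np.clip(v[..., 2], -1.0, 1.0))
    phi = np.mod(np.arctan2(v[..., 1], v[..., 0]), 2.0 * np.pi)
    return theta, phi


def sphere_points(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Inverse of :func:`spherical_coords`."""
    st = np.sin(theta)
    return np.stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)], axis=-1)


def vertex_area_weights(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Barycentric (one-third) lumped vertex areas of a closed triangle mesh.

    Each triangle contributes one third of its area to each of its corners;
    the weights sum to the total surface area.  Degenerate (zero-area)
    triangles contribute nothing and trigger a warning.
    """
    v = np.asarray(vertices, dtype=float)
    f = np.asarray(faces, dtype=np.int64)
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    area = 0.5 * np.linalg.norm(cross, axis=1)
    if np.any(area == 0.0):
        warnings.warn("degenerate zero-area triangle(s); weight contribution 0")
    w = np.zeros(len(v))
    np.add.at(w, f.ravel(), np.repeat(area / 3.0, 3))
    return w


def ordered_vertex_rings(faces: np.ndarray, n_vertices: int) -> list[np.ndarray]:
    """Cyclically ordered 1-ring neighbours of every vertex of a closed mesh.

    The cycle follows the face orientation; the starting neighbour is
    arbitrary but deterministic.
    """
    nxt: list[dict[int, int]] = [dict() for _ in range(n_vertices)]
    for a, b, c in faces:
        nxt[a][b] = c
        nxt[b][c] = a
        nxt[c][a] = b
    rings = []
    for v in range(n_vertices):
        succ = nxt[v]
        if not succ:
            rings.append(np.empty(0, dtype=np.int64))
            continue
        start = min(succ)
        ring = [start]
        while True:
            n = succ[ring[-1]]
            if n == start:
                break
            ring.append(n)
            if len(ring) > len(succ):  # open fan: not a closed manifold
                raise ValueError("mesh is not a closed manifold around vertex %d" % v)
        rings.append(np.asarray(ring, dtype=np.int64))
    return rings


def _zorin_weights(k: int) -> np.ndarray:
    """Butterfly stencil weights around an extraordinary vertex of valence k."""
    if k == 3:
        return np.array([5.0 / 12.0, -1.0 / 12.0, -1.0 / 12.0])
    if k == 4:
        return np.array([3.0 / 8.0, 0.0, -1.0 / 8.0, 0.0])
    j = np.arange(k)
    return (0.25 + np.cos(2 * np.pi * j / k) + 0.5 * np.cos(4 * np.pi * j / k)) / k


def _butterfly_midpoints(vertices: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One new point per edge via the interpolating butterfly rules.

    Returns (edges, midpoints) with edges sorted lexicographically, so the
    vertex numbering of the subdivided mesh is deterministic.
    """
    n_v = len(vertices)
    edges = edges_from_faces(faces)
    edge_index = {(int(a), int(b)): i for i, (a, b) in enumerate(edges)}

    # adjacent faces of every undirected edge
    adj: dict[tuple[int, int], list[int]] = {tuple(e): [] for e in map(tuple, edges.tolist())}
    for fi, (a, b, c) in enumerate(faces):
        for u, w in ((a, b), (b, c), (c, a)):
            key = (u, w) if u < w else (w, u)
            adj[key].append(fi)

    def opposite(fi: int, a: int, b: int) -> int:
        tri = faces[fi]
        for x in tri:
            if x != a and x != b:
                return int(x)
        raise AssertionError

    rings = ordered_vertex_rings(faces, n_v)
    valence = np.array([len(r) for r in rings])

    def irregular_point(v: int, other: int) -> np.ndarray:
        ring = rings[v]
        k = len(ring)
        s = _zorin_weights(k)
        start = int(np.where(ring == other)[0][0])
        idx = np.roll(ring, -start)
        return 0.75 * vertices[v] + s @ vertices[idx]

    mids = np.empty((len(edges), 3))
    for (a, b), ei in edge_index.items():
        fa, fb = adj[(a, b)]
        ka, kb = valence[a], valence[b]
        if ka == 6 and kb == 6:
            c = opposite(fa, a, b)
            d = opposite(fb, a, b)
            wings = []
            for (u, w), skip in (((a, c), fa), ((b, c), fa), ((a, d), fb), ((b, d), fb)):
                key = (u, w) if u < w else (w, u)
                f1, f2 = adj[key]
                wings.append(opposite(f2 if f1 == skip else f1, u, w))
            p = (
                0.5 * (vertices[a] + vertices[b])
                + 0.125 * (vertices[c] + vertices[d])
                - 0.0625 * vertices[wings].sum(axis=0)
            )
        elif ka != 6 and kb != 6:
            p = 0.5 * (irregular_point(a, b) + irregular_point(b, a))
        elif ka != 6:
            p = irregular_point(a, b)
        else:
            p = irregular_point(b, a)
        mids[ei] = p
    return edges, mids


def _subdivide(vertices: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    edges, mids = _butterfly_midpoints(vertices, faces)
    # re-project new points onto the unit sphere (old points already on it)
    mids = mids / np.linalg.norm(mids, axis=1, keepdims=True)
    n_v = len(vertices)
    edge_index = {(int(a), int(b)): n_v + i for i, (a, b) in enumerate(edges)}

    def mid(a: int, b: int) -> int:
        return edge_index[(a, b) if a < b else (b, a)]

    new_faces = []
    for a, b, c in faces:
        ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
        new_faces.extend([(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)])
    return np.vstack([vertices, mids]), np.asarray(new_faces, dtype=np.int64)


def build_icosphere(subdivisions: int = 4) -> SphereMesh:
    """Icosphere: icosahedron plus ``subdivisions`` butterfly subdivisions.

    Level 0 is the icosahedron (V=12, F=20); each level maps F -> 4F and
    V -> V + E.  Connectivity is deterministic.  Levels above ~7 are refused
    to bound memory.
    """
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    if subdivisions > 7:
        raise ValueError("subdivision level > 7 not supported (memory cap)")
    v = _ICO_VERTICES / np.linalg.norm(_ICO_VERTICES, axis=1, keepdims=True)
    f = _ICO_FACES.copy()
    for _ in range(subdivisions):
        v, f = _subdivide(v, f)
    return SphereMesh(v, f, subdivisions)
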