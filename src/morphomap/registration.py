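"""Level-set-inspired registration of the sphere mesh onto embryo surfaces.

A fixed-topology sphere mesh is deformed onto each frame of a time-evolving
closed surface by descending the unsigned distance to the target: every
vertex moves toward its closest point on the target surface, with a small
tangential Laplacian smoothing step that keeps the vertex distribution even.
Chaining the fits across frames (warm-starting each frame from the previous
fit) yields Lagrangian markers: material points that co-move with the
surface in the small-deformation regime.

Marker quality is validated against cell-junction trajectories: junctions
(meeting points of three or more cells) are detected from per-cell meshes,
and the frame-to-frame change of the junction-to-marker distance, normalized
by the average apical edge length, measures how Lagrangian the markers are.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .sphere import SphereMesh, edges_from_faces

logger = logging.getLogger(__name__)

__all__ = [
    "FitParams",
    "FitResult",
    "EvolvingSurface",
    "Junction",
    "JunctionTrack",
    "MeshDistance",
    "fit_surface",
    "propagate_markers",
    "detect_junctions",
    "match_junction_tracks",
    "junction_displacement_error",
]


@dataclass
class FitParams:
    """Parameters of the distance-descent fit.

    step and tolerance are expressed as fractions of the median target edge
    length so the fit is scale free; absolute overrides take precedence when
    set.  ``alpha`` blends the warm start for frame k > 0 between the
    previous fit (alpha=0) and the centered, rescaled sphere (alpha=1).
    """

    step_factor: float = 0.3
    smooth_weight: float = 0.1
    tol_factor: float = 0.05
    tol_abs: float | None = None
    max_iter: int = 500
    min_iter: int = 1  # always re-project onto the current target at least once
    alpha: float = 0.0
    enclosing_margin: float = 1.05

    def resolve_tol(self, median_edge: float) -> float:
        return self.tol_abs if self.tol_abs is not None else self.tol_factor * median_edge


@dataclass
class FitResult:
    positions: np.ndarray
    converged: bool
    n_iter: int
    residual_max: float
    residual_mean: float
    residual_rms: float
    residual_history: np.ndarray  # max residual per iteration


@dataclass
class EvolvingSurface:
    """Per-frame vertex positions over fixed connectivity.

    ``provenance`` is ``"raw_input"`` for surfaces read from data or the
    simulator and ``"fitted"`` for the Lagrangian marker mesh S2(t).
    """

    times: np.ndarray
    positions: np.ndarray  # (n_frames, n_vertices, 3)
    faces: np.ndarray
    provenance: str = "raw_input"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_vertices, 3)")
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions disagree on frame count")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        # small-deformation advisory check
        if len(self.positions) > 1:
            disp = np.linalg.norm(np.diff(self.positions, axis=0), axis=2)
            med_edge = np.median(
                np.linalg.norm(
                    self.positions[0][self.faces[:, 0]] - self.positions[0][self.faces[:, 1]],
                    axis=1,
                )
            )
            if np.median(disp) > med_edge:
                logger.warning(
                    "median frame-to-frame displacement exceeds the median edge "
                    "length: outside the small-deformation regime"
                )

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_vertices(self) -> int:
        return self.positions.shape[1]

    def frame(self, k: int) -> np.ndarray:
        return self.positions[k]


# ---------------------------------------------------------------------------
# point-to-mesh distance queries


def _closest_point_on_triangles(p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Closest point on triangle (a,b,c) to p, all arrays (n, 3). Ericson's method."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def assign(mask, val):
        m = mask & ~done
        out[m] = val[m]
        done[m] = True

    assign((d1 <= 0) & (d2 <= 0), a)  # vertex a
    assign((d3 >= 0) & (d4 <= d3), b)  # vertex b
    assign((d6 >= 0) & (d5 <= d6), c)  # vertex c
    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)  # edge ab
    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)  # edge ac
    va = d3 * d6 - d5 * d4
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = np.where((d4 - d3) + (d5 - d6) != 0, (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0)
    assign((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + w_bc[:, None] * (c - b))  # edge bc
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 1.0 / 3.0)
        w = np.where(denom != 0, vc / denom, 1.0 / 3.0)
    inside = ~done
    out[inside] = (a + v[:, None] * ab + w[:, None] * ac)[inside]
    return out


class MeshDistance:
    """Exact closest-point queries against a triangle mesh.

    Candidate triangles are pre-selected with a k-d tree over triangle
    centroids (k nearest, padded by the largest triangle radius), then the
    exact point-triangle distance decides.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray, k: int = 12):
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = np.asarray(faces, dtype=np.int64)
        self.tri = self.vertices[self.faces]  # (F, 3, 3)
        self.centroids = self.tri.mean(axis=1)
        self.tree = cKDTree(self.centroids)
        self.k = min(k, len(self.faces))
        # radius of the largest triangle around its centroid: query guard band
        self.max_tri_radius = np.max(np.linalg.norm(self.tri - self.centroids[:, None, :], axis=2))
        e = self.vertices[self.faces[:, 0]] - self.vertices[self.faces[:, 1]]
        self.median_edge = float(np.median(np.linalg.norm(e, axis=1)))

    def closest_point(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (closest points on the surface, distances)."""
        points = np.asarray(points, dtype=float)
        _, idx = self.tree.query(points, k=self.k)
        if self.k == 1:
            idx = idx[:, None]
        n, k = idx.shape
        flat = idx.ravel()
        rep = np.repeat(points, k, axis=0)
        cp = _closest_point_on_triangles(
            rep, self.tri[flat, 0], self.tri[flat, 1], self.tri[flat, 2]
        ).reshape(n, k, 3)
        d2 = np.sum((cp - points[:, None, :]) ** 2, axis=2)
        best = np.argmin(d2, axis=1)
        rows = np.arange(n)
        return cp[rows, best], np.sqrt(d2[rows, best])


# ---------------------------------------------------------------------------
# fitting


def vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Area-weighted vertex normals of a triangle mesh."""
    fn = np.cross(
        vertices[faces[:, 1]] - vertices[faces[:, 0]],
        vertices[faces[:, 2]] - vertices[faces[:, 0]],
    )
    n = np.zeros_like(vertices)
    np.add.at(n, faces.ravel(), np.repeat(fn, 3, axis=0).reshape(-1, 3))
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return n / norm


def _adjacency(faces: np.ndarray, n_vertices: int):
    from scipy.sparse import coo_matrix

    e = edges_from_faces(faces)
    i = np.concatenate([e[:, 0], e[:, 1]])
    j = np.concatenate([e[:, 1], e[:, 0]])
    a = coo_matrix((np.ones(len(i)), (i, j)), shape=(n_vertices, n_vertices)).tocsr()
    deg = np.asarray(a.sum(axis=1)).ravel()
    return a, deg


def fit_surface(
    target_vertices: np.ndarray,
    target_faces: np.ndarray,
    source_vertices: np.ndarray,
    source_faces: np.ndarray,
    params: FitParams | None = None,
    distance: MeshDistance | None = None,
) -> FitResult:
    """Deform ``source`` onto ``target`` by unsigned-distance descent.

    Every source vertex moves toward its closest point on the target by at
    most ``step`` per iteration, followed by a tangential umbrella-Laplacian
    smoothing step (weight ``smooth_weight``) that preserves mesh quality.
    Terminates when the max per-vertex distance drops below the tolerance or
    at ``max_iter``; non-convergence is flagged, not raised.
    """
    params = params or FitParams()
    if distance is None:
        distance = MeshDistance(target_vertices, target_faces)
    step = params.step_factor * distance.median_edge
    tol = params.resolve_tol(distance.median_edge)

    v = np.array(source_vertices, dtype=float)
    center = np.asarray(target_vertices).mean(axis=0)
    if np.max(np.linalg.norm(v - center, axis=1)) < 0.98 * np.max(
        np.linalg.norm(target_vertices - center, axis=1)
    ):
        logger.warning("source does not enclose the target; distance descent proceeds anyway")
    adj, deg = _adjacency(source_faces, len(v))
    history = []
    converged = False
    n_iter = 0
    last_update = np.inf
    cp, d = distance.closest_point(v)
    for n_iter in range(1, params.max_iter + 1):
        history.append(d.max())
        # converged once the residual is within tolerance AND the mesh has
        # stopped moving (the smoothing term needs a few extra iterations to
        # equilibrate after the vertices reach the surface)
        if d.max() < tol and last_update < 0.5 * tol and n_iter > params.min_iter:
            converged = True
            n_iter -= 1
            break
        # descend the unsigned distance: move toward the closest point
        move = np.minimum(d, step)
        with np.errstate(invalid="ignore", divide="ignore"):
            direction = np.where(d[:, None] > 0, (cp - v) / np.maximum(d, 1e-300)[:, None], 0.0)
        v_old = v
        v = v + direction * move[:, None]
        if params.smooth_weight > 0:
            lap = adj @ v / deg[:, None] - v
            normals = vertex_normals(v, source_faces)
            lap -= np.einsum("ij,ij->i", lap, normals)[:, None] * normals
            v = v + params.smooth_weight * lap
        last_update = float(np.linalg.norm(v - v_old, axis=1).max())
        cp, d = distance.closest_point(v)
    else:
        history.append(d.max())
    if not converged:
        logger.warning("fit did not converge in %d iterations (max residual %.3g)", params.max_iter, d.max())
    return FitResult(
        positions=v,
        converged=converged,
        n_iter=n_iter,
        residual_max=float(d.max()),
        residual_mean=float(d.mean()),
        residual_rms=float(np.sqrt(np.mean(d**2))),
        residual_history=np.asarray(history),
    )


def enclosing_sphere(base: SphereMesh, target_vertices: np.ndarray, margin: float = 1.05) -> np.ndarray:
    """Sphere-mesh vertices centered on the target and enclosing it."""
    center = np.asarray(target_vertices).mean(axis=0)
    radius = margin * np.max(np.linalg.norm(target_vertices - center, axis=1))
    return base.vertices * radius + center


def propagate_markers(
    raw_frames,
    times: np.ndarray,
    base: SphereMesh,
    params: FitParams | None = None,
) -> tuple[EvolvingSurface, list[FitResult]]:
    """Fit the sphere mesh to every frame, chaining fits into markers.

    ``raw_frames`` is a sequence of ``(vertices, faces)`` closed meshes in
    temporal order.  Frame 0 is fitted from a sphere enclosing the embryo;
    frame k > 0 starts from ``(1 - alpha) * fit_{k-1} + alpha * sphere_k``
    (``alpha = 0``: pure warm start).  On a fit failure the pipeline stops at
    that frame and returns the partial result.
    """
    params = params or FitParams()
    if len(raw_frames) < 2:
        raise ValueError("need at least 2 frames")
    times = np.asarray(times, dtype=float)
    if len(times) != len(raw_frames):
        raise ValueError("times and frames disagree")

    fitted = []
    results = []
    source = None
    for k, (tv, tf) in enumerate(raw_frames):
        dist = MeshDistance(tv, tf)
        if source is None:
            source = enclosing_sphere(base, tv, params.enclosing_margin)
        elif params.alpha > 0:
            sphere_k = enclosing_sphere(base, tv, params.enclosing_margin)
            source = (1.0 - params.alpha) * source + params.alpha * sphere_k
        res = fit_surface(tv, tf, source, base.faces, params, distance=dist)
        results.append(res)
        fitted.append(res.positions)
        source = res.positions
        if not res.converged:
            logger.error("fit failed at frame %d; returning partial result", k)
            surf = EvolvingSurface(times[: k + 1], np.asarray(fitted), base.faces, "fitted")
            return surf, results
    surf = EvolvingSurface(times, np.asarray(fitted), base.faces, "fitted")
    return surf, results


# ---------------------------------------------------------------------------
# junction detection and validation


@dataclass(frozen=True)
class Junction:
    """A point where >= 3 cells meet; identity is the member-cell set."""

    members: frozenset
    position: np.ndarray

    def __eq__(self, other):  # identity by member set
        return isinstance(other, Junction) and self.members == other.members

    def __hash__(self):
        return hash(self.members)


@dataclass
class JunctionTrack:
    """A junction followed over frames; NaN rows where undefined."""

    members: frozenset
    positions: np.ndarray  # (n_frames, 3), NaN where all member cells absent

    def defined(self) -> np.ndarray:
        return ~np.any(np.isnan(self.positions), axis=1)


def _cell_barycenters(cells: dict) -> dict:
    out = {}
    for cid, (v, f) in cells.items():
        v = np.asarray(v, float)
        f = np.asarray(f, np.int64)
        out[cid] = v[f].mean(axis=1)
    return out


def detect_junctions(cells: dict, contact_tol: float | None = None) -> list[Junction]:
    """Detect >= 3-cell junctions from per-cell closed meshes of one frame.

    For each maximal set of >= 3 cells whose triangle barycenters come
    mutually within ``contact_tol``, one junction is emitted at the mean of
    the participating barycenters.  Because cells are 3D shells, three cells
    meet along a radial contact line; junctions are apical structures, so
    the averaging keeps only the outermost band (within ``contact_tol`` of
    the largest centroid distance among the participants).  Default
    tolerance: 1.5x the median cell-mesh edge length.
    """
    if len(cells) < 3:
        return []
    if contact_tol is None:
        edges = []
        for v, f in cells.values():
            v = np.asarray(v, float)
            f = np.asarray(f, np.int64)
            edges.append(np.linalg.norm(v[f[:, 0]] - v[f[:, 1]], axis=1))
        contact_tol = 1.5 * float(np.median(np.concatenate(edges)))

    bary = _cell_barycenters(cells)
    trees = {cid: cKDTree(b) for cid, b in bary.items()}
    ids = sorted(bary, key=str)
    center = np.concatenate(list(bary.values())).mean(axis=0)

    contact = nx.Graph()
    contact.add_nodes_from(ids)
    for i, j in itertools.combinations(ids, 2):
        pairs = trees[i].query_ball_tree(trees[j], contact_tol)
        if any(pairs):
            contact.add_edge(i, j)

    junctions = []
    for clique in nx.find_cliques(contact):
        if len(clique) < 3:
            continue
        pts = []
        ok = True
        for cid in clique:
            near = np.ones(len(bary[cid]), dtype=bool)
            for other in clique:
                if other == cid:
                    continue
                lists = trees[cid].query_ball_tree(trees[other], contact_tol)
                near &= np.array([len(l) > 0 for l in lists])
            if not near.any():
                ok = False
                break
            pts.append(bary[cid][near])
        if ok:
            p = np.concatenate(pts)
            r = np.linalg.norm(p - center, axis=1)
            apical = p[r >= r.max() - contact_tol]
            junctions.append(Junction(frozenset(clique), apical.mean(axis=0)))
    return junctions


def match_junction_tracks(per_frame_junctions: list[list[Junction]], n_frames: int | None = None) -> list[JunctionTrack]:
    """Assemble per-frame junction sets into tracks keyed by member-cell set."""
    if n_frames is None:
        n_frames = len(per_frame_junctions)
    keys = sorted({j.members for frame in per_frame_junctions for j in frame}, key=lambda s: sorted(map(str, s)))
    tracks = []
    for key in keys:
        pos = np.full((n_frames, 3), np.nan)
        for k, frame in enumerate(per_frame_junctions):
            for j in frame:
                if j.members == key:
                    pos[k] = j.position
        tracks.append(JunctionTrack(key, pos))
    return tracks


def junction_displacement_error(
    tracks: list[JunctionTrack],
    fitted: EvolvingSurface,
    apex_edge_length: float,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Relative junction-marker displacement per frame (dimensionless).

    At frame t each junction is paired with its nearest fitted vertex (its
    marker); the error contribution is the change, from t to t+1, of the
    junction-marker distance, normalized by the average apical edge length.
    Returns the per-frame mean series and the (junction x frame) error map.
    """
    n_f = fitted.n_frames
    err = np.full((len(tracks), n_f - 1), np.nan)
    for ji, tr in enumerate(tracks):
        defined = tr.defined()
        if defined.sum() < 2:
            logger.info("junction %s defined at <2 frames; skipped", set(tr.members))
            continue
        for t in range(n_f - 1):
            if not (defined[t] and defined[t + 1]):
                continue
            tree = cKDTree(fitted.positions[t])
            d0, m = tree.query(tr.positions[t])
            d1 = np.linalg.norm(tr.positions[t + 1] - fitted.positions[t + 1][m])
            err[ji, t] = abs(d1 - d0) / apex_edge_length
    frames = np.arange(n_f - 1)
    with np.errstate(invalid="ignore"):
        mean_err = np.nanmean(err, axis=0)
    df = pd.DataFrame(
        {
            "frame": frames,
            "time": fitted.times[:-1],
            "mean_error": mean_err,
            "n_junctions": np.sum(~np.isnan(err), axis=0),
        }
    )
    return df, err


def mean_apical_edge_length(cells: dict, surface_center: np.ndarray | None = None) -> float:
    """Average edge length of outward-facing (apical) cell triangles.

    Apical triangles are identified by outward normal orientation relative to
    the aggregate cell centroid; when orientation is ambiguous the mean over
    all cell-surface edges is returned.
    """
    allv = np.concatenate([np.asarray(v, float) for v, _ in cells.values()])
    center = allv.mean(axis=0) if surface_center is None else surface_center
    lengths = []
    for v, f in cells.values():
        v = np.asarray(v, float)
        f = np.asarray(f, np.int64)
        tri = v[f]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        out = np.einsum("ij,ij->i", n, tri.mean(axis=1) - center) > 0
        # apical = outward-facing AND far from the centroid (outer shell)
        r = np.linalg.norm(tri.mean(axis=1) - center, axis=1)
        shell = r > np.percentile(r, 60)
        sel = f[out & shell] if (out & shell).any() else f
        e = np.concatenate([sel[:, [0, 1]], sel[:, [1, 2]], sel[:, [2, 0]]])
        lengths.append(np.linalg.norm(v[e[:, 0]] - v[e[:, 1]], axis=1))
    return float(np.mean(np.concatenate(lengths)))
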