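"""Surface strain-rate kinematics from Lagrangian marker trajectories.

The marker mesh gives a velocity field v(x, t) at every vertex.  The
strain-rate tensor is the symmetric part of the velocity gradient,
D = sym(grad v), restricted to what surface data can observe: the gradient
is computed intrinsically (per-triangle linear interpolation, which is exact
for affine velocity fields), and D is projected onto the local tangent
plane, D = P sym(G) P.  This kills the spurious symmetric part a rigid
rotation would otherwise leave behind (the normal-derivative block is
unobservable from surface data) and gives the radial-expansion convention
eigenvalues {c, c, 0} for v = c x.

The derived scalar field f = sqrt(lambda1^2 + lambda2^2 + lambda3^2) equals
the Frobenius norm of D and measures the local magnitude of the rate of
shape change; it is the field that is decomposed spectrally downstream.
Gaussian smoothing over the ring-1/ring-2 mesh neighbourhood (and over
frames) is applied to the tensor field before the eigen-decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.ndimage import gaussian_filter1d

from .registration import EvolvingSurface

__all__ = [
    "StrainField",
    "velocity_field",
    "triangle_gradients",
    "strain_rate_tensor",
    "smooth_field",
    "eigen_decomposition",
    "scalar_strain_rate",
    "compute_strain_field",
    "ring_weight_matrix",
]


def velocity_field(surface: EvolvingSurface) -> np.ndarray:
    """Per-frame, per-vertex 3D velocity by finite differences in time.

    Central differences in the interior, one-sided at the first and last
    frame.  Units: length per hour.
    """
    t = surface.times
    x = surface.positions
    if len(t) < 2:
        raise ValueError("need at least 2 frames")
    if np.any(np.diff(t) == 0):
        raise ValueError("duplicate timestamps")
    v = np.empty_like(x)
    v[0] = (x[1] - x[0]) / (t[1] - t[0])
    v[-1] = (x[-1] - x[-2]) / (t[-1] - t[-2])
    if len(t) > 2:
        dt = (t[2:] - t[:-2])[:, None, None]
        v[1:-1] = (x[2:] - x[:-2]) / dt
    return v


def triangle_gradients(vertices: np.ndarray, faces: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Per-triangle surface gradient of per-vertex values (linear interp).

    ``values`` has shape (V,) or (V, C); returns (F, 3) or (F, C, 3).
    Exact for fields that are affine in space.
    """
    p0, p1, p2 = (vertices[faces[:, i]] for i in range(3))
    n = np.cross(p1 - p0, p2 - p0)
    a2 = np.linalg.norm(n, axis=1)  # 2 * area
    deg = a2 == 0
    a2safe = np.where(deg, 1.0, a2)
    nhat = n / a2safe[:, None]
    # gradients of barycentric coordinates
    g0 = np.cross(nhat, p2 - p1) / a2safe[:, None]
    g1 = np.cross(nhat, p0 - p2) / a2safe[:, None]
    g2 = np.cross(nhat, p1 - p0) / a2safe[:, None]
    vals = np.asarray(values)
    squeeze = vals.ndim == 1
    if squeeze:
        vals = vals[:, None]
    v0, v1, v2 = (vals[faces[:, i]] for i in range(3))
    g = v0[..., None] * g0[:, None, :] + v1[..., None] * g1[:, None, :] + v2[..., None] * g2[:, None, :]
    g[deg] = 0.0
    return g[:, 0, :] if squeeze else g


def strain_rate_tensor(vertices: np.ndarray, faces: np.ndarray, velocity: np.ndarray) -> np.ndarray:
    """Per-vertex symmetric strain-rate tensor D = P sym(grad v) P.

    Per-triangle: rows of G are the in-plane gradients of vx, vy, vz; the
    symmetrized tensor is projected onto the triangle plane (P = I - n n^T)
    and the per-triangle tensors are area-averaged onto vertices.  Vertices
    whose whole incident ring is degenerate receive the mean tensor of their
    ring neighbours.
    """
    vertices = np.asarray(vertices, float)
    faces = np.asarray(faces, np.int64)
    velocity = np.asarray(velocity, float)

    p0, p1, p2 = (vertices[faces[:, i]] for i in range(3))
    n = np.cross(p1 - p0, p2 - p0)
    a2 = np.linalg.norm(n, axis=1)
    area = 0.5 * a2
    deg = a2 == 0
    nhat = n / np.where(deg, 1.0, a2)[:, None]

    g = triangle_gradients(vertices, faces, velocity)  # (F, 3 comps, 3)
    sym = 0.5 * (g + np.transpose(g, (0, 2, 1)))
    proj = np.eye(3)[None] - nhat[:, :, None] * nhat[:, None, :]
    d_tri = proj @ sym @ proj
    d_tri[deg] = 0.0

    n_v = len(vertices)
    d = np.zeros((n_v, 3, 3))
    w = np.zeros(n_v)
    contrib = (area[:, None, None] * d_tri)
    for i in range(3):
        np.add.at(d, faces[:, i], contrib)
        np.add.at(w, faces[:, i], area)
    bad = w == 0
    d[~bad] /= w[~bad, None, None]
    if bad.any():
        # fall back to the mean tensor of ring neighbours
        from .sphere import edges_from_faces

        e = edges_from_faces(faces)
        for v in np.flatnonzero(bad):
            nbr = np.concatenate([e[e[:, 0] == v, 1], e[e[:, 1] == v, 0]])
            good = nbr[~bad[nbr]]
            d[v] = d[good].mean(axis=0) if len(good) else 0.0
    return 0.5 * (d + np.transpose(d, (0, 2, 1)))


def ring_weight_matrix(faces: np.ndarray, n_vertices: int, sigma: float = 1.0) -> sparse.csr_matrix:
    """Row-normalized Gaussian kernel over the ring-1/ring-2 neighbourhood.

    Weights w(r) ~ exp(-r^2 / (2 sigma^2)) with r the ring index (0, 1, 2),
    truncated at ring 2 and normalized to sum to one per vertex.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    from .sphere import edges_from_faces

    e = edges_from_faces(faces)
    i = np.concatenate([e[:, 0], e[:, 1]])
    j = np.concatenate([e[:, 1], e[:, 0]])
    adj = sparse.coo_matrix((np.ones(len(i)), (i, j)), shape=(n_vertices, n_vertices)).tocsr()
    adj.data[:] = 1.0
    ring1 = adj
    two_hop = (adj @ adj).tocsr()
    two_hop.setdiag(0)
    two_hop.eliminate_zeros()
    two_hop.data[:] = 1.0
    ring2 = (two_hop - two_hop.multiply(ring1)).tocsr()
    ring2.eliminate_zeros()

    w = [np.exp(-(r**2) / (2.0 * sigma**2)) for r in (0, 1, 2)]
    m = (w[0] * sparse.eye(n_vertices, format="csr") + w[1] * ring1 + w[2] * ring2).tocsr()
    rowsum = np.asarray(m.sum(axis=1)).ravel()
    return sparse.diags(1.0 / rowsum) @ m


def smooth_field(
    field: np.ndarray,
    faces: np.ndarray,
    spatial_sigma: float = 1.0,
    temporal_sigma: float = 1.0,
) -> np.ndarray:
    """Gaussian smoothing over mesh rings (space) and frames (time).

    ``field`` has shape (V, ...) for a single frame or (T, V, ...) for a
    sequence; smoothing is componentwise, hence linear and
    symmetry-preserving for tensor fields.  The temporal pass uses a discrete
    Gaussian with reflecting boundaries; set ``temporal_sigma=0`` to skip it.
    """
    field = np.asarray(field, float)
    single = False
    # disambiguate: a single frame is (V, ...), a sequence (T, V, ...)
    n_mesh = int(faces.max()) + 1
    if field.ndim == 1:
        single = True
        field = field[None, :]
    elif field.ndim >= 2 and field.shape[0] == n_mesh and field.shape[1] != n_mesh:
        single = True
        field = field[None, ...]
    n_v = field.shape[1]
    m = ring_weight_matrix(faces, n_v, spatial_sigma)
    flat = field.reshape(field.shape[0], n_v, -1)
    out = np.empty_like(flat)
    for k in range(flat.shape[0]):
        out[k] = m @ flat[k]
    out = out.reshape(field.shape)
    if not single and temporal_sigma > 0 and len(out) > 1:
        out = gaussian_filter1d(out, temporal_sigma, axis=0, mode="reflect")
    return out[0] if single else out


def eigen_decomposition(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (descending) and eigenvectors of symmetric tensors.

    ``d`` has shape (..., 3, 3).  Eigenvector signs are fixed by making the
    largest-magnitude component positive, for reproducible output files.
    """
    vals, vecs = np.linalg.eigh(d)
    order = np.argsort(vals, axis=-1)[..., ::-1]
    vals = np.take_along_axis(vals, order, axis=-1)
    vecs = np.take_along_axis(vecs, order[..., None, :], axis=-1)
    # sign fix per eigenvector (columns of vecs)
    comp = np.argmax(np.abs(vecs), axis=-2, keepdims=True)
    sign = np.sign(np.take_along_axis(vecs, comp, axis=-2))
    sign[sign == 0] = 1.0
    vecs = vecs * sign
    return vals, vecs


def scalar_strain_rate(eigvals: np.ndarray) -> np.ndarray:
    """f = sqrt(sum of squared eigenvalues); the Frobenius norm of D."""
    return np.sqrt(np.sum(np.asarray(eigvals) ** 2, axis=-1))


@dataclass
class StrainField:
    """Strain-rate tensors, eigenpairs and the scalar field per frame/vertex."""

    times: np.ndarray
    tensors: np.ndarray  # (T, V, 3, 3), 1/hour
    eigvals: np.ndarray  # (T, V, 3), descending
    eigvecs: np.ndarray  # (T, V, 3, 3), columns are unit eigenvectors
    scalar: np.ndarray  # (T, V), 1/hour


def compute_strain_field(
    fitted: EvolvingSurface,
    spatial_sigma: float = 1.0,
    temporal_sigma: float = 1.0,
) -> StrainField:
    """Velocity -> tensor -> smoothing -> eigenpairs -> scalar field.

    Smoothing is applied to the tensor field before the eigen-decomposition;
    pass ``spatial_sigma=0`` to disable smoothing entirely.
    """
    vel = velocity_field(fitted)
    tensors = np.stack(
        [strain_rate_tensor(fitted.positions[k], fitted.faces, vel[k]) for k in range(fitted.n_frames)]
    )
    if spatial_sigma > 0:
        tensors = smooth_field(tensors, fitted.faces, spatial_sigma, temporal_sigma)
    vals, vecs = eigen_decomposition(tensors)
    return StrainField(fitted.times, tensors, vals, vecs, scalar_strain_rate(vals))
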