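"""Velocity fields, strain-rate tensors and Gaussian field smoothing."""

import numpy as np
import pytest

from morphomap.kinematics import (
    eigen_decomposition,
    scalar_strain_rate,
    smooth_field,
    strain_rate_tensor,
    triangle_gradients,
    velocity_field,
)
from morphomap.registration import EvolvingSurface
from morphomap.sphere import build_icosphere, vertex_area_weights


def surface_from(positions, times, faces):
    return EvolvingSurface(times, positions, faces, "fitted")


class TestVelocityField:
    def test_static_surface_has_zero_velocity(self, sphere2):
        surf = surface_from(np.stack([sphere2.vertices] * 3), np.arange(3.0), sphere2.faces)
        assert np.abs(velocity_field(surf)).max() == 0.0

    def test_uniform_translation_velocity(self, sphere2):
        d = np.array([1.0, -2.0, 0.5])
        pos = np.stack([sphere2.vertices + k * d for k in range(4)])
        v = velocity_field(surface_from(pos, np.arange(4.0), sphere2.faces))
        np.testing.assert_allclose(v, np.broadcast_to(d, v.shape), atol=1e-12)

    def test_radial_pulsation_matches_analytic_rate(self, sphere2):
        r0, eps, omega = 2.0, 0.1, 2 * np.pi
        times = np.linspace(0.0, 0.5, 26)  # dt = 0.02
        pos = np.stack([sphere2.vertices * r0 * (1 + eps * np.sin(omega * t)) for t in times])
        v = velocity_field(surface_from(pos, times, sphere2.faces))
        dt = times[1] - times[0]
        for k in (5, 12, 20):  # interior frames: O(dt^2) finite-difference error
            analytic = sphere2.vertices * r0 * eps * omega * np.cos(omega * times[k])
            err = np.linalg.norm(v[k] - analytic, axis=1).max()
            assert err < r0 * eps * omega**3 * dt**2  # |f'''| dt^2 / 6 bound, generous

    def test_duplicate_timestamps_rejected(self, sphere2):
        pos = np.stack([sphere2.vertices] * 2)
        surf = surface_from(pos, np.array([0.0, 1.0]), sphere2.faces)
        surf.times = np.array([1.0, 1.0])  # bypass constructor validation
        with pytest.raises(ValueError, match="duplicate|increasing"):
            velocity_field(surf)


class TestStrainRateTensor:
    def test_uniform_translation_gives_zero_tensor(self, sphere4):
        vel = np.tile([3.0, -1.0, 2.0], (sphere4.n_vertices, 1))
        d = strain_rate_tensor(sphere4.vertices, sphere4.faces, vel)
        assert np.abs(d).max() < 1e-10

    def test_uniform_expansion_matches_tangential_oracle(self, sphere4):
        """v = c x on the unit sphere: D ~ c P, eigenvalues {c, c, 0}, f ~ c sqrt(2)."""
        c = 0.7
        d = strain_rate_tensor(sphere4.vertices, sphere4.faces, c * sphere4.vertices)
        vals, _ = eigen_decomposition(d)
        assert np.abs(vals[:, 0] - c).max() < 0.05 * c
        assert np.abs(vals[:, 1] - c).max() < 0.05 * c
        assert np.abs(vals[:, 2]).max() < 0.05 * c
        f = scalar_strain_rate(vals)
        assert np.abs(f - c * np.sqrt(2)).max() < 0.05 * c * np.sqrt(2)

    def test_rigid_rotation_removed(self, sphere4):
        """The tangential-block projection annihilates rigid-body rotation."""
        omega = np.array([0.0, 0.0, 1.0])
        vel = np.cross(omega, sphere4.vertices)
        d = strain_rate_tensor(sphere4.vertices, sphere4.faces, vel)
        f_rot = scalar_strain_rate(eigen_decomposition(d)[0])
        # reference: expansion of equal velocity magnitude (|v| = 1 on the sphere)
        d_exp = strain_rate_tensor(sphere4.vertices, sphere4.faces, sphere4.vertices)
        f_exp = scalar_strain_rate(eigen_decomposition(d_exp)[0])
        assert f_rot.max() < f_exp.mean() / 100.0

    def test_matches_brute_force_triangle_oracle(self, sphere2):
        """Independent per-triangle recomputation of the area-averaged tensor."""
        rng = np.random.default_rng(7)
        a = rng.normal(size=(3, 3))
        vel = sphere2.vertices @ a.T  # affine velocity field
        d = strain_rate_tensor(sphere2.vertices, sphere2.faces, vel)

        v, faces = sphere2.vertices, sphere2.faces
        acc = np.zeros((len(v), 3, 3))
        wsum = np.zeros(len(v))
        for tri in faces:
            p = v[tri]
            n = np.cross(p[1] - p[0], p[2] - p[0])
            area = np.linalg.norm(n) / 2.0
            nhat = n / np.linalg.norm(n)
            proj = np.eye(3) - np.outer(nhat, nhat)
            g = np.zeros((3, 3))
            for comp in range(3):
                # solve the linear interpolant explicitly: grad is the
                # in-plane vector with g . (p_j - p_0) = f_j - f_0
                e1, e2 = p[1] - p[0], p[2] - p[0]
                m = np.array([e1, e2, nhat])
                rhs = np.array([vel[tri[1], comp] - vel[tri[0], comp],
                                vel[tri[2], comp] - vel[tri[0], comp], 0.0])
                g[comp] = np.linalg.solve(m, rhs)
            dt = proj @ (0.5 * (g + g.T)) @ proj
            for vi in tri:
                acc[vi] += area * dt
                wsum[vi] += area
        oracle = acc / wsum[:, None, None]
        np.testing.assert_allclose(d, oracle, atol=1e-10)

    def test_translation_invariance(self, sphere2):
        rng = np.random.default_rng(0)
        vel = rng.normal(size=(sphere2.n_vertices, 3))
        d1 = strain_rate_tensor(sphere2.vertices, sphere2.faces, vel)
        d2 = strain_rate_tensor(sphere2.vertices, sphere2.faces, vel + np.array([5.0, -3.0, 1.0]))
        np.testing.assert_allclose(d1, d2, atol=1e-10)

    def test_scaling_covariance_is_exact(self, sphere2):
        rng = np.random.default_rng(1)
        vel = rng.normal(size=(sphere2.n_vertices, 3))
        d1 = strain_rate_tensor(sphere2.vertices, sphere2.faces, vel)
        d2 = strain_rate_tensor(sphere2.vertices, sphere2.faces, 2.5 * vel)
        np.testing.assert_allclose(d2, 2.5 * d1, rtol=1e-12)

    def test_refinement_improves_expansion_accuracy(self):
        errs = []
        for level in (3, 5):
            m = build_icosphere(level)
            d = strain_rate_tensor(m.vertices, m.faces, m.vertices)
            f = scalar_strain_rate(eigen_decomposition(d)[0])
            errs.append(np.abs(f - np.sqrt(2)).max())
        assert errs[1] < errs[0]

    def test_symmetry_invariant(self, sphere2):
        rng = np.random.default_rng(3)
        vel = rng.normal(size=(sphere2.n_vertices, 3))
        d = strain_rate_tensor(sphere2.vertices, sphere2.faces, vel)
        assert np.abs(d - np.transpose(d, (0, 2, 1))).max() < 1e-10


class TestEigenAndScalar:
    def test_scalar_is_frobenius_norm(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(50, 3, 3))
        d = 0.5 * (a + np.transpose(a, (0, 2, 1)))
        vals, vecs = eigen_decomposition(d)
        f = scalar_strain_rate(vals)
        np.testing.assert_allclose(f, np.linalg.norm(d, axis=(1, 2)), atol=1e-10)
        # eigenvalues descending, eigenvectors orthonormal
        assert np.all(np.diff(vals, axis=1) <= 1e-12)
        eye = vecs @ np.transpose(vecs, (0, 2, 1))
        assert np.abs(eye - np.eye(3)).max() < 1e-8

    def test_three_four_five(self):
        d = np.diag([3.0, 4.0, 0.0])[None]
        vals, _ = eigen_decomposition(d)
        assert scalar_strain_rate(vals)[0] == pytest.approx(5.0)

    def test_zero_tensor(self):
        vals, _ = eigen_decomposition(np.zeros((1, 3, 3)))
        assert scalar_strain_rate(vals)[0] == 0.0


class TestSmoothField:
    def test_constant_field_unchanged(self, sphere3):
        out = smooth_field(np.ones(sphere3.n_vertices), sphere3.faces)
        np.testing.assert_allclose(out, 1.0, atol=1e-12)

    def test_delta_mass_conserved_on_ring_patch(self, sphere3):
        delta = np.zeros(sphere3.n_vertices)
        delta[100] = 1.0
        out = smooth_field(delta, sphere3.faces, temporal_sigma=0)
        assert out.sum() == pytest.approx(1.0, abs=0.02)
        # support confined to the ring-2 patch
        assert np.count_nonzero(out) <= 19 + 1  # ring-1 (6) + ring-2 (12) + self

    def test_white_noise_variance_shrinks(self, sphere3):
        reductions = []
        for seed in range(100):
            x = np.random.default_rng(seed).normal(size=sphere3.n_vertices)
            y = smooth_field(x, sphere3.faces)
            reductions.append(y.var() < x.var())
        assert all(reductions)

    def test_tensor_symmetry_preserved_and_linear(self, sphere2):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(3, sphere2.n_vertices, 3, 3))
        a = 0.5 * (a + np.swapaxes(a, 2, 3))
        b = rng.normal(size=a.shape)
        b = 0.5 * (b + np.swapaxes(b, 2, 3))
        sa = smooth_field(a, sphere2.faces)
        sb = smooth_field(b, sphere2.faces)
        sab = smooth_field(2.0 * a - 3.0 * b, sphere2.faces)
        np.testing.assert_allclose(sab, 2.0 * sa - 3.0 * sb, atol=1e-10)
        assert np.abs(sa - np.swapaxes(sa, 2, 3)).max() < 1e-12

    def test_nonpositive_sigma_rejected(self, sphere2):
        with pytest.raises(ValueError, match="sigma"):
            smooth_field(np.ones(sphere2.n_vertices), sphere2.faces, spatial_sigma=0.0)


def test_triangle_gradient_exact_for_linear_fields(sphere2):
    a = np.array([0.3, -1.2, 0.7])
    field = sphere2.vertices @ a
    g = triangle_gradients(sphere2.vertices, sphere2.faces, field)
    # oracle: gradient of a linear field is the in-plane projection of a
    p = sphere2.vertices[sphere2.faces]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    proj = a[None, :] - np.einsum("fj,j->f", n, a)[:, None] * n
    np.testing.assert_allclose(g, proj, atol=1e-12)
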