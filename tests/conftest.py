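"""Shared fixtures: reference meshes and the heavier end-to-end pipelines.

The expensive products (fitted marker sequences, strain fields, variance
tables) are computed once per session and shared between unit and
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from morphomap.harmonics import HarmonicSeries, sh_forward, variance_ratios
from morphomap.kinematics import compute_strain_field
from morphomap.registration import JunctionTrack, propagate_markers
from morphomap.sphere import build_icosphere, vertex_area_weights
from morphomap.synthetic import (
    default_pulsation_script,
    make_cell_tessellation,
    make_deforming_sphere,
    make_invagination_embryo,
    mode_recovery_script,
    two_phase_depth,
)


@pytest.fixture(scope="session")
def sphere2():
    return build_icosphere(2)


@pytest.fixture(scope="session")
def sphere3():
    return build_icosphere(3)


@pytest.fixture(scope="session")
def sphere4():
    return build_icosphere(4)


def fit_all_frames(surface, base, params=None):
    frames = [(surface.positions[k], surface.faces) for k in range(surface.n_frames)]
    fitted, results = propagate_markers(frames, surface.times, base, params)
    return fitted, results


@pytest.fixture(scope="session")
def pulsation(sphere4):
    """Default small-deformation sequence: raw frames, ground truth, fit."""
    script = default_pulsation_script()
    surf, truth = make_deforming_sphere(script, sphere4)
    fitted, results = fit_all_frames(surf, sphere4)
    return {"script": script, "raw": surf, "truth": truth, "fitted": fitted, "results": results}


@pytest.fixture(scope="session")
def pulsation_junctions(pulsation, sphere4):
    """40-cell tessellation of the pulsating embryo with exact junction tracks.

    Under a global radial pulsation every surface point keeps its direction,
    so the material trajectory of a junction is its frame-0 position scaled
    by R(t)/R(0).
    """
    script = pulsation["script"]
    surf = pulsation["raw"]
    cells, true_j = make_cell_tessellation(surf.positions[0], sphere4.faces, 40, seed=1)
    zero = np.zeros(1)
    ratio = np.array([script.relative_radius(zero, zero, t)[0] for t in surf.times])
    ratio /= ratio[0]
    tracks = [JunctionTrack(j.members, np.outer(ratio, j.position)) for j in true_j]
    return {"cells": cells, "true_junctions": true_j, "tracks": tracks}


@pytest.fixture(scope="session")
def mode_recovery(sphere4):
    """End-to-end run of the polar-mode script up to variance ratios."""
    script = mode_recovery_script(n_frames=40)
    surf, truth = make_deforming_sphere(script, sphere4)
    fitted, _ = fit_all_frames(surf, sphere4)
    strain = compute_strain_field(fitted)
    w = vertex_area_weights(sphere4.vertices, sphere4.faces)
    coeffs = sh_forward(strain.scalar, w, sphere4.theta, sphere4.phi, 12)
    series = HarmonicSeries(strain.times, 12, coeffs)
    return {"truth": truth, "strain": strain, "series": series, "vr": variance_ratios(series)}


@pytest.fixture(scope="session")
def invagination_two_phase(sphere4):
    """Two-ramp polar indentation run through strain and harmonics."""
    n_frames, dt = 60, 2.0 / 60.0
    span = n_frames * dt
    centers = (0.3 * span, 0.7 * span)
    depth = two_phase_depth(centers, (0.05 * span, 0.05 * span), (6.0, 6.0))
    cap_angle = np.pi / 3.0
    surf, truth = make_invagination_embryo(depth, cap_angle, n_frames, dt, sphere4)
    fitted, _ = fit_all_frames(surf, sphere4)
    strain = compute_strain_field(fitted)
    w = vertex_area_weights(sphere4.vertices, sphere4.faces)
    series = HarmonicSeries(strain.times, 12, sh_forward(strain.scalar, w, sphere4.theta, sphere4.phi, 12))
    return {
        "centers": centers,
        "cap_angle": cap_angle,
        "depth": depth,
        "raw": surf,
        "fitted": fitted,
        "strain": strain,
        "series": series,
    }
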