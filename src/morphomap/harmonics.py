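"""Spherical-harmonic decomposition of scalar fields on the marker mesh.

Every marker carries the (theta, phi) coordinates of its rest position on
the unit sphere, so a per-vertex scalar field is a sampled function
f(theta, phi, t).  The forward transform is the quadrature

    f_lm(t) = sum_v f(v, t) conj(Y_lm(theta_v, phi_v)) w_v,

with Y_lm the complex orthonormal harmonics and w_v the vertex area weights
of the unit-sphere mesh, rescaled to total 4*pi (the exact measure of the
sphere).  Mode importance is ranked by the variance ratio
vr_lm = |f_lm| / sum |f_l'm'|, which sums to one per frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import sph_harm_y

logger = logging.getLogger(__name__)

__all__ = [
    "HarmonicSeries",
    "VarianceTable",
    "lm_pairs",
    "lm_index",
    "sh_basis_matrix",
    "sh_forward",
    "sh_reconstruct",
    "variance_ratios",
    "real_sph_harm",
]


def lm_pairs(lmax: int) -> list[tuple[int, int]]:
    """(l, m) pairs in canonical order: l ascending, m from -l to l."""
    return [(l, m) for l in range(lmax + 1) for m in range(-l, l + 1)]


def lm_index(l: int, m: int) -> int:
    """Position of (l, m) in the canonical coefficient vector."""
    if abs(m) > l:
        raise ValueError("|m| must be <= l")
    return l * l + l + m


def sh_basis_matrix(theta: np.ndarray, phi: np.ndarray, lmax: int) -> np.ndarray:
    """Complex orthonormal Y_lm sampled at (theta, phi): shape (V, (lmax+1)^2)."""
    theta = np.asarray(theta, float)
    phi = np.asarray(phi, float)
    cols = np.empty((len(theta), (lmax + 1) ** 2), dtype=complex)
    for l in range(lmax + 1):
        for m in range(-l, l + 1):
            cols[:, lm_index(l, m)] = sph_harm_y(l, m, theta, phi)
    return cols


def real_sph_harm(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Real orthonormal spherical harmonic (the basis driving the simulator).

    m = 0: Y_l0; m > 0: sqrt(2) (-1)^m Re(Y_lm); m < 0: sqrt(2) (-1)^m Im(Y_l|m|).
    """
    if m == 0:
        return np.real(sph_harm_y(l, 0, theta, phi))
    y = sph_harm_y(l, abs(m), theta, phi)
    s = np.sqrt(2.0) * (-1.0) ** abs(m)
    return s * (np.real(y) if m > 0 else np.imag(y))


@dataclass
class HarmonicSeries:
    """Coefficient time series f_lm(t), complex orthonormal basis."""

    times: np.ndarray
    lmax: int
    coeffs: np.ndarray  # (T, (lmax+1)^2) complex

    def __post_init__(self) -> None:
        self.times = np.atleast_1d(np.asarray(self.times, float))
        self.coeffs = np.atleast_2d(np.asarray(self.coeffs, complex))
        if self.coeffs.shape[1] != (self.lmax + 1) ** 2:
            raise ValueError("coefficient count must be (lmax+1)^2")

    def series(self, l: int, m: int) -> np.ndarray:
        """The time series of one coefficient, f_lm(t)."""
        return self.coeffs[:, lm_index(l, m)]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for ti, t in enumerate(self.times):
            for l, m in lm_pairs(self.lmax):
                c = self.coeffs[ti, lm_index(l, m)]
                rows.append((t, l, m, c.real, c.imag, abs(c)))
        return pd.DataFrame(rows, columns=["time", "l", "m", "re", "im", "abs"])


@dataclass
class VarianceTable:
    """Per-frame and time-averaged variance ratios vr_lm in [0, 1]."""

    lmax: int
    per_frame: np.ndarray  # (T, (lmax+1)^2); NaN rows where all coeffs vanish
    time_averaged: np.ndarray  # ((lmax+1)^2,)

    def ratio(self, l: int, m: int) -> float:
        return float(self.time_averaged[lm_index(l, m)])

    def to_dataframe(self) -> pd.DataFrame:
        rows = [(l, m, self.time_averaged[lm_index(l, m)]) for l, m in lm_pairs(self.lmax)]
        return pd.DataFrame(rows, columns=["l", "m", "vr"])


def sh_forward(
    field: np.ndarray,
    weights: np.ndarray,
    theta: np.ndarray,
    phi: np.ndarray,
    lmax: int,
    basis: np.ndarray | None = None,
) -> np.ndarray:
    """Forward transform of a per-vertex field (or stack of fields).

    ``field`` has shape (V,) or (T, V); returns ((lmax+1)^2,) or
    (T, (lmax+1)^2) complex coefficients.  Weights are rescaled so their sum
    is exactly 4*pi, the measure of the unit sphere, which removes the flat
    triangle area deficit of the discretization.  An aliasing guard warns
    when (lmax+1)^2 exceeds half the vertex count.
    """
    field = np.asarray(field, float)
    weights = np.asarray(weights, float)
    if lmax < 0:
        raise ValueError("lmax must be >= 0")
    n_v = weights.shape[0]
    if (lmax + 1) ** 2 > n_v / 2:
        logger.warning(
            "(lmax+1)^2 = %d exceeds half the vertex count %d: risk of aliasing",
            (lmax + 1) ** 2,
            n_v,
        )
    w = weights * (4.0 * np.pi / weights.sum())
    y = sh_basis_matrix(theta, phi, lmax) if basis is None else basis
    return field @ (np.conj(y) * w[:, None])


def sh_reconstruct(
    coeffs: np.ndarray,
    theta: np.ndarray,
    phi: np.ndarray,
    basis: np.ndarray | None = None,
    imag_tol: float = 1e-8,
) -> np.ndarray:
    """Evaluate sum_lm f_lm Y_lm at (theta, phi); returns a real field.

    The input must contain the complete (l, m) set up to some lmax.  For
    conjugate-symmetric coefficients the imaginary residue is checked
    against ``imag_tol`` (relative to the field magnitude) and dropped.
    """
    coeffs = np.asarray(coeffs, complex)
    n = coeffs.shape[-1]
    lmax = int(np.sqrt(n)) - 1
    if (lmax + 1) ** 2 != n:
        raise ValueError("coefficient vector length must be a perfect square (complete (l,m) set)")
    y = sh_basis_matrix(theta, phi, lmax) if basis is None else basis
    out = coeffs @ y.T
    scale = max(np.abs(out).max(), 1.0)
    resid = np.abs(out.imag).max() / scale
    if resid > imag_tol:
        logger.warning("non-negligible imaginary residue %.3g in reconstruction", resid)
    return out.real


def variance_ratios(series: HarmonicSeries) -> VarianceTable:
    """Normalized coefficient magnitudes vr_lm(t) = |f_lm| / sum |f_l'm'|.

    Frames whose coefficients all vanish yield NaN rows (logged); the
    time-averaged table is the mean over the valid frames.
    """
    mag = np.abs(series.coeffs)
    tot = mag.sum(axis=1)
    bad = tot == 0
    if bad.any():
        logger.warning("%d frame(s) with all-zero coefficients: vr undefined there", bad.sum())
    vr = np.full_like(mag, np.nan)
    vr[~bad] = mag[~bad] / tot[~bad, None]
    with np.errstate(invalid="ignore"):
        avg = np.nanmean(vr, axis=0) if (~bad).any() else np.full(mag.shape[1], np.nan)
    return VarianceTable(series.lmax, vr, avg)
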