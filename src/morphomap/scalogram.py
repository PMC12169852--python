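"""Ricker-wavelet scalograms of harmonic-coefficient time series.

Each spherical-harmonic coefficient f_lm(t) is a time series describing one
spatial mode of morphogenetic activity.  Within an analysis window the
series is z-scored and correlated with Ricker (Mexican-hat) wavelets

    psi_s(x) = (2 / (sqrt(3 s) pi^(1/4))) (1 - (x/s)^2) exp(-x^2 / (2 s^2)),

one per scale s, producing a scale-by-time coefficient matrix (the
scalogram) whose local extrema localize morphogenetic events in time and
duration.  Boundaries are zero-padded; a cone-of-influence mask marks the
entries contaminated by the padding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Scalogram",
    "normalize_series",
    "ricker",
    "ricker_cwt",
    "find_events",
    "default_scales",
]


def normalize_series(
    ts: np.ndarray, times: np.ndarray, window: tuple[float, float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """z-score a series over a time window (population statistics).

    Returns the normalized series and the times of the retained samples.
    A window with fewer than 3 samples or zero variance is degenerate.
    """
    ts = np.asarray(ts, float)
    times = np.asarray(times, float)
    if window is None:
        mask = np.ones(len(ts), dtype=bool)
    else:
        t0, t1 = window
        if t0 < times[0] - 1e-12 or t1 > times[-1] + 1e-12:
            raise ValueError("window outside series support")
        mask = (times >= t0) & (times <= t1)
    seg = ts[mask]
    if len(seg) < 3:
        raise ValueError("window must contain at least 3 samples")
    std = seg.std()
    if std == 0:
        raise ValueError("zero variance in window: degenerate series")
    return (seg - seg.mean()) / std, times[mask]


def ricker(x: np.ndarray, scale: float) -> np.ndarray:
    """Ricker (Mexican-hat) wavelet of width ``scale``, L2-normalized."""
    x = np.asarray(x, float)
    a = 2.0 / (np.sqrt(3.0 * scale) * np.pi**0.25)
    u = x / scale
    return a * (1.0 - u**2) * np.exp(-(u**2) / 2.0)


def default_scales(n_samples: int, n_scales: int = 32) -> np.ndarray:
    """Geometric scale grid from 1 frame to n_samples / 4 frames."""
    smax = max(n_samples / 4.0, 1.5)
    return np.geomspace(1.0, smax, n_scales)


@dataclass
class Scalogram:
    """Scale-by-time matrix of signed Ricker-wavelet coefficients."""

    times: np.ndarray
    scales: np.ndarray
    coefficients: np.ndarray  # (n_scales, n_times), signed
    series_id: tuple[int, int] | None = None  # (l, m) label

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.scales = np.asarray(self.scales, float)
        self.coefficients = np.asarray(self.coefficients, float)
        if self.coefficients.shape != (len(self.scales), len(self.times)):
            raise ValueError("coefficient matrix must be (n_scales, n_times)")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite scalogram entries")

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.coefficients)

    def cone_of_influence(self, extent: float = 5.0) -> np.ndarray:
        """Boolean mask, True where zero padding contaminates a coefficient.

        A coefficient at (s, t) is flagged when the wavelet support
        (``extent`` * s samples) overruns either end of the window.
        """
        n = len(self.times)
        idx = np.arange(n)
        reach = extent * self.scales
        return (idx[None, :] < reach[:, None]) | ((n - 1 - idx)[None, :] < reach[:, None])


def ricker_cwt(
    ts: np.ndarray,
    scales: np.ndarray,
    times: np.ndarray | None = None,
    series_id: tuple[int, int] | None = None,
) -> Scalogram:
    """Continuous Ricker-wavelet transform of a uniformly sampled series.

    C(s, t) = sum_tau ts(tau) psi_s(tau - t), with zero-padded boundaries.
    The transform is linear in the input; shifting the input shifts the
    scalogram columns (away from the boundary pad).
    """
    ts = np.asarray(ts, float)
    scales = np.asarray(scales, float)
    if np.any(scales <= 0):
        raise ValueError("scales must be positive")
    n = len(ts)
    if times is None:
        times = np.arange(n, dtype=float)
    else:
        times = np.asarray(times, float)
        dt = np.diff(times)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("non-uniform sampling: resample upstream")
    c = np.empty((len(scales), n))
    for i, s in enumerate(scales):
        # Ricker tails fall like x^2 exp(-x^2/2): support of 8 s keeps the
        # truncation error at the 1e-13 level
        half = max(int(np.ceil(8.0 * s)), 1)
        x = np.arange(-half, half + 1, dtype=float)
        psi = ricker(x, s)
        # psi is even, so correlation equals convolution; slice the center
        # of the full convolution (robust when the kernel outgrows the series)
        c[i] = np.convolve(ts, psi, mode="full")[half : half + n]
    return Scalogram(times, scales, c, series_id)


def find_events(
    scalogram: Scalogram,
    min_separation: int = 3,
    min_scale: float = 0.0,
) -> list[tuple[float, float, float]]:
    """Dominant (time, scale, coefficient) local maxima of |C|.

    Local maxima of the coefficient magnitude on the (scale, time) grid are
    collected and thinned by non-maximum suppression within
    ``min_separation`` frames; the survivors are returned sorted by
    decreasing magnitude, ties broken by (earlier time, smaller scale).
    ``min_scale`` restricts the search to coarser scales.
    """
    mag = scalogram.magnitude
    ns, nt = mag.shape
    if ns == 0 or nt == 0:
        return []
    keep = scalogram.scales >= min_scale
    padded = np.full((ns + 2, nt + 2), -np.inf)
    padded[1:-1, 1:-1] = mag
    nbr = np.stack(
        [
            padded[1 + di : 1 + di + ns, 1 + dj : 1 + dj + nt]
            for di in (-1, 0, 1)
            for dj in (-1, 0, 1)
            if not (di == 0 and dj == 0)
        ]
    )
    is_max = (mag >= nbr.max(axis=0)) & (mag > 0) & keep[:, None]
    si, ti = np.nonzero(is_max)
    if len(si) == 0:
        return []
    cand = sorted(
        zip(ti, si, mag[si, ti]),
        key=lambda r: (-r[2], r[0], scalogram.scales[r[1]]),
    )
    chosen: list[tuple[int, int]] = []
    for t, s, _ in cand:
        if all(abs(t - tc) > min_separation for tc, _ in chosen):
            chosen.append((t, s))
    return [
        (float(scalogram.times[t]), float(scalogram.scales[s]), float(scalogram.coefficients[s, t]))
        for t, s in chosen
    ]
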