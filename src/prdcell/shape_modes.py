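"""Fourier shape-mode representation of cell contours.

A cell outline at one time point is reduced to the radial profile
R(theta), the distance from the area centroid to the rim as a function of
the polar angle theta measured counterclockwise from the +x axis.  The
profile is expanded in circular Fourier modes

    R(theta, t) = R0 + sum_{n>=2} ( C_n(t) e^{-i n theta} + conj(C_n) e^{i n theta} ),

so |C_n| is the magnitude of the n-fold deformation and
phi_n = arg(C_n)/n the direction of maximum deformation (under a
rotation of the cell by theta0, C_n picks up the factor e^{i n theta0}).  Mode n = 1 corresponds to a shift of
the centroid and is absorbed into centroid motion by recomputing the area
centroid for every frame; it is retained only as a quality-control
diagnostic.  Mode n = 2 is elongation, n = 3 triangular deformation.

Time derivatives follow the tracking-data convention: a 3-point centered
moving average of the series followed by a forward difference over the
sampling interval (default 5 min), reported per hour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ContourFrame",
    "FourierModes",
    "ShapeModeSeries",
    "DegeneratePolygonError",
    "NonStarConvexError",
    "NonUniformGridError",
    "radial_profile",
    "fourier_modes",
    "reconstruct_profile",
    "phase_decomposition",
    "smooth_and_differentiate",
    "mode_series_from_frames",
]


class DegeneratePolygonError(ValueError):
    """Polygon has (near-)zero area or too few vertices."""


class NonStarConvexError(ValueError):
    """A ray from the centroid failed to cross the contour (centroid outside)."""


class NonUniformGridError(ValueError):
    """Time grid is not uniformly sampled at the stated interval."""


@dataclass(frozen=True)
class ContourFrame:
    """One time point's cell boundary and its radial profile.

    Attributes
    ----------
    time_min : float
        Frame time in minutes.
    boundary : (N, 2) ndarray
        Ordered closed polygon vertices (x, y) in micrometres.  The first
        vertex is not repeated at the end.
    centroid : (2,) ndarray
        Area centroid of the polygon, micrometres.
    theta_grid : (n_theta,) ndarray
        Uniform angles in radians covering [0, 2*pi).
    radial : (n_theta,) ndarray
        R(theta) in micrometres, aligned to ``theta_grid``.
    """

    time_min: float
    boundary: np.ndarray
    centroid: np.ndarray
    theta_grid: np.ndarray
    radial: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.radial)) or np.any(self.radial <= 0):
            raise ValueError("radial profile must be finite and strictly positive")


@dataclass(frozen=True)
class FourierModes:
    """Mode decomposition of a single radial profile.

    ``modes`` maps n -> C_n for n = 2..m_max.  ``c1`` is the first mode,
    kept only as a diagnostic of centroid placement (it should be ~0 when
    the profile is taken about the area centroid).
    """

    R0: float
    modes: Mapping[int, complex]
    c1: complex
    m_max: int


@dataclass
class ShapeModeSeries:
    """Time-indexed shape modes C_n(t) with optional smoothed derivatives.

    ``modes[n]`` holds the complex amplitude series of mode n (n >= 2) on
    the (uniform) ``times_min`` grid.  When derivatives have been computed,
    ``derivative_modes[n]`` holds dC_n/dt in um/h on ``deriv_times_min``,
    one sample shorter than the mode series (forward difference, aligned
    to the left sample).
    """

    times_min: np.ndarray
    R0: np.ndarray
    modes: dict[int, np.ndarray]
    m_max: int
    cell_id: str = "cell0"
    derivative_modes: dict[int, np.ndarray] = field(default_factory=dict)
    smoothed_modes: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def deriv_times_min(self) -> np.ndarray:
        return self.times_min[:-1]

    def differentiate(self, window: int = 3) -> "ShapeModeSeries":
        """Populate smoothed modes and forward-difference derivatives (um/h)."""
        for n, series in self.modes.items():
            sm, dv = smooth_and_differentiate(
                self.times_min, series, window=window
            )
            self.smoothed_modes[n] = sm
            self.derivative_modes[n] = dv
        return self


def _polygon_area_centroid(vertices: np.ndarray) -> tuple[float, np.ndarray]:
    """Signed area and area centroid of a simple polygon (shoelace)."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise DegeneratePolygonError("polygon needs >= 3 (x, y) vertices")
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * cross.sum()
    if abs(area) < 1e-12:
        raise DegeneratePolygonError("polygon area is zero (degenerate contour)")
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    return area, np.array([cx, cy])


def _ray_crossings(vertices: np.ndarray, origin: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Outermost positive ray-boundary crossing distance for each angle.

    Solves origin + t*(cos th, sin th) = p + s*(q - p) for every edge
    (s in [0, 1)) and keeps the largest positive t, which preserves
    protrusions when the contour is not star-convex about the centroid.
    """
    p = vertices
    q = np.roll(vertices, -1, axis=0)
    e = q - p  # (E, 2)
    d = np.stack([np.cos(theta), np.sin(theta)], axis=1)  # (A, 2)
    w = p - origin  # (E, 2)

    # 2x2 solve per (angle, edge): t*d - s*e = w
    denom = d[:, None, 0] * (-e[None, :, 1]) - d[:, None, 1] * (-e[None, :, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (w[None, :, 0] * (-e[None, :, 1]) - w[None, :, 1] * (-e[None, :, 0])) / denom
        s = (d[:, None, 0] * w[None, :, 1] - d[:, None, 1] * w[None, :, 0]) / denom
    # a ray through a shared vertex must not slip between the two edges
    eps = 1e-9
    valid = np.isfinite(t) & (t > 0) & (s >= -eps) & (s < 1 + eps)
    t = np.where(valid, t, -np.inf)
    r = t.max(axis=1)
    if np.any(~np.isfinite(r)):
        bad = int(np.argmax(~np.isfinite(r)))
        raise NonStarConvexError(
            f"no boundary crossing along theta={theta[bad]:.4f} rad; "
            "centroid lies outside the contour"
        )
    return r


def _circular_mean_filter(values: np.ndarray, halfwidth_samples: int) -> np.ndarray:
    """Mean over a symmetric circular window of +/- halfwidth samples."""
    if halfwidth_samples <= 0:
        return values.copy()
    k = 2 * halfwidth_samples + 1
    kernel = np.ones(k) / k
    padded = np.concatenate(
        [values[-halfwidth_samples:], values, values[:halfwidth_samples]]
    )
    return np.convolve(padded, kernel, mode="valid")


def radial_profile(
    boundary: np.ndarray,
    n_theta: int = 360,
    smooth_halfwidth: float = 6.0,
    time_min: float = 0.0,
) -> ContourFrame:
    """Radial profile R(theta) of a closed contour about its area centroid.

    Parameters
    ----------
    boundary : (N, 2) array
        Ordered vertices of a simple polygon, micrometres.
    n_theta : int
        Number of uniform angular samples over [0, 2*pi).
    smooth_halfwidth : float
        Half-width, in degrees, of the circular averaging window applied
        to R(theta) (each sample replaced by the mean over theta +/- this
        angle).  The default 6 degrees with the default 1-degree grid is a
        13-sample window.  Set to 0 to disable.
    time_min : float
        Frame time stamp carried through to the result.

    Returns
    -------
    ContourFrame

    Raises
    ------
    DegeneratePolygonError
        If the polygon has fewer than 3 vertices or zero area.
    NonStarConvexError
        If some ray from the centroid never crosses the boundary, i.e.
        the centroid is outside the contour.
    """
    v = np.asarray(boundary, dtype=float)
    _, centroid = _polygon_area_centroid(v)
    theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
    r = _ray_crossings(v, centroid, theta)
    if smooth_halfwidth > 0:
        step_deg = 360.0 / n_theta
        half = int(round(smooth_halfwidth / step_deg))
        r = _circular_mean_filter(r, half)
    return ContourFrame(
        time_min=float(time_min),
        boundary=v,
        centroid=centroid,
        theta_grid=theta,
        radial=r,
    )


def fourier_modes(frame: ContourFrame, m_max: int = 3) -> FourierModes:
    """Complex Fourier coefficients C_n of a radial profile.

    C_n = (1/n_theta) * sum_theta R(theta) e^{+i n theta}, so the profile
    is R0 + sum_n (C_n e^{-i n theta} + c.c.) and an order-n quantity
    transforms as C_n -> C_n e^{i n theta0} under a rotation by theta0.
    With this sign the phase arg(C_n)/n points along the direction of
    maximum deformation.  Mode 1 is computed as a diagnostic but excluded
    from the returned mode set (about the area centroid it nearly
    vanishes).

    Raises
    ------
    ValueError
        If ``m_max`` is at or beyond the Nyquist mode ``n_theta // 2``.
    """
    r = frame.radial
    n_theta = r.size
    if m_max >= n_theta / 2:
        raise ValueError(
            f"m_max={m_max} aliases on a {n_theta}-point grid (need m_max < n_theta/2)"
        )
    theta = frame.theta_grid
    R0 = float(r.mean())
    modes = {
        n: complex(np.mean(r * np.exp(1j * n * theta)))
        for n in range(2, m_max + 1)
    }
    c1 = complex(np.mean(r * np.exp(1j * theta)))
    return FourierModes(R0=R0, modes=modes, c1=c1, m_max=m_max)


def reconstruct_profile(
    R0: float,
    modes: Mapping[int, complex],
    theta_grid: np.ndarray,
    m_used: int | None = None,
) -> np.ndarray:
    """Evaluate the truncated Fourier series R0 + sum_n 2 Re(C_n e^{-i n theta})."""
    theta = np.asarray(theta_grid, dtype=float)
    r = np.full(theta.shape, float(R0))
    for n, c in modes.items():
        if m_used is not None and n > m_used:
            continue
        r += 2.0 * np.real(c * np.exp(-1j * n * theta))
    return r


def phase_decomposition(c_n: complex, n: int) -> tuple[float, float]:
    """Magnitude and deformation direction of a shape mode.

    With the convention C_n = |C_n| e^{i n phi_n}, the direction of
    maximum deformation is phi_n = arg(C_n)/n on the principal branch
    [0, 2*pi/n).  A vanishing mode has no defined direction: the phase is
    returned as NaN rather than an arbitrary angle.
    """
    if n < 2:
        raise ValueError("phase decomposition is defined for modes n >= 2")
    mag = abs(c_n)
    if mag == 0.0:
        return 0.0, float("nan")
    phi = (np.angle(c_n) % (2.0 * np.pi)) / n
    return float(mag), float(phi)


def smooth_and_differentiate(
    times_min: np.ndarray,
    values: np.ndarray,
    tau_min: float = 5.0,
    window: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Moving-average smoothing and forward-difference derivative.

    Applies a centered ``window``-point moving average (ends shrink the
    window symmetrically, so the first and last samples are copied for
    window 3) and then the forward difference

        d[k] = (s[k+1] - s[k]) / tau,

    with tau the sampling interval, converted to per-hour units.  The
    derivative series is one sample shorter and aligned to the left
    sample time.  Works elementwise on real or complex series.

    Raises
    ------
    NonUniformGridError
        If successive time stamps do not all differ by ``tau_min``.
    ValueError
        If the series is shorter than ``window + 1`` samples.
    """
    t = np.asarray(times_min, dtype=float)
    s = np.asarray(values)
    if s.shape[0] != t.shape[0]:
        raise ValueError("times and values must have the same length")
    if s.shape[0] < window + 1:
        raise ValueError(f"need at least {window + 1} samples, got {s.shape[0]}")
    gaps = np.diff(t)
    bad = np.nonzero(~np.isclose(gaps, tau_min, rtol=0, atol=1e-9))[0]
    if bad.size:
        k = int(bad[0])
        raise NonUniformGridError(
            f"non-uniform time grid: gap t[{k}]->t[{k + 1}] is {gaps[k]:g} min, "
            f"expected {tau_min:g} min"
        )
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be a positive odd integer")

    half = window // 2
    n = s.shape[0]
    smoothed = np.empty_like(s, dtype=complex if np.iscomplexobj(s) else float)
    for k in range(n):
        h = min(half, k, n - 1 - k)  # symmetric shrink at the ends
        smoothed[k] = s[k - h : k + h + 1].mean()
    tau_h = tau_min / 60.0
    deriv = (smoothed[1:] - smoothed[:-1]) / tau_h
    return smoothed, deriv


def mode_series_from_frames(
    frames: Sequence[ContourFrame],
    m_max: int = 3,
    cell_id: str = "cell0",
) -> ShapeModeSeries:
    """Decompose a contour movie into a time-indexed mode series."""
    if not frames:
        raise ValueError("no frames supplied")
    times = np.array([f.time_min for f in frames], dtype=float)
    decomps = [fourier_modes(f, m_max=m_max) for f in frames]
    modes = {
        n: np.array([d.modes[n] for d in decomps]) for n in range(2, m_max + 1)
    }
    R0 = np.array([d.R0 for d in decomps])
    return ShapeModeSeries(
        times_min=times, R0=R0, modes=modes, m_max=m_max, cell_id=cell_id
    )
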