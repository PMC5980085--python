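"""Synthetic contour movies and mode programs.

Fixture generators that emulate what the imaging pipeline would deliver:
a sequence of cell-boundary polygons whose radial profile follows a
prescribed program of Fourier modes (ramps, sinusoids, or a PRD
simulation) plus vertex-wise radial noise.  The generating ("ground
truth") mode series is always returned alongside, so recovery errors can
be computed without re-simulation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from prdcell.shape_modes import (
    ContourFrame,
    ShapeModeSeries,
    radial_profile,
    reconstruct_profile,
)

logger = logging.getLogger(__name__)

__all__ = ["ModeProgram", "ramp_program", "sinusoid_program", "generate_contour_movie",
           "smooth_random_modes", "track_positions_from_velocity"]


@dataclass
class ModeProgram:
    """Deterministic mode amplitudes as functions of time.

    ``mode_funcs`` maps n -> f(t_min) -> complex amplitude (um).  The
    program must keep R(theta) > 0 everywhere; this is validated frame by
    frame when the movie is generated.
    """

    duration_h: float
    sampling_min: float
    R0: float
    mode_funcs: Mapping[int, Callable[[float], complex]]
    contour_noise_sd: float = 0.0

    @property
    def times_min(self) -> np.ndarray:
        n = int(round(self.duration_h * 60.0 / self.sampling_min))
        return np.arange(n + 1) * self.sampling_min

    def modes_at(self, t_min: float) -> dict[int, complex]:
        return {n: complex(f(t_min)) for n, f in self.mode_funcs.items()}

    def truth_series(self, cell_id: str = "truth") -> ShapeModeSeries:
        t = self.times_min
        modes = {
            n: np.array([complex(f(tm)) for tm in t])
            for n, f in self.mode_funcs.items()
        }
        m_max = max(modes) if modes else 2
        return ShapeModeSeries(
            times_min=t,
            R0=np.full(t.shape, self.R0),
            modes=modes,
            m_max=m_max,
            cell_id=cell_id,
        )


def ramp_program(
    duration_h: float = 2.0,
    sampling_min: float = 5.0,
    R0: float = 20.0,
    c2_rate: float = 2.0,
    c3_const: complex = 1.0 + 0j,
    c2_phase: float = 0.0,
    contour_noise_sd: float = 0.0,
) -> ModeProgram:
    """Linearly growing elongation over a constant triangular mode
    (the single-pseudopod-extension prototype)."""
    return ModeProgram(
        duration_h=duration_h,
        sampling_min=sampling_min,
        R0=R0,
        mode_funcs={
            2: lambda t: (c2_rate * t / 60.0) * np.exp(1j * 2 * c2_phase),
            3: lambda t: complex(c3_const),
        },
        contour_noise_sd=contour_noise_sd,
    )


def sinusoid_program(
    duration_h: float = 4.0,
    sampling_min: float = 5.0,
    R0: float = 20.0,
    amplitudes: Mapping[int, float] | None = None,
    periods_min: Mapping[int, float] | None = None,
    phases: Mapping[int, float] | None = None,
    contour_noise_sd: float = 0.0,
) -> ModeProgram:
    """Band-limited oscillating mode program (default: modes 2 and 3)."""
    amplitudes = dict(amplitudes or {2: 1.5, 3: 0.8})
    periods_min = dict(periods_min or {2: 200.0, 3: 130.0})
    phases = dict(phases or {n: 0.3 * n for n in amplitudes})

    def make(n: int) -> Callable[[float], complex]:
        a, T, ph = amplitudes[n], periods_min[n], phases[n]
        return lambda t: a * np.exp(1j * (2 * np.pi * t / T + ph))

    return ModeProgram(
        duration_h=duration_h,
        sampling_min=sampling_min,
        R0=R0,
        mode_funcs={n: make(n) for n in amplitudes},
        contour_noise_sd=contour_noise_sd,
    )


def generate_contour_movie(
    program: ModeProgram,
    n_vertices: int = 240,
    rng: np.random.Generator | int | None = None,
    clip_negative: bool = False,
    max_resample: int = 10,
) -> tuple[list[ContourFrame], ShapeModeSeries]:
    """Render a mode program as a sequence of noisy boundary polygons.

    For each frame the radial profile is evaluated from the program,
    vertex-wise Gaussian radial noise of sd ``contour_noise_sd`` is
    added, and the polygon is re-analyzed with :func:`radial_profile`
    (area centroid, default smoothing) to produce a ContourFrame exactly
    as real segmented contours would be.  Noise draws that would make a
    radius nonpositive are resampled (or clipped, with a warning, when
    ``clip_negative``).

    Returns the frames and the ground-truth mode series.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    theta_v = 2.0 * np.pi * np.arange(n_vertices) / n_vertices
    frames: list[ContourFrame] = []
    for t_min in program.times_min:
        modes = program.modes_at(float(t_min))
        r = reconstruct_profile(program.R0, modes, theta_v)
        if np.any(r <= 0):
            raise ValueError(
                f"mode program produces nonpositive radius at t={t_min} min"
            )
        if program.contour_noise_sd > 0:
            noisy = r + program.contour_noise_sd * rng.standard_normal(n_vertices)
            tries = 0
            while np.any(noisy <= 0) and tries < max_resample and not clip_negative:
                bad = noisy <= 0
                noisy[bad] = r[bad] + program.contour_noise_sd * rng.standard_normal(
                    int(bad.sum())
                )
                tries += 1
            if np.any(noisy <= 0):
                warnings.warn("clipping nonpositive radii in contour noise")
                noisy = np.clip(noisy, 0.05 * program.R0, None)
            r = noisy
        poly = np.column_stack([r * np.cos(theta_v), r * np.sin(theta_v)])
        frames.append(radial_profile(poly, time_min=float(t_min)))
    return frames, program.truth_series()


def track_positions_from_velocity(
    v: np.ndarray, tau_min: float = 5.0, window: int = 3
) -> np.ndarray:
    """Raw positions whose smoothed series integrates a given velocity.

    The analysis pipeline smooths positions with a centered
    ``window``-point moving average before forward differencing.  To
    build a track whose *derived* velocity equals ``v`` exactly, the
    cumulative positions P (P[k+1] - P[k] = v[k] * tau) are mapped back
    through the inverse of the smoothing operator (a banded linear
    solve; the end rows are identities because the window shrinks
    symmetrically there).  Returns complex raw positions, one sample
    longer than ``v``.
    """
    v = np.asarray(v)
    tau_h = tau_min / 60.0
    P = np.concatenate([[0.0 + 0j], np.cumsum(v) * tau_h])
    n = P.size
    half = window // 2
    A = np.zeros((n, n))
    for k in range(n):
        h = min(half, k, n - 1 - k)
        A[k, k - h : k + h + 1] = 1.0 / (2 * h + 1)
    return np.linalg.solve(A, P)


def smooth_random_modes(
    n_samples: int = 500,
    sampling_min: float = 5.0,
    amplitude: float = 2.0,
    n_harmonics: int = 6,
    min_period_min: float = 60.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smooth random complex mode series as sums of sinusoids.

    Returns (times_min, C2, C3): each mode is a sum of ``n_harmonics``
    complex sinusoids with random phases and periods of at least
    ``min_period_min``, scaled so the rms amplitude is ``amplitude`` um.
    Useful as a well-conditioned regressor series for migration-law
    recovery experiments.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    t = np.arange(n_samples) * sampling_min

    def one() -> np.ndarray:
        s = np.zeros(n_samples, dtype=complex)
        span = t[-1] - t[0]
        for _ in range(n_harmonics):
            period = rng.uniform(min_period_min, max(2 * min_period_min, span / 2))
            phase = rng.uniform(0, 2 * np.pi)
            weight = rng.uniform(0.5, 1.0)
            sign = rng.choice([-1.0, 1.0])
            s += weight * np.exp(1j * (sign * 2 * np.pi * t / period + phase))
        rms = np.sqrt(np.mean(np.abs(s) ** 2))
        return amplitude * s / rms

    return t, one(), one()
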