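"""Deformation-based migration law and its estimation.

The centroid velocity, written as the complex number v1 = v_x + i v_y, is
modeled as a bilinear coupling of the elongation mode C2 and triangular
mode C3 with their time derivatives:

    v1 = beta1 * conj(dC2/dt) * C3 - beta2 * conj(C2) * dC3/dt,

which is rotationally equivariant (rotating the cell by theta0 rotates v1
by theta0) and time-reverse symmetric: running a shape trajectory
backwards exactly negates the predicted velocity, so contraction retraces
extension.  A shape-determined term beta_c * conj(C2) * C3 (the
keratocyte-type law, where a steady shape sustains steady motion) can be
added to form the general law.

The mobilities beta1, beta2 (1/um) are estimated by linear least squares
on the stacked real and imaginary parts of observed velocities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from prdcell.shape_modes import reconstruct_profile

logger = logging.getLogger(__name__)

__all__ = [
    "MobilityEstimate",
    "predict_velocity",
    "predict_velocity_general",
    "fit_mobility",
    "phase_joint_distribution",
    "binned_velocity_agreement",
    "archetype_motion",
    "ArchetypeResult",
]


def predict_velocity(C2, C3, dC2, dC3, beta1: float, beta2: float):
    """Velocity predicted by the deformation-based law (elementwise).

    v1 = beta1 * conj(dC2) * C3 - beta2 * conj(C2) * dC3.
    Amplitudes in um, derivatives in um/h, betas in 1/um -> um/h.
    """
    return beta1 * np.conj(dC2) * C3 - beta2 * np.conj(C2) * dC3


def predict_velocity_general(C2, C3, dC2, dC3, beta1, beta2, betac):
    """General migration law: the deformation law plus the shape-determined
    term betac * conj(C2) * C3.

    betac = 0 recovers the deformation law exactly; beta1 = beta2 = 0
    gives the keratocyte-type law where a constant shape sustains motion.
    """
    return predict_velocity(C2, C3, dC2, dC3, beta1, beta2) + betac * np.conj(C2) * C3


@dataclass(frozen=True)
class MobilityEstimate:
    """Least-squares mobility estimate.

    ``ci95`` holds 95% confidence half-widths in the same order as the
    coefficients (beta1, beta2[, betac]).  ``residual_S`` is
    S = sum |V - v|^2 over samples (um^2 h^-2).
    """

    beta1: float
    beta2: float
    betac: float | None
    ci95: tuple[float, ...]
    residual_S: float
    n_obs: int

    @property
    def coefficients(self) -> tuple[float, ...]:
        if self.betac is None:
            return (self.beta1, self.beta2)
        return (self.beta1, self.beta2, self.betac)


def _stack_real(*cols: np.ndarray) -> np.ndarray:
    """Stack complex regressor columns into a real design matrix."""
    return np.column_stack(
        [np.concatenate([np.real(c), np.imag(c)]) for c in cols]
    )


def fit_mobility(
    v_obs: np.ndarray,
    C2: np.ndarray,
    C3: np.ndarray,
    dC2: np.ndarray,
    dC3: np.ndarray,
    include_general: bool = False,
) -> MobilityEstimate:
    """Fit the migration-law mobilities by linear least squares.

    Minimizes S = sum |V - v1(beta)|^2 over the pooled samples by solving
    the normal equations of the real system obtained by stacking real and
    imaginary parts (2n equations, k coefficients).  95% confidence
    half-widths come from the usual linear-model covariance with residual
    variance S / (2n - k).

    Samples where every regressor vanishes carry no information and are
    dropped (logged at DEBUG level).

    Raises
    ------
    ValueError
        On fewer than 3 usable samples or a singular normal matrix
        (collinear or all-zero regressors).
    """
    v_obs, C2, C3, dC2, dC3 = map(np.asarray, (v_obs, C2, C3, dC2, dC3))
    r1 = np.conj(dC2) * C3
    r2 = -np.conj(C2) * dC3
    regs = [r1, r2]
    if include_general:
        regs.append(np.conj(C2) * C3)

    keep = np.zeros(v_obs.shape, dtype=bool)
    for r in regs:
        keep |= np.abs(r) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.debug("fit_mobility: dropped %d zero-regressor samples", n_dropped)
    if keep.sum() < 3:
        raise ValueError("need at least 3 samples with non-vanishing regressors")

    X = _stack_real(*(r[keep] for r in regs))
    y = np.concatenate([np.real(v_obs[keep]), np.imag(v_obs[keep])])
    k = X.shape[1]

    xtx = X.T @ X
    if np.linalg.cond(xtx) > 1e12:
        raise ValueError("rank-deficient normal matrix: regressors collinear or zero")
    coef = np.linalg.solve(xtx, X.T @ y)

    resid = y - X @ coef
    S = float(resid @ resid)
    dof = y.size - k
    sigma2 = S / dof if dof > 0 else np.nan
    cov = sigma2 * np.linalg.inv(xtx)
    tcrit = stats.t.ppf(0.975, dof) if dof > 0 else np.nan
    ci = tuple(float(tcrit * np.sqrt(cov[i, i])) for i in range(k))

    return MobilityEstimate(
        beta1=float(coef[0]),
        beta2=float(coef[1]),
        betac=float(coef[2]) if include_general else None,
        ci95=ci,
        residual_S=S,
        n_obs=int(keep.sum()),
    )


@dataclass(frozen=True)
class PhaseJointDistribution:
    """Normalized joint histogram over (arg a, arg b) with circular stats."""

    edges: np.ndarray          # shared bin edges on [-pi, pi]
    table: np.ndarray          # (n_bins, n_bins), sums to 1
    mean_resultant: float      # |<exp i(arg a - arg b)>|
    mean_phase_diff: float     # arg <exp i(arg a - arg b)>, radians


def phase_joint_distribution(
    a: np.ndarray,
    b: np.ndarray,
    n_bins: int = 24,
    mag_floor: float = 0.0,
) -> PhaseJointDistribution:
    """Joint probability table of the phases of two complex series.

    When the law holds, arg(v1) concentrates on the diagonal against
    arg(conj(dC2) C3).  The mean resultant length of the phase difference
    summarizes how tight that alignment is (1 = perfectly locked,
    0 = independent phases).

    Samples with |a| or |b| at or below ``mag_floor`` are excluded (their
    phases are meaningless near zero magnitude).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.size == 0 or a.shape != b.shape:
        raise ValueError("need two nonempty aligned complex series")
    keep = (np.abs(a) > mag_floor) & (np.abs(b) > mag_floor)
    if not keep.any():
        raise ValueError("no samples above the magnitude floor")
    pa = np.angle(a[keep])
    pb = np.angle(b[keep])
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    table, _, _ = np.histogram2d(pa, pb, bins=[edges, edges])
    table /= table.sum()
    z = np.mean(np.exp(1j * (pa - pb)))
    return PhaseJointDistribution(
        edges=edges,
        table=table,
        mean_resultant=float(np.abs(z)),
        mean_phase_diff=float(np.angle(z)),
    )


def binned_velocity_agreement(
    v_pred: np.ndarray,
    v_obs: np.ndarray,
    gamma: float = 12.0,
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Observed velocity averaged in bins of the predicted velocity.

    Each Cartesian component j of the predicted velocity is binned into
    intervals |v_j - gamma*m| <= gamma/2 (width gamma, centered on integer
    multiples m*gamma, default gamma = 12 um/h); within each non-empty bin
    the mean, standard deviation and count of the observed component are
    reported.  When the law captures the data, the per-bin means lie on
    the identity line.

    Returns the per-bin table and, per component, the central 99% range
    of the predicted values.
    """
    v_pred = np.asarray(v_pred)
    v_obs = np.asarray(v_obs)
    rows = []
    ranges: dict[str, tuple[float, float]] = {}
    for comp, (p, o) in {
        "x": (np.real(v_pred), np.real(v_obs)),
        "y": (np.imag(v_pred), np.imag(v_obs)),
    }.items():
        idx = np.round(p / gamma).astype(int)
        for m in np.unique(idx):
            sel = idx == m
            rows.append(
                {
                    "component": comp,
                    "bin_center": m * gamma,
                    "mean_obs": float(o[sel].mean()),
                    "sd_obs": float(o[sel].std(ddof=0)),
                    "count": int(sel.sum()),
                }
            )
        lo, hi = np.percentile(p, [0.5, 99.5])
        ranges[comp] = (float(lo), float(hi))
    return pd.DataFrame(rows), ranges


@dataclass(frozen=True)
class ArchetypeResult:
    times_h: np.ndarray
    C2: np.ndarray
    C3: np.ndarray
    velocity: np.ndarray
    displacement: complex
    initial_profile: np.ndarray
    final_profile: np.ndarray
    theta_grid: np.ndarray


_ARCHETYPES = {
    # case -> (phase of C2, phase of C3, which mode ramps dominantly)
    "elongation": (0.0, 0.0, 2),
    "bipolar": (0.0, np.pi, 3),
    "repolarize": (np.pi, 0.0, 3),
}


def archetype_motion(
    case: str,
    beta1: float,
    beta2: float,
    ramp_rate: float = 2.0,
    base_amplitude: float = 1.0,
    duration_h: float = 1.0,
    n_steps: int = 400,
    R0: float = 20.0,
    n_theta: int = 180,
    reverse: bool = False,
) -> ArchetypeResult:
    """Prototype motions produced by the migration law under amplitude ramps.

    Three stylized deformation programs, all with fixed phases:

    - ``elongation``: arg C2 = arg C3 = 0 and |dC2| >> |dC3| -- one of
      three pseudopodia extends and the centroid moves toward it (+x).
    - ``bipolar``: arg C2 = 0, arg C3 = pi with |dC3| >> |dC2| -- two
      pseudopodia (lamellipodia) extend.
    - ``repolarize``: arg C2 = pi, arg C3 = 0 with |dC3| >> |dC2| -- an
      already-elongated cell grows a new pseudopod.

    The ramping mode grows linearly at ``ramp_rate`` (um/h) from
    ``base_amplitude``; the other mode stays at ``base_amplitude``.  The
    law is integrated over the ramp (trapezoid on a dense grid; the
    integrand is polynomial in t so this is effectively exact).  With
    ``reverse=True`` the ramp runs backwards; time-reverse symmetry makes
    the displacement exactly negate.
    """
    if case not in _ARCHETYPES:
        raise ValueError(f"unknown archetype {case!r}; choose from {sorted(_ARCHETYPES)}")
    ph2, ph3, ramping = _ARCHETYPES[case]
    t = np.linspace(0.0, duration_h, n_steps + 1)
    amp_ramp = base_amplitude + ramp_rate * t
    amp_flat = np.full_like(t, base_amplitude)
    if ramping == 2:
        a2, a3 = amp_ramp, amp_flat
        d2, d3 = np.full_like(t, ramp_rate), np.zeros_like(t)
    else:
        a2, a3 = amp_flat, amp_ramp
        d2, d3 = np.zeros_like(t), np.full_like(t, ramp_rate)
    if reverse:
        a2, a3, d2, d3 = a2[::-1], a3[::-1], -d2[::-1], -d3[::-1]
    C2 = a2 * np.exp(1j * ph2)
    C3 = a3 * np.exp(1j * ph3)
    dC2 = d2 * np.exp(1j * ph2)
    dC3 = d3 * np.exp(1j * ph3)
    v = predict_velocity(C2, C3, dC2, dC3, beta1, beta2)
    disp = complex(np.trapezoid(v, t))

    theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
    prof0 = reconstruct_profile(R0, {2: C2[0], 3: C3[0]}, theta)
    prof1 = reconstruct_profile(R0, {2: C2[-1], 3: C3[-1]}, theta)
    return ArchetypeResult(
        times_h=t,
        C2=C2,
        C3=C3,
        velocity=v,
        displacement=disp,
        initial_profile=prof0,
        final_profile=prof1,
        theta_grid=theta,
    )
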