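"""Trajectory and shape statistics for cell tracks.

Implements the summary statistics used to characterize crawling:
time-averaged mean squared displacement (MSD) and its log-log exponent,
ensemble autocorrelation functions, symmetrized component PDFs, the
short-lag velocity-correlation series CV(t), segmentation of tracks into
persistent intervals (CV above 2/3 of its per-track median), persistent
lengths and their complementary cumulative distribution, and rotation
angles between successive persistent segments (a peak at 180 degrees
signals back-and-forth motion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from prdcell.shape_modes import smooth_and_differentiate

logger = logging.getLogger(__name__)

__all__ = [
    "CellTrack",
    "PersistenceSegments",
    "Segment",
    "filter_tracks",
    "msd",
    "msd_exponent",
    "autocorr",
    "pdf_symmetrized",
    "velocity_correlation_series",
    "persistent_segments",
    "rotation_angles",
    "rotation_angle_histogram",
    "ccdf",
]

SAMPLE_INTERVAL_MIN = 5.0


@dataclass
class CellTrack:
    """A single cell's centroid track on a uniform 5-min grid.

    ``x``/``y`` are the observed positions in micrometres.  Velocities are
    derived lazily with the standard pipeline: 3-point centered moving
    average of the positions followed by a forward difference over the
    sampling interval, in um/h.
    """

    cell_id: str
    times_min: np.ndarray
    x: np.ndarray
    y: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def positions(self) -> np.ndarray:
        """Complex positions x + i y (um)."""
        return self.x + 1j * self.y

    @property
    def duration_h(self) -> float:
        return float((self.times_min[-1] - self.times_min[0]) / 60.0)

    @property
    def sample_interval_min(self) -> float:
        return float(self.times_min[1] - self.times_min[0])

    def smoothed_positions(self, window: int = 3) -> np.ndarray:
        key = ("smooth", window)
        if key not in self._cache:
            sm, dv = smooth_and_differentiate(
                self.times_min, self.positions, tau_min=self.sample_interval_min,
                window=window,
            )
            self._cache[key] = sm
            self._cache[("vel", window)] = dv
        return self._cache[key]

    def velocity(self, window: int = 3) -> np.ndarray:
        """Complex velocity series (um/h), one sample shorter than the track."""
        self.smoothed_positions(window)
        return self._cache[("vel", window)]


def filter_tracks(
    tracks: Sequence[CellTrack], min_hours: float = 8.3
) -> list[CellTrack]:
    """Drop tracks observed for less than ``min_hours`` (logged)."""
    kept = []
    for tr in tracks:
        if tr.duration_h >= min_hours:
            kept.append(tr)
        else:
            logger.info(
                "excluding track %s: duration %.2f h < %.2f h",
                tr.cell_id, tr.duration_h, min_hours,
            )
    return kept


def msd(
    tracks: Sequence[CellTrack],
    max_lag_min: float,
    smoothed: bool = True,
) -> pd.DataFrame:
    """Time-averaged, then ensemble-averaged mean squared displacement.

    For each track the MSD at lag k is averaged over all start points;
    tracks are then combined with equal weight at each lag (tracks
    shorter than the lag simply do not contribute there).  Lags are on
    the track sampling grid.  ``smoothed`` uses the 3-point-averaged
    positions, matching the velocity pipeline.

    Returns a DataFrame with columns ``lag_min``, ``msd``, ``n_pairs``
    (total displacement pairs entering the lag) and ``n_tracks``.
    """
    if not tracks:
        raise ValueError("no tracks supplied")
    dt = tracks[0].sample_interval_min
    n_lags = int(round(max_lag_min / dt))
    if not any(tr.times_min.size > n_lags for tr in tracks):
        raise ValueError(f"max_lag {max_lag_min} min exceeds every track duration")
    per_lag: list[list[float]] = [[] for _ in range(n_lags)]
    pairs = np.zeros(n_lags, dtype=int)
    for tr in tracks:
        p = tr.smoothed_positions() if smoothed else tr.positions
        n = p.size
        for k in range(1, min(n_lags, n - 1) + 1):
            d = p[k:] - p[:-k]
            per_lag[k - 1].append(float(np.mean(np.abs(d) ** 2)))
            pairs[k - 1] += d.size
    rows = []
    for k in range(n_lags):
        if per_lag[k]:
            rows.append(
                {
                    "lag_min": (k + 1) * dt,
                    "msd": float(np.mean(per_lag[k])),
                    "n_pairs": int(pairs[k]),
                    "n_tracks": len(per_lag[k]),
                }
            )
    return pd.DataFrame(rows)


def msd_exponent(
    msd_table: pd.DataFrame, lag_window: tuple[float, float] = (10.0, 60.0)
) -> float:
    """Least-squares log-log slope of the MSD inside a lag window (minutes).

    Slope 2 is ballistic, 1 diffusive; crawling cells typically sit in
    between at short lags (superdiffusive persistent motion).
    """
    lo, hi = lag_window
    sel = (msd_table["lag_min"] >= lo) & (msd_table["lag_min"] <= hi)
    sub = msd_table[sel]
    if len(sub) < 3:
        raise ValueError("need at least 3 lags inside the window")
    if (sub["msd"] <= 0).any():
        raise ValueError("nonpositive MSD values in the fitting window")
    slope, _ = np.polyfit(np.log(sub["lag_min"]), np.log(sub["msd"]), 1)
    return float(slope)


def autocorr(series_list: Sequence[np.ndarray], max_lag: int) -> np.ndarray:
    """Ensemble-averaged normalized autocorrelation function.

    Per series: subtract the mean, compute
    ACF(k) = Re<a(t+k) conj(a(t))> / <|a|^2>, then average the per-series
    ACFs with equal weight.  Works for complex series (velocity, modes)
    and real series (speeds).  Lag 0 is included and equals 1.

    Raises
    ------
    ValueError
        If every series is constant (zero variance).
    """
    acfs = []
    for s in series_list:
        a = np.asarray(s)
        a = a - a.mean()
        var = np.mean(np.abs(a) ** 2)
        if var <= 0:
            continue
        n = a.size
        row = np.full(max_lag + 1, np.nan)
        for k in range(min(max_lag, n - 1) + 1):
            row[k] = float(np.mean(np.real(a[k:] * np.conj(a[: n - k])))) / var
        acfs.append(row)
    if not acfs:
        raise ValueError("all series are constant: autocorrelation undefined")
    return np.nanmean(np.vstack(acfs), axis=0)


def pdf_symmetrized(
    series: np.ndarray, bins: int | np.ndarray = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled density of the real and imaginary parts of a complex series.

    By spatial isotropy both Cartesian components follow the same
    distribution, so the PDF is estimated from the pooled components on
    bin edges symmetric about zero.  Returns (bin_centers, density).
    """
    s = np.asarray(series)
    if s.size == 0:
        raise ValueError("empty series")
    pooled = np.concatenate([np.real(s), np.imag(s)])
    if isinstance(bins, (int, np.integer)):
        m = float(np.max(np.abs(pooled))) or 1.0
        edges = np.linspace(-m, m, int(bins) + 1)
    else:
        edges = np.asarray(bins)
    density, edges = np.histogram(pooled, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, density


def velocity_correlation_series(
    track: CellTrack, dt_min: float = 10.0, window: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Short-lag velocity correlation CV(t) = v(t + dt) . v(t).

    CV is small both when the cell stalls and when it turns sharply, so
    thresholding CV isolates persistent motion.  ``dt_min`` must be a
    multiple of the sampling interval.  Returns (times_min, CV) with CV
    in um^2/h^2.
    """
    v = track.velocity(window)
    step = dt_min / track.sample_interval_min
    if abs(step - round(step)) > 1e-9:
        raise ValueError("dt must be a multiple of the sampling interval")
    k = int(round(step))
    if v.size <= k:
        raise ValueError("track too short for the requested correlation lag")
    cv = np.real(v[k:] * np.conj(v[:-k]))
    return track.times_min[: cv.size], cv


@dataclass(frozen=True)
class Segment:
    """One maximal persistent interval of a track.

    Indices refer to the velocity sample grid; ``path_length_um`` is the
    summed step length of the (smoothed) positions across the interval
    and ``net_displacement`` the complex end-to-end vector.
    """

    start: int
    end: int  # inclusive, in CV-sample indices
    path_length_um: float
    net_displacement: complex


@dataclass
class PersistenceSegments:
    cell_id: str
    segments: list[Segment]
    cv_times_min: np.ndarray
    cv: np.ndarray
    median_cv: float
    threshold: float


def persistent_segments(
    track: CellTrack,
    dt_min: float = 10.0,
    threshold_fraction: float = 2.0 / 3.0,
    window: int = 3,
) -> PersistenceSegments:
    """Segment a track into maximal persistent intervals.

    A sample is persistent when CV(t) exceeds ``threshold_fraction``
    times the per-track median of CV(t).  Maximal runs of persistent
    samples form segments; each segment's persistent length is the path
    length of the smoothed trajectory across it.
    """
    times, cv = velocity_correlation_series(track, dt_min, window)
    med = float(np.median(cv))
    thr = threshold_fraction * med
    mask = cv > thr
    pos = track.smoothed_positions(window)
    lag = int(round(dt_min / track.sample_interval_min))

    # CV(t) certifies the stretch covered by v(t) and v(t + dt), i.e.
    # position samples t .. t + dt + tau; spanning the full stretch makes
    # the segmentation exactly covariant under time reversal of the track
    segments: list[Segment] = []
    i = 0
    n = mask.size
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and mask[j + 1]:
            j += 1
        stop = j + 1 + lag  # last position index covered by the run
        steps = pos[i + 1 : stop + 1] - pos[i:stop]
        segments.append(
            Segment(
                start=i,
                end=j,
                path_length_um=float(np.sum(np.abs(steps))),
                net_displacement=complex(pos[stop] - pos[i]),
            )
        )
        i = j + 1
    return PersistenceSegments(
        cell_id=track.cell_id,
        segments=segments,
        cv_times_min=times,
        cv=cv,
        median_cv=med,
        threshold=thr,
    )


def rotation_angles(seg: PersistenceSegments) -> np.ndarray:
    """Rotation angles between successive persistent segments, degrees.

    The angle between the net-displacement vectors of consecutive
    segments, reported in [0, 360): 0 continues straight, 180 is a full
    reversal.  Pairs involving a zero net displacement are skipped.
    """
    out = []
    for s1, s2 in zip(seg.segments[:-1], seg.segments[1:]):
        d1, d2 = s1.net_displacement, s2.net_displacement
        if abs(d1) == 0 or abs(d2) == 0:
            logger.info("skipping zero-displacement segment pair in %s", seg.cell_id)
            continue
        ang = np.degrees(np.angle(d2 * np.conj(d1))) % 360.0
        out.append(float(ang))
    return np.array(out)


def rotation_angle_histogram(
    angles_deg: np.ndarray, bin_width: float = 20.0
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of rotation angles in bins centered on multiples of the width.

    Bins are circular and centered at 0, bin_width, 2*bin_width, ...
    (so a reversal falls in the bin centered exactly at 180 degrees).
    Returns (bin_centers_deg, counts).
    """
    a = np.asarray(angles_deg, dtype=float) % 360.0
    n_bins = int(round(360.0 / bin_width))
    idx = np.floor(((a + bin_width / 2.0) % 360.0) / bin_width).astype(int)
    counts = np.bincount(idx, minlength=n_bins)[:n_bins]
    centers = np.arange(n_bins) * bin_width
    return centers, counts


def ccdf(values: np.ndarray) -> pd.DataFrame:
    """Empirical complementary cumulative distribution P(X > x).

    Tabulated at the sorted sample points; immediately below the minimum
    the CCDF is 1 and at the maximum it is 0.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if x.size == 0:
        raise ValueError("empty sample")
    n = x.size
    p = 1.0 - np.arange(1, n + 1) / n
    return pd.DataFrame({"value": x, "ccdf": p})
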