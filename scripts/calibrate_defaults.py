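#!/usr/bin/env python
"""Qualitative calibration report for the simulator's shared coefficients.

The substrate presets carry the published mobilities, relaxation rates
and noise amplitudes; the remaining coupling coefficients (alpha_v,
gamma_v, alpha2, alpha3, gamma3, beta3, kappa_f, sigma6) ship as
package defaults chosen so that a simulated soft-gel ensemble shows the
qualitative signatures of fibroblast crawling:

  - mean speed in the tens of um/h,
  - velocity decorrelating faster than C3, which decorrelates faster
    than C2 (shape outlives velocity),
  - heavier-than-Gaussian velocity components (excess kurtosis > 0),
  - modal rotation angle between persistent segments at 180 degrees,
  - superdiffusive short-lag MSD (log-log slope 1.6-1.7 over 10-60 min).

This script recomputes those metrics at the shipped defaults (and, with
--scan, on a multiplicative grid around them) so the calibration can be
audited or redone after a model change.

Usage:  python scripts/calibrate_defaults.py [--seed 1] [--cells 100] [--scan kappa_f]
"""

from __future__ import annotations

import argparse

import numpy as np
from scipy import stats as sstats

from prdcell import prd_sim, track_stats


def metrics(params, n_cells: int, seed: int) -> dict:
    cfg = prd_sim.SimConfig(duration_h=16.0, n_cells=n_cells, seed=seed)
    ensemble = prd_sim.simulate_ensemble(params, cfg)
    tracks = [t for t, _ in ensemble]
    series = [s for _, s in ensemble]

    v = np.concatenate([t.velocity() for t in tracks])
    comp = np.concatenate([np.real(v), np.imag(v)])
    msd_table = track_stats.msd(tracks, max_lag_min=240.0)

    angles: list[float] = []
    for t in tracks:
        seg = track_stats.persistent_segments(t)
        angles.extend(track_stats.rotation_angles(seg))
    centers, counts = track_stats.rotation_angle_histogram(np.array(angles))

    def efold_minutes(acf):
        below = acf < np.exp(-1)
        return float(np.argmax(below) * 5.0) if below.any() else float("inf")

    return {
        "mean_speed_um_h": float(np.mean(np.abs(v))),
        "velocity_excess_kurtosis": float(sstats.kurtosis(comp)),
        "msd_exponent_10_60min": float(track_stats.msd_exponent(msd_table)),
        "modal_rotation_angle_deg": float(centers[int(np.argmax(counts))]),
        "reversal_bin_enrichment": float(counts[9] / counts.mean()),
        "acf_efold_min_v": efold_minutes(
            track_stats.autocorr([t.velocity() for t in tracks], 36)),
        "acf_efold_min_c2": efold_minutes(
            track_stats.autocorr([s.smoothed_modes[2] for s in series], 36)),
        "acf_efold_min_c3": efold_minutes(
            track_stats.autocorr([s.smoothed_modes[3] for s in series], 36)),
    }


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--cells", type=int, default=100)
    ap.add_argument("--preset", default="table2_35kPa",
                    choices=sorted(prd_sim.PRESETS))
    ap.add_argument("--scan", default=None,
                    help="coefficient name to scan at x0.5 / x1 / x2")
    args = ap.parse_args()

    base = prd_sim.preset(args.preset)
    variants = [("defaults", base)]
    if args.scan:
        for factor in (0.5, 2.0):
            value = getattr(base, args.scan) * factor
            variants.append((f"{args.scan} x{factor:g}",
                             base.replace(**{args.scan: value})))

    for label, params in variants:
        print(f"--- {args.preset} [{label}] ---")
        try:
            for key, val in metrics(params, args.cells, args.seed).items():
                print(f"  {key}: {val:.3f}")
        except Exception as exc:  # a scan point may be unstable
            print(f"  failed: {exc}")


if __name__ == "__main__":
    main()
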