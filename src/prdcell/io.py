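"""File formats: versioned CSV tables, parameter files, manifests.

All tables are plain CSV with a single versioned header comment line

    # prdcell schema=<name> version=<int>

followed by a normal column header.  Units are carried in the column
names (``x_um``, ``time_min``, ...).  Angles are stored in degrees in
files and converted to radians in memory.  Readers validate required
columns and report offending files/lines; unknown extra columns are
preserved in the returned frames.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from prdcell._version import SCHEMA_VERSION, __version__
from prdcell.prd_sim import PRDParams, SimConfig
from prdcell.shape_modes import ContourFrame, NonUniformGridError, ShapeModeSeries
from prdcell.track_stats import CellTrack

__all__ = [
    "SchemaError",
    "write_tracks_csv", "read_tracks_csv",
    "write_modes_csv", "read_modes_csv",
    "write_contours_csv", "read_contours_csv",
    "write_radial_csv", "read_radial_csv",
    "write_params_yaml", "read_params_yaml",
    "write_fit_result_json", "write_manifest",
]


class SchemaError(ValueError):
    """A file does not conform to its declared schema."""


def _header(schema: str) -> str:
    return f"# prdcell schema={schema} version={SCHEMA_VERSION}\n"


def _write_table(df: pd.DataFrame, path: Path | str, schema: str) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(schema))
        df.to_csv(fh, index=False)


def _read_table(path: Path | str, schema: str, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# prdcell schema="):
            raise SchemaError(f"{path}: line 1: missing versioned schema header")
        declared = first.split("schema=")[1].split()[0]
        if declared != schema:
            raise SchemaError(
                f"{path}: line 1: schema is {declared!r}, expected {schema!r}"
            )
        try:
            df = pd.read_csv(fh)
        except (pd.errors.ParserError, ValueError) as exc:
            raise SchemaError(f"{path}: malformed CSV: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col in required:
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0]) + 3  # header + column line
            raise SchemaError(f"{path}: line {row}: missing value in column {col!r}")
    return df


# ---------------------------------------------------------------- tracks

def write_tracks_csv(tracks: Sequence[CellTrack], path: Path | str) -> None:
    rows = [
        pd.DataFrame(
            {"cell_id": tr.cell_id, "time_min": tr.times_min, "x_um": tr.x, "y_um": tr.y}
        )
        for tr in tracks
    ]
    _write_table(pd.concat(rows, ignore_index=True), path, "tracks")


def read_tracks_csv(
    path: Path | str, expected_interval_min: float = 5.0
) -> list[CellTrack]:
    df = _read_table(path, "tracks", ["cell_id", "time_min", "x_um", "y_um"])
    tracks = []
    for cell_id, g in df.groupby("cell_id", sort=False):
        t = g["time_min"].to_numpy(dtype=float)
        gaps = np.diff(t)
        bad = np.nonzero(~np.isclose(gaps, expected_interval_min, atol=1e-9))[0]
        if bad.size:
            k = int(bad[0])
            raise NonUniformGridError(
                f"{path}: cell {cell_id}: gap t[{k}]->t[{k + 1}] is {gaps[k]:g} min, "
                f"expected {expected_interval_min:g} min"
            )
        tracks.append(
            CellTrack(
                cell_id=str(cell_id),
                times_min=t,
                x=g["x_um"].to_numpy(dtype=float),
                y=g["y_um"].to_numpy(dtype=float),
            )
        )
    return tracks


# ----------------------------------------------------------------- modes

def write_modes_csv(series_list: Sequence[ShapeModeSeries], path: Path | str) -> None:
    frames = []
    for s in series_list:
        data = {"cell_id": s.cell_id, "time_min": s.times_min, "R0_um": s.R0}
        for n in sorted(s.modes):
            data[f"re_c{n}"] = np.real(s.modes[n])
            data[f"im_c{n}"] = np.imag(s.modes[n])
        frames.append(pd.DataFrame(data))
    _write_table(pd.concat(frames, ignore_index=True), path, "modes")


def read_modes_csv(path: Path | str) -> list[ShapeModeSeries]:
    df = _read_table(path, "modes", ["cell_id", "time_min", "R0_um"])
    mode_ns = sorted(
        int(c[4:]) for c in df.columns if c.startswith("re_c") and c[4:].isdigit()
    )
    if not mode_ns:
        raise SchemaError(f"{path}: no mode columns (re_cN/im_cN) found")
    out = []
    for cell_id, g in df.groupby("cell_id", sort=False):
        modes = {}
        for n in mode_ns:
            if f"im_c{n}" not in g.columns:
                raise SchemaError(f"{path}: column im_c{n} missing for re_c{n}")
            modes[n] = g[f"re_c{n}"].to_numpy(float) + 1j * g[f"im_c{n}"].to_numpy(float)
        out.append(
            ShapeModeSeries(
                times_min=g["time_min"].to_numpy(float),
                R0=g["R0_um"].to_numpy(float),
                modes=modes,
                m_max=max(mode_ns),
                cell_id=str(cell_id),
            )
        )
    return out


# -------------------------------------------------------------- contours

def write_contours_csv(
    frames: Sequence[ContourFrame], path: Path | str, cell_id: str = "cell0"
) -> None:
    rows = []
    for i, f in enumerate(frames):
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": cell_id,
                    "frame": i,
                    "time_min": f.time_min,
                    "vertex_index": np.arange(f.boundary.shape[0]),
                    "x_um": f.boundary[:, 0],
                    "y_um": f.boundary[:, 1],
                }
            )
        )
    _write_table(pd.concat(rows, ignore_index=True), path, "contours")


def read_contours_csv(path: Path | str) -> dict[str, dict[str, list]]:
    """Read polygon movies.

    Returns ``{cell_id: {"polygons": [(N, 2) arrays], "times_min": [...]}}``;
    analysis re-derives centroids and radial profiles from the raw
    polygons.
    """
    df = _read_table(
        path, "contours",
        ["cell_id", "frame", "time_min", "vertex_index", "x_um", "y_um"],
    )
    movies: dict[str, dict[str, list]] = {}
    for (cell_id, _), g in df.groupby(["cell_id", "frame"], sort=True):
        g = g.sort_values("vertex_index")
        entry = movies.setdefault(str(cell_id), {"polygons": [], "times_min": []})
        entry["polygons"].append(g[["x_um", "y_um"]].to_numpy(dtype=float))
        entry["times_min"].append(float(g["time_min"].iloc[0]))
    return movies


# ---------------------------------------------------------------- radial

def write_radial_csv(
    frames: Sequence[ContourFrame], path: Path | str, cell_id: str = "cell0"
) -> None:
    rows = [
        pd.DataFrame(
            {
                "cell_id": cell_id,
                "time_min": f.time_min,
                "theta_deg": np.degrees(f.theta_grid),
                "r_um": f.radial,
            }
        )
        for f in frames
    ]
    _write_table(pd.concat(rows, ignore_index=True), path, "radial")


def read_radial_csv(path: Path | str) -> pd.DataFrame:
    df = _read_table(path, "radial", ["cell_id", "time_min", "theta_deg", "r_um"])
    df["theta_rad"] = np.radians(df["theta_deg"])
    return df


# ---------------------------------------------------------------- config

def write_params_yaml(
    path: Path | str, params: PRDParams, config: SimConfig | None = None
) -> None:
    doc = {"prdcell_version": __version__, "schema_version": SCHEMA_VERSION,
           "params": dataclasses.asdict(params)}
    if config is not None:
        doc["config"] = dataclasses.asdict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_params_yaml(path: Path | str) -> tuple[PRDParams, SimConfig | None]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "params" not in doc:
        raise SchemaError(f"{path}: expected a mapping with a 'params' section")
    try:
        params = PRDParams(**doc["params"])
    except TypeError as exc:
        raise SchemaError(f"{path}: bad params section: {exc}") from exc
    config = None
    if "config" in doc:
        try:
            config = SimConfig(**doc["config"])
        except TypeError as exc:
            raise SchemaError(f"{path}: bad config section: {exc}") from exc
    return params, config


# ------------------------------------------------------------------ json

def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_fit_result_json(result, path: Path | str) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(result.to_dict()), fh, indent=2)


def write_manifest(
    path: Path | str,
    seed: int,
    params: PRDParams | None = None,
    config: SimConfig | None = None,
    **extra,
) -> None:
    """Run manifest: seed, code/schema versions, parameters, extras."""
    doc = {
        "prdcell_version": __version__,
        "schema_version": SCHEMA_VERSION,
        "seed": int(seed),
    }
    if params is not None:
        doc["params"] = dataclasses.asdict(params)
    if config is not None:
        doc["config"] = dataclasses.asdict(config)
    doc.update(_jsonable(extra))
    with open(path, "w") as fh:
        json.dump(_jsonable(doc), fh, indent=2)
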