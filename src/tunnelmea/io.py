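"""Readers and writers: spike-list CSV, channel-geometry YAML.

Spike lists follow a fixed, documented dialect so that write -> read round
trips are lossless::

    # tunnelmea-spikelist v1
    # duration_s=300.000000
    # div=21              (optional)
    # condition=H-H       (optional)
    time_s,well,electrode_row,electrode_col,amplitude_uv
    0.000080,A1,0,0,32.5
    ...

Times are written in seconds with six fractional digits; at the 12.5 kHz
sample grid (80 us period) every on-grid time is exactly representable.
Vendor spike-list exports with different column names can be ingested by
passing ``column_map``.
"""

from __future__ import annotations

import io as _io
import warnings
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .types import (
    ChannelGeometry,
    ElectrodeId,
    GeometryError,
    Recording,
    SpikeListFormatError,
    SpikeTrain,
    DEFAULT_SAMPLING_RATE_HZ,
)

DIALECT_HEADER = "# tunnelmea-spikelist v1"
REQUIRED_COLUMNS = ("time_s", "well", "electrode_row", "electrode_col")
TIME_DECIMALS = 6

PathLike = Union[str, Path]

__all__ = [
    "read_spike_list",
    "write_spike_list",
    "read_geometry",
    "write_geometry",
    "load_yaml",
]


def _parse_metadata(lines: list[str]) -> dict[str, str]:
    meta: dict[str, str] = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if "=" in body:
            key, value = body.split("=", 1)
            meta[key.strip()] = value.strip()
    return meta


def read_spike_list(
    path: PathLike,
    column_map: Optional[Mapping[str, str]] = None,
    duration_s: Optional[float] = None,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
) -> Recording:
    """Read a spike-list CSV into a :class:`Recording`.

    Parameters
    ----------
    column_map
        Optional mapping from the dialect's column names to the names used in
        the file, e.g. ``{"time_s": "Time (s)", "well": "Well"}``, for
        permissive ingestion of vendor exports.
    duration_s
        Overrides the duration declared in the file header (required when the
        file carries no ``duration_s`` metadata line).
    """
    path = Path(path)
    text = path.read_text()
    comment_lines = [ln for ln in text.splitlines() if ln.startswith("#")]
    meta = _parse_metadata(comment_lines)

    df = pd.read_csv(_io.StringIO(text), comment="#", dtype={"well": str})
    if column_map:
        inverse = {v: k for k, v in column_map.items()}
        df = df.rename(columns=inverse)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SpikeListFormatError(
                f"{path.name}: missing required column {col!r} "
                f"(have {list(df.columns)})"
            )

    if duration_s is None:
        if "duration_s" in meta:
            duration_s = float(meta["duration_s"])
        elif len(df):
            duration_s = float(df["time_s"].max())
        else:
            raise SpikeListFormatError(
                f"{path.name}: no duration_s metadata and no events to infer it from"
            )
    div = int(meta["div"]) if "div" in meta else None
    condition = meta.get("condition", "")

    if len(df) and (df["time_s"] < 0).any():
        raise ValueError(f"{path.name}: negative event times")
    if len(df) and not df["time_s"].is_monotonic_increasing:
        warnings.warn(f"{path.name}: event times not sorted; sorting", stacklevel=2)

    has_amp = "amplitude_uv" in df.columns and df["amplitude_uv"].notna().all()
    trains: dict[ElectrodeId, SpikeTrain] = {}
    if len(df):
        for (well, row, col), grp in df.groupby(
            ["well", "electrode_row", "electrode_col"], sort=True
        ):
            eid = ElectrodeId(str(well), int(row), int(col))
            amps = grp["amplitude_uv"].to_numpy() if has_amp else None
            trains[eid] = SpikeTrain.from_times(
                eid, grp["time_s"].to_numpy(), amps, sampling_rate_hz
            )
    return Recording(
        spike_trains=trains,
        duration_s=duration_s,
        div=div,
        condition=condition,
    )


def write_spike_list(rec: Recording, path: PathLike) -> Path:
    """Write a :class:`Recording` to the spike-list CSV dialect.

    One row per event, sorted by time then electrode; bit-stable for a fixed
    input.
    """
    path = Path(path)
    rows: list[tuple[float, str, int, int, float]] = []
    has_amp = any(
        t.amplitudes_uv is not None for t in rec.spike_trains.values() if len(t)
    )
    for eid in sorted(rec.spike_trains):
        train = rec.spike_trains[eid]
        amps = train.amplitudes_uv
        for k, t in enumerate(train.times_s):
            amp = float(amps[k]) if amps is not None else np.nan
            rows.append((float(t), eid.well_id, eid.row, eid.col, amp))
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))

    with path.open("w") as fh:
        fh.write(DIALECT_HEADER + "\n")
        fh.write(f"# duration_s={rec.duration_s:.{TIME_DECIMALS}f}\n")
        if rec.div is not None:
            fh.write(f"# div={rec.div}\n")
        if rec.condition:
            fh.write(f"# condition={rec.condition}\n")
        cols = "time_s,well,electrode_row,electrode_col"
        fh.write(cols + (",amplitude_uv\n" if has_amp else "\n"))
        for t, well, row, col, amp in rows:
            line = f"{t:.{TIME_DECIMALS}f},{well},{row},{col}"
            if has_amp:
                line += f",{amp:.3f}" if np.isfinite(amp) else ","
            fh.write(line + "\n")
    return path


def _electrode_from_entry(well: str, entry) -> ElectrodeId:
    if isinstance(entry, int):
        return ElectrodeId.from_index(well, entry)
    if isinstance(entry, (list, tuple)) and len(entry) == 2:
        return ElectrodeId(well, int(entry[0]), int(entry[1]))
    raise GeometryError(f"cannot interpret electrode entry {entry!r}")


def read_geometry(path: PathLike) -> list[ChannelGeometry]:
    """Read channel geometries from a YAML file.

    Schema::

        channels:
          - channel: A1-t0
            well: A1
            electrodes: [[0, 0], [0, 1], ...]   # [row, col] pairs or flat indices
            positions_um: [0, 200, ...]          # optional; default k * spacing
            spacing_um: 200                      # optional
            side_a: MO
            side_b: HBO
    """
    data = load_yaml(path)
    if not isinstance(data, dict) or "channels" not in data:
        raise GeometryError(f"{path}: expected a top-level 'channels' list")
    geometries = []
    for entry in data["channels"]:
        well = str(entry["well"])
        electrodes = tuple(_electrode_from_entry(well, e) for e in entry["electrodes"])
        geometries.append(
            ChannelGeometry(
                channel_id=str(entry.get("channel", f"{well}-t{len(geometries)}")),
                electrodes=electrodes,
                positions_um=tuple(entry.get("positions_um", ())),
                side_a_label=str(entry.get("side_a", "MO")),
                side_b_label=str(entry.get("side_b", "HBO")),
                spacing_um=float(entry.get("spacing_um", 200.0)),
            )
        )
    return geometries


def write_geometry(geometries: Sequence[ChannelGeometry], path: PathLike) -> Path:
    path = Path(path)
    payload = {
        "channels": [
            {
                "channel": g.channel_id,
                "well": g.well_id,
                "electrodes": [[e.row, e.col] for e in g.electrodes],
                "positions_um": list(g.positions_um),
                "side_a": g.side_a_label,
                "side_b": g.side_b_label,
                "spacing_um": g.spacing_um,
            }
            for g in geometries
        ]
    }
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def load_yaml(path: PathLike):
    with Path(path).open() as fh:
        return yaml.safe_load(fh)
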