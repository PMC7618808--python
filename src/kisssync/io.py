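"""Readers and writers for the pipeline's table formats.

Trace matrices travel as wide CSV (first column ``time_s`` or ``time_min``,
one further column per cell) or as HDF5 (``/timestamps``, ``/values``,
``/cell_ids`` datasets with modality/units stored as root attributes).
Events and synchronizations are flat CSV tables, one row per event (per
member for synchronizations, sharing a ``sync_id``).
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from typing import List, Optional, Sequence, Union

import h5py
import numpy as np
import pandas as pd

from .model import (
    AnalysisWindow,
    CalciumEvent,
    CellMeta,
    SyncEvent,
    TraceMatrix,
    ValidationError,
)

EVENT_COLUMNS = [
    "cell_id",
    "onset_time_s",
    "peak_time_s",
    "end_time_s",
    "peak_amplitude",
    "baseline_value",
    "half_width_s",
    "rise_time_s",
    "decay_time_s",
]
SYNC_COLUMNS = ["sync_id", "kind", "cell_id", "peak_time_s", "peak_amplitude"]


def read_trace_matrix(path: Union[str, os.PathLike], modality: str) -> TraceMatrix:
    """Read a wide trace table (CSV or HDF5) into a validated TraceMatrix.

    CSV must carry a leading ``time_s`` (seconds) or ``time_min`` (minutes,
    converted on read) column; remaining columns are one cell each. Units
    default to ``raw``; a ``# units:`` comment line, when present, overrides.
    """
    path = os.fspath(path)
    if path.endswith((".h5", ".hdf5")):
        return _read_trace_h5(path, modality)
    units = "raw"
    with open(path) as fh:
        header_comments = []
        while True:
            pos = fh.tell()
            line = fh.readline()
            if line.startswith("#"):
                header_comments.append(line)
            else:
                fh.seek(pos)
                break
        for line in header_comments:
            if "units:" in line:
                units = line.split("units:")[1].strip()
        df = pd.read_csv(fh)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: need a time column and at least one cell")
    time_col = df.columns[0]
    if time_col not in ("time_s", "time_min"):
        raise ValidationError(
            f"{path}: first column must be 'time_s' or 'time_min', got {time_col!r}"
        )
    t = df[time_col].to_numpy(dtype=float)
    if time_col == "time_min":
        t = t * 60.0
    vals = df.iloc[:, 1:].to_numpy(dtype=float).T
    bad = np.argwhere(~np.isfinite(vals))
    if len(bad):
        r, c = bad[0]
        raise ValidationError(
            f"{path}: non-finite value for cell {df.columns[1 + r]!r} at row {c + 1}"
        )
    return TraceMatrix(
        cell_ids=list(df.columns[1:]),
        timestamps=t,
        values=vals,
        modality=modality,
        units=units,
    )


def write_trace_matrix(traces: TraceMatrix, path: Union[str, os.PathLike]) -> None:
    """Write a TraceMatrix as wide CSV or HDF5 (by extension)."""
    path = os.fspath(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "w") as f:
            f.create_dataset("timestamps", data=traces.timestamps)
            f.create_dataset("values", data=traces.values)
            f.create_dataset(
                "cell_ids", data=np.array(traces.cell_ids, dtype=h5py.string_dtype())
            )
            f.attrs["modality"] = traces.modality
            f.attrs["units"] = traces.units
        return
    with open(path, "w") as fh:
        fh.write(f"# units: {traces.units}\n# modality: {traces.modality}\n")
        df = pd.DataFrame(
            traces.values.T, columns=traces.cell_ids,
        )
        df.insert(0, "time_s", traces.timestamps)
        df.to_csv(fh, index=False, float_format="%.17g")


def _read_trace_h5(path: str, modality: str) -> TraceMatrix:
    with h5py.File(path, "r") as f:
        for key in ("timestamps", "values", "cell_ids"):
            if key not in f:
                raise ValidationError(f"{path}: missing dataset /{key}")
        return TraceMatrix(
            cell_ids=[c.decode() if isinstance(c, bytes) else str(c)
                      for c in f["cell_ids"][()]],
            timestamps=f["timestamps"][()],
            values=f["values"][()],
            modality=modality,
            units=f.attrs.get("units", "raw"),
        )


def read_cell_meta(path: Union[str, os.PathLike]) -> List[CellMeta]:
    """Read a ``cell_id,x,y`` coordinate table."""
    df = pd.read_csv(path, comment="#")
    for col in ("cell_id", "x", "y"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    if df["cell_id"].astype(str).duplicated().any():
        raise ValidationError(f"{path}: duplicate cell_id")
    return [
        CellMeta(str(r.cell_id), float(r.x), float(r.y)) for r in df.itertuples()
    ]


def write_cell_meta(cells: Sequence[CellMeta], path: Union[str, os.PathLike]) -> None:
    pd.DataFrame(
        [(c.cell_id, c.x, c.y) for c in cells], columns=["cell_id", "x", "y"]
    ).to_csv(path, index=False)


def events_to_frame(events: Sequence[CalciumEvent]) -> pd.DataFrame:
    rows = [
        (
            e.cell_id, e.onset_time, e.peak_time, e.end_time,
            e.peak_amplitude, e.baseline_value, e.half_width,
            e.rise_time, e.decay_time,
        )
        for e in events
    ]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def syncs_to_frame(syncs: Sequence[SyncEvent]) -> pd.DataFrame:
    rows = [
        (i, s.kind, cell, t, amp)
        for i, s in enumerate(syncs)
        for cell, t, amp in s.members
    ]
    return pd.DataFrame(rows, columns=SYNC_COLUMNS)


def write_events(
    events: Sequence[Union[CalciumEvent, SyncEvent]],
    path: Union[str, os.PathLike],
) -> None:
    """Write events (or synchronizations) as a flat CSV table.

    Times are seconds; amplitudes are in the units of the trace the events
    were detected on. SyncEvents expand to one row per member sharing a
    ``sync_id``. An empty list produces a header-only event table.
    """
    if events and isinstance(events[0], SyncEvent):
        df = syncs_to_frame(events)  # type: ignore[arg-type]
    else:
        df = events_to_frame(events)  # type: ignore[arg-type]
    with open(path, "w") as fh:
        fh.write("# times in seconds; amplitudes in trace units\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_events(path: Union[str, os.PathLike]) -> List[CalciumEvent]:
    df = pd.read_csv(path, comment="#")
    return [
        CalciumEvent(
            cell_id=str(r.cell_id),
            onset_time=r.onset_time_s,
            peak_time=r.peak_time_s,
            end_time=r.end_time_s,
            peak_amplitude=r.peak_amplitude,
            baseline_value=r.baseline_value,
            half_width=r.half_width_s if not pd.isna(r.half_width_s) else math.nan,
            rise_time=r.rise_time_s if not pd.isna(r.rise_time_s) else math.nan,
            decay_time=r.decay_time_s if not pd.isna(r.decay_time_s) else math.nan,
        )
        for r in df.itertuples()
    ]


def read_syncs(path: Union[str, os.PathLike]) -> List[SyncEvent]:
    df = pd.read_csv(path, comment="#")
    syncs = []
    for _, grp in df.groupby("sync_id", sort=True):
        syncs.append(
            SyncEvent(
                kind=grp["kind"].iloc[0],
                members=[
                    (str(r.cell_id), r.peak_time_s, r.peak_amplitude)
                    for r in grp.itertuples()
                ],
            )
        )
    return syncs


def read_windows(path: Union[str, os.PathLike]) -> List[AnalysisWindow]:
    """Read analysis windows from JSON: [{"label":..,"start":..,"end":..}]."""
    with open(path) as fh:
        raw = json.load(fh)
    return [AnalysisWindow(w["label"], float(w["start"]), float(w["end"])) for w in raw]


def file_sha256(path: Union[str, os.PathLike]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
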