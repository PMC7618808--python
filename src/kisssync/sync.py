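"""Synchronization-event clustering and participation statistics.

In vitro, per-cell calcium events are chained into miniature
synchronization events (mSEs): a chain starts at the earliest unassigned
event and admits any later event peaking within 10 s of the chain's current
last peak; chains spanning ≥2 distinct cells are mSEs. In vivo, the same
chaining applied to >1-SD excursions yields population synchronization
events (SEs) when more than 5 cells co-participate. On photometry traces,
low-amplitude SEs are >1-SD excursions sustained for ≥45 s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import PipelineConfig
from .events import suprathreshold_runs, _peak_of_run
from .model import CalciumEvent, SyncEvent, TraceMatrix, ValidationError


def cluster_mse(
    events: Sequence[CalciumEvent], config: Optional[PipelineConfig] = None
) -> List[SyncEvent]:
    """Greedy chronological chaining of per-cell events into mSEs.

    Events are scanned in peak-time order. The earliest unassigned event
    seeds a chain; each later unassigned event whose peak lies within
    ``chain_window_s`` of the chain's current last peak joins it — unless
    its cell is already a member, in which case it is left for a later
    chain (a cell contributes at most its earliest qualifying event).
    Chains with at least two distinct cells become mSEs.
    """
    config = config or PipelineConfig()
    w = config.chain_window_s
    ordered = sorted(events, key=lambda e: (e.peak_time, e.cell_id))
    assigned = [False] * len(ordered)
    syncs: List[SyncEvent] = []
    for i, seed in enumerate(ordered):
        if assigned[i]:
            continue
        assigned[i] = True
        members = [(seed.cell_id, seed.peak_time, seed.peak_amplitude)]
        cells = {seed.cell_id}
        last_peak = seed.peak_time
        for j in range(i + 1, len(ordered)):
            if assigned[j]:
                continue
            ev = ordered[j]
            if ev.peak_time - last_peak > w:
                break  # sorted: nothing later can join either
            if ev.cell_id in cells:
                continue  # may seed a new chain after this one closes
            assigned[j] = True
            members.append((ev.cell_id, ev.peak_time, ev.peak_amplitude))
            cells.add(ev.cell_id)
            last_peak = ev.peak_time
        if len(cells) >= 2:
            syncs.append(SyncEvent("mse", members, chain_window_s=w))
    return syncs


@dataclass
class Excursion:
    """One maximal suprathreshold excursion of a single trace."""

    cell_id: str
    onset_time: float
    peak_time: float
    end_time: float
    peak_value: float
    duration: float


def extract_excursions(
    timestamps: np.ndarray,
    values: np.ndarray,
    threshold: float,
    cell_id: str = "trace",
    merge_gap_s: float = 0.0,
) -> List[Excursion]:
    """Maximal runs above ``threshold`` with their peak sample.

    ``merge_gap_s`` > 0 merges consecutive runs separated by a
    sub-threshold gap shorter than that many seconds into one excursion
    (noise dithering at a threshold crossing otherwise splits one long
    excursion into spurious pieces).
    """
    t = np.asarray(timestamps, dtype=float)
    x = np.asarray(values, dtype=float)
    runs = suprathreshold_runs(x, threshold)
    if merge_gap_s > 0 and len(runs) > 1:
        merged = [list(runs[0])]
        for start, stop in runs[1:]:
            if t[start] - t[merged[-1][1] - 1] < merge_gap_s:
                merged[-1][1] = stop
            else:
                merged.append([start, stop])
        runs = [(a, b) for a, b in merged]
    out = []
    for start, stop in runs:
        ipk = _peak_of_run(x, start, stop)
        out.append(
            Excursion(
                cell_id=cell_id,
                onset_time=float(t[start]),
                peak_time=float(t[ipk]),
                end_time=float(t[stop - 1]),
                peak_value=float(x[ipk]),
                duration=float(t[stop - 1] - t[start]),
            )
        )
    return out


def detect_population_se(
    traces: TraceMatrix, config: Optional[PipelineConfig] = None
) -> List[SyncEvent]:
    """Population synchronization events on a z-unit miniscope matrix.

    Per cell, excursions above ``se_threshold_sd`` (1 SD; traces are in
    z-units already) are extracted with their peak times and chained across
    cells exactly as :func:`cluster_mse` chains events; chains touching more
    than 5 distinct cells are SEs.
    """
    config = config or PipelineConfig()
    if traces.n_cells < config.se_min_cells:
        raise ValidationError(
            f"need at least {config.se_min_cells} cells, got {traces.n_cells}"
        )
    if traces.units != "z":
        raise ValidationError("detect_population_se expects z-unit traces")
    pseudo_events: List[CalciumEvent] = []
    for i, cid in enumerate(traces.cell_ids):
        for exc in extract_excursions(
            traces.timestamps, traces.values[i], config.se_threshold_sd, cid,
            merge_gap_s=config.flicker_window_s,
        ):
            pseudo_events.append(
                CalciumEvent(
                    cell_id=cid,
                    onset_time=exc.onset_time,
                    peak_time=exc.peak_time,
                    end_time=exc.end_time,
                    peak_amplitude=exc.peak_value,
                    baseline_value=exc.peak_value - 1.0,
                )
            )
    chains = cluster_mse(pseudo_events, config)
    return [
        SyncEvent("se", s.members, chain_window_s=config.chain_window_s)
        for s in chains
        if s.n_cells >= config.se_min_cells
    ]


def detect_low_amplitude_se(
    traces: TraceMatrix, config: Optional[PipelineConfig] = None
) -> List[SyncEvent]:
    """Low-amplitude SEs on a single baseline-corrected photometry z trace:
    excursions whose peak exceeds 1 SD of the mean and whose above-threshold
    duration is at least 45 s."""
    config = config or PipelineConfig()
    if traces.n_cells != 1:
        raise ValidationError("expected a single population trace")
    out = []
    for exc in extract_excursions(
        traces.timestamps, traces.values[0], config.se_threshold_sd,
        traces.cell_ids[0], merge_gap_s=config.flicker_window_s,
    ):
        if exc.duration >= config.low_amp_min_duration_s:
            out.append(
                SyncEvent(
                    "low_amplitude_se",
                    [(exc.cell_id, exc.peak_time, exc.peak_value)],
                )
            )
    return out


def inter_peak_intervals(syncs: Sequence[SyncEvent]) -> np.ndarray:
    """Intervals between successive synchronization reference times (s);
    always one element shorter than the sync list."""
    refs = sorted(s.reference_time for s in syncs)
    return np.diff(refs)


def se_mean_profile(
    traces: TraceMatrix,
    se: SyncEvent,
    half_span_s: float = 60.0,
) -> Tuple[np.ndarray, np.ndarray, Dict[str, float]]:
    """Mean z profile of an SE's contributing cells around its peak.

    Returns (lag_s, mean_profile, metrics) where metrics holds the SE
    duration, rise and decay to the half-width-full-maximum level relative
    to the profile minimum within the span.
    """
    t = traces.timestamps
    center = float(np.mean([m[1] for m in se.members]))
    sel = (t >= center - half_span_s) & (t <= center + half_span_s)
    if sel.sum() < 3:
        raise ValidationError("SE too close to the recording edge for a profile")
    lag = t[sel] - center
    rows = [traces.values[traces.cell_ids.index(c)][sel] for c in se.member_cells]
    prof = np.mean(rows, axis=0)
    base = float(prof.min())
    peak_i = int(np.argmax(prof))
    half = base + 0.5 * (prof[peak_i] - base)
    above = prof >= half
    # half-maximum crossing nearest the peak on each side
    lo = peak_i
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = peak_i
    while hi < len(prof) - 1 and above[hi + 1]:
        hi += 1
    metrics = {
        "duration_s": float(lag[hi] - lag[lo]),
        "rise_to_half_s": float(lag[peak_i] - lag[lo]),
        "decay_to_half_s": float(lag[hi] - lag[peak_i]),
        "peak_z": float(prof[peak_i]),
    }
    return lag, prof, metrics


def participation_stats(
    syncs: Sequence[SyncEvent], cell_ids: Sequence[str]
) -> Dict[str, object]:
    """Participation fractions, in percent.

    ``per_cell``: for each recorded cell, the share of synchronizations it
    joined. ``per_sync``: for each synchronization, the share of recorded
    cells participating. Also reports the fraction of cells seen in at
    least one, in all, and in exactly one synchronization.
    """
    if not syncs:
        raise ValidationError("participation_stats needs at least one sync")
    cell_ids = list(cell_ids)
    n_syncs = len(syncs)
    counts = {c: 0 for c in cell_ids}
    for s in syncs:
        for c in s.member_cells:
            if c in counts:
                counts[c] += 1
    per_cell = {c: 100.0 * k / n_syncs for c, k in counts.items()}
    per_sync = [100.0 * s.n_cells / len(cell_ids) for s in syncs]
    n = len(cell_ids)
    return {
        "per_cell_pct": per_cell,
        "per_sync_pct": per_sync,
        "mean_per_cell_pct": float(np.mean(list(per_cell.values()))),
        "mean_per_sync_pct": float(np.mean(per_sync)),
        "pct_cells_in_any": 100.0 * sum(k >= 1 for k in counts.values()) / n,
        "pct_cells_in_all": 100.0 * sum(k == n_syncs for k in counts.values()) / n,
        "pct_cells_in_exactly_one": 100.0 * sum(k == 1 for k in counts.values()) / n,
    }
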