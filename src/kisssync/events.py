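"""Per-cell calcium event detection, shape metrics and rate normalisation.

An event is a maximal run of samples exceeding mean + 2 SD of the trace,
peaking at the run maximum; a suprathreshold re-crossing within 10 s of the
previous accepted event's peak in the same cell is discarded as indicator
"flicker" rather than a distinct transient. Rates are normalised to
events/cell/hour so recordings with different cell counts are comparable.
"""

from __future__ import annotations

import logging
import math
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .config import PipelineConfig
from .model import AnalysisWindow, CalciumEvent, TraceMatrix, ValidationError

logger = logging.getLogger(__name__)


def suprathreshold_runs(values: np.ndarray, threshold: float) -> List[Tuple[int, int]]:
    """Maximal runs of strictly suprathreshold samples as [start, stop) pairs."""
    above = values > threshold
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1)
    stops = list(edges[above[edges]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(len(values))
    return list(zip(starts, stops))


def _peak_of_run(values: np.ndarray, start: int, stop: int) -> int:
    # plateau ties resolve to the earliest maximal sample
    return start + int(np.argmax(values[start:stop]))


def detect_events(
    timestamps: np.ndarray,
    values: np.ndarray,
    cell_id: str = "cell",
    config: Optional[PipelineConfig] = None,
    threshold: Optional[float] = None,
) -> List[CalciumEvent]:
    """Detect calcium events in one cell's dff/z trace.

    The threshold is ``mean + event_threshold_sd × SD`` over the analysis
    span (pass ``threshold`` explicitly to reuse statistics from a wider
    span). Each maximal suprathreshold run yields one candidate peaking at
    its maximum sample; a candidate whose peak falls within
    ``flicker_window_s`` after the previous accepted peak is discarded.
    """
    config = config or PipelineConfig()
    t = np.asarray(timestamps, dtype=float)
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError(f"cell {cell_id!r}: trace must be finite")
    if t[-1] - t[0] < 2 * config.flicker_window_s:
        raise ValidationError(
            f"cell {cell_id!r}: trace shorter than twice the flicker window"
        )
    if threshold is None:
        sd = x.std()
        if sd <= 0:
            raise ValidationError(f"cell {cell_id!r}: zero-variance trace")
        threshold = x.mean() + config.event_threshold_sd * sd

    events: List[CalciumEvent] = []
    last_peak_t = -math.inf
    for start, stop in suprathreshold_runs(x, threshold):
        ipk = _peak_of_run(x, start, stop)
        t_pk = t[ipk]
        if t_pk - last_peak_t <= config.flicker_window_s:
            continue  # flicker: keep the earlier event, drop this one
        last_peak_t = t_pk
        events.append(
            CalciumEvent(
                cell_id=cell_id,
                onset_time=t[start],
                peak_time=t_pk,
                end_time=t[stop - 1],
                peak_amplitude=float(x[ipk]),
                # placeholder until event_shape computes the true baseline
                baseline_value=float(np.min(x)),
            )
        )
    return events


def detect_events_matrix(
    traces: TraceMatrix,
    config: Optional[PipelineConfig] = None,
    windows: Optional[Sequence[AnalysisWindow]] = None,
) -> List[CalciumEvent]:
    """Detect events for every cell of a matrix.

    With ``windows`` given and ``config.threshold_scope == 'window'``, the
    mean/SD threshold is computed per measurement window (drugs change the
    variance, and windows are analysed independently); otherwise statistics
    come from the whole trace.
    """
    config = config or PipelineConfig()
    out: List[CalciumEvent] = []
    for i, cid in enumerate(traces.cell_ids):
        x = traces.values[i]
        ts = traces.timestamps
        if traces.flags is not None:
            # skip the leading warm-up span (expanding-baseline samples)
            good = np.flatnonzero(~traces.flags[i])
            if len(good) == 0:
                continue
            ts, x = ts[good[0]:], x[good[0]:]
        if windows and config.threshold_scope == "window":
            for w in windows:
                sel = (ts >= w.start) & (ts < w.end)
                if sel.sum() < 4:
                    continue
                out.extend(
                    detect_events(ts[sel], x[sel], cell_id=cid, config=config)
                )
        else:
            out.extend(detect_events(ts, x, cell_id=cid, config=config))
    out.sort(key=lambda e: (e.peak_time, e.cell_id))
    return out


def trace_baseline(values: np.ndarray, config: Optional[PipelineConfig] = None) -> float:
    """Baseline of a trace: median of all samples below mean + 0.5 SD."""
    config = config or PipelineConfig()
    x = np.asarray(values, dtype=float)
    band = x.mean() + config.baseline_band_sd * x.std()
    low = x[x < band]
    if len(low) == 0:
        raise ValidationError("no samples below the baseline band")
    return float(np.median(low))


def _cross_time(
    t: np.ndarray, x: np.ndarray, i_lo: int, i_hi: int, level: float
) -> float:
    """Linear-interpolated time where x crosses ``level`` between samples."""
    x0, x1 = x[i_lo], x[i_hi]
    if x1 == x0:
        return float(t[i_lo])
    frac = (level - x0) / (x1 - x0)
    return float(t[i_lo] + frac * (t[i_hi] - t[i_lo]))


def event_shape(
    timestamps: np.ndarray,
    values: np.ndarray,
    event: CalciumEvent,
    config: Optional[PipelineConfig] = None,
) -> CalciumEvent:
    """Fill an event's shape metrics from its trace.

    Baseline is the whole-trace baseline (median below mean + 0.5 SD);
    amplitude is peak − baseline. Half-width is the width at
    baseline + 50% amplitude around the peak (linear interpolation between
    samples); rise time runs from the 20% to the 80% level on the rising
    flank, decay time the reverse. The search span extends from the peak
    outward to the first baseline crossings, capped at ±``event_span_cap_s``
    (in vivo events last 30–130 s, so a cap avoids merging neighbours).
    A flank that never crosses a required level leaves that metric NaN.
    """
    config = config or PipelineConfig()
    t = np.asarray(timestamps, dtype=float)
    x = np.asarray(values, dtype=float)
    base = trace_baseline(x, config)
    ipk = int(np.argmin(np.abs(t - event.peak_time)))
    peak = float(x[ipk])
    if peak <= base:
        raise ValidationError("event peak not above the computed baseline")
    amp = peak - base

    cap = config.event_span_cap_s
    lo = ipk
    while lo > 0 and x[lo - 1] > base and t[ipk] - t[lo - 1] <= cap:
        lo -= 1
    hi = ipk
    while hi < len(x) - 1 and x[hi + 1] > base and t[hi + 1] - t[ipk] <= cap:
        hi += 1

    def rising_cross(level: float) -> float:
        # last upward crossing of `level` before the peak (the sample just
        # outside the span is included so step edges are measurable)
        for i in range(ipk, max(lo - 1, 0), -1):
            if x[i - 1] <= level < x[i] or x[i - 1] < level <= x[i]:
                return _cross_time(t, x, i - 1, i, level)
        return math.nan

    def falling_cross(level: float) -> float:
        # first downward crossing of `level` after the peak
        for i in range(ipk, min(hi + 1, len(x) - 1)):
            if x[i] >= level > x[i + 1] or x[i] > level >= x[i + 1]:
                return _cross_time(t, x, i, i + 1, level)
        return math.nan

    half = base + 0.5 * amp
    t_up, t_dn = rising_cross(half), falling_cross(half)
    half_width = t_dn - t_up if not (math.isnan(t_up) or math.isnan(t_dn)) else math.nan

    t20u, t80u = rising_cross(base + 0.2 * amp), rising_cross(base + 0.8 * amp)
    rise = t80u - t20u if not (math.isnan(t20u) or math.isnan(t80u)) else math.nan
    t80d, t20d = falling_cross(base + 0.8 * amp), falling_cross(base + 0.2 * amp)
    decay = t20d - t80d if not (math.isnan(t80d) or math.isnan(t20d)) else math.nan
    for name, v in (("half_width", half_width), ("rise_time", rise),
                    ("decay_time", decay)):
        if math.isnan(v):
            logger.info(
                "event_shape: %s undefined for cell %s event at %.2f s",
                name, event.cell_id, event.peak_time,
            )

    return CalciumEvent(
        cell_id=event.cell_id,
        onset_time=min(event.onset_time, t[lo]),
        peak_time=event.peak_time,
        end_time=max(event.end_time, t[hi]),
        peak_amplitude=peak,
        baseline_value=base,
        half_width=half_width,
        rise_time=rise,
        decay_time=decay,
    )


def rate_per_cell_hour(count: int, n_cells: int, window: AnalysisWindow) -> float:
    """Normalise a count to events per cell per hour over a window."""
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    if window.duration_s <= 0:
        raise ValidationError("zero-length window")
    return count / n_cells / window.duration_h


def percent_change(pre_rate: float, post_rate: float) -> float:
    """Signed percent reduction from pre to post: 100·(pre − post)/pre."""
    if pre_rate <= 0:
        raise ValidationError("pre_rate must be > 0")
    return 100.0 * (pre_rate - post_rate) / pre_rate
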