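"""Raw fluorescence → analysis units.

Slice movies are converted to ΔF/F against a trailing lower-percentile
baseline; miniscope traces are z-scored; photometry is channel-subtracted
(465 − 405), slow-baseline corrected with a moving lower-envelope estimator,
and z-scored; duty-cycled signals can be regularised onto a uniform grid.
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .model import TraceMatrix, ValidationError

logger = logging.getLogger(__name__)


def _rolling_low_mean(
    t: np.ndarray, x: np.ndarray, window_s: float, fraction: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Trailing-window mean of the lower ``fraction`` of samples.

    For each sample i the window is the half-open interval
    ``(t_i - window_s, t_i]``. Samples at or below the ``fraction`` quantile
    (linear interpolation) of the window are averaged; windows holding fewer
    than ``ceil(1/fraction)`` samples fall back to the window minimum.
    Returns the baseline and a warm-up flag (window not yet fully covered).
    """
    n = len(x)
    out = np.empty(n)
    min_count = int(math.ceil(1.0 / fraction))
    lo_idx = np.searchsorted(t, t - window_s, side="right")
    for i in range(n):
        seg = x[lo_idx[i]: i + 1]
        if len(seg) < min_count:
            out[i] = seg.min()
        else:
            q = np.quantile(seg, fraction)
            out[i] = seg[seg <= q].mean()
    warmup = (t - t[0]) < window_s
    return out, warmup


def compute_dff(
    raw: TraceMatrix,
    background: Optional[np.ndarray] = None,
    config: Optional[PipelineConfig] = None,
) -> TraceMatrix:
    """ΔF/F for slice imaging: ``(F_t − F_bg) / F0(t)``.

    ``F0(t)`` is the mean of the lower ``f0_fraction`` (8%) of the
    background-subtracted fluorescence over the trailing ``f0_window_s``
    (26 s = 40 × the GCaMP6s decay constant 0.65 s). Samples earlier than
    one full window use the expanding available window and are flagged.

    Parameters
    ----------
    raw
        Raw-unit traces.
    background
        Per-cell background ROI traces, shape ``(n_cells, n_samples)`` or a
        single row shared by all cells. ``None`` means zero background (the
        synthetic-data fallback; logged).
    """
    config = config or PipelineConfig()
    if raw.units != "raw":
        raise ValidationError("compute_dff expects raw-unit traces")
    if background is None:
        logger.info("compute_dff: no background traces supplied; assuming zero")
        bg = np.zeros_like(raw.values)
    else:
        bg = np.atleast_2d(np.asarray(background, dtype=float))
        if bg.shape[1] != raw.n_samples or bg.shape[0] not in (1, raw.n_cells):
            raise ValidationError(
                "background must align sample-for-sample with raw traces"
            )
        if bg.shape[0] == 1:
            bg = np.broadcast_to(bg, raw.values.shape)
    t = raw.timestamps
    in_window = (t - t[0]) <= config.f0_window_s
    if in_window.sum() < 2:
        raise ValidationError("f0_window_s must cover at least 2 samples")
    df = raw.values - bg
    out = np.empty_like(df)
    flags = np.zeros_like(df, dtype=bool)
    for i, cid in enumerate(raw.cell_ids):
        f0, warm = _rolling_low_mean(t, df[i], config.f0_window_s, config.f0_fraction)
        bad = f0 <= 0
        if bad.any():
            j = int(np.argmax(bad))
            raise ValidationError(
                f"degenerate baseline: F0 <= 0 for cell {cid!r} at t={t[j]:.3f} s"
            )
        out[i] = df[i] / f0
        flags[i] = warm
    return TraceMatrix(
        raw.cell_ids, t, out, modality=raw.modality, units="dff", flags=flags
    )


def zscore_traces(traces: TraceMatrix, per: str = "cell") -> TraceMatrix:
    """Normalise traces to z-scores over the full recording.

    ``per='cell'`` standardises each row independently; ``per='population'``
    uses the grand mean and SD of the whole matrix.
    """
    vals = traces.values
    if per == "cell":
        mu = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, keepdims=True)
    elif per == "population":
        mu = np.full((traces.n_cells, 1), vals.mean())
        sd = np.full((traces.n_cells, 1), vals.std())
    else:
        raise ValueError("per must be 'cell' or 'population'")
    if np.any(sd <= 0):
        i = int(np.argmax(sd.ravel() <= 0))
        raise ValidationError(f"zero-variance trace (cell {traces.cell_ids[i]!r})")
    return TraceMatrix(
        traces.cell_ids, traces.timestamps, (vals - mu) / sd,
        modality=traces.modality, units="z", flags=traces.flags,
    )


def _centered_rolling(
    x: np.ndarray, window: int, stat: str, quantile: float = 0.10
) -> np.ndarray:
    s = pd.Series(x)
    roll = s.rolling(window=window, center=True, min_periods=1)
    if stat == "quantile":
        return roll.quantile(quantile).to_numpy()
    return roll.mean().to_numpy()


def estimate_drift_baseline(
    t: np.ndarray, x: np.ndarray, window_s: float, quantile: float = 0.10
) -> np.ndarray:
    """Slow-baseline estimate: centered rolling lower-quantile envelope over
    ``window_s``, smoothed by a centered moving average of the same width.

    The envelope systematically sits below the signal by the within-window
    lower-quantile offset of the fast fluctuations; the caller removes any
    such constant offset implicitly by z-scoring afterwards.
    """
    dt = float(np.median(np.diff(t)))
    window = max(int(round(window_s / dt)), 2)
    env = _centered_rolling(x, window, "quantile", quantile)
    return _centered_rolling(env, window, "mean")


def correct_photometry(
    channels: TraceMatrix, config: Optional[PipelineConfig] = None
) -> TraceMatrix:
    """Photometry pipeline: (465 − 405) → moving-window baseline-shift
    correction (900 s) → z-score. Returns a single-row z-unit TraceMatrix.

    A missing 405 row degrades the subtraction to identity (logged).
    """
    config = config or PipelineConfig()
    if channels.modality != "photometry":
        raise ValidationError("correct_photometry expects a photometry matrix")
    t = channels.timestamps
    if t[-1] - t[0] < config.photometry_baseline_window_s:
        raise ValidationError(
            "recording shorter than one baseline window "
            f"({config.photometry_baseline_window_s} s)"
        )
    sig = channels.values[0].astype(float)
    if channels.n_cells == 2:
        sig = sig - channels.values[1]
    else:
        logger.warning("correct_photometry: no 405 channel; subtraction skipped")
    baseline = estimate_drift_baseline(
        t, sig, config.photometry_baseline_window_s,
        config.photometry_baseline_quantile,
    )
    corrected = sig - baseline
    sd = corrected.std()
    if sd <= 0:
        raise ValidationError(
            "zero variance after channel subtraction and baseline correction "
            "(identical 465/405 channels?)"
        )
    z = (corrected - corrected.mean()) / sd
    return TraceMatrix(
        ["465-405"], t, z[None, :], modality="photometry", units="z"
    )


def regularize_duty_cycle(
    traces: TraceMatrix, policy: str = "concatenate"
) -> TraceMatrix:
    """Handle 5 s-on/10 s-off duty-cycled recordings.

    ``concatenate`` keeps only the acquired samples with their true
    wall-clock timestamps (durations remain wall-clock, not on-time).
    ``interpolate`` fills the off-periods by linear interpolation onto a
    uniform grid at the nominal (modal) sampling rate; filled samples are
    flagged. Continuous input passes through unchanged under either policy.
    """
    if policy not in ("concatenate", "interpolate"):
        raise ValueError("policy must be 'concatenate' or 'interpolate'")
    t = traces.timestamps
    dts = np.diff(t)
    dt = float(np.median(dts))
    has_gaps = bool(np.any(dts > 1.5 * dt))
    if policy == "concatenate" or not has_gaps:
        return traces
    grid = np.arange(t[0], t[-1] + dt / 2, dt)
    vals = np.vstack([np.interp(grid, t, row) for row in traces.values])
    # a grid sample is "filled" when no acquired sample lies within dt/2
    idx = np.searchsorted(t, grid)
    idx = np.clip(idx, 1, len(t) - 1)
    nearest = np.minimum(np.abs(t[idx] - grid), np.abs(t[idx - 1] - grid))
    filled = nearest > dt / 2
    flags = np.broadcast_to(filled, vals.shape).copy()
    return TraceMatrix(
        traces.cell_ids, grid, vals, modality=traces.modality,
        units=traces.units, flags=flags,
    )
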