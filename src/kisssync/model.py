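"""Core domain types shared by every pipeline stage.

The pipeline's unit of data is the :class:`TraceMatrix` — a wide table of
fluorescence values, one row per cell and one column per timestamp — in one
of three unit systems (raw a.u., ΔF/F, or z-scores) and one of three
acquisition modalities (2-Hz brain-slice GCaMP movie, 10-Hz miniscope, or
duty-cycled fiber photometry).  Detected per-cell transients become
:class:`CalciumEvent`; clusters of transients across cells become
:class:`SyncEvent` (mSE in vitro, SE in vivo, low-amplitude SE on
photometry).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

MODALITIES = ("slice_gcamp", "miniscope", "photometry")
UNITS = ("raw", "dff", "z")
SYNC_KINDS = ("mse", "se", "low_amplitude_se")


class ValidationError(ValueError):
    """An object violates one of its declared invariants."""


@dataclass
class TraceMatrix:
    """Multi-cell fluorescence time series.

    Parameters
    ----------
    cell_ids
        Opaque string identifiers, one per row. Row order is preserved but
        carries no meaning.
    timestamps
        Sample times in seconds, strictly increasing; may be non-uniform
        (duty-cycled photometry).
    values
        ``(n_cells, n_timestamps)`` array in the declared ``units``.
    modality
        One of ``slice_gcamp``, ``miniscope``, ``photometry``.
    units
        One of ``raw``, ``dff``, ``z``.
    flags
        Optional boolean array matching ``values`` marking samples that are
        warm-up (expanding F0 window) or interpolated fill; ``None`` means
        nothing flagged.
    """

    cell_ids: List[str]
    timestamps: np.ndarray
    values: np.ndarray
    modality: str = "slice_gcamp"
    units: str = "raw"
    flags: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        if self.units not in UNITS:
            raise ValidationError(f"unknown units {self.units!r}")
        if self.timestamps.ndim != 1:
            raise ValidationError("timestamps must be one-dimensional")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValidationError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.timestamps)):
            raise ValidationError("timestamps must be finite")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values must be finite (no NaN/inf)")
        if self.values.shape != (len(self.cell_ids), len(self.timestamps)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.timestamps)} timestamps"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("cell_ids must be unique")
        if self.modality == "photometry" and self.n_cells not in (1, 2):
            raise ValidationError(
                "photometry matrices carry one (465) or two (465, 405) rows"
            )
        if self.flags is not None:
            self.flags = np.asarray(self.flags, dtype=bool)
            if self.flags.shape != self.values.shape:
                raise ValidationError("flags must match values shape")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_samples(self) -> int:
        return len(self.timestamps)

    @property
    def duration_s(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    def sample_interval(self) -> float:
        """Median inter-sample interval in seconds (robust to duty-cycle gaps)."""
        return float(np.median(np.diff(self.timestamps)))

    def row(self, cell_id: str) -> np.ndarray:
        return self.values[self.cell_ids.index(cell_id)]


@dataclass(frozen=True)
class CellMeta:
    """Imaging-plane coordinates of one cell (pixels or μm, per session)."""

    cell_id: str
    x: float
    y: float


@dataclass
class CalciumEvent:
    """One suprathreshold calcium transient in one cell.

    Shape metrics (``half_width``, ``rise_time``, ``decay_time``) are NaN
    until filled in by :func:`kisssync.events.event_shape`; a metric that
    cannot be measured (flank never crosses the required level inside the
    event span) stays NaN.
    """

    cell_id: str
    onset_time: float
    peak_time: float
    end_time: float
    peak_amplitude: float
    baseline_value: float = 0.0
    half_width: float = math.nan
    rise_time: float = math.nan
    decay_time: float = math.nan

    def __post_init__(self) -> None:
        if not self.onset_time <= self.peak_time <= self.end_time:
            raise ValidationError(
                f"event times out of order: onset={self.onset_time} "
                f"peak={self.peak_time} end={self.end_time}"
            )
        if not self.peak_amplitude > self.baseline_value:
            raise ValidationError("peak_amplitude must exceed baseline_value")
        for name in ("half_width", "rise_time", "decay_time"):
            v = getattr(self, name)
            if not math.isnan(v) and v < 0:
                raise ValidationError(f"{name} must be >= 0")

    @property
    def amplitude(self) -> float:
        """Peak height above the computed baseline."""
        return self.peak_amplitude - self.baseline_value


@dataclass
class SyncEvent:
    """A synchronization: a chained cluster of per-cell peaks.

    ``members`` is a list of ``(cell_id, peak_time, peak_amplitude)``
    sorted by peak time, at most one entry per cell. ``kind`` is ``mse``
    (in vitro, ≥2 cells), ``se`` (in vivo population event, >5 cells) or
    ``low_amplitude_se`` (single photometry trace; members holds the one
    population "cell").
    """

    kind: str
    members: List[Tuple[str, float, float]]
    chain_window_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in SYNC_KINDS:
            raise ValidationError(f"unknown sync kind {self.kind!r}")
        if not self.members:
            raise ValidationError("a SyncEvent needs at least one member")
        self.members = sorted(
            [(str(c), float(t), float(a)) for c, t, a in self.members],
            key=lambda m: m[1],
        )
        cells = [m[0] for m in self.members]
        if len(set(cells)) != len(cells):
            raise ValidationError("at most one member per cell_id")
        if self.kind == "mse" and self.n_cells < 2:
            raise ValidationError("an mSE needs events from at least two cells")
        if self.kind == "se" and self.n_cells <= 5:
            raise ValidationError("an SE needs more than 5 participating cells")
        if self.chain_window_s is not None:
            gaps = np.diff([m[1] for m in self.members])
            if len(gaps) and gaps.max() > self.chain_window_s + 1e-9:
                raise ValidationError(
                    "consecutive member peaks exceed the chain window"
                )

    @property
    def n_cells(self) -> int:
        return len(self.members)

    @property
    def reference_time(self) -> float:
        """Earliest member peak time (s)."""
        return self.members[0][1]

    @property
    def duration(self) -> float:
        """Span from first to last member peak (s)."""
        return self.members[-1][1] - self.members[0][1]

    @property
    def mean_amplitude(self) -> float:
        return float(np.mean([m[2] for m in self.members]))

    @property
    def member_cells(self) -> List[str]:
        return [m[0] for m in self.members]


@dataclass(frozen=True)
class AnalysisWindow:
    """A labelled epoch (pre/drug/wash, or pre/infusion/post), seconds."""

    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(f"window {self.label!r}: start must precede end")

    @property
    def duration_s(self) -> float:
        return self.end - self.start

    @property
    def duration_h(self) -> float:
        return (self.end - self.start) / 3600.0

    def contains(self, t: float) -> bool:
        return self.start <= t < self.end


def check_windows_disjoint(windows: Sequence[AnalysisWindow]) -> None:
    """Raise if any two windows of a comparison overlap."""
    ordered = sorted(windows, key=lambda w: w.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValidationError(f"windows {a.label!r} and {b.label!r} overlap")


@dataclass
class SpikeTrain:
    """Sorted spike times (s) from a whole-cell recording."""

    spike_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.ndim != 1:
            raise ValidationError("spike_times must be one-dimensional")
        if len(self.spike_times) > 1 and not np.all(np.diff(self.spike_times) > 0):
            raise ValidationError("spike_times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)

    def isis(self) -> np.ndarray:
        """Inter-spike intervals; ``isis()[k-1]`` is the ISI following spike k."""
        if self.n_spikes < 2:
            raise ValidationError("need >= 2 spikes for any ISI computation")
        return np.diff(self.spike_times)
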