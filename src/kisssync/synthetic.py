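"""Synthetic session generator with ground truth.

Emulates the three recording modalities the pipeline analyses — 2-Hz
brain-slice GCaMP movies, 10-Hz miniscope recordings and duty-cycled fiber
photometry — as baseline fluorescence plus kernel-convolved event trains,
scheduled synchronizations with partial cell participation and jittered
member peak times, optional pre-synchronization baseline ramps, and additive
Gaussian noise.  Every generated session carries a :class:`GroundTruth`
(true event times, synchronization schedule, membership matrix, ramping
flags) so detector sensitivity, false-discovery rate, synchronization
recovery and ramping classification can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .config import GCAMP6S_TAU_S
from .model import CellMeta, TraceMatrix, ValidationError

#: Start-of-recording margin (s) kept free of scheduled activity so the
#: trailing-baseline warm-up never overlaps an event.
_EDGE_MARGIN_S = 30.0

#: Minimum separation (s) between scheduled synchronizations. Real
#: synchronization events are discrete episodes minutes apart (every
#: ~10 min in gonadectomized animals); scheduling them as a thinned
#: Poisson process keeps them resolvable as distinct population events.
_MIN_SYNC_SEPARATION_S = 60.0


class SimulationSpec(BaseModel):
    """Stated world for one simulated session.

    Rates are per hour; times in seconds; amplitudes and noise in the raw
    trace units of the session (arbitrary fluorescence units on top of
    ``baseline_offset``).
    """

    model_config = ConfigDict(extra="forbid")

    n_cells: int = 10
    duration_s: float = 2400.0
    sample_rate_hz: float = 2.0
    baseline_event_rate_per_cell_per_h: float = 11.3
    sync_rate_per_h: float = 9.0
    participation_p: float = 0.5
    peak_jitter_s: float = 3.0
    amplitude_mean_sd: Tuple[float, float] = (30.0, 6.0)
    burst_duration_s: Tuple[float, float] = (2.0, 8.0)
    noise_sd: float = 2.0
    ramping_fraction: float = 0.0
    ramp_slope: float = 0.3  # units/min over the 3 min before each sync
    indicator_tau_s: float = GCAMP6S_TAU_S
    indicator_rise_s: float = 0.2
    baseline_offset: float = 100.0
    duty_cycle: Optional[Tuple[float, float]] = None  # (on_s, off_s)
    drift_amplitude: float = 0.0  # photometry slow drift, raw units
    rng_seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationSpec":
        if not 0 <= self.participation_p <= 1:
            raise ValueError("participation_p must lie in [0, 1]")
        if not 0 <= self.ramping_fraction <= 1:
            raise ValueError("ramping_fraction must lie in [0, 1]")
        for name in ("baseline_event_rate_per_cell_per_h", "sync_rate_per_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.indicator_tau_s <= 0:
            raise ValueError("indicator_tau_s must be > 0")
        if self.duty_cycle is not None and min(self.duty_cycle) <= 0:
            raise ValueError("duty_cycle periods must be > 0")
        if not 0 < self.burst_duration_s[0] <= self.burst_duration_s[1]:
            raise ValueError("burst_duration_s must be an increasing positive pair")
        return self


@dataclass
class GroundTruth:
    """Exact generating quantities for one simulated session."""

    event_times: Dict[str, np.ndarray]  # per cell, sorted, seconds
    sync_times: np.ndarray  # scheduled synchronization times, sorted
    membership: np.ndarray  # (n_syncs, n_cells) booleans
    ramping_cells: Dict[str, bool]
    cell_ids: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sync_times = np.asarray(self.sync_times, dtype=float)
        self.membership = np.asarray(self.membership, dtype=bool).reshape(
            len(self.sync_times), -1 if len(self.sync_times) else 0
        )
        if len(self.sync_times) and self.membership.shape[0] != len(self.sync_times):
            raise ValidationError("membership rows must match number of syncs")

    @property
    def n_syncs(self) -> int:
        return len(self.sync_times)

    def total_events(self, cell_id: str) -> int:
        return len(self.event_times[cell_id])

    def to_json(self, path: str) -> None:
        payload = {
            "cell_ids": self.cell_ids,
            "event_times": {c: t.tolist() for c, t in self.event_times.items()},
            "sync_times": self.sync_times.tolist(),
            "membership": self.membership.astype(int).tolist(),
            "ramping_cells": self.ramping_cells,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            event_times={c: np.asarray(t, float) for c, t in d["event_times"].items()},
            sync_times=np.asarray(d["sync_times"], float),
            membership=np.asarray(d["membership"], bool),
            ramping_cells={c: bool(v) for c, v in d["ramping_cells"].items()},
            cell_ids=list(d["cell_ids"]),
        )


def make_kernel(
    tau_s: float, rise_s: float, sample_rate_hz: float
) -> np.ndarray:
    """Unit-peak causal indicator kernel.

    Double exponential ``exp(-t/tau) - exp(-t/rise)`` normalised to peak 1,
    collapsing to a single decaying exponential when ``rise_s`` is 0.
    Truncated once the tail falls below 1e-4 of the peak.
    """
    if tau_s <= 0:
        raise ValueError("tau_s must be > 0")
    if rise_s < 0:
        raise ValueError("rise_s must be >= 0")
    if rise_s >= tau_s:
        raise ValueError("rise_s must be smaller than tau_s")
    dt = 1.0 / sample_rate_hz
    # decay to 1e-4 of peak takes ~ tau * ln(1e4) plus the rise-to-peak lag
    t_peak = 0.0
    if rise_s > 0:
        t_peak = np.log(tau_s / rise_s) * tau_s * rise_s / (tau_s - rise_s)
    horizon = t_peak + tau_s * np.log(1e4)
    t = np.arange(0.0, horizon + dt, dt)
    if rise_s > 0:
        k = np.exp(-t / tau_s) - np.exp(-t / rise_s)
    else:
        k = np.exp(-t / tau_s)
    k /= k.max()
    keep = np.nonzero(k >= 1e-4)[0]
    return k[: keep[-1] + 1]


def kernel_peak_lag_s(tau_s: float, rise_s: float) -> float:
    """Time from impulse to kernel peak (0 for a pure decay kernel)."""
    if rise_s <= 0:
        return 0.0
    return float(np.log(tau_s / rise_s) * tau_s * rise_s / (tau_s - rise_s))


def _poisson_times(
    rng: np.random.Generator,
    rate_per_h: float,
    t_lo: float,
    t_hi: float,
    min_sep: float = 0.0,
) -> np.ndarray:
    """Homogeneous Poisson event times on [t_lo, t_hi), optionally thinned
    so consecutive events are at least ``min_sep`` apart."""
    if rate_per_h <= 0 or t_hi <= t_lo:
        return np.empty(0)
    n = rng.poisson(rate_per_h * (t_hi - t_lo) / 3600.0)
    times = np.sort(rng.uniform(t_lo, t_hi, size=n))
    if min_sep > 0 and len(times) > 1:
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= min_sep:
                kept.append(t)
        times = np.asarray(kept)
    return times


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Gaussian amplitudes truncated at zero by redraw."""
    out = rng.normal(mean, sd, size=size)
    for _ in range(100):
        bad = out <= 0
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.maximum(out, 1e-6)


def duty_cycle_mask(timestamps: np.ndarray, on_s: float, off_s: float) -> np.ndarray:
    """Boolean mask of samples falling in the on-phase of a duty cycle."""
    period = on_s + off_s
    return (timestamps % period) < on_s


def _burst_waveform(
    duration_s: float, kernel: np.ndarray, dt: float
) -> Tuple[np.ndarray, int]:
    """Unit-peak waveform of one burst event and its peak-sample offset.

    A calcium "event" in these cells is a burst of spikes, not a single
    action potential: the firing-rate envelope is modelled as a symmetric
    triangle of the given duration, convolved with the indicator kernel.
    The triangular apex keeps the fluorescence peak sharp and unique, so
    true peak times are well defined.
    """
    n = max(int(round(duration_s / dt)), 1)
    env = 1.0 - np.abs(np.arange(n) - (n - 1) / 2) / max((n - 1) / 2, 1)
    w = np.convolve(env, kernel)
    ipk = int(np.argmax(w))
    return w / w[ipk], ipk


def simulate_session(
    spec: SimulationSpec,
) -> Tuple[TraceMatrix, List[CellMeta], GroundTruth]:
    """Generate one session: traces, cell coordinates and ground truth.

    Raw-unit traces are ``baseline_offset`` + burst events (triangular
    firing-rate envelopes convolved with the indicator kernel, durations
    uniform over ``burst_duration_s``) + optional pre-synchronization ramps
    + i.i.d. Gaussian noise. Sync membership is Bernoulli
    (``participation_p``) per cell; member peak times are the sync time
    plus Gaussian jitter. Fully reproducible from ``rng_seed``.
    """
    cfgwin = 40.0 * spec.indicator_tau_s
    if spec.duration_s < 2 * cfgwin:
        raise ValidationError(
            f"duration_s={spec.duration_s} too short to hold one baseline "
            f"window ({cfgwin:.1f} s) plus analysis span"
        )
    rng = np.random.default_rng(spec.rng_seed)
    dt = 1.0 / spec.sample_rate_hz
    t = np.arange(0.0, spec.duration_s, dt)
    n_t = len(t)
    cell_ids = [f"cell{i:03d}" for i in range(spec.n_cells)]

    kernel = make_kernel(spec.indicator_tau_s, spec.indicator_rise_s,
                         spec.sample_rate_hz)

    margin_hi = spec.duration_s - _EDGE_MARGIN_S
    sync_times = _poisson_times(
        rng, spec.sync_rate_per_h, _EDGE_MARGIN_S, margin_hi,
        min_sep=_MIN_SYNC_SEPARATION_S,
    )
    membership = rng.random((len(sync_times), spec.n_cells)) < spec.participation_p

    n_ramping = int(round(spec.ramping_fraction * spec.n_cells))
    ramping_idx = rng.choice(spec.n_cells, size=n_ramping, replace=False)
    ramping = {cell_ids[i]: bool(i in set(ramping_idx)) for i in range(spec.n_cells)}

    values = np.full((spec.n_cells, n_t), float(spec.baseline_offset))
    event_times: Dict[str, np.ndarray] = {}

    for i, cid in enumerate(cell_ids):
        ev = list(
            _poisson_times(
                rng, spec.baseline_event_rate_per_cell_per_h,
                _EDGE_MARGIN_S, margin_hi,
            )
        )
        for s, t_sync in enumerate(sync_times):
            if membership[s, i]:
                ev.append(t_sync + rng.normal(0.0, spec.peak_jitter_s))
        ev = np.sort(np.clip(np.asarray(ev), dt, spec.duration_s - 2 * dt))
        amps = _truncated_normal(
            rng, spec.amplitude_mean_sd[0], spec.amplitude_mean_sd[1], len(ev)
        )
        durations = rng.uniform(*spec.burst_duration_s, size=len(ev))
        true_peaks = np.empty(len(ev))
        for k, (t_pk, amp, dur) in enumerate(zip(ev, amps, durations)):
            w, ipk = _burst_waveform(dur, kernel, dt)
            # place the waveform so its apex lands on the requested peak time
            peak_idx = int(np.clip(round(t_pk / dt), 0, n_t - 1))
            start = peak_idx - ipk
            lo, hi = max(start, 0), min(start + len(w), n_t)
            values[i, lo:hi] += amp * w[lo - start: hi - start]
            true_peaks[k] = peak_idx * dt
        event_times[cid] = np.sort(true_peaks)

        if ramping[cid] and spec.ramp_slope != 0:
            for t_sync in sync_times:
                lo, hi = t_sync - 180.0, t_sync
                seg = (t >= lo) & (t < hi)
                values[i, seg] += spec.ramp_slope * (t[seg] - lo) / 60.0

    if spec.noise_sd > 0:
        values += rng.normal(0.0, spec.noise_sd, size=values.shape)

    coords = [
        CellMeta(cid, float(x), float(y))
        for cid, (x, y) in zip(
            cell_ids, rng.uniform(0.0, 500.0, size=(spec.n_cells, 2))
        )
    ]
    modality = "slice_gcamp" if spec.sample_rate_hz <= 5 else "miniscope"
    traces = TraceMatrix(cell_ids, t, values, modality=modality, units="raw")

    if spec.duty_cycle is not None:
        mask = duty_cycle_mask(t, *spec.duty_cycle)
        traces = TraceMatrix(
            cell_ids, t[mask], values[:, mask], modality=modality, units="raw"
        )

    gt = GroundTruth(
        event_times=event_times,
        sync_times=sync_times,
        membership=membership,
        ramping_cells=ramping,
        cell_ids=cell_ids,
    )
    return traces, coords, gt


def simulate_photometry_session(
    spec: SimulationSpec, include_405: bool = True
) -> Tuple[TraceMatrix, GroundTruth]:
    """Population photometry session: mean of per-cell traces plus a slow
    drift (sum of sinusoids, periods > 900 s), duty-cycled when requested.

    The 405-nm isosbestic row, when present, carries no calcium signal —
    just its own offset and noise — so channel subtraction removes the
    shared offset while the slow drift is left for baseline correction.
    """
    cell_spec = spec.model_copy(update={"duty_cycle": None})
    traces, _, gt = simulate_session(cell_spec)
    rng = np.random.default_rng(spec.rng_seed + 1)
    t = traces.timestamps
    pop = traces.values.mean(axis=0)
    if spec.drift_amplitude > 0:
        # photobleaching-like monotone decay over the session plus a gentle
        # physiological oscillation — both far slower than the 900-s
        # correction window, as real photometry drift is
        bleach = np.exp(-t / (0.75 * spec.duration_s))
        slow = 0.4 * np.sin(2 * np.pi * t / spec.duration_s
                            + rng.uniform(0, 2 * np.pi))
        pop = pop + spec.drift_amplitude * (bleach + slow)
    rows = [pop]
    ids = ["465"]
    if include_405:
        iso = spec.baseline_offset * 0.5 + rng.normal(
            0.0, max(spec.noise_sd, 1e-12), size=len(t)
        )
        rows.append(iso)
        ids.append("405")
    values = np.vstack(rows)
    if spec.duty_cycle is not None:
        mask = duty_cycle_mask(t, *spec.duty_cycle)
        t, values = t[mask], values[:, mask]
    return (
        TraceMatrix(ids, t, values, modality="photometry", units="raw"),
        gt,
    )


def simulate_spike_train(
    n_spikes: int, first_isi_s: float, adaptation_ratio_per_step: float
):
    """Spike train whose ISIs form a geometric sequence.

    ``ISI_k = first_isi_s * r**(k-1)`` with ``r = adaptation_ratio_per_step``;
    ``r = 1`` gives a constant-ISI (non-adapting) train, ``r > 1`` a train
    whose firing slows — spike-frequency adaptation.
    """
    from .model import SpikeTrain

    if adaptation_ratio_per_step <= 0:
        raise ValueError("adaptation ratio must be > 0")
    if n_spikes < 2:
        raise ValueError("need at least 2 spikes")
    if first_isi_s <= 0:
        raise ValueError("first_isi_s must be > 0")
    isis = first_isi_s * adaptation_ratio_per_step ** np.arange(n_spikes - 1)
    return SpikeTrain(np.concatenate([[0.0], np.cumsum(isis)]))


def slice_preset(seed: int = 0, **overrides) -> SimulationSpec:
    """In vitro brain-slice regime: 2 Hz, ~11 events/cell/h, mSEs with
    ~50% participation (single neurons participate in ~48% of mSEs)."""
    base = dict(
        n_cells=10, duration_s=2400.0, sample_rate_hz=2.0,
        baseline_event_rate_per_cell_per_h=11.3, sync_rate_per_h=9.0,
        participation_p=0.5, peak_jitter_s=3.0, amplitude_mean_sd=(30.0, 6.0),
        noise_sd=2.0, rng_seed=seed,
    )
    base.update(overrides)
    return SimulationSpec(**base)


def miniscope_preset(seed: int = 0, **overrides) -> SimulationSpec:
    """In vivo miniscope regime: 10 Hz, population SEs every ~10 min with
    ~80% participation, per-cell transients lasting tens of seconds
    (in vivo events run 30–130 s), a third of cells ramping before each SE.
    Extracted (CNMF-E-style) traces carry little sample noise, so the
    amplitude-to-noise ratio is high."""
    base = dict(
        n_cells=20, duration_s=3600.0, sample_rate_hz=10.0,
        baseline_event_rate_per_cell_per_h=2.0, sync_rate_per_h=6.0,
        participation_p=0.8, peak_jitter_s=3.0, amplitude_mean_sd=(10.0, 2.0),
        burst_duration_s=(40.0, 100.0), noise_sd=0.5,
        ramping_fraction=0.33, ramp_slope=0.3, rng_seed=seed,
    )
    base.update(overrides)
    return SimulationSpec(**base)


def ramping_preset(seed: int = 0, **overrides) -> SimulationSpec:
    """Miniscope-like session tuned for assessing the baseline-ramping
    classifier: no isolated background events, so the 7.5-min pre-SE blocks
    contain only the injected linear ramps plus noise (a green classifier
    test on this preset establishes clean-baseline behaviour, not robustness
    to transients inside the blocks)."""
    return miniscope_preset(
        seed,
        **{
            "baseline_event_rate_per_cell_per_h": 0.0,
            "sync_rate_per_h": 4.0,
            "duration_s": 7200.0,
            "ramping_fraction": 0.33,
            "ramp_slope": 0.3,
            "noise_sd": 0.5,
            **overrides,
        },
    )


def photometry_preset(seed: int = 0, **overrides) -> SimulationSpec:
    """Fiber photometry regime: 10 Hz in a 5 s-on/10 s-off schedule, 120-min
    session, population events once every ~19.5 min (the measured
    low-amplitude SE interval in intact males) lasting tens of seconds,
    slow drift to correct."""
    base = dict(
        n_cells=20, duration_s=7200.0, sample_rate_hz=10.0,
        baseline_event_rate_per_cell_per_h=2.0, sync_rate_per_h=3.1,
        participation_p=0.8, peak_jitter_s=3.0, amplitude_mean_sd=(10.0, 2.0),
        burst_duration_s=(40.0, 100.0), noise_sd=0.5,
        duty_cycle=(5.0, 10.0), drift_amplitude=3.0, rng_seed=seed,
    )
    base.update(overrides)
    return SimulationSpec(**base)
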