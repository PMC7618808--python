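"""Pipeline configuration.

Every detector threshold used anywhere in the pipeline lives here, so that
the in vitro (brain slice), in vivo (miniscope) and photometry variants of
the analysis are plain configuration profiles rather than code paths.
Defaults are the values used throughout the analysis of arcuate kisspeptin
(ARN KISS1) neuron recordings: a 2-Hz slice movie analysed in ΔF/F units, a
10-Hz miniscope recording in z-units, and a duty-cycled two-channel
photometry signal.
"""

from __future__ import annotations

from typing import Optional, Tuple

from pydantic import BaseModel, ConfigDict, model_validator

#: GCaMP6s fluorescence decay time constant, seconds.
GCAMP6S_TAU_S = 0.65

#: Multiplier turning the indicator decay constant into the trailing
#: baseline window for the ΔF/F computation (40 × 0.65 s = 26 s).
F0_WINDOW_TAU_MULTIPLE = 40.0


class PipelineConfig(BaseModel):
    """All tunable analysis parameters with their standard defaults.

    Attributes
    ----------
    f0_fraction
        Quantile defining the "lower 8%" of trailing ΔF samples whose mean
        is the running baseline F0.
    f0_window_s
        Length of the trailing F0 window in seconds. Defaults to
        40 × ``indicator_tau_s``; if omitted in a config file it is derived
        from the tau actually supplied.
    indicator_tau_s
        GCaMP6s decay time constant (s).
    event_threshold_sd
        Per-cell calcium event threshold, in SDs above the trace mean.
    flicker_window_s
        A suprathreshold re-crossing within this many seconds of the
        previous accepted event in the same cell is discarded as flicker.
    chain_window_s
        Maximum peak-to-peak gap between consecutive members of a
        synchronization chain (mSE / SE).
    baseline_band_sd
        Samples below mean + this·SD define the trace baseline used for
        event shape metrics.
    se_threshold_sd
        Per-cell excursion threshold (z) for in vivo synchronization
        events.
    se_min_cells
        Minimum number of co-active cells for a population SE ("more than
        5 cells" → 6).
    low_amp_min_duration_s
        Minimum above-threshold duration for a low-amplitude SE on a
        photometry trace.
    photometry_baseline_window_s
        Moving-window length of the slow-baseline (drift) estimator.
    ramp_block_edges_min
        Edges (minutes before the SE peak) of the two 3-min blocks used by
        the baseline-ramping classifier: (1.5, 4.5, 7.5).
    ramp_slope_change
        Relative slope change between the two blocks above which a cell is
        called "ramping" (0.05 = 5%).
    ramp_slope_floor
        Floor (z-units/min) for the denominator of the relative slope
        change, guarding near-zero early slopes.
    measurement_window_s
        Length of a drug-comparison measurement window (12 min).
    window_gap_s
        Wash-in/out gap between measurement windows (2 min).
    family_alpha
        Family-wise significance level used for Bonferroni thresholds.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    f0_fraction: float = 0.08
    f0_window_s: Optional[float] = None
    indicator_tau_s: float = GCAMP6S_TAU_S
    event_threshold_sd: float = 2.0
    flicker_window_s: float = 10.0
    chain_window_s: float = 10.0
    baseline_band_sd: float = 0.5
    se_threshold_sd: float = 1.0
    se_min_cells: int = 6
    low_amp_min_duration_s: float = 45.0
    photometry_baseline_window_s: float = 900.0
    photometry_baseline_quantile: float = 0.10
    ramp_block_edges_min: Tuple[float, float, float] = (1.5, 4.5, 7.5)
    ramp_slope_change: float = 0.05
    ramp_slope_floor: float = 0.01
    ramp_change_mode: str = "absolute"  # "absolute" (z/min) or "relative"
    measurement_window_s: float = 720.0
    window_gap_s: float = 120.0
    family_alpha: float = 0.05
    event_span_cap_s: float = 60.0
    threshold_scope: str = "window"  # "window" or "trace"
    grubbs_screen: bool = True
    grubbs_alpha: float = 0.05
    normality_alpha: float = 0.05
    mean_order_scope: str = "loo"  # "loo" (leave-one-out) or "pooled"
    rng_seed: int = 0

    @model_validator(mode="after")
    def _derive_and_check(self) -> "PipelineConfig":
        if self.f0_window_s is None:
            object.__setattr__(
                self, "f0_window_s", F0_WINDOW_TAU_MULTIPLE * self.indicator_tau_s
            )
        positive = [
            ("f0_fraction", self.f0_fraction),
            ("f0_window_s", self.f0_window_s),
            ("indicator_tau_s", self.indicator_tau_s),
            ("event_threshold_sd", self.event_threshold_sd),
            ("flicker_window_s", self.flicker_window_s),
            ("chain_window_s", self.chain_window_s),
            ("baseline_band_sd", self.baseline_band_sd),
            ("se_threshold_sd", self.se_threshold_sd),
            ("low_amp_min_duration_s", self.low_amp_min_duration_s),
            ("photometry_baseline_window_s", self.photometry_baseline_window_s),
            ("ramp_slope_change", self.ramp_slope_change),
            ("ramp_slope_floor", self.ramp_slope_floor),
            ("measurement_window_s", self.measurement_window_s),
            ("family_alpha", self.family_alpha),
        ]
        for name, value in positive:
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value!r}")
        if self.se_min_cells < 2:
            raise ValueError("se_min_cells must be >= 2")
        if not 0 < self.f0_fraction < 1:
            raise ValueError("f0_fraction must lie in (0, 1)")
        e = self.ramp_block_edges_min
        if not (0 < e[0] < e[1] < e[2]):
            raise ValueError("ramp_block_edges_min must be strictly increasing and > 0")
        if self.threshold_scope not in ("window", "trace"):
            raise ValueError("threshold_scope must be 'window' or 'trace'")
        if self.ramp_change_mode not in ("absolute", "relative"):
            raise ValueError("ramp_change_mode must be 'absolute' or 'relative'")
        if self.mean_order_scope not in ("loo", "pooled"):
            raise ValueError("mean_order_scope must be 'loo' or 'pooled'")
        return self
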