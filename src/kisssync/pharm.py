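"""Drug-effect statistics: windowed rates, normality-routed comparisons,
photometry infusion analysis, SE probability, and intrinsic-excitability
metrics (spike-frequency adaptation, ISI variability).

Slice pharmacology compares 12-min pre-drug / drug / wash measurement
windows separated by 2-min wash gaps; in vivo infusions compare the mean
z-scored photometry signal 40 min before, 10 min during and 40 min after
the infusion, together with the probability that at least one SE occurs
during the infusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .config import PipelineConfig
from .events import rate_per_cell_hour
from .model import (
    AnalysisWindow,
    CalciumEvent,
    SpikeTrain,
    SyncEvent,
    TraceMatrix,
    ValidationError,
    check_windows_disjoint,
)
from .sync import detect_low_amplitude_se


@dataclass
class TestResult:
    """Outcome of one routed two-sample comparison."""

    test_name: str
    statistic: float
    p_value: float
    n: int
    outliers_removed: int = 0


@dataclass
class TrialOutcome:
    """One infusion trial summarised."""

    trial_id: str
    drug: str
    se_during_infusion: bool
    se_count_during: int
    mean_z_pre: float
    mean_z_during: float
    mean_z_post: float
    amplitude_ratio: float = math.nan  # mean SE amplitude during+post / pre

    def __post_init__(self) -> None:
        for name in ("mean_z_pre", "mean_z_during", "mean_z_post"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")
        if not math.isnan(self.amplitude_ratio) and self.amplitude_ratio <= 0:
            raise ValidationError("amplitude_ratio must be > 0 when defined")


def windowed_rates(
    events: Sequence[CalciumEvent],
    syncs: Sequence[SyncEvent],
    windows: Sequence[AnalysisWindow],
    n_cells: int,
) -> Dict[str, Dict[str, float]]:
    """Event and synchronization rates (per cell per hour) per window.

    Events are assigned by peak time, syncs by reference time; activity in
    the wash-in/out gaps between windows counts toward no window. Also
    reports the participation-normalised mSE rate (cell-participations per
    cell per hour), since "per cell" admits either reading.
    """
    check_windows_disjoint(windows)
    out: Dict[str, Dict[str, float]] = {}
    for w in windows:
        ev_n = sum(1 for e in events if w.contains(e.peak_time))
        sy = [s for s in syncs if w.contains(s.reference_time)]
        participations = sum(s.n_cells for s in sy)
        out[w.label] = {
            "event_rate": rate_per_cell_hour(ev_n, n_cells, w),
            "sync_rate": rate_per_cell_hour(len(sy), n_cells, w),
            "participation_rate": rate_per_cell_hour(participations, n_cells, w),
            "n_events": float(ev_n),
            "n_syncs": float(len(sy)),
        }
    return out


def grubbs_outlier(values: np.ndarray, alpha: float = 0.05) -> Optional[int]:
    """Index of the single most extreme value if it fails Grubbs' test.

    Two-sided Grubbs at level ``alpha``; returns None when no outlier.
    """
    x = np.asarray(values, float)
    n = len(x)
    if n < 3 or x.std(ddof=1) == 0:
        return None
    g = np.abs(x - x.mean()) / x.std(ddof=1)
    i = int(np.argmax(g))
    t2 = stats.t.ppf(1 - alpha / (2 * n), n - 2) ** 2
    g_crit = (n - 1) / math.sqrt(n) * math.sqrt(t2 / (n - 2 + t2))
    return i if g[i] > g_crit else None


def compare_periods(
    pre: Sequence[float],
    post: Sequence[float],
    design: str = "paired",
    config: Optional[PipelineConfig] = None,
) -> TestResult:
    """Two-sided comparison routed by a Shapiro-Wilk normality check.

    Paired designs test the per-pair differences: paired t when normal,
    Wilcoxon signed-rank otherwise. Unpaired designs use Student's t or
    Mann-Whitney U. A single Grubbs outlier screen (at most one removal,
    on the differences for paired designs) runs first when enabled.
    """
    config = config or PipelineConfig()
    x = np.asarray(pre, float)
    y = np.asarray(post, float)
    removed = 0
    if design == "paired":
        if len(x) != len(y):
            raise ValidationError("paired design needs equal-length samples")
        if len(x) < 3:
            raise ValidationError("need at least 3 pairs")
        d = y - x
        if config.grubbs_screen:
            i = grubbs_outlier(d, config.grubbs_alpha)
            if i is not None:
                keep = np.ones(len(d), bool)
                keep[i] = False
                x, y, d = x[keep], y[keep], d[keep]
                removed = 1
        if np.all(d == 0):
            raise ValidationError("degenerate data: all paired differences zero")
        normal = stats.shapiro(d).pvalue > config.normality_alpha if len(d) >= 3 else True
        if normal:
            res = stats.ttest_rel(y, x)
            return TestResult("paired t", float(res.statistic), float(res.pvalue),
                              len(d), removed)
        res = stats.wilcoxon(y, x, zero_method="wilcox", mode="auto")
        return TestResult("wilcoxon signed-rank", float(res.statistic),
                          float(res.pvalue), len(d), removed)
    if design == "unpaired":
        if len(x) < 3 or len(y) < 3:
            raise ValidationError("need at least 3 observations per group")
        if config.grubbs_screen:
            pooled = np.concatenate([x, y])
            i = grubbs_outlier(pooled, config.grubbs_alpha)
            if i is not None:
                removed = 1
                if i < len(x):
                    x = np.delete(x, i)
                else:
                    y = np.delete(y, i - len(x))
        if x.std() == 0 and y.std() == 0 and x.mean() == y.mean():
            raise ValidationError("degenerate data: no variation in either group")
        normal = (
            stats.shapiro(x).pvalue > config.normality_alpha
            and stats.shapiro(y).pvalue > config.normality_alpha
        )
        if normal:
            res = stats.ttest_ind(x, y)
            return TestResult("unpaired t", float(res.statistic), float(res.pvalue),
                              len(x) + len(y), removed)
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        return TestResult("mann-whitney u", float(res.statistic), float(res.pvalue),
                          len(x) + len(y), removed)
    raise ValueError("design must be 'paired' or 'unpaired'")


def repeated_measures_anova(samples: Dict[str, Sequence[float]]) -> Dict[str, float]:
    """One-way repeated-measures ANOVA across labelled windows (thin wrapper:
    subjects × conditions), plus Dunnett-style paired t comparisons of every
    condition against the first label."""
    labels = list(samples)
    mat = np.column_stack([np.asarray(samples[k], float) for k in labels])
    n, k = mat.shape
    if n < 2 or k < 2:
        raise ValidationError("need >= 2 subjects and >= 2 conditions")
    grand = mat.mean()
    ss_cond = n * ((mat.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((mat.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((mat - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df_cond, df_err = k - 1, (k - 1) * (n - 1)
    f = (ss_cond / df_cond) / (ss_err / df_err)
    p = float(stats.f.sf(f, df_cond, df_err))
    out = {"F": float(f), "p_value": p, "df": (df_cond, df_err)}
    ref = labels[0]
    m = k - 1  # Bonferroni-adjusted Dunnett-style contrasts vs the reference
    for lab in labels[1:]:
        res = stats.ttest_rel(samples[lab], samples[ref])
        out[f"p_{lab}_vs_{ref}"] = float(min(1.0, res.pvalue * m))
    return out


def infusion_analysis(
    trace: TraceMatrix,
    infusion: AnalysisWindow,
    config: Optional[PipelineConfig] = None,
    trial_id: str = "trial",
    drug: str = "vehicle",
    pre_min: float = 40.0,
    post_min: float = 40.0,
) -> TrialOutcome:
    """Summarise one photometry infusion trial.

    Windows are fixed at ``pre_min`` before infusion start, the infusion
    itself, and ``post_min`` after infusion end. SEs are detected on the
    whole z trace; a trial is SE-positive when any SE reference time falls
    inside the infusion window. The amplitude ratio is the mean SE peak z
    during+post divided by the mean pre-infusion SE peak z (NaN when either
    side has no SEs).
    """
    config = config or PipelineConfig()
    if trace.units != "z" or trace.n_cells != 1:
        raise ValidationError("infusion_analysis expects a single-row z trace")
    t = trace.timestamps
    pre = AnalysisWindow("pre", infusion.start - pre_min * 60.0, infusion.start)
    post = AnalysisWindow("post", infusion.end, infusion.end + post_min * 60.0)
    if t[0] > pre.start + 1e-9 or t[-1] < post.end - 1e-9:
        raise ValidationError(
            "trace does not cover pre/during/post infusion windows"
        )
    x = trace.values[0]

    def mean_in(w: AnalysisWindow) -> float:
        sel = (t >= w.start) & (t < w.end)
        return float(x[sel].mean())

    ses = detect_low_amplitude_se(trace, config)
    during = [s for s in ses if infusion.contains(s.reference_time)]
    pre_amps = [s.mean_amplitude for s in ses if pre.contains(s.reference_time)]
    later_amps = [
        s.mean_amplitude
        for s in ses
        if infusion.contains(s.reference_time) or post.contains(s.reference_time)
    ]
    ratio = (
        float(np.mean(later_amps) / np.mean(pre_amps))
        if pre_amps and later_amps
        else math.nan
    )
    return TrialOutcome(
        trial_id=trial_id,
        drug=drug,
        se_during_infusion=bool(during),
        se_count_during=len(during),
        mean_z_pre=mean_in(pre),
        mean_z_during=mean_in(infusion),
        mean_z_post=mean_in(post),
        amplitude_ratio=ratio,
    )


def se_probability(
    outcomes: Dict[str, Sequence[TrialOutcome]],
) -> Dict[str, object]:
    """Per-condition SE-occurrence probability, with a 2×2 chi-squared test
    between two conditions.

    Returns percentages (7 of 8 positive trials → 87.5). The chi-squared
    statistic is the uncorrected Pearson statistic on the positive/negative
    contingency table.
    """
    if not outcomes or any(len(v) == 0 for v in outcomes.values()):
        raise ValidationError("every condition needs at least one trial")
    fractions = {
        cond: 100.0 * sum(o.se_during_infusion for o in trials) / len(trials)
        for cond, trials in outcomes.items()
    }
    result: Dict[str, object] = {"probability_pct": fractions}
    if len(outcomes) == 2:
        table = np.array(
            [
                [
                    sum(o.se_during_infusion for o in trials),
                    sum(not o.se_during_infusion for o in trials),
                ]
                for trials in outcomes.values()
            ]
        )
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        result["chi2"] = float(chi2)
        result["p_value"] = float(p)
    return result


def sfa_index(train: SpikeTrain) -> float:
    """Spike-frequency adaptation index: ISI following spike 1 divided by
    ISI following spike 10 (1 = no adaptation, 0.5 = a 50% reduction in
    firing rate by the tenth interval)."""
    if train.n_spikes < 11:
        raise ValidationError("SFA index needs at least 11 spikes")
    isis = train.isis()
    return float(isis[0] / isis[9])


def isi_profile(
    trains: Sequence[SpikeTrain], n_spikes: int = 30
) -> Dict[str, np.ndarray]:
    """Mean ± SEM inter-spike interval per spike number across trains.

    ``mean[k-1]`` is the average ISI following spike k over trains, with its
    SEM and coefficient of variation as variability summaries.
    """
    rows = []
    for j, tr in enumerate(trains):
        if tr.n_spikes < n_spikes + 1:
            raise ValidationError(
                f"train {j} has {tr.n_spikes} spikes; need {n_spikes + 1}"
            )
        rows.append(tr.isis()[:n_spikes])
    mat = np.vstack(rows)
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1) if len(rows) > 1 else np.zeros(n_spikes)
    return {
        "spike_number": np.arange(1, n_spikes + 1),
        "mean_isi_s": mean,
        "sem_isi_s": sd / math.sqrt(len(rows)),
        "cv": np.divide(sd, mean, out=np.zeros_like(sd), where=mean > 0),
    }


def _profile_metrics(lag: np.ndarray, prof: np.ndarray) -> Tuple[float, float]:
    """(half_width, decay_to_half) of an amplitude-normalised profile."""
    base = float(prof.min())
    peak_i = int(np.argmax(prof))
    half = base + 0.5 * (prof[peak_i] - base)
    above = prof >= half
    lo = peak_i
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = peak_i
    while hi < len(prof) - 1 and above[hi + 1]:
        hi += 1
    return float(lag[hi] - lag[lo]), float(lag[hi] - lag[peak_i])


def se_shape_comparison(
    profiles_pre: Sequence[Tuple[np.ndarray, np.ndarray]],
    profiles_post: Sequence[Tuple[np.ndarray, np.ndarray]],
    design: str = "unpaired",
    config: Optional[PipelineConfig] = None,
) -> Dict[str, object]:
    """Compare SE shape before vs during/after an infusion.

    Each profile is a ``(lag_s, values)`` pair; profiles are normalised to
    unit amplitude (so pure amplitude scaling cannot masquerade as a shape
    change) before half-width and decay-to-half are measured and compared
    with the routed two-sided test.
    """
    if not profiles_pre or not profiles_post:
        raise ValidationError("need at least one SE profile per side")

    def metrics(profiles):
        hw, dec = [], []
        for lag, prof in profiles:
            prof = np.asarray(prof, float)
            rng = prof.max() - prof.min()
            if rng <= 0:
                raise ValidationError("flat SE profile")
            normed = (prof - prof.min()) / rng
            h, d = _profile_metrics(np.asarray(lag, float), normed)
            hw.append(h)
            dec.append(d)
        return np.asarray(hw), np.asarray(dec)

    hw_pre, dec_pre = metrics(profiles_pre)
    hw_post, dec_post = metrics(profiles_post)
    out: Dict[str, object] = {  # noqa: C408 — explicit keys read better here
        "half_width_pre_s": float(hw_pre.mean()),
        "half_width_post_s": float(hw_post.mean()),
        "half_width_delta_s": float(hw_post.mean() - hw_pre.mean()),
        "decay_pre_s": float(dec_pre.mean()),
        "decay_post_s": float(dec_post.mean()),
        "decay_delta_s": float(dec_post.mean() - dec_pre.mean()),
    }
    if min(len(hw_pre), len(hw_post)) >= 3:
        for key, a, b in (("half_width_test", hw_pre, hw_post),
                          ("decay_test", dec_pre, dec_post)):
            try:
                out[key] = compare_periods(a, b, design, config)
            except ValidationError:
                out[key] = None  # degenerate (e.g. identical profile sets)
    return out
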