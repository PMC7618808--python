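# Methods

This note documents the analysis model the package implements, the defaults
and why they hold, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the procedure was genuinely
open.

## 1. Signal model and unit conversion

**Slice ΔF/F.** Raw somatic fluorescence `F_t` minus a background-ROI trace
`F_bg` is divided by a running baseline `F0(t)`: the mean of the samples at
or below the 8% quantile (linear-interpolation quantile) of the
background-subtracted signal over the trailing half-open window
`(t − 26 s, t]`. The window is 40 × the GCaMP6s decay constant
(τ = 0.65 s), long enough that a single transient cannot dominate its own
baseline. Two edge rules: windows holding fewer than ⌈1/0.08⌉ = 13 samples
fall back to the window minimum, and samples closer than one full window to
the recording start use the expanding available window and are flagged as
warm-up. Warm-up samples are excluded from downstream detection statistics
(whether the original analysis did this is unstated; excluding them avoids
the spuriously high ΔF/F the expanding window produces at the very start).
`F0 ≤ 0` anywhere is an error naming the cell and time, since the ratio is
then meaningless.

**In vivo z-scores.** Miniscope traces are standardised per cell over the
full recording (population-wide standardisation is available). Zero-variance
rows are errors, not silently passed.

**Photometry.** Order of operations: subtract the 405-nm isosbestic channel
from the 465-nm signal channel (a missing 405 row degrades to identity with
a logged warning), subtract a slow-baseline estimate, then z-score. The
baseline estimator generalises MATLAB's `msbackadj`: a centered rolling
10%-quantile envelope over 900 s, smoothed by a centered moving average of
the same width. *Working regime and limitation:* any envelope estimator with
900-s support can only track drift much slower than the window. Measured on
pure sinusoidal drift, the residual falls below 20% of the drift amplitude
only for periods ≳ 7200 s; at a period of 1800 s (twice the window) every
variant tested — this estimator, stepped-window quantile points with pchip
regression, Savitzky-Golay-smoothed envelopes — leaves 40–75% residual.
That is acceptable in practice because real photometry drift is dominated by
photobleaching and fiber/tissue warming, which evolve over tens of minutes
to the whole session; the 900-s window choice itself presumes that. Brief
events are preserved through the correction (measured: square events riding
on session-scale drift keep their height within 10%).

**Duty cycle.** 5 s-on/10 s-off recordings can be kept as acquired with
wall-clock timestamps (`concatenate`) or linearly filled onto the nominal
uniform grid with filled samples flagged (`interpolate`). The pipeline
interpolates photometry before baseline correction and event detection:
on concatenated data the measured above-threshold duration of an excursion
loses up to one off-period (10 s) at each threshold crossing, which biases
the ≥45-s low-amplitude-SE rule downward. Durations remain wall-clock in
either policy.

## 2. Event detection and shape

A calcium event is a maximal run of samples strictly above
`mean + 2 SD` of the analysis span, peaking at the run maximum (plateau
ties resolve to the earliest sample). A candidate peaking within 10 s
*after* the previous accepted peak in the same cell is discarded as
indicator flicker (the earlier event is kept). Detection statistics are
computed per 12-min measurement window when windows are supplied
(drug applications change the variance; windows are analysed independently)
and over the whole trace otherwise.

The mean+2SD rule is *relative*: it adapts to whatever the trace contains.
Its behaviour therefore depends on how much of the trace variance the
events themselves carry. On event-rich cells the threshold sits many noise
SDs above baseline and false detections are rare; on a nearly silent cell
the threshold converges to the 2.3% upper tail of the noise and chance
crossings are detected at a bounded rate (one per 10 s at most, via the
flicker rule). This is an inherent property of the published rule, not of
this implementation; the recovery tests therefore score sensitivity and
false-discovery on event-rich sessions (~200 true events), where the rule
is well-conditioned.

Shape metrics use the whole-trace baseline — the median of samples below
`mean + 0.5 SD` — and measure, with linear interpolation between samples:
half-width at baseline + 50% of (peak − baseline); rise time from the 20%
to the 80% level on the rising flank; decay time 80% → 20% on the falling
flank. The search span runs from the peak outward to the first baseline
crossings, capped at ±60 s so neighbouring events are not swallowed
(in vivo events run 30–130 s). A flank that never crosses a required level
leaves that metric NaN and logs it.

## 3. Synchronization clustering

mSE chaining is greedy and chronological: sort all events by peak time,
seed a chain at the earliest unassigned event, and admit each later
unassigned event whose peak lies within 10 s of the chain's *current last*
peak. A cell contributes at most its earliest qualifying event per chain; a
second event from the same cell is left unassigned and may seed the next
chain. Chains with ≥2 distinct cells are mSEs. Greedy chaining (rather than
transitive-closure clustering) matches the incremental wording of the rule:
membership is judged against "the previous event peak" of the growing
cluster.

In vivo SEs reuse the same machinery: per cell, excursions above 1 SD are
extracted with their peaks and chained identically; chains with more than 5
distinct cells are SEs. One debounce is applied at the excursion level:
consecutive suprathreshold runs in the same cell separated by a
sub-threshold gap shorter than 10 s merge into one excursion. Without it,
sample noise dithering at a threshold crossing splits one long transient
into several pieces whose spurious late peaks chain into phantom SEs (the
open question of what counts as one "increase in fluorescence" is resolved
as: one excursion, allowing sub-10-s interruptions).

Low-amplitude photometry SEs are excursions of the corrected z trace above
1 SD sustained for ≥45 s, with the same debounce.

Participation statistics report, in percent, each cell's share of
synchronizations and each synchronization's share of recorded cells, plus
the fractions of cells in ≥1, all, or exactly one synchronization. Because
"mSE rate per cell" admits two readings, `windowed_rates` reports both the
mSE count normalised by cells and hours *and* the participation count
normalised the same way.

## 4. Activation order

Ranks are assigned within each qualifying synchronization by member peak
time (average ranks on ties). Synchronizations with fewer than 5 cells are
excluded and at least 3 must survive, otherwise the session is declared not
analyzable. Mean order uses only the synchronizations a cell joined —
non-participation is not last place.

The consistency statistic pools (per-sync rank, comparison rank) pairs over
all participations and takes their Spearman correlation. The comparison
ranking for sync *s* is built from each cell's mean order computed with
sync *s* excluded. This leave-one-sync-out construction matters: ranking
cells by their plain all-sync mean order correlates with the scored ranks by
construction (measured null mean rho ≈ +0.42 at 10 cells × 5 syncs, about
`1/sqrt(n_syncs)`), and even per-pair leave-one-out means retain a −0.05
within-cell self-exclusion bias. With the left-out-sync ranking the
comparison is independent of the scored sync and the permutation-null mean
rho is ≈ −0.01. Perfectly repeated orders still give rho = 1. The naive
pooled variant remains available (`mean_order_scope="pooled"`) for
comparison with analyses that used it; its rho values are inflated at small
sync counts. Bonferroni thresholds are `family_alpha / n_tests` with
`n_tests` supplied by the caller (7 sessions → 0.007).

The spatial order map joins ranks to cell coordinates and reports a
descriptive direction statistic: the circular mean and resultant length of
the unit displacement vectors between consecutively activated cells
(1 = perfect wave; compare against a within-session shuffle null).

## 5. Baseline ramping and block spectra

For each (cell, SE) pair with 7.5 min of clean pre-peak trace, ordinary
least-squares slopes (z-units/min) are fitted to the blocks 4.5–7.5 min
("early") and 1.5–4.5 min ("late") before the peak. The default
classification is **absolute**: ramping when
`|slope_late − slope_early| > 0.05 z/min`. The published rule — "a change
in slope > 5%" — does not define its denominator; reading it as a relative
change between the block slopes makes the classifier degenerate whenever
the early slope is near zero, because the slope *estimate* of a flat noisy
block has an SE of ~0.006–0.014 z/min and the 5%-relative criterion then
fires on essentially every quiet cell (measured false-positive rate ≈ 1).
Reading "5%" as 5% of a z-unit per minute gives a well-conditioned absolute
criterion: ~3–8 estimation SEs on typical blocks. The relative rule, with
its 0.01 z/min denominator floor, remains available
(`ramp_change_mode="relative"`). Ramping is only assessable when no other
SE falls inside the 8.5 min before the scored peak; transients inside the
blocks dominate the fitted slopes.

Block spectra are plain periodograms of each 3-min block, linearly
detrended (so a ramp does not masquerade as low-frequency power) and scaled
so the power sums to the detrended block variance. Note that raw
periodogram bins on white noise are approximately exponential: the largest
of ~900 bins is routinely ~10× the median bin, so "no isolated peak" must
be judged against the exponential-null Bonferroni bound
`mean × ln(n_bins/α)`, which the tests use.

## 6. Pharmacology and excitability

Window rates assign events by peak time and synchronizations by their first
member peak (reference time); gap-period activity counts toward no window.
Pre/post comparisons route on a Shapiro-Wilk normality check
(α = 0.05): paired t or Wilcoxon signed-rank for paired designs, Student's
t or Mann-Whitney U for unpaired, all two-sided, with an optional
single-removal Grubbs outlier screen (default on, at most one point, as in
the original analysis). Measured type-I error of the routed paired test on
Gaussian nulls (n = 8, 2000 replicates): 0.061 with the screen on, 0.045
off. Repeated-measures pre/during/post comparisons are a standard one-way
RM-ANOVA wrapper with Bonferroni-adjusted paired contrasts against "pre" —
a labelled convenience, not novel statistics.

Infusion trials fix 40/10/40-min windows around the infusion, detect SEs on
the whole corrected trace, call a trial SE-positive when any SE's reference
time falls inside the infusion window (onset is what the infusion can
causally gate), and form the amplitude ratio from per-SE peak z during+post
over pre. SE probability across trials is a percentage per condition with
an uncorrected 2×2 Pearson chi-squared between two conditions.

SFA index = ISI after spike 1 ÷ ISI after spike 10 (≥11 spikes required);
it is invariant to time translation and uniform rescaling. ISI profiles
report mean ± SEM and the coefficient of variation of the k-th ISI across
trains. SE shape comparisons normalise each profile to unit amplitude
before measuring half-width and decay-to-half, so amplitude changes cannot
masquerade as kinetic changes.

## 7. The synthetic world

`simulate_session` generates: a constant baseline offset (100 a.u.);
per-cell *burst* events — a symmetric triangular firing-rate envelope
convolved with the indicator kernel (double exponential, rise 0.2 s, decay
0.65 s, unit peak, truncated at 10⁻⁴) — at a homogeneous Poisson background
rate; scheduled synchronizations (Poisson, thinned to ≥60-s separation
because real SEs are discrete episodes minutes apart) with independent
Bernoulli membership and Gaussian member-peak jitter; optional linear
baseline ramps over the 3 min before each synchronization in a fixed subset
of cells; and i.i.d. Gaussian sample noise. Photometry sessions average the
cell traces, add bleaching-like drift (exponential decay over ~0.75 of the
session plus one session-period sinusoid), an isosbestic row without
calcium signal, and the 5 s-on/10 s-off duty mask.

Defaults are the measured regimes of the system: 11.3 background
events/cell/h and ~50% mSE participation in vitro; SEs every ~10 min with
~80% participation in vivo; low-amplitude SEs every ~19.5 min for the
photometry preset; peak jitter SD 3 s so member spreads of ~10 s (up to
20 s) occur in the tails; a third of cells ramping at 0.3 units/min. Burst
durations are 2–8 s in vitro and 40–100 s in vivo — within the reported
30–130 s per-cell event range and calibrated so the population SE
half-width (≈ half the mean triangle base) matches the measured ≈34-s SE
half-width. Event amplitudes are Gaussian truncated at zero (no amplitude
distribution is reported; truncated-Gaussian is the simplest positive
choice). Noise SDs give amplitude-to-noise ratios of 15 (slice, raw imaging
of somatic ROIs) and 20 (in vivo, CNMF-E-extracted traces, which are
denoised model reconstructions and carry little sample noise).

What a green test on this world establishes — and what it does not: the
generator has no bleaching within cells, no motion artifacts, no correlated
(pink) noise, no cross-contamination between ROIs, no cell-specific latency
structure inside synchronizations, and no refractory interaction between
background events and synchronizations. Detector recovery on it validates
the *rules*, not robustness to those real-data pathologies. Ramping
accuracy is assessed on a dedicated preset without background events; it
establishes clean-baseline classification, not robustness to transients
inside the slope blocks.

## 8. Determinism and numerics

Every stochastic choice flows from one `numpy` `default_rng` seed; two runs
with the same spec and seed are bit-identical, and the pipeline manifest
records config, input hashes and seed so a run is reproducible from the
manifest alone. Trace CSVs are written at 17 significant digits (float64
round-trip). Quantiles use linear interpolation. Half-width/rise/decay
crossings interpolate linearly between samples and include one sample
beyond the event span so step edges are measurable. Spearman correlations
use average ranks; the chi-squared test is uncorrected Pearson on the 2×2
table; Grubbs critical values use the standard t-based formula.

## 9. Known limitations

- The baseline-shift estimator does not remove drift with periods below
  ~4× its window (see §1); configure a shorter window for faster drift.
- The mean+2SD event rule is noise-limited on nearly silent cells (§2);
  rates from such cells reflect the rule, and shape analyses should be
  restricted to active cells (the active-in-both-windows and ≥3-neuron
  rules are available as config values).
- `detect_ramping` assumes the pre-SE blocks are free of other SEs; the
  caller must exclude contaminated epochs (the pipeline stage skips SEs
  without 7.5 min of in-recording history but does not yet screen for
  neighbouring SEs).
- The spatial direction statistic is descriptive; no wave-propagation model
  is fitted.
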