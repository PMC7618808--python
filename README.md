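# kisssync

Analysis pipeline for calcium-imaging studies of **arcuate kisspeptin
(ARN KISS1) neuron synchronization** — the hypothalamic population that acts
as the GnRH pulse generator. These neurons fire in episodic, population-wide
synchronizations; understanding how individual cells recruit into those
episodes requires the same chain of operations across three recording
modalities:

- **brain-slice GCaMP movies** (2 Hz): ΔF/F conversion, per-cell calcium
  event detection, clustering of events into *miniature synchronization
  events* (mSEs), and drug-window rate statistics;
- **in vivo miniscope recordings** (10 Hz): z-scoring, population
  *synchronization event* (SE) detection, activation-order consistency,
  pre-SE baseline-ramping classification and per-block spectra;
- **fiber photometry** (465/405 nm, 10 Hz, 5 s-on/10 s-off duty cycle):
  channel subtraction, slow-baseline correction, low-amplitude SE detection
  and infusion statistics.

It also quantifies intrinsic excitability from whole-cell recordings
(spike-frequency adaptation, ISI variability) and ships a synthetic-session
generator with exact ground truth so every stage is testable without any
recording on disk.

## The core definitions

- **ΔF/F**: `(F_t − F_bg) / F0(t)` where `F0(t)` is the mean of the lower 8%
  of background-subtracted fluorescence over the trailing 26 s
  (40 × the GCaMP6s decay constant τ = 0.65 s).
- **Calcium event**: a maximal run of ΔF/F (or z) samples above
  `mean + 2 SD` of the trace, peaking at the run maximum; a re-crossing
  within 10 s of the previous event's peak in the same cell is discarded as
  indicator flicker.
- **mSE**: events from ≥2 cells chained by peak time — each new member must
  peak within 10 s of the previous member's peak.
- **SE (in vivo)**: the same chaining applied to >1-SD excursions, requiring
  more than 5 participating cells.
- **Low-amplitude SE (photometry)**: an excursion above 1 SD of the mean
  sustained for ≥45 s.
- **Rates** are reported per cell per hour; drug comparisons use 12-min
  measurement windows separated by 2-min wash gaps, and infusions use
  40/10/40-min pre/during/post windows.
- **SFA index**: ISI following spike 1 ÷ ISI following spike 10
  (1 = no adaptation, 0.5 = a 50% rate reduction).

## Worked example

```python
from kisssync.synthetic import slice_preset, simulate_session
from kisssync.preprocessing import compute_dff
from kisssync.events import detect_events_matrix, rate_per_cell_hour, percent_change
from kisssync.sync import cluster_mse, participation_stats
from kisssync.model import AnalysisWindow

spec = slice_preset(seed=1)                      # 10 cells, 40 min at 2 Hz
traces, cells, truth = simulate_session(spec)    # raw traces + ground truth
dff = compute_dff(traces)                        # trailing lower-8% baseline
events = detect_events_matrix(dff)               # mean + 2 SD, 10-s flicker
mses = cluster_mse(events)                       # 10-s peak chaining
window = AnalysisWindow("session", 0.0, spec.duration_s)
print(len(events), rate_per_cell_hour(len(events), traces.n_cells, window))
print(len(mses), participation_stats(mses, traces.cell_ids)["mean_per_cell_pct"])
print(percent_change(8.7, 1.6))
```

prints (seed 1):

```
cells: 10, 40-min session at 2 Hz
events detected: 138  (20.7 events/cell/h)
mSEs: 24  (3.60 mSE/cell/h)
scheduled synchronizations in ground truth: 8
mean per-cell mSE participation: 33.8%
pre->post demo: percent_change(8.7, 1.6) = 82%
```

The 138 detected events are the per-cell suprathreshold transients
(scheduled synchronization members, background events, and chance
threshold crossings on sparse cells); the 24 mSEs include the 8 scheduled
synchronizations plus chance coincidences of background events, exactly as
the chaining rule defines them. `percent_change` is the pre→post drug
reduction used for rate comparisons (8.7 → 1.6 events/cell/h is an 82%
reduction).

## Command line

```bash
kisssync simulate --preset slice --seed 1 --out session/
kisssync run --input session/ --modality slice_gcamp --out results/
```

`run` executes preprocess → detect → sync → order/ramp → pharm and writes a
`manifest.json` (config echo, input hashes, seed, stage timings, output
inventory) that fully determines a re-run. Single-stage subcommands
(`preprocess`, `detect`, `sync`, `order`, `ramp`, `pharm`) expose the same
operations on existing tables.

## Acceptance script

`scripts/acceptance.py` recomputes the package's acceptance quantities from
scratch — it builds the required inputs with the synthetic generator, runs
the corresponding analysis operation, and writes one JSON object per target:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

```
src/kisssync/
  config.py         analysis constants (all thresholds, one config object)
  model.py          TraceMatrix, CalciumEvent, SyncEvent, windows, spike trains
  io.py             CSV/HDF5 trace tables, event/sync tables, manifests
  synthetic.py      session generator with ground truth + modality presets
  preprocessing.py  ΔF/F, z-scoring, photometry correction, duty cycle
  events.py         event detection, shape metrics, rate normalisation
  sync.py           mSE chaining, SE detection, participation statistics
  temporal.py       activation order, spatial maps, ramping, block spectra
  pharm.py          windowed rates, routed tests, infusions, SFA/ISI
  pipeline.py       staged runs, config validation, run manifests
  cli.py            `kisssync` command group
```

See `docs/methods.md` for the model assumptions, parameter defaults, the
synthetic world the generator emulates, and known limitations.
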