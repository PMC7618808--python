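"""End-to-end orchestration: config validation, staged runs, manifests.

A run reads a trace matrix (plus optional windows, coordinates and
background traces) from an input directory, executes the stages enabled for
its modality — preprocess → detect → sync → order/ramp → pharm — and writes
every output table plus a JSON manifest (config echo, input hashes, seed,
per-stage timing and output inventory) that fully determines a re-run.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .io import (
    file_sha256,
    read_cell_meta,
    read_trace_matrix,
    read_windows,
    write_events,
    write_trace_matrix,
)
from .model import AnalysisWindow, TraceMatrix, ValidationError
from .preprocessing import (
    compute_dff,
    correct_photometry,
    regularize_duty_cycle,
    zscore_traces,
)
from .events import detect_events_matrix
from .sync import (
    cluster_mse,
    detect_low_amplitude_se,
    detect_population_se,
    participation_stats,
)
from .temporal import (
    NotAnalyzableError,
    build_order_table,
    detect_ramping,
    order_correlation,
)
from .pharm import windowed_rates

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    config: Dict
    inputs: Dict[str, str]  # path -> sha256
    outputs: List[str] = field(default_factory=list)
    seed: int = 0
    package_version: str = __version__
    stage_seconds: Dict[str, float] = field(default_factory=dict)
    stage_counts: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True, default=str)


def validate_config(path: Optional[str]) -> PipelineConfig:
    """Load and validate a JSON config; unknown keys are rejected and every
    omitted key takes its standard default (an empty file is a full default
    config; ``f0_window_s`` omitted derives 40 × indicator tau)."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        text = fh.read().strip()
    raw = json.loads(text) if text else {}
    try:
        return PipelineConfig(**raw)
    except Exception as exc:  # pydantic error carries the key path
        raise ValidationError(f"invalid config {path}: {exc}") from exc


def _default_windows(traces: TraceMatrix, config: PipelineConfig) -> List[AnalysisWindow]:
    """Pre/drug/wash measurement windows (12 min each, 2-min gaps) laid out
    from the start of the recording, as many as fit."""
    labels = ["pre_drug", "drug", "wash"]
    windows = []
    t0 = float(traces.timestamps[0])
    for i, label in enumerate(labels):
        start = t0 + i * (config.measurement_window_s + config.window_gap_s)
        end = start + config.measurement_window_s
        if end <= traces.timestamps[-1] + 1e-9:
            windows.append(AnalysisWindow(label, start, end))
    return windows or [
        AnalysisWindow("all", t0, float(traces.timestamps[-1]) + 1e-9)
    ]


def run_pipeline(
    config_path: Optional[str],
    input_dir: str,
    out_dir: str,
    modality: str = "slice_gcamp",
    seed: int = 0,
) -> RunManifest:
    """Execute the staged analysis for one session directory.

    ``input_dir`` must hold ``traces.csv`` (or ``traces.h5``); optional
    ``windows.json``, ``cells.csv`` and ``background.csv`` refine the run.
    Deterministic: identical inputs, config and seed give identical outputs.
    """
    os.makedirs(out_dir, exist_ok=True)
    config = validate_config(config_path)
    inputs: Dict[str, str] = {}
    if config_path:
        inputs[config_path] = file_sha256(config_path)

    trace_path = None
    for cand in ("traces.csv", "traces.h5"):
        p = os.path.join(input_dir, cand)
        if os.path.exists(p):
            trace_path = p
            break
    if trace_path is None:
        raise StageError("read", FileNotFoundError(f"no traces.csv/h5 in {input_dir}"))
    inputs[trace_path] = file_sha256(trace_path)

    manifest = RunManifest(config=json.loads(config.model_dump_json()),
                           inputs=inputs, seed=seed)
    outputs: List[str] = []

    def _out(name: str) -> str:
        path = os.path.join(out_dir, name)
        outputs.append(path)
        return path

    def _stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                manifest.stage_seconds[name] = round(
                    time.perf_counter() - self_inner.t0, 6
                )
                if exc is not None:
                    manifest.outputs = outputs
                    manifest.write(os.path.join(out_dir, "manifest.json"))
                    raise StageError(name, exc) from exc

        return _Timer()

    traces = read_trace_matrix(trace_path, modality)

    win_path = os.path.join(input_dir, "windows.json")
    if os.path.exists(win_path):
        inputs[win_path] = file_sha256(win_path)
        windows = read_windows(win_path)
    else:
        windows = _default_windows(traces, config)

    with _stage("preprocess"):
        if modality == "photometry":
            processed = correct_photometry(
                regularize_duty_cycle(traces, "interpolate"), config
            )
        elif modality == "miniscope":
            processed = zscore_traces(traces, per="cell")
        else:
            bg_path = os.path.join(input_dir, "background.csv")
            background = None
            if os.path.exists(bg_path):
                inputs[bg_path] = file_sha256(bg_path)
                background = read_trace_matrix(bg_path, modality).values
            processed = compute_dff(traces, background, config)
        write_trace_matrix(processed, _out("processed.csv"))
        manifest.stage_counts["preprocess"] = {
            "n_cells": processed.n_cells, "n_samples": processed.n_samples,
        }

    with _stage("detect"):
        if modality == "photometry":
            events = []
        else:
            events = detect_events_matrix(processed, config, windows)
        write_events(events, _out("events.csv"))
        manifest.stage_counts["detect"] = {"n_events": len(events)}

    with _stage("sync"):
        if modality == "photometry":
            syncs = detect_low_amplitude_se(processed, config)
        elif modality == "miniscope":
            syncs = detect_population_se(processed, config)
        else:
            syncs = cluster_mse(events, config)
        write_events(syncs, _out("syncs.csv"))
        manifest.stage_counts["sync"] = {"n_syncs": len(syncs)}
        if syncs and processed.n_cells > 1:
            with open(_out("participation.json"), "w") as fh:
                json.dump(participation_stats(syncs, processed.cell_ids), fh,
                          indent=1)

    with _stage("order"):
        order_report = {"analyzable": False}
        if modality != "photometry" and syncs:
            try:
                table = build_order_table(syncs)
                rho, p, bonf = order_correlation(table, n_tests=1, config=config)
                table.ranks.to_csv(_out("order_ranks.csv"), index=False)
                order_report = {
                    "analyzable": True, "rho": rho, "p_value": p,
                    "bonferroni_threshold": bonf,
                    "n_syncs": table.n_syncs,
                }
            except NotAnalyzableError as exc:
                order_report = {"analyzable": False, "reason": str(exc)}
        with open(_out("order.json"), "w") as fh:
            json.dump(order_report, fh, indent=1)

    with _stage("ramp"):
        ramp_rows = []
        if modality == "miniscope" and syncs:
            need_s = config.ramp_block_edges_min[2] * 60.0
            for si, s in enumerate(syncs):
                if s.reference_time - processed.timestamps[0] < need_s:
                    continue
                for i, cid in enumerate(processed.cell_ids):
                    flag, early, late = detect_ramping(
                        processed.timestamps, processed.values[i],
                        s.reference_time, config,
                    )
                    ramp_rows.append((si, cid, flag, early, late))
        pd.DataFrame(
            ramp_rows,
            columns=["sync_id", "cell_id", "is_ramping",
                     "slope_early_per_min", "slope_late_per_min"],
        ).to_csv(_out("ramping.csv"), index=False)
        manifest.stage_counts["ramp"] = {"n_flags": len(ramp_rows)}

    with _stage("pharm"):
        if modality != "photometry" and len(windows) >= 2:
            rates = windowed_rates(events, syncs, windows, traces.n_cells)
            with open(_out("window_rates.json"), "w") as fh:
                json.dump(rates, fh, indent=1)

    manifest.inputs = inputs
    manifest.outputs = sorted(outputs)
    manifest.write(os.path.join(out_dir, "manifest.json"))
    return manifest
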