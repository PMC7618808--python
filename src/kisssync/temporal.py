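"""Activation-order statistics, spatial order maps, baseline ramping and
per-block spectra.

Across repeated synchronizations, each participating cell gets a rank by
its peak time; the consistency of those ranks against each cell's mean
order is summarised by a Spearman correlation. Before each in vivo SE, the
least-squares slopes of two 3-min baseline blocks (4.5–7.5 and 1.5–4.5 min
before the peak) classify a cell as "ramping" when the slope changes by
more than 5%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal, stats

from .config import PipelineConfig
from .model import CellMeta, SyncEvent, ValidationError


class NotAnalyzableError(ValidationError):
    """Session fails the minimum-data filters for this analysis."""


@dataclass
class OrderTable:
    """Activation ranks: one row per qualifying sync, one column per cell.

    ``ranks.iloc[s, i]`` is cell i's peak-time rank within sync s (1 =
    earliest, average ranks on ties, NaN = non-participant). Mean order per
    cell uses only the syncs that cell joined (non-participation is not
    last place).
    """

    ranks: pd.DataFrame

    @property
    def n_syncs(self) -> int:
        return len(self.ranks)

    @property
    def cell_ids(self) -> List[str]:
        return list(self.ranks.columns)

    def mean_order(self) -> pd.Series:
        return self.ranks.mean(axis=0, skipna=True)

    def cell_ranking(self) -> List[str]:
        """Cells sorted by mean order (earliest first)."""
        return list(self.mean_order().sort_values(kind="mergesort").index)


def build_order_table(
    syncs: Sequence[SyncEvent],
    min_cells_per_sync: int = 5,
    min_syncs: int = 3,
) -> OrderTable:
    """Rank members of each qualifying sync by peak time.

    Syncs with fewer than ``min_cells_per_sync`` members are excluded; at
    least ``min_syncs`` must survive, otherwise the session is not
    analyzable for order consistency.
    """
    kept = [s for s in syncs if s.n_cells >= min_cells_per_sync]
    if len(kept) < min_syncs:
        raise NotAnalyzableError(
            f"only {len(kept)} syncs with >= {min_cells_per_sync} cells; "
            f"need at least {min_syncs}"
        )
    cells = sorted({c for s in kept for c in s.member_cells})
    rows = []
    for s in kept:
        times = np.array([m[1] for m in s.members])
        ranks = stats.rankdata(times, method="average")
        row = {c: math.nan for c in cells}
        for (cid, _, _), r in zip(s.members, ranks):
            row[cid] = float(r)
        rows.append(row)
    return OrderTable(pd.DataFrame(rows, columns=cells))


def order_pairs(
    table: OrderTable, mean_order_scope: str = "loo"
) -> Tuple[np.ndarray, np.ndarray]:
    """Pooled (per-sync rank, cell mean-order rank) pairs over all
    participations.

    ``mean_order_scope='loo'`` ranks the cells of each sync by their mean
    order computed with that sync left out entirely, so the comparison
    ranking is statistically independent of the sync being scored — under a
    null of independent random orders the pooled correlation is exactly
    mean-zero. Cells participating in no other sync are dropped from that
    sync's pairs. ``'pooled'`` uses the plain all-sync mean order (the
    naive reading; note it is positively self-correlated when few syncs
    are available).
    """
    R = table.ranks.to_numpy()
    n_syncs, n_cells = R.shape
    present = ~np.isnan(R)
    with np.errstate(invalid="ignore"):
        col_sum = np.nansum(R, axis=0)
        col_n = present.sum(axis=0)
    xs, ys = [], []
    for s in range(n_syncs):
        if mean_order_scope == "loo":
            cells = [
                i for i in range(n_cells)
                if present[s, i] and col_n[i] - 1 >= 1
            ]
            if not cells:
                continue
            loo_mean = np.array(
                [(col_sum[i] - R[s, i]) / (col_n[i] - 1) for i in cells]
            )
            y_rank = stats.rankdata(loo_mean, method="average")
            xs.extend(R[s, i] for i in cells)
            ys.extend(y_rank)
        else:
            for i in range(n_cells):
                if present[s, i]:
                    xs.append(R[s, i])
                    ys.append(col_sum[i] / col_n[i])
    return np.asarray(xs), np.asarray(ys)


def order_correlation(
    table: OrderTable,
    n_tests: int = 1,
    config: Optional[PipelineConfig] = None,
) -> Tuple[float, float, float]:
    """Spearman consistency of activation order within one session.

    Pools (per-sync rank, mean-order) pairs over all participations and
    returns (rho, two-sided p, Bonferroni threshold = family_alpha /
    n_tests) — with 7 sessions in a family, 0.05/7 ≈ 0.007.
    """
    config = config or PipelineConfig()
    x, y = order_pairs(table, config.mean_order_scope)
    if len(x) < 3:
        raise NotAnalyzableError("fewer than 3 pooled order pairs")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p), config.family_alpha / n_tests


def spatial_order_map(
    syncs: Sequence[SyncEvent],
    cells: Sequence[CellMeta],
    sync_index: int,
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Activation ranks joined to imaging-plane coordinates for one sync.

    Also returns a descriptive direction statistic: the circular mean angle
    and resultant length of the unit displacement vectors between
    consecutively activated cells (resultant length 1 = a perfect
    directional wave, near 0 = no consistent direction).
    """
    se = syncs[sync_index]
    if se.n_cells < 2:
        raise ValidationError("single-member sync: no displacement defined")
    coords = {c.cell_id: (c.x, c.y) for c in cells}
    missing = [c for c in se.member_cells if c not in coords]
    if missing:
        raise ValidationError(f"missing coordinates for cells: {missing}")
    rows = []
    for rank, (cid, t_pk, _) in enumerate(se.members, start=1):
        x, y = coords[cid]
        rows.append((cid, x, y, rank, t_pk))
    df = pd.DataFrame(rows, columns=["cell_id", "x", "y", "rank", "peak_time_s"])
    dx = np.diff(df["x"].to_numpy())
    dy = np.diff(df["y"].to_numpy())
    norms = np.hypot(dx, dy)
    ok = norms > 0
    if not ok.any():
        raise ValidationError("all consecutive cells co-located; no direction")
    angles = np.arctan2(dy[ok], dx[ok])
    resultant = np.mean(np.exp(1j * angles))
    direction = {
        "circular_mean_rad": float(np.angle(resultant)),
        "resultant_length": float(np.abs(resultant)),
        "n_steps": int(ok.sum()),
    }
    return df, direction


def _ols_slope_per_min(t_s: np.ndarray, x: np.ndarray) -> float:
    """Least-squares slope in units per minute."""
    t_min = np.asarray(t_s, float) / 60.0
    A = np.vstack([t_min - t_min.mean(), np.ones_like(t_min)]).T
    slope, _ = np.linalg.lstsq(A, np.asarray(x, float), rcond=None)[0]
    return float(slope)


def detect_ramping(
    timestamps: np.ndarray,
    values: np.ndarray,
    se_peak_time: float,
    config: Optional[PipelineConfig] = None,
) -> Tuple[bool, float, float]:
    """Classify pre-SE baseline ramping for one cell.

    Fits ordinary least-squares slopes (z-units/min) to the two 3-min
    blocks ending 4.5 and 1.5 min before the SE peak. In the default
    ``absolute`` mode the cell is ramping when
    ``|slope_late − slope_early| > ramp_slope_change`` z-units/min (a 5%
    z-score change per minute). The ``relative`` mode instead tests
    ``|slope_late − slope_early| / max(|slope_early|, slope_floor)`` against
    the same threshold; note that with a near-zero early slope this ratio is
    dominated by slope-estimation noise and flags almost every cell on noisy
    traces. Returns ``(is_ramping, slope_early, slope_late)``.
    """
    config = config or PipelineConfig()
    t = np.asarray(timestamps, float)
    x = np.asarray(values, float)
    e1, e2, e3 = (edge * 60.0 for edge in config.ramp_block_edges_min)
    if se_peak_time - e3 < t[0]:
        raise ValidationError(
            f"need {config.ramp_block_edges_min[2]} min of trace before the SE peak"
        )
    late = (t >= se_peak_time - e2) & (t < se_peak_time - e1)
    early = (t >= se_peak_time - e3) & (t < se_peak_time - e2)
    if late.sum() < 3 or early.sum() < 3:
        raise ValidationError("too few samples in a ramping block")
    slope_early = _ols_slope_per_min(t[early], x[early])
    slope_late = _ols_slope_per_min(t[late], x[late])
    delta = abs(slope_late - slope_early)
    if config.ramp_change_mode == "relative":
        change = delta / max(abs(slope_early), config.ramp_slope_floor)
    else:
        change = delta
    return change > config.ramp_slope_change, slope_early, slope_late


def block_spectra(
    timestamps: np.ndarray,
    values: np.ndarray,
    se_peak_time: float,
    config: Optional[PipelineConfig] = None,
) -> pd.DataFrame:
    """Periodogram of each 3-min pre-SE baseline block.

    Blocks are linearly detrended (so a ramp does not masquerade as
    low-frequency power) and mean-removed before the transform; both blocks
    share one frequency grid. Returns a tidy frame
    ``(block, frequency_hz, power)`` with ``power`` scaled so that its sum
    equals the detrended block variance (Parseval).
    """
    config = config or PipelineConfig()
    t = np.asarray(timestamps, float)
    x = np.asarray(values, float)
    e1, e2, e3 = (edge * 60.0 for edge in config.ramp_block_edges_min)
    if se_peak_time - e3 < t[0]:
        raise ValidationError(
            f"need {config.ramp_block_edges_min[2]} min of trace before the SE peak"
        )
    fs = 1.0 / float(np.median(np.diff(t)))
    sel_late = (t >= se_peak_time - e2) & (t < se_peak_time - e1)
    sel_early = (t >= se_peak_time - e3) & (t < se_peak_time - e2)
    n = min(int(sel_late.sum()), int(sel_early.sum()))
    if n < 8:
        raise ValidationError("too few samples in a spectral block")
    frames = []
    for label, sel in (("early", sel_early), ("late", sel_late)):
        seg = x[sel][:n]
        f, p = signal.periodogram(seg, fs=fs, detrend="linear", scaling="spectrum")
        frames.append(pd.DataFrame({"block": label, "frequency_hz": f, "power": p}))
    return pd.concat(frames, ignore_index=True)
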