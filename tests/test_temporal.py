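"""Activation order, spatial maps, ramping classification, block spectra."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from kisssync.config import PipelineConfig
from kisssync.model import CellMeta, SyncEvent, ValidationError
from kisssync.temporal import (
    NotAnalyzableError,
    OrderTable,
    block_spectra,
    build_order_table,
    detect_ramping,
    order_correlation,
    order_pairs,
    spatial_order_map,
)


def sync_from_order(cells, t0=0.0, kind="mse"):
    return SyncEvent(kind, [(c, t0 + 2.0 * i, 1.0) for i, c in enumerate(cells)])


class TestOrderTable:
    def test_identical_order_constant_columns(self):
        cells = [f"c{i}" for i in range(6)]
        table = build_order_table(
            [sync_from_order(cells, 100.0 * k) for k in range(3)]
        )
        assert table.n_syncs == 3
        assert (table.ranks.nunique(axis=0) == 1).all()
        assert table.cell_ranking() == cells

    def test_small_sync_filter(self):
        cells = [f"c{i}" for i in range(6)]
        syncs = [sync_from_order(cells, 100.0 * k) for k in range(3)]
        syncs += [sync_from_order(cells[:3], 1000.0 + 100.0 * k)
                  for k in range(5)]
        table = build_order_table(syncs)  # the five 3-cell syncs are dropped
        assert table.n_syncs == 3

    def test_insufficient_syncs_not_analyzable(self):
        cells = [f"c{i}" for i in range(6)]
        with pytest.raises(NotAnalyzableError):
            build_order_table(
                [sync_from_order(cells, 100.0 * k) for k in range(2)]
            )

    def test_tied_peaks_get_average_ranks(self):
        s = SyncEvent("mse", [("a", 0.0, 1.0), ("b", 0.0, 1.0),
                              ("c", 5.0, 1.0), ("d", 6.0, 1.0),
                              ("e", 7.0, 1.0)])
        table = build_order_table([s, s, s], min_cells_per_sync=5)
        assert table.ranks.loc[0, "a"] == 1.5 == table.ranks.loc[0, "b"]


class TestOrderCorrelation:
    def test_perfectly_consistent_order(self):
        cells = [f"c{i}" for i in range(8)]
        table = build_order_table(
            [sync_from_order(cells, 100.0 * k) for k in range(5)]
        )
        rho, p, _ = order_correlation(table)
        assert rho == pytest.approx(1.0)
        assert p < 1e-6

    def test_bonferroni_threshold_for_seven_sessions(self):
        cells = [f"c{i}" for i in range(8)]
        table = build_order_table(
            [sync_from_order(cells, 100.0 * k) for k in range(3)]
        )
        _, _, bonf = order_correlation(table, n_tests=7)
        assert round(bonf, 3) == 0.007

    def test_permutation_null_mean_near_zero(self, rng):
        rhos = []
        for _ in range(400):
            ranks = np.array([rng.permutation(10) + 1.0 for _ in range(5)])
            table = OrderTable(
                pd.DataFrame(ranks, columns=[f"c{i}" for i in range(10)])
            )
            rhos.append(order_correlation(table)[0])
        assert abs(float(np.mean(rhos))) <= 0.05

    def test_invariant_to_relabeling_and_sync_order(self, rng):
        ranks = np.array([rng.permutation(8) + 1.0 for _ in range(4)])
        cols = [f"c{i}" for i in range(8)]
        base = OrderTable(pd.DataFrame(ranks, columns=cols))
        rho0 = order_correlation(base)[0]
        perm = rng.permutation(8)
        relabeled = OrderTable(
            pd.DataFrame(ranks[:, perm], columns=[cols[j] for j in perm])
        )
        assert order_correlation(relabeled)[0] == pytest.approx(rho0, abs=1e-12)
        shuffled = OrderTable(
            pd.DataFrame(ranks[rng.permutation(4)], columns=cols)
        )
        assert order_correlation(shuffled)[0] == pytest.approx(rho0, abs=1e-12)

    def test_rank_reversal_flips_rho(self, rng):
        ranks = np.array([rng.permutation(9) + 1.0 for _ in range(5)])
        table = OrderTable(pd.DataFrame(ranks, columns=[f"c{i}" for i in range(9)]))
        x, y = order_pairs(table, "loo")
        rho = sps.spearmanr(x, y).statistic
        rho_rev = sps.spearmanr(10.0 - x, y).statistic
        assert rho_rev == pytest.approx(-rho, abs=1e-12)


class TestSpatialOrder:
    def test_linear_wave_has_unit_resultant(self):
        cells = [CellMeta(f"c{i}", 10.0 * i, 0.0) for i in range(6)]
        sync = sync_from_order([c.cell_id for c in cells])
        df, direction = spatial_order_map([sync], cells, 0)
        assert direction["resultant_length"] == pytest.approx(1.0)
        assert direction["circular_mean_rad"] == pytest.approx(0.0, abs=1e-9)
        assert list(df["rank"]) == [1, 2, 3, 4, 5, 6]

    def test_random_order_below_shuffle_null(self, rng):
        n = 12
        coords = rng.uniform(0, 500, (n, 2))
        cells = [CellMeta(f"c{i}", *coords[i]) for i in range(n)]
        order = rng.permutation(n)
        sync = sync_from_order([f"c{i}" for i in order])
        _, direction = spatial_order_map([sync], cells, 0)
        null = []
        for _ in range(500):
            shuffled = sync_from_order([f"c{i}" for i in rng.permutation(n)])
            null.append(spatial_order_map([shuffled], cells, 0)[1][
                "resultant_length"])
        assert direction["resultant_length"] < np.quantile(null, 0.95)

    def test_single_member_and_missing_coords_rejected(self):
        cells = [CellMeta("a", 0, 0)]
        single = SyncEvent("mse", [("a", 0.0, 1.0), ("b", 1.0, 1.0)])
        with pytest.raises(ValidationError, match="b"):
            spatial_order_map([single], cells, 0)
        lone = SyncEvent("low_amplitude_se", [("a", 0.0, 1.0)])
        with pytest.raises(ValidationError):
            spatial_order_map([lone], cells, 0)


class TestRamping:
    fs = 10.0

    def _trace(self, slope_early, slope_late, peak=600.0, noise=0.0, seed=0):
        t = np.arange(0, peak + 60, 1 / self.fs)
        x = np.zeros_like(t)
        e1, e2, e3 = 90.0, 270.0, 450.0  # block edges in s before the peak
        late = (t >= peak - e2) & (t < peak - e1)
        early = (t >= peak - e3) & (t < peak - e2)
        x[early] = slope_early * (t[early] - (peak - e3)) / 60.0
        x[late] = x[early][-1] if early.any() else 0.0
        x[late] += slope_late * (t[late] - (peak - e2)) / 60.0
        if noise:
            x += np.random.default_rng(seed).normal(0, noise, len(t))
        return t, x

    def test_flat_trace_not_ramping(self):
        t, x = self._trace(0.0, 0.0, noise=0.02)
        flag, early, late = detect_ramping(t, x, 600.0)
        assert not flag
        assert abs(early) < 0.02 and abs(late) < 0.02

    def test_late_rise_forces_ramping(self):
        t, x = self._trace(0.0, 0.5)
        flag, early, late = detect_ramping(t, x, 600.0)
        assert flag
        assert late == pytest.approx(0.5, abs=0.01)

    def test_slopes_match_normal_equations_oracle(self, rng):
        t = np.arange(0, 700, 1 / self.fs)
        x = 0.02 * (t / 60.0) + rng.normal(0, 0.3, len(t))
        _, early, late = detect_ramping(t, x, 600.0)
        # closed-form least squares per block, in z per minute
        for edges, got in (((-450.0, -270.0), early), ((-270.0, -90.0), late)):
            sel = (t >= 600.0 + edges[0]) & (t < 600.0 + edges[1])
            tm = t[sel] / 60.0
            n = sel.sum()
            sxx = (tm ** 2).sum() - tm.sum() ** 2 / n
            sxy = (tm * x[sel]).sum() - tm.sum() * x[sel].sum() / n
            assert got == pytest.approx(sxy / sxx, abs=1e-9)

    def test_insufficient_pre_peak_data_rejected(self):
        t = np.arange(0, 300, 1 / self.fs)
        with pytest.raises(ValidationError):
            detect_ramping(t, np.zeros_like(t), 299.0)

    def test_relative_mode_available(self):
        t, x = self._trace(0.2, 0.3)
        cfg = PipelineConfig(ramp_change_mode="relative")
        flag, early, late = detect_ramping(t, x, 600.0, cfg)
        assert flag == (abs(late - early) / max(abs(early), 0.01) > 0.05)


class TestBlockSpectra:
    def test_sinusoid_peak_in_late_block(self):
        fs = 10.0
        t = np.arange(0, 700, 1 / fs)
        x = np.zeros_like(t)
        late = (t >= 600 - 270) & (t < 600 - 90)
        x[late] = np.sin(2 * np.pi * 0.05 * t[late])
        spectra = block_spectra(t, x, 600.0)
        late_spec = spectra[spectra.block == "late"]
        f_peak = late_spec.loc[late_spec.power.idxmax(), "frequency_hz"]
        df = np.diff(late_spec.frequency_hz.iloc[:2])[0]
        assert abs(f_peak - 0.05) <= df

    def test_parseval(self, rng):
        t = np.arange(0, 700, 0.1)
        x = rng.normal(0, 1, len(t)) + 0.3 * np.sin(2 * np.pi * 0.2 * t)
        spectra = block_spectra(t, x, 600.0)
        for block in ("early", "late"):
            sel = (t >= 600 - (450 if block == "early" else 270)) & (
                t < 600 - (270 if block == "early" else 90)
            )
            seg = x[sel][: (spectra.block == block).sum() * 0 + sel.sum()]
            from scipy.signal import detrend

            var = detrend(seg, type="linear").var()
            total = spectra.loc[spectra.block == block, "power"].sum()
            assert total == pytest.approx(var, rel=0.01)

    def test_white_noise_no_bin_above_exponential_null_bound(self, rng):
        # periodogram bins of white noise are ~exponential; the Bonferroni
        # bound mean*ln(n_bins/alpha) is exceeded in <= ~alpha of replicates
        hits = 0
        reps = 100
        t = np.arange(0, 700, 0.1)
        for _ in range(reps):
            x = rng.normal(0, 1, len(t))
            spec = block_spectra(t, x, 600.0)
            for block in ("early", "late"):
                p = spec.loc[spec.block == block, "power"].to_numpy()[1:]
                bound = p.mean() * np.log(len(p) / 0.05)
                if (p > bound).any():
                    hits += 1
                    break
        assert hits / reps <= 0.15

    def test_ramp_does_not_masquerade_as_low_frequency_power(self):
        t = np.arange(0, 700, 0.1)
        flat = np.zeros_like(t)
        ramped = 0.5 * t / 60.0
        s_flat = block_spectra(t, flat + 1e-9 * np.sin(t), 600.0)
        s_ramp = block_spectra(t, ramped + 1e-9 * np.sin(t), 600.0)
        # linear detrending removes the ramp: low-frequency power comparable
        lf_flat = s_flat[s_flat.frequency_hz < 0.02].power.sum()
        lf_ramp = s_ramp[s_ramp.frequency_hz < 0.02].power.sum()
        assert lf_ramp == pytest.approx(lf_flat, abs=1e-12)
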