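"""Windowed drug statistics, routed tests, infusions, SFA and ISI metrics."""

import itertools
import math

import numpy as np
import pytest

from kisssync.config import PipelineConfig
from kisssync.model import (
    AnalysisWindow,
    CalciumEvent,
    SpikeTrain,
    SyncEvent,
    TraceMatrix,
    ValidationError,
)
from kisssync.pharm import (
    TrialOutcome,
    compare_periods,
    grubbs_outlier,
    infusion_analysis,
    isi_profile,
    repeated_measures_anova,
    se_probability,
    se_shape_comparison,
    sfa_index,
    windowed_rates,
)
from kisssync.synthetic import simulate_spike_train


def ev(cell, t):
    return CalciumEvent(cell, t - 1, t, t + 1, 1.0)


def three_windows():
    return [
        AnalysisWindow("pre_drug", 0.0, 720.0),
        AnalysisWindow("drug", 840.0, 1560.0),
        AnalysisWindow("wash", 1680.0, 2400.0),
    ]


class TestWindowedRates:
    def test_gap_events_excluded(self):
        events = [ev("a", 730.0), ev("b", 800.0)]  # inside the 2-min gap
        rates = windowed_rates(events, [], three_windows(), n_cells=4)
        assert all(r["event_rate"] == 0.0 for r in rates.values())

    def test_rates_and_conservation(self):
        events = (
            [ev("a", t) for t in (10, 100, 700)]
            + [ev("b", t) for t in (900, 1000)]
            + [ev("c", 2000.0)]
        )
        syncs = [SyncEvent("mse", [("a", 10.0, 1.0), ("b", 12.0, 1.0)])]
        rates = windowed_rates(events, syncs, three_windows(), n_cells=5)
        assert rates["pre_drug"]["event_rate"] == pytest.approx(3 / 5 / 0.2)
        assert rates["drug"]["event_rate"] == pytest.approx(2 / 5 / 0.2)
        assert rates["pre_drug"]["sync_rate"] == pytest.approx(1 / 5 / 0.2)
        total = sum(r["n_events"] for r in rates.values())
        assert total == len(events)  # no gap events here

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValidationError):
            windowed_rates(
                [], [],
                [AnalysisWindow("a", 0, 720), AnalysisWindow("b", 700, 1400)],
                n_cells=1,
            )

    def test_halved_rate_recovered_on_poisson_sessions(self, rng):
        # Poisson oracle: drug window has half the pre-drug rate
        windows = three_windows()
        ratios = []
        for _ in range(50):
            pre = np.sort(rng.uniform(0, 720, rng.poisson(40)))
            drug = np.sort(rng.uniform(840, 1560, rng.poisson(20)))
            events = [ev("a", t) for t in np.concatenate([pre, drug])]
            r = windowed_rates(events, [], windows, 1)
            if r["pre_drug"]["event_rate"] > 0:
                ratios.append(r["drug"]["event_rate"] / r["pre_drug"]["event_rate"])
        se = np.std(ratios, ddof=1) / math.sqrt(len(ratios))
        assert abs(np.mean(ratios) - 0.5) <= 3 * se


def exact_wilcoxon_two_sided(d):
    """Exact signed-rank p by enumerating all 2^n sign assignments
    (two-sided by doubling the smaller tail)."""
    from scipy.stats import rankdata

    d = np.asarray(d, float)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    w_all = np.asarray(
        [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([False, True], repeat=n)
        ]
    )
    lower = np.mean(w_all <= w_obs + 1e-12)
    upper = np.mean(w_all >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(lower, upper))


class TestComparePeriods:
    def test_identical_pairs_degenerate(self):
        x = [1.0, 2.0, 3.0, 4.0]
        with pytest.raises(ValidationError):
            compare_periods(x, list(x), "paired")

    def test_routes_to_paired_t_on_gaussian_data(self, rng):
        x = rng.normal(0, 1, 10)
        y = x + rng.normal(0.1, 0.5, 10)
        res = compare_periods(x, y, "paired", PipelineConfig(grubbs_screen=False))
        assert res.test_name == "paired t"

    def test_wilcoxon_matches_exact_enumeration(self):
        # heavy-tailed differences fail Shapiro and route to Wilcoxon
        pre = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        post = pre + np.array([0.1, 0.2, -0.12, 0.15, 12.0, 0.05])
        cfg = PipelineConfig(grubbs_screen=False)
        res = compare_periods(pre, post, "paired", cfg)
        assert res.test_name == "wilcoxon signed-rank"
        assert res.p_value == pytest.approx(
            exact_wilcoxon_two_sided(post - pre), abs=1e-12
        )

    def test_power_against_a_two_sd_shift(self, rng):
        hits = 0
        reps = 500
        for _ in range(reps):
            x = rng.normal(0, 1, 8)
            y = x + 2.0 + rng.normal(0, 0.5, 8)
            hits += compare_periods(x, y, "paired").p_value < 0.05
        assert hits / reps > 0.5

    def test_unpaired_routing(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(2, 1, 12)
        res = compare_periods(x, y, "unpaired",
                              PipelineConfig(grubbs_screen=False))
        assert res.test_name == "unpaired t" and res.p_value < 0.01

    def test_grubbs_removes_at_most_one(self, rng):
        d = np.concatenate([rng.normal(0, 1, 9), [25.0]])
        assert grubbs_outlier(d) == 9
        x = rng.normal(0, 1, 10)
        res = compare_periods(x, x + d, "paired")
        assert res.outliers_removed == 1 and res.n == 9


class TestInfusion:
    def _trace(self, duration=7200.0, fs=10.0, bumps=(), step=None):
        t = np.arange(0, duration, 1 / fs)
        x = np.zeros_like(t)
        for center, amp, half_dur in bumps:
            x += amp * np.maximum(0, 1 - np.abs(t - center) / half_dur)
        if step is not None:
            lo, hi, height = step
            x += height * ((t >= lo) & (t < hi))
        return TraceMatrix(["pop"], t, x[None, :], modality="photometry",
                           units="z")

    def test_no_ses_anywhere(self):
        infusion = AnalysisWindow("infusion", 3000.0, 3600.0)
        out = infusion_analysis(self._trace(), infusion)
        assert not out.se_during_infusion and out.se_count_during == 0
        assert math.isnan(out.amplitude_ratio)

    def test_step_height_recovered(self):
        infusion = AnalysisWindow("infusion", 3000.0, 3600.0)
        out = infusion_analysis(
            self._trace(step=(3000.0, 3600.0, 1.25)), infusion
        )
        assert out.mean_z_during - out.mean_z_pre == pytest.approx(1.25, abs=0.05)

    def test_se_assignment_and_amplitude_ratio(self):
        infusion = AnalysisWindow("infusion", 3000.0, 3600.0)
        # triangular bumps wide enough to stay >1 z for at least 45 s
        bumps = [(1500.0, 2.0, 100.0), (3300.0, 1.5, 200.0), (5000.0, 2.5, 100.0)]
        out = infusion_analysis(self._trace(bumps=bumps), infusion)
        assert out.se_during_infusion and out.se_count_during == 1
        assert out.amplitude_ratio == pytest.approx((1.5 + 2.5) / 2 / 2.0,
                                                    rel=0.05)

    def test_insufficient_coverage_rejected(self):
        infusion = AnalysisWindow("infusion", 600.0, 1200.0)  # pre needs 40 min
        with pytest.raises(ValidationError):
            infusion_analysis(self._trace(duration=3600.0), infusion)


class TestSeProbability:
    def _outcome(self, positive):
        return TrialOutcome("t", "drug", positive, int(positive), 0.0, 0.0, 0.0)

    def test_seven_of_eight(self):
        out = se_probability(
            {"vehicle": [self._outcome(i < 7) for i in range(8)]}
        )
        assert out["probability_pct"]["vehicle"] == pytest.approx(87.5)

    def test_zero_over_n(self):
        out = se_probability({"drug": [self._outcome(False) for _ in range(9)]})
        assert out["probability_pct"]["drug"] == 0.0

    def test_chi_squared_matches_hand_formula(self):
        a = {"veh": [self._outcome(i < 7) for i in range(8)],
             "drug": [self._outcome(i < 3) for i in range(9)]}
        out = se_probability(a)
        table = np.array([[7, 1], [3, 6]])
        n = table.sum()
        exp = np.outer(table.sum(1), table.sum(0)) / n
        chi2_hand = ((table - exp) ** 2 / exp).sum()
        assert out["chi2"] == pytest.approx(chi2_hand, rel=1e-12)
        swapped = se_probability({"drug": a["drug"], "veh": a["veh"]})
        assert swapped["chi2"] == pytest.approx(out["chi2"], rel=1e-12)

    def test_empty_condition_rejected(self):
        with pytest.raises(ValidationError):
            se_probability({"veh": []})


class TestSfaAndIsi:
    def test_constant_train_index_one(self):
        assert sfa_index(simulate_spike_train(12, 0.05, 1.0)) == pytest.approx(
            1.0, rel=1e-12
        )

    def test_fifty_and_hundred_ms(self):
        isis = [0.05 * (2 ** (k / 9)) for k in range(11)]
        train = SpikeTrain(np.concatenate([[0.0], np.cumsum(isis)]))
        assert sfa_index(train) == pytest.approx(0.5)

    @pytest.mark.parametrize("r", [0.9, 1.2, 1.5])
    def test_geometric_train_identity(self, r):
        assert sfa_index(simulate_spike_train(12, 0.04, r)) == pytest.approx(
            r ** -9, rel=1e-12
        )

    def test_translation_and_rescale_invariance(self):
        train = simulate_spike_train(15, 0.05, 1.1)
        shifted = SpikeTrain(train.spike_times + 100.0)
        scaled = SpikeTrain(train.spike_times * 3.0)
        assert sfa_index(shifted) == pytest.approx(sfa_index(train), rel=1e-12)
        assert sfa_index(scaled) == pytest.approx(sfa_index(train), rel=1e-12)

    def test_too_few_spikes_rejected(self):
        with pytest.raises(ValidationError):
            sfa_index(simulate_spike_train(10, 0.05, 1.0))

    def test_identical_trains_zero_sem_and_cv(self):
        train = simulate_spike_train(31, 0.05, 1.05)
        prof = isi_profile([train, train, train], n_spikes=30)
        np.testing.assert_allclose(prof["sem_isi_s"], 0.0, atol=1e-15)
        prof_const = isi_profile(
            [simulate_spike_train(31, 0.05, 1.0)] * 3, n_spikes=30
        )
        np.testing.assert_allclose(prof_const["cv"], 0.0, atol=1e-15)

    def test_cv_matches_injected_jitter(self, rng):
        base = 0.1
        jitter_cv = 0.2
        cvs = []
        for _ in range(100):
            trains = []
            for _ in range(10):
                isis = base * (1 + jitter_cv * rng.normal(0, 1, 30))
                isis = np.maximum(isis, 1e-4)
                trains.append(SpikeTrain(np.concatenate([[0], np.cumsum(isis)])))
            cvs.append(isi_profile(trains, 30)["cv"].mean())
        se = np.std(cvs, ddof=1) / 10
        # sample CV of n=10 underestimates slightly; allow 3 SE around ~0.2
        assert abs(np.mean(cvs) - jitter_cv) <= max(3 * se, 0.02)

    def test_short_train_named_in_error(self):
        with pytest.raises(ValidationError, match="train 1"):
            isi_profile(
                [simulate_spike_train(31, 0.1, 1.0),
                 simulate_spike_train(5, 0.1, 1.0)],
                n_spikes=30,
            )


class TestSeShape:
    def _profile(self, width, amp=1.0, fs=10.0):
        lag = np.arange(-80, 80, 1 / fs)
        prof = amp * np.exp(-0.5 * (lag / width) ** 2)
        return lag, prof

    def test_identical_sets_zero_deltas(self):
        profs = [self._profile(10.0) for _ in range(3)]
        out = se_shape_comparison(profs, profs)
        assert out["half_width_delta_s"] == 0.0
        assert out["decay_delta_s"] == 0.0

    def test_time_stretch_scales_half_width(self):
        pre = [self._profile(10.0) for _ in range(3)]
        post = [self._profile(15.0) for _ in range(3)]
        out = se_shape_comparison(pre, post)
        assert out["half_width_post_s"] / out["half_width_pre_s"] == pytest.approx(
            1.5, abs=0.05
        )

    def test_amplitude_scaling_is_invisible(self):
        pre = [self._profile(10.0, amp=1.0)]
        post = [self._profile(10.0, amp=7.0)]
        out = se_shape_comparison(pre, post)
        assert out["half_width_delta_s"] == pytest.approx(0.0, abs=1e-9)

    def test_empty_side_rejected(self):
        with pytest.raises(ValidationError):
            se_shape_comparison([], [self._profile(10.0)])


class TestRmAnova:
    def test_detects_condition_effect(self, rng):
        subj = rng.normal(0, 1, 8)
        data = {
            "pre": subj + rng.normal(0, 0.2, 8),
            "during": subj - 1.0 + rng.normal(0, 0.2, 8),
            "post": subj + rng.normal(0, 0.2, 8),
        }
        out = repeated_measures_anova(data)
        assert out["p_value"] < 0.01
        assert out["p_during_vs_pre"] < 0.05
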