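"""Dosage statistics: slopes, qPCR weighting, bootstrap, amplitude fits."""

import numpy as np
import pandas as pd
import pytest

from dlgradient.borders import BorderObservation
from dlgradient.dosage_stats import (
    AmplitudeTrace,
    DosageSeries,
    bootstrap_amplitude_ratios,
    canonical_amplitude_curve,
    loglog_sensitivity,
    normal_range_probability,
    optimize_amplitude_pair,
    qpcr_weighted_stats,
    relative_abundance,
)


class TestLoglogSensitivity:
    def test_exact_power_law(self):
        doses = (0.5, 1.0, 2.0)
        series = DosageSeries({d: np.array([3.0 * d**0.2]) for d in doses})
        res = loglog_sensitivity(series)
        assert res.slope == pytest.approx(0.2, abs=1e-12)
        assert res.ci68 == pytest.approx(0.0, abs=1e-9)

    def test_mean_width_slope_matches_closed_form(self):
        # widths 0.13/0.15/0.17 at doses 0.5/1/2; closed-form OLS on 3 points
        series = DosageSeries(
            {0.5: np.array([0.13]), 1.0: np.array([0.15]), 2.0: np.array([0.17])}
        )
        lx = np.log([0.5, 1.0, 2.0])
        ly = np.log([0.13, 0.15, 0.17])
        expected = np.sum((lx - lx.mean()) * (ly - ly.mean())) / np.sum(
            (lx - lx.mean()) ** 2
        )
        res = loglog_sensitivity(series)
        assert res.slope == pytest.approx(expected, rel=1e-12)
        assert res.slope == pytest.approx(0.20, abs=0.01)

    def test_dosage_independent_null_gives_zero(self):
        series = DosageSeries({d: np.full(5, 0.15) for d in (0.5, 1, 2)})
        assert loglog_sensitivity(series).slope == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_excluded_with_warning(self):
        series = DosageSeries(
            {0.5: np.array([0.1, -0.2]), 1.0: np.array([0.2]), 2.0: np.array([0.4])}
        )
        with pytest.warns(UserWarning, match="non-positive"):
            res = loglog_sensitivity(series)
        assert res.n == 3


class TestQpcrStats:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows, columns=["genotype", "replicate", "delta_ct"])

    def test_uniform_weights_reduce_to_arithmetic_mean(self):
        rows = []
        for i, vals in enumerate([(1.0, 1.2), (2.0, 2.2), (3.0, 3.2)]):
            rows += [("2x", f"r{i}", v) for v in vals]
        stats = qpcr_weighted_stats(self._table(rows))
        assert stats.loc["2x", "weighted_mean"] == pytest.approx(
            np.mean([1.1, 2.1, 3.1])
        )

    def test_hand_substitution_n2(self):
        # y = (1, 3), s = (1, 1): ybar = 2, S = sqrt(n/(n-1) * sum w (y-ybar)^2)
        #                                    = sqrt(2 * (0.5 + 0.5)) = sqrt(2)
        rows = [("2x", "r0", 1.0 - 0.5), ("2x", "r0", 1.0 + 0.5)]
        rows += [("2x", "r1", 3.0 - 0.5), ("2x", "r1", 3.0 + 0.5)]
        # technical SDs: both sqrt(2)*0.5... use symmetric pairs with sd equal
        stats = qpcr_weighted_stats(self._table(rows))
        assert stats.loc["2x", "weighted_mean"] == pytest.approx(2.0)
        assert stats.loc["2x", "weighted_sem"] == pytest.approx(np.sqrt(2.0))

    def test_single_replicate_sem_flagged_nan(self):
        rows = [("2x", "r0", 1.0), ("2x", "r0", 1.4)]
        stats = qpcr_weighted_stats(self._table(rows))
        assert stats.loc["2x", "n_replicates"] == 1
        assert np.isnan(stats.loc["2x", "weighted_sem"])

    def test_fewer_than_two_technical_replicates_discarded(self):
        rows = [("2x", "r0", 1.0), ("2x", "r0", 1.2), ("2x", "r1", 9.0)]
        stats = qpcr_weighted_stats(self._table(rows))
        assert stats.loc["2x", "n_replicates"] == 1
        assert stats.loc["2x", "weighted_mean"] == pytest.approx(1.1)

    def test_weights_sum_to_one_property(self, rng):
        rows = []
        for i in range(6):
            vals = rng.normal(2.0, 0.5, 3)
            rows += [("2x", f"r{i}", v) for v in vals]
        t = self._table(rows)
        # reconstruct weights from the definition and check normalization
        per = t.groupby("replicate")["delta_ct"].agg(["mean", "std"])
        inv = 1 / per["std"]
        w = inv / inv.sum()
        assert w.sum() == pytest.approx(1.0)
        stats = qpcr_weighted_stats(t)
        assert stats.loc["2x", "weighted_mean"] == pytest.approx(
            float((w * per["mean"]).sum())
        )

    def test_conventional_method_differs_by_sqrt_n(self):
        rows = []
        for i in range(4):
            rows += [("2x", f"r{i}", 1.0 + i), ("2x", f"r{i}", 1.4 + i)]
        t = self._table(rows)
        paper = qpcr_weighted_stats(t, method="paper")
        conv = qpcr_weighted_stats(t, method="conventional")
        assert paper.loc["2x", "weighted_sem"] == pytest.approx(
            2.0 * conv.loc["2x", "weighted_sem"]
        )


class TestRelativeAbundance:
    @staticmethod
    def _stats(means, sems):
        return pd.DataFrame(
            {"weighted_mean": means, "weighted_sem": sems,
             "n_replicates": [9] * len(means)},
            index=list(means.keys()),
        )

    def test_zero_ddct_gives_fold_one(self):
        stats = self._stats({"2x": 1.0, "4x": 1.0}, {"2x": 0.1, "4x": 0.1})
        folds = relative_abundance(stats, "2x")
        assert folds.loc["4x", "fold"] == pytest.approx(1.0)

    def test_one_cycle_halves_abundance(self):
        stats = self._stats({"2x": 0.0, "1x": 1.0}, {"2x": 0.1, "1x": 0.1})
        folds = relative_abundance(stats, "2x")
        assert folds.loc["1x", "fold"] == pytest.approx(0.5)

    def test_planted_dose_coverage(self):
        # noisy synthetic tables: true folds within +/-2 propagated sem >= 90%
        from dlgradient.synth import SynthConfig, synth_qpcr

        hits = total = 0
        for seed in range(500):
            table, truth = synth_qpcr(SynthConfig(seed=seed))
            stats = qpcr_weighted_stats(table)
            folds = relative_abundance(stats, "2x")
            for g in ("1x", "4x"):
                total += 1
                lo = folds.loc[g, "fold"] - 2 * folds.loc[g, "fold_sem"]
                hi = folds.loc[g, "fold"] + 2 * folds.loc[g, "fold_sem"]
                if lo <= truth["doses"][g] <= hi:
                    hits += 1
        assert hits / total >= 0.90


class TestAmplitudeCurve:
    @staticmethod
    def _trace(peak=2.0, t_nc14=60.0, dt=1.0):
        t = np.arange(0.0, t_nc14 + dt / 2, dt)
        a = peak * (t / t_nc14) ** 2  # shared monotone shape
        return AmplitudeTrace(t, a, 0, t.size - 1)

    def test_identical_traces_reproduce_shape_and_peak(self):
        traces = [self._trace() for _ in range(3)]
        tau, canon, peaks = canonical_amplitude_curve(traces)
        assert np.allclose(canon, tau**2, atol=1e-6)
        assert np.allclose(peaks, 2.0, rtol=1e-6)

    def test_time_axis_stretched_by_duration(self):
        # 30- and 60-minute embryos share the canonical after stretching
        traces = [self._trace(t_nc14=30.0), self._trace(t_nc14=60.0)]
        _, canon, peaks = canonical_amplitude_curve(traces)
        tau = np.linspace(0, 1, canon.size)
        # linear interpolation of the coarser 30-min trace bounds the error
        assert np.allclose(canon, tau**2, atol=1e-3)
        assert np.allclose(peaks, 2.0, rtol=1e-3)

    def test_planted_peaks_recovered_under_noise(self, rng):
        planted = [1.0, 2.0, 4.0]
        traces = []
        for pk in planted:
            for _ in range(8):
                tr = self._trace(peak=pk, t_nc14=rng.uniform(40, 70))
                noisy = tr.amplitude * np.exp(rng.normal(0, 0.05, tr.amplitude.size))
                traces.append(AmplitudeTrace(tr.times, noisy, 0, tr.times.size - 1))
        _, _, peaks = canonical_amplitude_curve(traces)
        est = peaks.reshape(3, 8).mean(axis=1)
        assert np.allclose(est, planted, rtol=0.03)


class TestBootstrap:
    def test_degenerate_data_degenerate_distribution(self):
        m, s, samples = bootstrap_amplitude_ratios(
            np.full(5, 3.0), np.full(5, 1.5), n_boot=100, seed=0
        )
        assert m == pytest.approx(2.0) and s == pytest.approx(0.0)
        assert np.all(samples == 2.0)

    def test_self_ratio_near_one(self, rng):
        peaks = rng.normal(2.0, 0.3, 12)
        m, s, _ = bootstrap_amplitude_ratios(peaks, peaks, n_boot=5000, seed=1)
        assert m == pytest.approx(1.0, abs=3 * s + 0.02)

    def test_planted_ratio_recovered(self, rng):
        num = rng.normal(1.0, 0.1, 15)
        den = rng.normal(2.0, 0.2, 15)
        m, s, _ = bootstrap_amplitude_ratios(num, den, n_boot=5000, seed=2)
        assert abs(m - 0.5) < 2 * s

    def test_bootstrap_sd_scales_with_replicates(self, rng):
        # SD of the bootstrap MEAN estimate shrinks as 1/sqrt(n_boot)
        num = rng.normal(1.0, 0.2, 10)
        den = rng.normal(2.0, 0.2, 10)
        means_small = [
            bootstrap_amplitude_ratios(num, den, 100, seed=k)[0] for k in range(40)
        ]
        means_big = [
            bootstrap_amplitude_ratios(num, den, 1600, seed=k)[0] for k in range(40)
        ]
        ratio = np.std(means_small) / np.std(means_big)
        assert ratio == pytest.approx(4.0, rel=0.5)


class TestNormalRangeProbability:
    def test_one_sigma_identity(self):
        assert normal_range_probability(0, 1, -1, 1) == pytest.approx(0.6827, abs=1e-4)

    def test_reported_overlap_value(self):
        # P(1 < N(1.7, 0.4) < 1.5) = 0.27
        assert normal_range_probability(1.7, 0.4, 1.0, 1.5) == pytest.approx(
            0.27, abs=0.005
        )

    def test_half_mass_below_mean(self):
        assert normal_range_probability(2, 0.3, 2 - 3, 2) == pytest.approx(
            0.5, abs=1e-9
        )


class TestOptimizeAmplitudePair:
    @staticmethod
    def _curves_and_obs(scale_1x=1.0, scale_4x=1.0):
        x = np.linspace(0, 1, 301)
        base = np.exp(-(x**2) / (2 * 0.15**2)) + 0.01
        curves = {
            "1x": (x, base.copy()),
            "2x": (x, base.copy()),
            "4x": (x, base.copy()),
        }
        obs = []
        for gene, xb in (("sna", 0.2), ("sogd", 0.47)):
            theta = np.interp(xb, x, base)
            for g, s in (("1x", scale_1x), ("2x", 1.0), ("4x", scale_4x)):
                # observed border = interpolated crossing of s*base through theta
                xs = np.interp(theta, (s * base)[::-1], x[::-1])
                obs.append(BorderObservation(gene, g, float(xs), 0.02))
        return curves, obs

    def test_identical_everything_optimum_at_unity(self):
        curves, obs = self._curves_and_obs()
        res = optimize_amplitude_pair(curves, obs)
        assert res["alpha_1x"] == pytest.approx(1.0, abs=0.011)
        assert res["alpha_4x"] == pytest.approx(1.0, abs=0.011)
        assert res["sse_min"] == pytest.approx(0.0, abs=0.1)

    def test_planted_scalings_recovered_to_grid_resolution(self):
        curves, obs = self._curves_and_obs(scale_1x=0.8, scale_4x=1.1)
        res = optimize_amplitude_pair(curves, obs)
        assert res["alpha_1x"] == pytest.approx(0.8, abs=0.015)
        assert res["alpha_4x"] == pytest.approx(1.1, abs=0.015)

    def test_invariant_under_joint_curve_rescaling(self):
        curves, obs = self._curves_and_obs(scale_1x=0.8, scale_4x=1.1)
        scaled = {g: (x, 5.0 * c) for g, (x, c) in curves.items()}
        r1 = optimize_amplitude_pair(curves, obs)
        r2 = optimize_amplitude_pair(scaled, obs)
        assert r1["alpha_1x"] == r2["alpha_1x"]
        assert r1["alpha_4x"] == r2["alpha_4x"]
        assert np.allclose(r1["sse"], r2["sse"])

    def test_infeasible_region_mask(self):
        curves, obs = self._curves_and_obs()
        res = optimize_amplitude_pair(curves, obs)
        alphas = res["alphas"]
        i = np.searchsorted(alphas, 1.2)
        j = np.searchsorted(alphas, 0.6)
        assert res["infeasible"][i, j]  # alpha_1x > 1 and alpha_4x < 1
        assert not res["infeasible"][j, i]
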