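import numpy as np
import pytest
from scipy import stats

from optotract.config import RunConfig
from optotract.spikes import (
    ModelSupportError,
    Periods,
    PhotosensitivityModel,
    RateModel,
    SpikeRecord,
    UnitDecision,
    GofReport,
    classify_photosensitive,
    fit_rate,
    fluorescence_change,
    ogata_tests,
    population_stats,
    time_rescale,
)
from optotract.synthetic import SpikeGroundTruth, make_spike_trains


def record_from_times(times, off=(0, 60), on=(60, 120), post=(120, 180)):
    return SpikeRecord("u", np.asarray(times, float), Periods(off, on, post))


class TestSpikeRecord:
    def test_spike_outside_periods_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            record_from_times([10.0, 200.0])

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            record_from_times([10.0, 10.0])

    def test_disordered_periods_rejected(self):
        with pytest.raises(ValueError):
            Periods(off=(0, 60), on=(50, 120), post=(120, 180))

    def test_empty_record_allowed(self):
        rec = record_from_times([])
        assert rec.rate("OFF") == 0.0


class TestFitRateAndRescale:
    def test_constant_rate_and_cumulative(self):
        rec = record_from_times(np.linspace(0.5, 59.5, 60))
        model = fit_rate(rec, "OFF", "constant")
        assert model.rate_value == pytest.approx(1.0)
        assert model.total_mass == pytest.approx(60.0)

    def test_piecewise_two_halves(self):
        times = np.concatenate(
            [np.linspace(0.1, 29.9, 30), np.linspace(30.1, 59.9, 60)]
        )
        rec = record_from_times(times)
        model = fit_rate(rec, "OFF", "piecewise", bandwidth_or_binwidth=30.0)
        assert model.rate(np.array([10.0]))[0] == pytest.approx(1.0)
        assert model.rate(np.array([40.0]))[0] == pytest.approx(2.0)
        # closed-form integral through the breakpoint
        assert model.cumulative(np.array([45.0]))[0] == pytest.approx(
            30 * 1.0 + 15 * 2.0
        )

    def test_kernel_estimate_tracks_sinusoidal_rate(self):
        """Gaussian-kernel rate recovers lambda(t) = 10 + 5 sin(2 pi t / 10)
        within 10 % RMS at bandwidth 1 s, averaged over seeds."""
        rng = np.random.default_rng(0)
        T, lam_max = 200.0, 15.0
        grid = np.linspace(5, T - 5, 300)
        truth = 10 + 5 * np.sin(2 * np.pi * grid / 10)
        estimates = []
        for _ in range(20):
            # thinning
            cand = np.sort(rng.uniform(0, T, rng.poisson(lam_max * T)))
            keep = rng.random(len(cand)) < (
                (10 + 5 * np.sin(2 * np.pi * cand / 10)) / lam_max
            )
            times = cand[keep]
            rec = SpikeRecord("k", times, Periods((0, T), (T, T + 1), (T + 1, T + 2)))
            model = fit_rate(rec, "OFF", "kernel", bandwidth_or_binwidth=1.0)
            estimates.append(model.rate(grid))
        rms = np.sqrt(np.mean((np.mean(estimates, axis=0) - truth) ** 2))
        assert rms <= 0.10 * 10.0  # 10% of the mean rate

    def test_kernel_cumulative_matches_numerical_integral(self):
        rng = np.random.default_rng(1)
        times = np.sort(rng.uniform(0, 60, 100))
        rec = record_from_times(times)
        model = fit_rate(rec, "OFF", "kernel", bandwidth_or_binwidth=2.0)
        grid = np.linspace(0, 60, 20001)
        lam = model.rate(grid)
        num = np.trapezoid(lam, grid)
        assert model.total_mass == pytest.approx(num, rel=1e-6)

    def test_rescale_constant_closed_form(self):
        model = RateModel("constant", 0.0, 60.0, rate_value=2.0)
        tau = time_rescale(np.array([1.0, 5.0, 30.0]), model)
        assert np.allclose(tau, [2.0, 10.0, 60.0])

    def test_rescale_piecewise_closed_form(self):
        model = RateModel(
            "piecewise", 0.0, 20.0,
            bin_edges=np.array([0.0, 10.0, 20.0]),
            bin_rates=np.array([1.0, 2.0]),
        )
        tau = time_rescale(np.array([15.0]), model)
        assert tau[0] == pytest.approx(10 + 2 * 5)

    def test_rescale_preserves_count_and_order(self):
        rng = np.random.default_rng(2)
        times = np.sort(rng.uniform(0, 60, 200))
        model = RateModel(
            "piecewise", 0.0, 60.0,
            bin_edges=np.linspace(0, 60, 7),
            bin_rates=rng.uniform(0.5, 3.0, 6),
        )
        tau = time_rescale(times, model)
        assert len(tau) == 200
        assert np.all(np.diff(tau) > 0)

    def test_zero_rate_over_spikes_raises_support_error(self):
        model = RateModel(
            "piecewise", 0.0, 20.0,
            bin_edges=np.array([0.0, 10.0, 20.0]),
            bin_rates=np.array([1.0, 0.0]),
        )
        with pytest.raises(ModelSupportError):
            time_rescale(np.array([12.0, 15.0]), model)

    def test_rescaled_isis_pass_exponentiality_under_true_model(self):
        """Time-rescaling calibration: under the generating constant rate,
        rescaled ISIs pass a KS exponentiality test ~95/100 seeds."""
        passes = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            times = np.cumsum(rng.exponential(1 / 18.0, 1500))
            times = times[times < 60.0]
            model = RateModel("constant", 0.0, 60.0, rate_value=18.0)
            tau = time_rescale(times, model)
            p = stats.kstest(np.diff(np.r_[0.0, tau]), "expon").pvalue
            passes += p >= 0.05
        assert 88 <= passes <= 100


class TestOgataTests:
    def test_regular_train_rejected_by_exponentiality(self):
        tau = np.arange(1.0, 201.0)
        rep = ogata_tests(tau, 200.0, 0.05)
        assert rep.rejected["exponentiality"]
        assert rep.test_exponentiality[1] < 1e-6
        assert rep.overall_reject

    def test_empty_train_with_large_mass_rejected_by_counting_band(self):
        rep = ogata_tests(np.empty(0), 1000.0, 0.05)
        assert rep.underpowered
        assert rep.rejected["counting_band"]
        assert rep.overall_reject

    def test_few_events_small_mass_not_rejected(self):
        rep = ogata_tests(np.array([1.0, 2.5, 4.0]), 5.0, 0.05)
        assert rep.underpowered
        assert not rep.overall_reject

    def test_rate_step_power(self):
        """ON rate 1.45x the modeled rate (60 s at 18 Hz) is detected in
        >= 80/100 seeds."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            times = np.cumsum(rng.exponential(1 / (18.0 * 1.45), 3000))
            times = times[times < 60.0]
            model = RateModel("constant", 0.0, 60.0, rate_value=18.0)
            tau = time_rescale(times, model)
            rep = ogata_tests(tau, model.total_mass, 0.05)
            hits += rep.overall_reject
        assert hits >= 80

    def test_power_monotone_in_rate_multiplier(self):
        """Rejection rate does not decrease as the ON multiplier grows."""
        powers = []
        for mult in (1.1, 1.3, 1.5):
            hits = 0
            for seed in range(200):
                rng = np.random.default_rng(1000 + seed)
                times = np.cumsum(rng.exponential(1 / (18.0 * mult), 3000))
                times = times[times < 60.0]
                model = RateModel("constant", 0.0, 60.0, rate_value=18.0)
                rep = ogata_tests(
                    time_rescale(times, model), model.total_mass, 0.05
                )
                hits += rep.overall_reject
            powers.append(hits / 200)
        assert powers[0] <= powers[1] <= powers[2]


class TestClassify:
    def test_responsive_unit_detected_most_seeds(self):
        hits = 0
        for seed in range(50):
            gt = SpikeGroundTruth(on_rate_multiplier=1.5, baseline_rate_hz=18.0)
            rec = make_spike_trains([gt], rng_seed=seed)[0]
            hits += classify_photosensitive(rec).photosensitive
        assert hits >= 38  # ~91% power less self-check attrition

    def test_null_unit_rarely_flagged(self):
        hits = 0
        for seed in range(100):
            gt = SpikeGroundTruth(on_rate_multiplier=1.0, baseline_rate_hz=18.0)
            rec = make_spike_trains([gt], rng_seed=seed)[0]
            hits += classify_photosensitive(rec).photosensitive
        sem = np.sqrt(0.05 * 0.95 / 100)
        assert hits <= 100 * (0.05 + 2 * sem)

    def test_silenced_unit_is_photosensitive(self):
        gt = SpikeGroundTruth(on_rate_multiplier=1.0, baseline_rate_hz=18.0)
        rec = make_spike_trains([gt], rng_seed=3)[0]
        on = rec.periods.on
        keep = ~(
            (rec.spike_times_s > on[0]) & (rec.spike_times_s < on[1])
        )
        silenced = SpikeRecord("sil", rec.spike_times_s[keep], rec.periods)
        d = classify_photosensitive(silenced)
        assert d.photosensitive
        assert d.gof_on_vs_off.rejected["counting_band"]

    def test_unit_without_baseline_is_unclassifiable(self):
        rec = record_from_times([70.0, 80.0, 90.0])
        d = classify_photosensitive(rec)
        assert not d.classifiable
        assert not d.photosensitive


def rm_anova_oracle(rates):
    """Textbook two-way (subject x condition) decomposition with
    Greenhouse-Geisser epsilon from the covariance eigenvalues."""
    n, k = rates.shape
    grand = rates.mean()
    ss_cond = n * ((rates.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((rates.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((rates - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (n - 1) * (k - 1)
    F = (ss_cond / df1) / (ss_err / df2)
    S = np.cov(rates, rowvar=False)
    centered = S - S.mean(axis=0) - S.mean(axis=1)[:, None] + S.mean()
    lam = np.linalg.eigvalsh(centered)
    eps = lam.sum() ** 2 / ((k - 1) * (lam**2).sum())
    p = stats.f.sf(F, df1 * eps, df2 * eps)
    return F, df1, df2, eps, p


class TestPopulationStats:
    @staticmethod
    def decisions_from_rates(rates):
        gof = GofReport(50, (0, 1), (0, 1), (0, 1), (0, 1), {}, False)
        return [
            UnitDecision(
                unit_id=f"u{i}", photosensitive=True, gof_on_vs_off=gof,
                gof_off_selfcheck=gof, rate_off_hz=r[0], rate_on_hz=r[1],
                rate_post_hz=r[2],
                pct_change_on=100 * (r[1] - r[0]) / r[0],
            )
            for i, r in enumerate(rates)
        ]

    @staticmethod
    def flagged(n, k):
        gof = GofReport(50, (0, 1), (0, 1), (0, 1), (0, 1), {}, False)
        return [
            UnitDecision(
                unit_id=f"u{i}", photosensitive=i < k, gof_on_vs_off=gof,
                gof_off_selfcheck=gof, rate_off_hz=18.0,
                rate_on_hz=26.0 if i < k else 18.0, rate_post_hz=18.0,
                pct_change_on=0.0,
            )
            for i in range(n)
        ]

    def test_recorded_unit_fractions(self):
        assert population_stats(self.flagged(27, 8)).fraction_pct == pytest.approx(
            100 * 8 / 27
        )
        assert round(population_stats(self.flagged(27, 8)).fraction_pct, 1) == 29.6
        assert population_stats(self.flagged(36, 9)).fraction_pct == 25.0

    def test_anova_matches_textbook_oracle(self):
        rng = np.random.default_rng(8)
        rates = np.column_stack(
            [rng.normal(18, 2, 17), rng.normal(26, 3, 17), rng.normal(18, 2, 17)]
        )
        pop = population_stats(self.decisions_from_rates(rates))
        F, df1, df2, eps, p = rm_anova_oracle(rates)
        assert pop.anova["F"] == pytest.approx(F, abs=1e-8)
        assert pop.anova["df1"] == pytest.approx(df1 * eps, abs=1e-6)
        assert pop.anova["df2"] == pytest.approx(df2 * eps, abs=1e-6)
        assert pop.anova["p"] == pytest.approx(p, abs=1e-8)

    def test_tukey_matches_direct_studentized_range(self):
        rng = np.random.default_rng(9)
        rates = np.column_stack(
            [rng.normal(18, 2, 10), rng.normal(26, 3, 10), rng.normal(18, 2, 10)]
        )
        pop = population_stats(self.decisions_from_rates(rates))
        n, k = rates.shape
        grand = rates.mean()
        ss_err = (
            ((rates - grand) ** 2).sum()
            - n * ((rates.mean(axis=0) - grand) ** 2).sum()
            - k * ((rates.mean(axis=1) - grand) ** 2).sum()
        )
        ms_err = ss_err / ((n - 1) * (k - 1))
        means = rates.mean(axis=0)
        q01 = abs(means[0] - means[1]) / np.sqrt(ms_err / n)
        p01 = stats.studentized_range.sf(q01, k, (n - 1) * (k - 1))
        row = pop.tukey.iloc[0]
        assert row["q"] == pytest.approx(q01, abs=1e-8)
        assert row["p_adj"] == pytest.approx(p01, abs=1e-8)

    def test_shapiro_runs_on_differences(self):
        rng = np.random.default_rng(10)
        rates = np.column_stack(
            [rng.normal(18, 2, 8), rng.normal(26, 3, 8), rng.normal(18, 2, 8)]
        )
        pop = population_stats(self.decisions_from_rates(rates))
        w, p = stats.shapiro(rates[:, 1] - rates[:, 0])
        assert pop.shapiro == pytest.approx((w, p))

    def test_too_few_photosensitive_units_skips_anova(self):
        pop = population_stats(self.flagged(10, 2))
        assert pop.anova is None
        assert pop.fraction_pct == 20.0


class TestFluorescenceChange:
    def test_headline_percent_change(self):
        pct, p = fluorescence_change(np.full(10, 100.0), np.full(10, 155.7))
        assert pct == pytest.approx(55.7)
        assert p == pytest.approx(2 / 1024)

    def test_exact_p_for_ten_one_signed_pairs(self):
        rng = np.random.default_rng(11)
        before = rng.uniform(90, 110, 10)
        after = before + rng.uniform(1, 5, 10)
        _, p = fluorescence_change(before, after)
        assert p == pytest.approx(0.001953125, abs=1e-12)
        assert round(p, 3) == 0.002

    def test_identical_pairs_give_p_one_and_zero_change(self):
        x = np.linspace(90, 110, 8)
        pct, p = fluorescence_change(x, x)
        assert pct == 0.0
        assert p == 1.0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            fluorescence_change(np.ones(5), np.ones(6))


def test_photosensitivity_model_fit_and_summary():
    from optotract.synthetic import study_population

    pop = study_population(12, 5, rng_seed=0)
    records = make_spike_trains(pop, rng_seed=0)
    results = PhotosensitivityModel(records).fit()
    assert len(results.decisions) == 12
    assert results.population.n_photosensitive >= 3
    text = results.summary()
    assert "photosensitive" in text and "RM-ANOVA" in text
    frame = results.decisions_frame
    assert set(frame.columns) >= {"unit_id", "photosensitive", "rate_on_hz"}
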