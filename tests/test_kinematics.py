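"""Track-table kinematics: kymograms, frequency/speed, posture, statistics."""

import numpy as np
import pandas as pd
import pytest

from wormgait.kinematics import (
    ShrinkSeries,
    TrackTable,
    amplitude_and_wavelength,
    body_length_percent,
    fit_bimodal_frequency,
    freq_speed_regression,
    kymogram,
    permutation_test,
    shrink_series_from_track,
    sinusoidal_episode_filter,
    translocation_speed,
    undulation_frequency,
)
from wormgait.synthetic import UndulatorSpec, gen_frequency_samples, gen_shrink_track, gen_undulator


def rigid_track(speed=150.0, head_first=True, duration=4.0, fps=25.0):
    """Straight worm translating along +x; head at the +x end."""
    n = int(duration * fps) + 1
    times = np.arange(n) / fps
    xb = np.linspace(0.0, 1000.0, 17)  # head at offset 0
    skel = np.zeros((n, 17, 2))
    drift = speed * times if head_first else -speed * times
    skel[:, :, 0] = drift[:, None] - xb[None, :]
    return TrackTable(skeleton=skel, times=times, fps=fps)


class TestKymogram:
    def test_straight_translating_worm_is_all_zero(self):
        kym = kymogram(rigid_track())
        assert np.allclose(np.ma.filled(kym, 0.0), 0.0)

    def test_circle_arc_posture_gives_constant_two_per_mm(self):
        phi = np.linspace(0.0, np.pi, 17)
        skel = 500.0 * np.stack([np.cos(phi), np.sin(phi)], axis=1)  # R = 0.5 mm in um
        tr = TrackTable(skeleton=skel[None], times=np.array([0.0]), fps=25.0)
        kym = kymogram(tr)
        assert np.allclose(np.abs(kym[0]), 2.0, rtol=1e-2)

    def test_masked_frames_become_masked_columns(self):
        tr = gen_undulator(UndulatorSpec(duration=2.0))
        tr.mask[5] = False
        kym = kymogram(tr)
        assert np.all(kym.mask[5])
        assert not np.any(kym.mask[4])

    def test_undulator_stripes_have_the_generated_period(self):
        spec = UndulatorSpec(frequency=0.5, duration=8.0, speed=0.0)
        kym = kymogram(gen_undulator(spec))
        mid = kym[:, 8]
        # autocorrelation peak at one undulation period
        ac = np.correlate(mid - mid.mean(), mid - mid.mean(), mode="full")
        ac = ac[len(ac) // 2 :]
        lag = np.argmax(ac[5:]) + 5
        assert lag / spec.fps == pytest.approx(1.0 / spec.frequency, rel=0.1)


class TestFrequencyAndSpeed:
    def test_pure_tone_recovered_with_sign(self):
        tr = gen_undulator(UndulatorSpec(frequency=0.5, duration=10.0))
        assert undulation_frequency(tr) == pytest.approx(0.5, abs=0.02)

    def test_backward_undulator_reports_negative_frequency_and_speed(self):
        tr = gen_undulator(UndulatorSpec(frequency=-0.4, speed=-120.0, duration=10.0))
        assert undulation_frequency(tr) == pytest.approx(-0.4, abs=0.02)
        assert translocation_speed(tr) == pytest.approx(-120.0, rel=0.05)

    def test_largest_spectral_peak_wins(self):
        # 0.3 Hz amplitude 1 plus 0.9 Hz amplitude 0.3: report 0.3 Hz
        n = 251
        times = np.arange(n) / 25.0
        xb = np.linspace(0.0, 900.0, 17)
        y = 100.0 * np.sin(2 * np.pi * 0.3 * times)[:, None] * np.sin(
            2 * np.pi * xb / 700.0
        ) + 30.0 * np.sin(2 * np.pi * 0.9 * times)[:, None] * np.sin(2 * np.pi * xb / 700.0)
        skel = np.zeros((n, 17, 2))
        skel[:, :, 0] = 1000.0 - xb + 1e-3 * times[:, None]
        skel[:, :, 1] = y
        tr = TrackTable(skeleton=skel, times=times, fps=25.0)
        assert abs(undulation_frequency(tr)) == pytest.approx(0.3, abs=0.02)

    def test_rigid_translation_speed_signs(self):
        assert translocation_speed(rigid_track(head_first=True)) == pytest.approx(150.0, rel=1e-6)
        assert translocation_speed(rigid_track(head_first=False)) == pytest.approx(-150.0, rel=1e-6)

    def test_pinned_undulator_has_near_zero_speed(self):
        spec = UndulatorSpec(frequency=0.5, speed=0.0, amplitude=100.0, duration=10.0)
        v = translocation_speed(gen_undulator(spec))
        assert abs(v) < 0.05 * spec.amplitude * spec.frequency

    def test_short_window_is_rejected(self):
        tr = gen_undulator(UndulatorSpec(duration=4.0))
        with pytest.raises(ValueError, match="2 s"):
            undulation_frequency(tr, 0.0, 1.0)


class TestAmplitudeAndWavelength:
    def test_exact_sinusoid(self):
        x = np.linspace(0.0, 1400.0, 49)
        skel = np.stack([x, 100.0 * np.sin(2 * np.pi * x / 700.0)], axis=1)
        amp, lam1, _ = amplitude_and_wavelength(skel)
        assert amp == pytest.approx(100.0, rel=0.05)
        assert lam1 == pytest.approx(700.0, rel=0.05)

    def test_straight_posture_has_no_wavelength(self):
        skel = np.stack([np.linspace(0, 1000, 17), np.zeros(17)], axis=1)
        amp, lam1, lam2 = amplitude_and_wavelength(skel)
        assert amp == pytest.approx(0.0, abs=1e-9)
        assert lam1 is None and lam2 is None

    def test_two_harmonic_posture_orders_by_power(self):
        x = np.linspace(0.0, 1400.0, 99)
        y = 100.0 * np.sin(2 * np.pi * x / 700.0) + 35.0 * np.sin(2 * np.pi * x / 350.0)
        amp, lam1, lam2 = amplitude_and_wavelength(np.stack([x, y], axis=1))
        assert lam1 == pytest.approx(700.0, rel=0.07)
        assert lam2 == pytest.approx(350.0, rel=0.07)


class TestBodyLength:
    def test_no_shrink_stays_at_hundred_percent(self):
        tr = gen_undulator(UndulatorSpec(duration=4.0))
        series = shrink_series_from_track(tr, t_stim=2.0)
        assert body_length_percent(series, 3.0) == pytest.approx(100.0, abs=1.0)

    def test_step_shrink_measured_at_stimulus(self):
        tr = gen_shrink_track(UndulatorSpec(duration=6.0), shrink_to=94.0, recovery_tau=1.0, t_stim=2.0)
        series = shrink_series_from_track(tr, t_stim=2.0)
        # the stimulus frame itself is masked; nearest-frame fallback applies
        assert body_length_percent(series, 2.0) == pytest.approx(94.0, abs=1.0)

    def test_exponential_recovery_closed_form(self):
        tr = gen_shrink_track(UndulatorSpec(duration=8.0), shrink_to=90.0, recovery_tau=1.0, t_stim=2.0)
        series = shrink_series_from_track(tr, t_stim=2.0)
        assert body_length_percent(series, 4.0) == pytest.approx(100.0 - 10.0 * np.e**-2, abs=0.5)
        assert body_length_percent(series, 3.0) == pytest.approx(100.0 - 10.0 * np.e**-1, abs=0.5)

    def test_missing_frame_beyond_tolerance_is_absent(self):
        series = ShrinkSeries(
            times=np.arange(0.0, 5.0, 0.5),
            length=np.array([1000.0] * 4 + [np.nan] * 3 + [1000.0] * 3),
            t_stim=2.0,
        )
        assert np.isnan(body_length_percent(series, 2.6))


class TestEpisodeFilter:
    def table(self, rows):
        return pd.DataFrame(
            rows,
            columns=["speed", "frequency", "primary_wavelength", "secondary_wavelength"],
        )

    def test_path_exceeding_wavelength_is_kept(self):
        df = self.table([[200.0, 0.5, 350.0, np.nan]])  # path 400 > 350
        assert len(sinusoidal_episode_filter(df)) == 1

    def test_path_below_both_wavelengths_is_dropped(self):
        df = self.table([[150.0, 0.5, 350.0, 380.0]])  # path 300 < min(350, 380)
        assert len(sinusoidal_episode_filter(df)) == 0

    def test_rows_without_wavelengths_are_preexcluded(self):
        df = self.table([[500.0, 0.5, np.nan, np.nan]])
        assert len(sinusoidal_episode_filter(df)) == 0

    def test_zero_frequency_is_dropped(self):
        df = self.table([[500.0, 0.0, 300.0, np.nan]])
        assert len(sinusoidal_episode_filter(df)) == 0

    def test_filter_is_monotone_in_speed(self):
        rng = np.random.default_rng(11)
        df = self.table(
            np.stack(
                [
                    rng.uniform(50, 400, 200),
                    rng.uniform(0.2, 1.0, 200),
                    rng.uniform(200, 600, 200),
                    np.full(200, np.nan),
                ],
                axis=1,
            )
        )
        kept = set(sinusoidal_episode_filter(df).index)
        df2 = df.copy()
        df2["speed"] *= 1.5
        kept2 = set(sinusoidal_episode_filter(df2).index)
        assert kept <= kept2

    def test_generator_bookkeeping_recovers_compliant_fraction(self):
        # 60% compliant rows by construction
        rows = []
        for i in range(300):
            compliant = i % 5 < 3
            lam = 300.0
            speed = 250.0 if compliant else 100.0  # path 500 or 200 at 0.5 Hz
            rows.append([speed, 0.5, lam, np.nan])
        df = self.table(rows)
        frac = len(sinusoidal_episode_filter(df)) / len(df)
        assert frac == pytest.approx(0.6, abs=0.01)


class TestRegression:
    def test_exact_line(self):
        df = pd.DataFrame({"frequency": [0.2, 0.5, 0.8, 1.1], "speed": [60.0, 150.0, 240.0, 330.0]})
        slope, intercept, r2 = freq_speed_regression(df)
        assert slope == pytest.approx(300.0)
        assert intercept == pytest.approx(0.0, abs=1e-9)
        assert r2 == pytest.approx(1.0)

    def test_noisy_generator_slope_within_three_standard_errors(self):
        rng = np.random.default_rng(123)
        n, sigma, slope_true = 500, 30.0, 250.0
        f = rng.uniform(0.1, 1.0, n)
        v = slope_true * f + rng.normal(0.0, sigma, n)
        slope, _, _ = freq_speed_regression(pd.DataFrame({"frequency": f, "speed": v}))
        se = sigma / (np.std(f) * np.sqrt(n))
        assert abs(slope - slope_true) < 3.0 * se

    def test_degenerate_variance_raises(self):
        df = pd.DataFrame({"frequency": [0.5, 0.5, 0.5], "speed": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            freq_speed_regression(df)


class TestMixtureFit:
    def test_parameter_recovery_on_seeded_mixture(self):
        x = gen_frequency_samples([0.84, 0.16], [0.47, 0.17], [0.10, 0.05], 10_000, seed=5)
        fit = fit_bimodal_frequency(x, seed=0)
        mean_fast, sd_fast, w_fast = fit.fast
        assert mean_fast == pytest.approx(0.47, abs=0.02)
        assert w_fast == pytest.approx(0.84, abs=0.03)
        assert not fit.unimodal

    def test_identical_samples_flagged_degenerate(self):
        fit = fit_bimodal_frequency(np.full(200, 0.5))
        assert fit.degenerate

    def test_single_gaussian_flagged_unimodal(self):
        rng = np.random.default_rng(9)
        fit = fit_bimodal_frequency(rng.normal(0.5, 0.1, 5000), seed=0)
        assert fit.unimodal

    def test_requires_minimum_sample_size(self):
        with pytest.raises(ValueError):
            fit_bimodal_frequency(np.ones(50))


class TestPermutationTest:
    def test_identical_distributions_give_large_p(self):
        rng = np.random.default_rng(21)
        a = rng.normal(0, 1, 40)
        b = rng.permutation(a)
        res = permutation_test(a, b, seed=0)
        assert res.p_value >= 0.9

    def test_disjoint_groups_hit_the_extreme_tail(self):
        a = np.linspace(0.0, 1.0, 20)
        b = np.linspace(10.0, 11.0, 20)
        res = permutation_test(a, b, n_resamples=5000, seed=0)
        assert res.p_value <= 3.0 / 5001.0
        assert res.ci_high < 0.0  # a - b is decisively negative

    def test_scale_invariance_of_p_value(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.0, 1.0, 25)
        b = rng.normal(0.4, 1.0, 25)
        p1 = permutation_test(a, b, seed=7).p_value
        p2 = permutation_test(2.0 * a, 2.0 * b, seed=7).p_value
        assert p1 == pytest.approx(p2)
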