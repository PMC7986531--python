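"""Calcium pipeline: dF/F formula, channel phase, classification, binning."""

import numpy as np
import pytest

from wormgait.calcium import (
    ChannelGeometry,
    PhaseTrace,
    cell_frequency,
    collate_phase_bins,
    default_perimotor_table,
    delta_f_over_f,
    perimotor_correct,
    phase_from_position,
)
from wormgait.synthetic import MovieSpec, gen_fluorescence_movie

SQUARE_ROI = np.array([[2.0, 2.0], [2.0, 7.0], [7.0, 7.0], [7.0, 2.0]])


class TestDeltaFOverF:
    def test_top_half_mean_minus_frame_median(self):
        # ROI holds five bright (100) and five dark pixels on a zero frame
        frame = np.zeros((20, 20))
        frame[3, 3:8] = 100.0  # inside the ROI square
        stack = np.stack([frame, frame])
        trace = delta_f_over_f(stack, SQUARE_ROI)
        # F_top50% - F_BG = 100 each frame; self-normalization gives 1.0
        assert np.allclose(trace.values, 1.0)

    def test_constant_video_normalizes_to_one(self):
        frame = np.full((16, 16), 50.0)
        frame[3:7, 3:7] = 200.0
        stack = np.stack([frame] * 5)
        trace = delta_f_over_f(stack, SQUARE_ROI)
        assert np.allclose(trace.values, 1.0)
        assert not trace.flagged

    def test_two_level_trace_splits_around_one(self):
        lo, hi = np.zeros((16, 16)), np.zeros((16, 16))
        lo[3:7, 3:7], hi[3:7, 3:7] = 50.0, 150.0
        stack = np.stack([hi, lo] * 3)
        trace = delta_f_over_f(stack, SQUARE_ROI)
        assert np.allclose(trace.values[::2], 1.5)
        assert np.allclose(trace.values[1::2], 0.5)

    def test_mean_is_exactly_one_for_any_retained_trace(self):
        rng = np.random.default_rng(0)
        stack = rng.uniform(10.0, 60.0, size=(30, 24, 24))
        stack[:, 4:7, 4:7] += rng.uniform(50.0, 150.0, size=(30, 1, 1))
        trace = delta_f_over_f(stack, SQUARE_ROI)
        assert trace.values.mean() == pytest.approx(1.0, abs=1e-12)

    def test_all_equal_frames_are_flagged_not_crashed(self):
        stack = np.full((4, 16, 16), 77.0)
        trace = delta_f_over_f(stack, SQUARE_ROI)
        assert trace.flagged

    def test_roi_outside_frame_raises(self):
        stack = np.zeros((2, 8, 8))
        with pytest.raises(ValueError, match="outside"):
            delta_f_over_f(stack, np.array([[5.0, 5.0], [5.0, 12.0], [9.0, 12.0]]))


class TestPhaseFromPosition:
    geom = ChannelGeometry()

    def test_dorsal_apex_is_ninety_degrees(self):
        xy = (self.geom.wavelength / 4.0, self.geom.amplitude)
        assert phase_from_position(xy, self.geom) == pytest.approx(90.0, abs=1.0)

    def test_ventral_apex_is_two_seventy(self):
        xy = (0.75 * self.geom.wavelength, -self.geom.amplitude)
        assert phase_from_position(xy, self.geom) == pytest.approx(270.0, abs=1.0)

    def test_uniform_path_sampling_gives_uniform_phases(self):
        from scipy.stats import kstest

        x = np.linspace(0.0, self.geom.wavelength, 144, endpoint=False)
        phases = [phase_from_position((xi, self.geom.path_y(xi)), self.geom) for xi in x]
        stat = kstest(np.array(phases) / 360.0, "uniform")
        assert stat.pvalue > 0.01

    def test_far_positions_are_flagged(self):
        xy = (0.0, self.geom.amplitude + 2.0 * self.geom.width)
        assert np.isnan(phase_from_position(xy, self.geom))


class TestCellFrequency:
    def test_half_cycle_in_one_second(self):
        f, cls = cell_frequency(np.array([10.0, 100.0, 190.0]), np.array([0.0, 0.5, 1.0]))
        assert f == pytest.approx(0.5)
        assert cls == "low"

    def test_full_cycle_in_1_25_seconds_is_high(self):
        phases = (np.linspace(0.0, 360.0, 26)) % 360.0
        f, cls = cell_frequency(phases, np.linspace(0.0, 1.25, 26))
        assert f == pytest.approx(0.8)
        assert cls == "high"

    def test_exact_cutoff_counts_as_low(self):
        f, cls = cell_frequency(np.array([0.0, 216.0]), np.array([0.0, 1.0]))
        assert f == pytest.approx(0.6)
        assert cls == "low"

    def test_zero_elapsed_time_raises(self):
        with pytest.raises(ValueError):
            cell_frequency(np.array([0.0, 90.0]), np.array([1.0, 1.0]))


class TestPerimotorCorrect:
    def test_zero_offset_is_identity(self):
        phase, kind = perimotor_correct(123.0, "VD5")
        assert phase == 123.0 and kind == "neuron"

    def test_offset_wraps_around_360(self):
        table = dict(default_perimotor_table(), VD5=30.0)
        phase, _ = perimotor_correct(350.0, "VD5", table)
        assert phase == pytest.approx(20.0)

    def test_muscle_cells_pass_through_with_flag(self):
        phase, kind = perimotor_correct(200.0, "DM12")
        assert phase == 200.0 and kind == "muscle"

    def test_unknown_id_lists_known_cells(self):
        with pytest.raises(KeyError, match="VD3"):
            perimotor_correct(0.0, "XX9")


class TestCollatePhaseBins:
    def test_constant_trace_fills_bins_with_mean_one(self):
        tr = PhaseTrace("DM10", np.ones(720), np.linspace(0, 359.9, 720), 0.5)
        df = collate_phase_bins([tr])
        assert len(df) == 72
        occupied = df[df["n"] > 0]
        assert np.allclose(occupied["mean"], 1.0)
        assert np.allclose(occupied["sd"], 0.0)

    def test_vd_like_trough_is_localized_at_270(self):
        phases = np.linspace(0.0, 359.9, 1440)
        dff = 1.2 - 0.8 * np.exp(-0.5 * ((phases - 270.0) / 20.0) ** 2)
        tr = PhaseTrace("VD6", dff, phases, 0.8)
        df = collate_phase_bins([tr])
        trough = df.loc[df["mean"].idxmin(), "phase_deg"]
        assert abs(trough - 270.0) <= 10.0

    def test_antisymmetric_pair_averages_to_one(self):
        phases = np.linspace(0.0, 359.9, 360)
        v = 1.0 + 0.5 * np.sin(np.deg2rad(phases))
        a = PhaseTrace("DM9", v, phases, 0.5)
        b = PhaseTrace("DM9", 2.0 - v, phases, 0.5)
        df = collate_phase_bins([a, b])
        occupied = df[df["n"] > 0]
        assert np.allclose(occupied["mean"], 1.0, atol=1e-12)

    def test_empty_bins_are_marked(self):
        tr = PhaseTrace("VD4", np.ones(10), np.linspace(0.0, 40.0, 10), 0.3)
        df = collate_phase_bins([tr])
        assert (df["n"] == 0).sum() > 60
        assert df.loc[df["n"] == 0, "mean"].isna().all()


class TestEndToEndMovie:
    def test_flat_profile_yields_unit_dff(self):
        spec = MovieSpec(duration=1.5, frame_rate=50.0, traversal_frequency=0.5, noise_sd=0.5, seed=2)
        stack, rois, truth = gen_fluorescence_movie(spec)
        trace = delta_f_over_f(stack, rois)
        assert np.allclose(trace.values, 1.0, atol=0.05)

    def test_phase_assignment_consistent_with_cell_frequency(self):
        spec = MovieSpec(duration=2.0, frame_rate=50.0, traversal_frequency=0.8, seed=3)
        stack, rois, truth = gen_fluorescence_movie(spec)
        geom = spec.geometry
        phases = [
            phase_from_position(xy, geom) for xy in truth["cell_xy_um"]
        ]
        f, cls = cell_frequency(np.array(phases), truth["times"])
        assert f == pytest.approx(0.8, rel=0.02)
        assert cls == "high"
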