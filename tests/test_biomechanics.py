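"""Body mechanics: drag law, discrete curvature, stepping invariants."""

import numpy as np
import pytest

from wormgait import biomechanics as bm


@pytest.fixture(scope="module")
def mech():
    return bm.MechParams()


# a light, isotropic-ish test environment where relaxation is fast
FAST_ENV = bm.Environment(K_tau=0.5, K_nu=1.0, label="custom")


class TestDragForce:
    def test_stationary_body_feels_no_force(self, mech):
        st = bm.straight_body(16, mech)
        f = bm.drag_force(st, bm.Environment.agar_like(), np.zeros_like(st.x))
        assert np.allclose(f, 0.0)

    def test_tangential_glide_force_is_k_tau_v_and_tangential(self, mech):
        st = bm.straight_body(16, mech)
        env = bm.Environment.agar_like()
        v = np.tile([2.0, 0.0], (16, 1))  # body lies along +x
        f = bm.drag_force(st, env, v)
        assert np.allclose(np.linalg.norm(f, axis=1), env.K_tau * 2.0)
        assert np.allclose(f[:, 1], 0.0)

    def test_normal_to_tangential_force_ratio_is_drag_anisotropy(self, mech):
        st = bm.straight_body(16, mech)
        env = bm.Environment.agar_like()
        f_t = bm.drag_force(st, env, np.tile([1.0, 0.0], (16, 1)))
        f_n = bm.drag_force(st, env, np.tile([0.0, 1.0], (16, 1)))
        ratio = np.linalg.norm(f_n, axis=1) / np.linalg.norm(f_t, axis=1)
        assert np.allclose(ratio, env.K_nu / env.K_tau)

    def test_power_is_never_positive(self, mech):
        rng = np.random.default_rng(7)
        st = bm.body_from_curvature_wave(24, mech, amplitude=4.0)
        v = rng.normal(size=st.x.shape)
        f = bm.drag_force(st, bm.Environment.water_like(), v)
        assert np.sum(f * v) <= 0.0


class TestCurvatureFromCoords:
    def test_straight_line_gives_zero(self):
        x = np.stack([np.linspace(0, 1, 20), np.zeros(20)], axis=1)
        assert np.allclose(bm.curvature_from_coords(x), 0.0)

    def test_circle_radius_half_mm_gives_two_per_mm(self):
        phi = np.linspace(0, np.pi, 30)
        x = 0.5 * np.stack([np.cos(phi), np.sin(phi)], axis=1)
        kappa = bm.curvature_from_coords(x)
        assert np.allclose(np.abs(kappa), 2.0, rtol=1e-3)

    def test_matches_per_triplet_circumcircle_oracle(self):
        # independent oracle: circumscribed-circle radius from side lengths
        t = np.linspace(0.0, 1.0, 40)
        x = np.stack([t, 0.3 * np.sin(3.0 * t) + 0.1 * t**2], axis=1)
        kappa = bm.curvature_from_coords(x)
        for i in range(1, len(x) - 1):
            a = np.linalg.norm(x[i] - x[i - 1])
            b = np.linalg.norm(x[i + 1] - x[i])
            c = np.linalg.norm(x[i + 1] - x[i - 1])
            s = 0.5 * (a + b + c)
            area = np.sqrt(max(s * (s - a) * (s - b) * (s - c), 0.0))
            k_oracle = 4.0 * area / (a * b * c)
            assert abs(abs(kappa[i]) - k_oracle) < 1e-10

    def test_repeated_points_raise(self):
        x = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0]])
        with pytest.raises(bm.DegenerateGeometryError):
            bm.curvature_from_coords(x)


class TestStepBody:
    def test_straight_unforced_body_stays_put(self, mech):
        st = bm.straight_body(24, mech)
        x0 = st.x.copy()
        for _ in range(100):
            st = bm.step_body(st, np.zeros(22), mech, FAST_ENV, 1e-3)
        assert np.allclose(st.x, x0, atol=1e-12)
        assert np.allclose(st.kappa, 0.0, atol=1e-12)

    def test_uniform_drive_relaxes_to_preferred_curvature(self, mech):
        # long-horizon oracle: kappa climbs monotonically to beta0 (free-end
        # equilibrium has kappa = beta exactly)
        beta0 = 3.0
        st = bm.straight_body(24, mech)
        beta = np.full(22, beta0)
        mid_trace = []
        for i in range(4000):
            st = bm.step_body(st, beta, mech, FAST_ENV, 1e-3)
            if i % 200 == 0:
                mid_trace.append(st.kappa[12])
        assert np.all(np.diff(mid_trace) > -1e-12)
        assert abs(st.kappa[12] - beta0) < 0.01 * beta0

    def test_inextensibility_is_exact(self, mech):
        st = bm.body_from_curvature_wave(32, mech, amplitude=6.0)
        h0 = st.segment_length
        env = bm.Environment.agar_like()
        beta = 6.0 * np.sin(2 * np.pi * np.arange(30) / 29)
        for _ in range(500):
            st = bm.step_body(st, beta, mech, env, 1e-3)
        seg = np.linalg.norm(np.diff(st.x, axis=0), axis=1)
        assert np.max(np.abs(seg - h0)) / h0 < 1e-9

    @pytest.mark.parametrize("env", [bm.Environment.agar_like(), bm.Environment.water_like(1e6)])
    def test_passive_bent_body_straightens_monotonically(self, mech, env):
        st = bm.body_from_curvature_wave(32, mech, amplitude=5.0, wavelength=0.8)
        zero = np.zeros(30)
        energies = [bm.bending_energy(st, zero, mech)]
        for i in range(400):
            st = bm.step_body(st, zero, mech, env, 1e-3)
            if i % 40 == 0:
                energies.append(bm.bending_energy(st, zero, mech))
        assert np.all(np.diff(energies) <= 1e-12)

    def test_deterministic_bit_identical(self, mech):
        def run():
            st = bm.body_from_curvature_wave(24, mech, amplitude=5.0)
            beta = 5.0 * np.sin(2 * np.pi * np.arange(22) / 21)
            for _ in range(200):
                st = bm.step_body(st, beta, mech, bm.Environment.agar_like(), 1e-3)
            return st.x
        a, b = run(), run()
        assert np.array_equal(a, b)

    def test_bad_inputs_raise(self, mech):
        st = bm.straight_body(16, mech)
        with pytest.raises(ValueError):
            bm.step_body(st, np.zeros(14), mech, FAST_ENV, -1e-3)
        with pytest.raises(ValueError):
            bm.step_body(st, np.zeros(9), mech, FAST_ENV, 1e-3)

    def test_time_step_convergence_of_midbody_curvature(self, mech):
        # halving dt changes the mid-body curvature trace by well under 1%
        from wormgait.experiments import default_spec, run_experiment

        traces = {}
        for dt in (1e-3, 5e-4):
            spec = default_spec(
                "cpg", "agar_like", duration=4.0, transient=1.0, dt=dt,
                output_stride=int(round(0.02 / dt)),
            )
            res = run_experiment(spec)
            traces[dt] = res.kymogram[:, 23]
        a, b = traces[1e-3], traces[5e-4]
        m = min(len(a), len(b))
        rel = np.sqrt(np.mean((a[:m] - b[:m]) ** 2)) / np.sqrt(np.mean(b[:m] ** 2))
        assert rel < 0.01


class TestTensionRecovery:
    def test_tension_balances_nodal_forces(self, mech):
        env = bm.Environment.agar_like()
        st = bm.body_from_curvature_wave(24, mech, amplitude=4.0)
        beta = np.full(22, 2.0)
        new = bm.step_body(st, beta, mech, env, 1e-3, with_tension=True)
        assert new.tension.shape == (23,)
        assert np.all(np.isfinite(new.tension))
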