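"""Closed-loop locomotion experiments: wild type vs inhibition knockouts.

A single experiment couples the body (:mod:`wormgait.biomechanics`), a
controller (:mod:`wormgait.neural`) and the muscles (:mod:`wormgait.muscle`)
in one of two environments (agar-like or water-like), runs for a fixed
simulated duration, discards an initial transient, and measures:

* undulation frequency — dominant Fourier peak of mid-body curvature
  (Hann window, spectrum zero-padded to 0.01 Hz resolution);
* locomotion speed — net displacement of the body centroid divided by the
  elapsed time (mm/s);
* the curvature kymogram (time x body coordinate, mm^-1).

The perturbation matrix and parameter sweeps express each perturbed run
relative to the wild type of the same control mode and environment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .biomechanics import (
    BodyState,
    Environment,
    MechParams,
    body_from_curvature_wave,
    step_body,
)
from .muscle import MuscleField, PerturbationSpec, apply_perturbation, cpg_muscle_activation, muscle_step
from .neural import (
    CPGParams,
    NeuralState,
    ProprioParams,
    cpg_activation,
    neural_activation,
    proprioceptive_current_field,
    update_switches,
)

__all__ = [
    "ExperimentSpec",
    "ExperimentResult",
    "run_experiment",
    "relative_change",
    "perturbation_matrix",
    "parameter_sweep",
    "measure_frequency",
    "default_spec",
]

# Calibrated wild-type controller constants (see docs/methods.md): a single
# threshold scale theta0 and inhibition strength w, chosen once so that the
# proprioceptive wild type crawls at ~0.3-0.9 Hz (agar-like) and swims at
# ~1.5-2 Hz (water-like).
THETA0_DEFAULT = 2.0
W_INHIBITION_DEFAULT = 1.0
W_NMJ_EXC = 0.8
W_NMJ_INH = 0.2
AGAR_DRAG_SCALE = 3.5
WATER_DRAG_SCALE = 8.0e6


@dataclass(frozen=True)
class ExperimentSpec:
    """One simulation run: control mode, environment, perturbation, horizon."""

    control_mode: str = "proprioceptive"  # or "cpg"
    environment: str = "agar_like"  # or "water_like"
    perturbation: PerturbationSpec | None = None
    duration: float = 14.0
    transient: float = 2.0
    dt: float = 1.0e-3
    n_points: int = 48
    output_stride: int = 5
    seed: int = 0  # recorded; the model itself is deterministic
    mech: MechParams = field(default_factory=MechParams)
    cpg: CPGParams = field(default_factory=CPGParams)
    proprio: ProprioParams = field(
        default_factory=lambda: ProprioParams.collapsed(THETA0_DEFAULT, W_INHIBITION_DEFAULT)
    )
    tau_m: float = 0.1
    beta0: float = 10.0
    alpha: float = 3.0
    env_scale: float | None = None

    def __post_init__(self) -> None:
        if self.control_mode not in {"cpg", "proprioceptive"}:
            raise ValueError(f"unknown control mode {self.control_mode!r}")
        if self.environment not in {"agar_like", "water_like"}:
            raise ValueError(f"unknown environment {self.environment!r}")
        if self.duration <= self.transient:
            raise ValueError("duration must exceed the transient")
        if (
            self.perturbation is not None
            and self.perturbation.hyp3
            and self.control_mode == "cpg"
        ):
            raise ValueError(
                "hypothesis 3 (neural inhibitory reset) is only defined for "
                "proprioceptive control"
            )

    def build_environment(self) -> Environment:
        if self.environment == "agar_like":
            scale = AGAR_DRAG_SCALE if self.env_scale is None else self.env_scale
            return Environment.agar_like(scale)
        scale = WATER_DRAG_SCALE if self.env_scale is None else self.env_scale
        return Environment.water_like(scale)


@dataclass
class ExperimentResult:
    """Measured outcome of one run."""

    spec: ExperimentSpec
    frequency: float  # Hz
    speed: float  # mm/s, magnitude of net centroid drift per time
    peak_power: float  # spectral power at the dominant peak (a.u.)
    times: np.ndarray  # output sample times (s), post-transient included
    kymogram: np.ndarray  # (frames, M junctions) curvature, mm^-1
    midline: np.ndarray  # (frames, N, 2) midline coordinates, mm
    normalized_frequency: float = np.nan  # filled by perturbation_matrix
    normalized_speed: float = np.nan


def default_spec(
    control_mode: str,
    environment: str,
    perturbation: PerturbationSpec | None = None,
    **overrides,
) -> ExperimentSpec:
    """Spec with a horizon long enough for >= 10 undulation periods of the
    wild type in that environment (crawling is the slow case)."""
    duration = overrides.pop(
        "duration", 22.0 if environment == "agar_like" else 14.0
    )
    if control_mode == "cpg":
        cpg = overrides.get("cpg", CPGParams())
        duration = max(duration, 2.0 + 10.0 * cpg.T_f)
    return ExperimentSpec(
        control_mode=control_mode,
        environment=environment,
        perturbation=perturbation,
        duration=duration,
        **overrides,
    )


def measure_frequency(
    signal: np.ndarray, sample_rate: float, resolution: float = 0.01, f_min: float = 0.05
) -> tuple[float, float]:
    """Dominant-peak frequency of a time series (Hz) and its spectral power.

    Hann-windowed rFFT zero-padded so the frequency grid is at least as fine
    as ``resolution``.  Peaks below ``f_min`` (the DC/drift band) are ignored.
    An all-zero (or constant) signal reports frequency 0 with zero power —
    the caller can treat that as a quality flag.
    """
    signal = np.asarray(signal, dtype=float)
    sig = signal - signal.mean()
    if not np.any(np.abs(sig) > 0):
        return 0.0, 0.0
    win = np.hanning(len(sig))
    n_fft = int(2 ** np.ceil(np.log2(max(len(sig), sample_rate / resolution))))
    spec = np.abs(np.fft.rfft(sig * win, n=n_fft)) ** 2
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    valid = freqs >= f_min
    if not np.any(valid):
        return 0.0, 0.0
    i = np.argmax(spec[valid])
    f_peak = float(freqs[valid][i])
    power = float(spec[valid][i] / len(sig))
    # refine by continuous-frequency sinusoid least squares around the peak:
    # the windowed-FFT maximum is biased when the record holds few cycles
    t = np.arange(len(sig)) / sample_rate

    def captured(f):
        basis = np.stack([np.cos(2 * np.pi * f * t), np.sin(2 * np.pi * f * t)], axis=1)
        coef, *_ = np.linalg.lstsq(basis, sig, rcond=None)
        fit = basis @ coef
        return float(fit @ fit)

    from scipy.optimize import minimize_scalar

    half_width = 1.5 * sample_rate / len(sig)  # ~1.5 raw bins
    res = minimize_scalar(
        lambda f: -captured(f),
        bounds=(max(f_min, f_peak - half_width), f_peak + half_width),
        method="bounded",
        options={"xatol": resolution / 10.0},
    )
    return float(res.x), power


def _simulate(spec: ExperimentSpec):
    """Run the closed loop; returns (times, midline, kymogram) at the output
    stride.  Deterministic for identical specs."""
    n = spec.n_points
    m = n - 2
    mech = spec.mech
    env = spec.build_environment()
    pert = spec.perturbation or PerturbationSpec(hypothesis="none")
    hyp3 = pert.hyp3

    # initial condition: body laid along one period of the target waveform
    wavelength = spec.cpg.lambda_f if spec.control_mode == "cpg" else 0.65
    state = body_from_curvature_wave(n, mech, amplitude=0.6 * spec.beta0, wavelength=wavelength)
    u_j = np.arange(1, n - 1) / (n - 1)
    h = mech.L / (n - 1)

    kappa_j = np.diff(state.theta) / h
    mf = MuscleField(beta=kappa_j.copy(), tau_m=spec.tau_m, beta0=spec.beta0, alpha=spec.alpha)
    mf = apply_perturbation(mf, pert)
    ns = NeuralState.from_curvature(
        proprioceptive_current_field(kappa_j, spec.proprio.delta)
    )

    n_steps = int(round(spec.duration / spec.dt))
    out_every = spec.output_stride
    n_out = n_steps // out_every + 1
    times = np.empty(n_out)
    midline = np.empty((n_out, n, 2))
    kymo = np.empty((n_out, m))
    times[0], midline[0], kymo[0] = 0.0, state.x, kappa_j
    k_out = 1

    for step in range(1, n_steps + 1):
        if spec.control_mode == "cpg":
            A = cpg_activation(u_j, state.t, spec.cpg)
            if pert.tau_factor != 1.0:  # hyp2: drop the sigmoid, pure sinusoid
                beta = pert.c * spec.beta0 * A
            else:
                beta = pert.c * cpg_muscle_activation(A, spec.beta0, spec.alpha)
            state = step_body(state, beta, mech, env, spec.dt)
            kappa_j = np.diff(state.theta) / h
        else:
            state = step_body(state, mf.beta, mech, env, spec.dt)
            kappa_j = np.diff(state.theta) / h
            I_k = proprioceptive_current_field(kappa_j, spec.proprio.delta)
            ns = update_switches(ns, I_k, spec.proprio, hyp3)
            A = neural_activation(ns, W_NMJ_EXC, W_NMJ_INH)
            mf = muscle_step(mf, A, spec.dt)
        if step % out_every == 0:
            times[k_out] = state.t
            midline[k_out] = state.x
            kymo[k_out] = kappa_j
            k_out += 1
    return times[:k_out], midline[:k_out], kymo[:k_out]



def run_experiment(spec: ExperimentSpec) -> ExperimentResult:
    """Simulate one condition and measure frequency, speed and the kymogram."""
    times, midline, kymo = _simulate(spec)
    keep = times >= spec.transient
    t_keep = times[keep]
    sr = 1.0 / (times[1] - times[0])
    mid_idx = kymo.shape[1] // 2
    freq, power = measure_frequency(kymo[keep, mid_idx], sr)
    centroid = midline[keep].mean(axis=1)
    disp = np.linalg.norm(centroid[-1] - centroid[0])
    speed = float(disp / (t_keep[-1] - t_keep[0]))
    return ExperimentResult(
        spec=spec,
        frequency=freq,
        speed=speed,
        peak_power=power,
        times=times,
        kymogram=kymo,
        midline=midline,
    )


def relative_change(wt: ExperimentResult, mut: ExperimentResult) -> dict:
    """Percent reduction of mutant frequency and speed relative to wild type."""
    if wt.spec.control_mode != mut.spec.control_mode or wt.spec.environment != mut.spec.environment:
        raise ValueError("wild type and mutant must share control mode and environment")
    if wt.frequency == 0:
        raise ValueError("wild-type frequency is zero; relative change undefined")
    out = {"frequency_reduction_pct": 100.0 * (1.0 - mut.frequency / wt.frequency)}
    if wt.speed == 0:
        raise ValueError("wild-type speed is zero; relative change undefined")
    out["speed_reduction_pct"] = 100.0 * (1.0 - mut.speed / wt.speed)
    return out


def perturbation_matrix(
    control_mode: str,
    hypotheses: tuple[str, ...] = ("none", "1", "2", "1+2"),
    environments: tuple[str, ...] = ("agar_like", "water_like"),
    magnitude: float = 0.2,
    **overrides,
) -> dict:
    """Run wild type and each perturbation in each environment.

    Returns {environment: {hypothesis: ExperimentResult}} with normalized
    frequency/speed filled in (wild type normalizes to 1 by construction).
    """
    out: dict = {}
    for env in environments:
        wt = run_experiment(default_spec(control_mode, env, None, **overrides))
        wt.normalized_frequency = 1.0
        wt.normalized_speed = 1.0
        out[env] = {"none": wt}
        for hyp in hypotheses:
            if hyp == "none":
                continue
            pert = PerturbationSpec(hypothesis=hyp, magnitude=magnitude)
            res = run_experiment(default_spec(control_mode, env, pert, **overrides))
            res.normalized_frequency = res.frequency / wt.frequency
            res.normalized_speed = res.speed / wt.speed if wt.speed else np.nan
            out[env][hyp] = res
    return out


def parameter_sweep(
    control_mode: str,
    parameter: str,
    values: np.ndarray,
    environments: tuple[str, ...] = ("agar_like", "water_like"),
    **overrides,
) -> list[dict]:
    """Sweep a muscle parameter (c, tau, or alpha) and normalize by the
    wild-type operating point of the same environment.

    Failed points are recorded with NaN results; the sweep continues.
    """
    if parameter not in {"c", "tau", "alpha"}:
        raise ValueError("parameter must be one of 'c', 'tau', 'alpha'")
    rows: list[dict] = []
    for env in environments:
        wt = run_experiment(default_spec(control_mode, env, None, **overrides))
        for v in values:
            try:
                if parameter == "c":
                    mag = 1.0 - float(v)
                    pert = PerturbationSpec("1", abs(mag), allow_above_cap=True) if mag > 0 else None
                    res = run_experiment(default_spec(control_mode, env, pert, **overrides))
                elif parameter == "tau":
                    res = run_experiment(
                        default_spec(control_mode, env, None, tau_m=float(v), **overrides)
                    )
                else:
                    res = run_experiment(
                        default_spec(control_mode, env, None, alpha=float(v), **overrides)
                    )
                nf = res.frequency / wt.frequency
                nv = res.speed / wt.speed if wt.speed else np.nan
            except Exception:
                nf = nv = np.nan
            rows.append(
                {
                    "environment": env,
                    "parameter": parameter,
                    "value": float(v),
                    "normalized_frequency": nf,
                    "normalized_speed": nv,
                }
            )
    return rows
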