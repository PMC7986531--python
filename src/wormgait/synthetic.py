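"""Seeded generators for every synthetic input the pipelines consume.

All generators are pure functions of (spec, seed) and embed their ground
truth in the output metadata, so recovery tests read truth from metadata
only.  The emulated structures:

* sinusoidal undulator tracks (controllable frequency, amplitude,
  wavelength, speed, noise) standing in for tracked midline skeletons;
* shrink events: a step drop of body length at a stimulus time with
  exponential recovery, plus the one-frame tracking gap a harsh touch
  leaves;
* bimodal crawl-frequency samples from a two-Gaussian mixture;
* fluorescence movies of a cell moving along the sinusoidal waveform-channel
  path with a phase-locked intensity profile.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.optimize import brentq

from .calcium import ChannelGeometry
from .kinematics import TrackTable

__all__ = [
    "UndulatorSpec",
    "MovieSpec",
    "gen_undulator",
    "gen_shrink_track",
    "gen_frequency_samples",
    "gen_fluorescence_movie",
]


@dataclass(frozen=True)
class UndulatorSpec:
    """Ground truth for one synthetic undulating animal.

    frequency is the temporal oscillation rate of each material point (Hz,
    signed: negative = backward locomotion); amplitude/wavelength describe
    the posture sinusoid (um); speed is the translation of the whole body
    (um/s, signed with frequency).
    """

    frequency: float = 0.5
    amplitude: float = 100.0
    wavelength: float = 700.0
    speed: float = 150.0
    body_length: float = 1000.0
    n_points: int = 49
    fps: float = 25.0
    duration: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 2.0 * abs(self.frequency):
            raise ValueError(
                f"fps {self.fps} aliases a {self.frequency} Hz undulation"
            )
        if self.n_points < 9:
            raise ValueError("need at least 9 skeleton points")


def _axis_span(amplitude: float, wavelength: float, body_length: float, phase: float) -> float:
    """Axis-projected span X so the sinusoid arclength equals body_length."""
    k = 2.0 * np.pi / wavelength

    def arclen(X):
        x = np.linspace(0.0, X, 512)
        slope = amplitude * k * np.cos(k * x + phase)
        return np.trapezoid(np.sqrt(1.0 + slope**2), x) - body_length

    return brentq(arclen, 0.1 * body_length, body_length, xtol=1e-6)


def gen_undulator(spec: UndulatorSpec) -> TrackTable:
    """Traveling-wave midline advected at the given speed, sampled at fps.

    Material points oscillate at exactly |frequency| Hz and the posture has
    the stated axis wavelength and amplitude at every frame; the axis span is
    re-solved per frame so the polyline arclength stays at body_length.
    The head leads in the +x direction; negative speed moves the body
    tail-first (backward locomotion).
    """
    rng = np.random.default_rng(spec.seed)
    n_frames = int(round(spec.duration * spec.fps)) + 1
    times = np.arange(n_frames) / spec.fps
    k = 2.0 * np.pi / spec.wavelength
    skel = np.empty((n_frames, spec.n_points, 2))
    for i, t in enumerate(times):
        phase = -2.0 * np.pi * abs(spec.frequency) * t
        X = _axis_span(spec.amplitude, spec.wavelength, spec.body_length, phase)
        xb = np.linspace(0.0, X, spec.n_points)  # head at xb=0
        y = spec.amplitude * np.sin(k * xb + phase)
        x_head = spec.speed * t
        skel[i, :, 0] = x_head - xb
        skel[i, :, 1] = y
    if spec.noise_sd > 0:
        skel = skel + rng.normal(0.0, spec.noise_sd, size=skel.shape)
    return TrackTable(
        skeleton=skel,
        times=times,
        fps=spec.fps,
        meta={"generator": "undulator", **asdict(spec)},
    )


def gen_shrink_track(
    baseline: UndulatorSpec,
    shrink_to: float = 94.0,
    recovery_tau: float = 1.0,
    t_stim: float = 2.0,
) -> TrackTable:
    """Undulator whose arclength steps to shrink_to% at t_stim and recovers
    exponentially toward 100% with timescale recovery_tau.

    The frame at t_stim itself is masked, emulating the tracking gap during
    the touch stimulation.  recovery_tau -> 0 means full recovery by the
    next frame.
    """
    if not (0.0 < shrink_to <= 100.0):
        raise ValueError("shrink_to must be a percentage in (0, 100]")
    track = gen_undulator(baseline)
    scale = np.ones(track.n_frames)
    post = track.times >= t_stim - 1e-9
    dt_post = track.times[post] - t_stim
    if recovery_tau > 1e-12:
        scale[post] = (
            shrink_to + (100.0 - shrink_to) * (1.0 - np.exp(-dt_post / recovery_tau))
        ) / 100.0
    else:
        scale[post] = 1.0
        i_stim = np.argmin(np.abs(track.times - t_stim))
        scale[i_stim] = shrink_to / 100.0
    centroid = track.skeleton.mean(axis=1, keepdims=True)
    track.skeleton = centroid + scale[:, None, None] * (track.skeleton - centroid)
    i_stim = int(np.argmin(np.abs(track.times - t_stim)))
    track.mask[i_stim] = False
    track.meta.update(
        {
            "generator": "shrink",
            "shrink_to": shrink_to,
            "recovery_tau": recovery_tau,
            "t_stim": t_stim,
        }
    )
    return track


def gen_frequency_samples(
    weights, means, sds, n: int, seed: int = 0
) -> np.ndarray:
    """i.i.d. draws from a Gaussian mixture (weights must sum to 1)."""
    weights = np.asarray(weights, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if n < 1:
        raise ValueError("need n >= 1 draws")
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("mixture weights must sum to 1")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(weights), size=n, p=weights)
    return rng.normal(means[comp], sds[comp])


@dataclass(frozen=True)
class MovieSpec:
    """Synthetic waveform-channel fluorescence movie.

    The cell traverses the sinusoidal channel path at traversal_frequency
    cycles/s while its raw intensity follows profile(phase_deg); the frame
    rate mirrors the acquisition conventions (100 fps in the low-viscosity
    medium, 50 fps in the high-viscosity ones).
    """

    geometry: ChannelGeometry = field(default_factory=ChannelGeometry)
    traversal_frequency: float = 0.5
    duration: float = 2.0
    frame_rate: float = 50.0
    px_size: float = 5.0  # um per pixel
    cell_radius: float = 10.0  # um
    cell_peak: float = 200.0
    background: float = 50.0
    noise_sd: float = 2.0
    phase0: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate not in (50.0, 100.0):
            raise ValueError("frame rate is 50 or 100 fps by acquisition convention")


def gen_fluorescence_movie(spec: MovieSpec, profile=None):
    """Render the movie; returns (stack, rois, truth).

    stack : (F, H, W) float32 image stack (also writable as multi-page TIFF).
    rois : (F, 4, 2) square ROI polygon per frame, (row, col) vertices,
        tracking the cell exactly.
    truth : dict with per-frame ground-truth phase (deg) and cell centers.

    ``profile`` maps phase in degrees to a multiplicative activity level
    (default: flat 1.0); raw cell intensity is background + peak * level.
    """
    if profile is None:
        profile = lambda ph: np.ones_like(np.asarray(ph, dtype=float))
    geom = spec.geometry
    rng = np.random.default_rng(spec.seed)
    n_frames = int(round(spec.duration * spec.frame_rate)) + 1
    times = np.arange(n_frames) / spec.frame_rate
    phase = (spec.phase0 + 360.0 * spec.traversal_frequency * times) % 360.0
    phase_unwrapped = spec.phase0 + 360.0 * spec.traversal_frequency * times
    x_cell = geom.wavelength * phase_unwrapped / 360.0
    y_cell = geom.amplitude * np.sin(2.0 * np.pi * x_cell / geom.wavelength)

    margin = 4.0 * spec.cell_radius
    x_min, x_max = x_cell.min() - margin, x_cell.max() + margin
    y_min, y_max = -geom.amplitude - margin, geom.amplitude + margin
    w = int(np.ceil((x_max - x_min) / spec.px_size))
    h = int(np.ceil((y_max - y_min) / spec.px_size))
    cols = x_min + spec.px_size * np.arange(w)
    rows = y_min + spec.px_size * np.arange(h)
    cc, rr = np.meshgrid(cols, rows)

    stack = np.empty((n_frames, h, w), dtype=np.float32)
    rois = np.empty((n_frames, 4, 2))
    level = profile(phase)
    # integer half-width and pixel-snapped centers keep the rasterized ROI
    # pixel count identical across frames (no sampling flicker in dF/F)
    half = max(2, int(round(1.5 * spec.cell_radius / spec.px_size)))
    for i in range(n_frames):
        img = np.full((h, w), spec.background, dtype=float)
        d2 = (cc - x_cell[i]) ** 2 + (rr - y_cell[i]) ** 2
        img += spec.cell_peak * float(level[i]) * np.exp(-d2 / (2.0 * (spec.cell_radius / 1.5) ** 2))
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
        stack[i] = img
        r0 = round((y_cell[i] - y_min) / spec.px_size)
        c0 = round((x_cell[i] - x_min) / spec.px_size)
        rois[i] = [
            (r0 - half, c0 - half),
            (r0 - half, c0 + half),
            (r0 + half, c0 + half),
            (r0 + half, c0 - half),
        ]
    truth = {
        "phase_deg": phase,
        "phase_unwrapped_deg": phase_unwrapped,
        "times": times,
        "cell_xy_um": np.stack([x_cell, y_cell], axis=1),
        "origin_um": (x_min, y_min),
        "px_size": spec.px_size,
        "traversal_frequency": spec.traversal_frequency,
    }
    return stack, rois, truth
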