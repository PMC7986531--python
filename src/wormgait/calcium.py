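"""Calcium-trace extraction and phase binning for waveform-channel imaging.

Animals undulate through a microfluidic channel whose sinusoidal shape fixes
the locomotor phase at every spatial position: the crest of a maximal dorsal
bend is 90 deg and the maximal ventral bend 270 deg.  For each imaged cell:

* dF/F per frame is (F_top50% - F_BG) / mean(F_top50% - F_BG), where
  F_top50% is the mean of the brightest half of the ROI pixels and F_BG the
  median of the whole frame — so every retained trace has mean exactly 1;
* the undulatory phase is the position of the nearest point on the channel
  path, increasing monotonically along the travel direction;
* motoneuron soma phases are shifted to their neuromuscular-junction phase
  via a perimotor lookup table (muscle cells need no correction);
* the cell's undulation frequency is the fraction of a cycle traveled per
  unit time, classified low/high with a 0.6 Hz cutoff (a tie counts as low);
* traces are collated into 5-degree phase bins (72 bins) with mean and SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ChannelGeometry",
    "PhaseTrace",
    "DFFTrace",
    "FREQUENCY_CUTOFF_HZ",
    "delta_f_over_f",
    "phase_from_position",
    "cell_frequency",
    "default_perimotor_table",
    "perimotor_correct",
    "collate_phase_bins",
]

FREQUENCY_CUTOFF_HZ = 0.6


@dataclass(frozen=True)
class ChannelGeometry:
    """Waveform-channel dimensions (um) and the phase convention."""

    wavelength: float = 686.5
    amplitude: float = 322.5
    width: float = 133.5

    def __post_init__(self) -> None:
        if min(self.wavelength, self.amplitude, self.width) <= 0:
            raise ValueError("all channel dimensions must be positive")

    def path_y(self, x):
        return self.amplitude * np.sin(2.0 * np.pi * np.asarray(x, float) / self.wavelength)


@dataclass
class DFFTrace:
    """dF/F series of one cell; ``flagged`` marks a degenerate extraction
    (zero mean numerator, e.g. an all-equal frame)."""

    values: np.ndarray
    flagged: bool = False


@dataclass
class PhaseTrace:
    """dF/F of one cell indexed by (perimotor-corrected) phase in degrees."""

    cell_id: str
    dff: np.ndarray
    phase: np.ndarray  # degrees in [0, 360)
    frequency: float  # Hz

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float) % 360.0
        if self.dff.shape != self.phase.shape:
            raise ValueError("dF/F and phase must align sample-by-sample")

    @property
    def frequency_class(self) -> str:
        return "high" if self.frequency > FREQUENCY_CUTOFF_HZ else "low"


def _roi_mask(shape: tuple[int, int], polygon: np.ndarray) -> np.ndarray:
    from skimage.draw import polygon as draw_polygon

    poly = np.asarray(polygon, dtype=float)
    if (
        poly[:, 0].min() < -0.5
        or poly[:, 1].min() < -0.5
        or poly[:, 0].max() > shape[0] - 0.5
        or poly[:, 1].max() > shape[1] - 0.5
    ):
        raise ValueError("ROI polygon extends outside the frame bounds")
    rr, cc = draw_polygon(poly[:, 0], poly[:, 1], shape=shape)
    if len(rr) == 0:
        raise ValueError("empty ROI polygon")
    return rr, cc


def delta_f_over_f(frames: np.ndarray, rois) -> DFFTrace:
    """Background-subtracted, self-normalized fluorescence series.

    ``frames`` is an (F, H, W) stack and ``rois`` one (P, 2) polygon of
    (row, col) vertices per frame (a single polygon is broadcast).  Frames
    with lost focus are expected to be removed upstream; the mean is taken
    over the retained frames only.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must be an (F, H, W) stack")
    n = frames.shape[0]
    rois = np.asarray(rois, dtype=float)
    if rois.ndim == 2:
        rois = np.broadcast_to(rois, (n,) + rois.shape)
    raw = np.empty(n)
    for i in range(n):
        rr, cc = _roi_mask(frames.shape[1:], rois[i])
        vals = np.sort(frames[i, rr, cc])[::-1]
        top = vals[: max(1, int(np.ceil(0.5 * len(vals))))]
        f_bg = np.median(frames[i])
        raw[i] = top.mean() - f_bg
    denom = raw.mean()
    if denom == 0.0:
        return DFFTrace(values=np.zeros(n), flagged=True)
    return DFFTrace(values=raw / denom, flagged=False)


def phase_from_position(
    xy, geom: ChannelGeometry = ChannelGeometry(), direction: str = "forward"
) -> float:
    """Locomotor phase (deg) of a position on/near the channel path.

    The path is y = A sin(2 pi x / lambda); phase = 360 x / lambda of the
    nearest path point, so a dorsal-bend apex (y = +A) maps to 90 deg and a
    ventral apex to 270 deg.  Positions farther than half the channel width
    from the path are flagged by returning NaN.
    """
    if direction != "forward":
        raise ValueError("only forward traversal is analyzed")
    x0, y0 = float(xy[0]), float(xy[1])
    from scipy.optimize import minimize_scalar

    def dist2(x):
        dy = geom.path_y(x) - y0
        return (x - x0) ** 2 + dy * dy

    # coarse grid over one wavelength around x0, then local refinement
    grid = x0 + np.linspace(-0.5, 0.5, 101) * geom.wavelength
    xg = grid[np.argmin([dist2(x) for x in grid])]
    res = minimize_scalar(
        dist2, bracket=(xg - 0.02 * geom.wavelength, xg, xg + 0.02 * geom.wavelength)
    )
    x_star = float(res.x)
    if np.sqrt(dist2(x_star)) > 0.5 * geom.width:
        return float("nan")
    return float((360.0 * x_star / geom.wavelength) % 360.0)


def cell_frequency(phase_deg: np.ndarray, times: np.ndarray) -> tuple[float, str]:
    """Undulation frequency from phase traveled per unit time, with class.

    f = (delta phase / 360) / delta t on the unwrapped phase; class is
    "high" iff f is strictly above the 0.6 Hz cutoff (a tie is low).
    """
    phase = np.asarray(phase_deg, dtype=float)
    times = np.asarray(times, dtype=float)
    if phase.size < 2:
        raise ValueError("need at least 2 samples")
    dt = times[-1] - times[0]
    if dt == 0:
        raise ValueError("elapsed time is zero")
    # phase advances monotonically along the travel direction, so each
    # increment lies in [0, 360); tolerate small backward jitter near 0
    d = np.diff(phase) % 360.0
    d[d > 350.0] -= 360.0
    f = abs(d.sum()) / 360.0 / dt
    return float(f), ("high" if f > FREQUENCY_CUTOFF_HZ else "low")


def default_perimotor_table() -> dict[str, float]:
    """Editable soma -> neuromuscular-junction phase offsets (degrees).

    Placeholder zeros for the GABAergic motoneurons imaged in the mid-body
    (DD2-DD5, VD3-VD10); the published perimotor coordinates from the
    connectome atlases are supplied by the user via this table.
    """
    table = {f"DD{i}": 0.0 for i in range(2, 6)}
    table.update({f"VD{i}": 0.0 for i in range(3, 11)})
    return table


def perimotor_correct(
    soma_phase: float, cell_id: str, table: dict[str, float] | None = None
) -> tuple[float, str]:
    """Shift a motoneuron soma phase to its neuromuscular-junction phase.

    Returns (phase in [0, 360), kind) where kind is "neuron" or "muscle";
    muscle cells (ids starting with DM/VM) have no perimotor correction and
    pass through unchanged.  Unknown ids raise with the known ids listed.
    """
    if table is None:
        table = default_perimotor_table()
    if cell_id.startswith(("DM", "VM")):
        return float(soma_phase % 360.0), "muscle"
    if cell_id not in table:
        raise KeyError(
            f"unknown cell id {cell_id!r}; known ids: {sorted(table)} "
            "(muscle ids start with DM/VM)"
        )
    return float((soma_phase + table[cell_id]) % 360.0), "neuron"


def collate_phase_bins(traces, bin_deg: float = 5.0) -> pd.DataFrame:
    """Mean and SD of dF/F per phase bin across all samples of all traces.

    Returns a frame with one row per bin (default 72 bins of 5 deg):
    phase_deg (bin center), mean, sd, n.  Bins with no samples have n = 0
    and NaN statistics.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("need at least one trace")
    edges = np.arange(0.0, 360.0 + bin_deg / 2, bin_deg)
    centers = edges[:-1] + bin_deg / 2.0
    phase = np.concatenate([t.phase for t in traces])
    dff = np.concatenate([t.dff for t in traces])
    idx = np.clip(np.digitize(phase, edges) - 1, 0, len(centers) - 1)
    rows = []
    for b in range(len(centers)):
        vals = dff[idx == b]
        rows.append(
            {
                "phase_deg": centers[b],
                "mean": vals.mean() if len(vals) else np.nan,
                "sd": vals.std(ddof=0) if len(vals) else np.nan,
                "n": len(vals),
            }
        )
    return pd.DataFrame(rows)
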