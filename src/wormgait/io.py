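"""File formats: HDF5 trajectories and track tables, CSV exports, TIFF stacks.

Layouts
-------
Simulation trajectory (HDF5): datasets ``/time`` (s), ``/midline``
(frames x N x 2, mm), ``/curvature`` (frames x M, mm^-1), optionally
``/neural`` (frames x M x 4, VB/DB/VD/DD binary states).

Track tables (HDF5): one group ``animal_<id>`` per animal with datasets
``skeleton`` (frames x K x 2, um), ``times`` (s), ``mask`` and attributes
``fps`` plus JSON-encoded metadata.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .kinematics import TrackTable

__all__ = [
    "save_trajectory",
    "load_trajectory",
    "kymogram_to_csv",
    "save_tracks",
    "load_tracks",
    "save_movie_tiff",
    "load_movie_tiff",
]


def save_trajectory(path, times, midline, curvature, neural=None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("time", data=np.asarray(times))
        f.create_dataset("midline", data=np.asarray(midline))
        f.create_dataset("curvature", data=np.asarray(curvature))
        if neural is not None:
            f.create_dataset("neural", data=np.asarray(neural, dtype=np.int8))


def load_trajectory(path) -> dict:
    with h5py.File(path, "r") as f:
        out = {k: f[k][...] for k in f.keys()}
    return out


def kymogram_to_csv(path, times, kymogram) -> None:
    """Curvature kymogram as CSV: one row per frame, columns = body coord."""
    kym = np.asarray(kymogram)
    cols = [f"u_{i}" for i in range(kym.shape[1])]
    df = pd.DataFrame(kym, columns=cols)
    df.insert(0, "time_s", np.asarray(times))
    df.to_csv(path, index=False)


def save_tracks(path, tracks: list[TrackTable]) -> None:
    with h5py.File(path, "w") as f:
        for tr in tracks:
            g = f.create_group(f"animal_{tr.animal_id}")
            g.create_dataset("skeleton", data=tr.skeleton)
            g.create_dataset("times", data=tr.times)
            g.create_dataset("mask", data=tr.mask)
            g.attrs["fps"] = tr.fps
            g.attrs["meta"] = json.dumps(tr.meta, default=float)


def load_tracks(path) -> list[TrackTable]:
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            g = f[name]
            out.append(
                TrackTable(
                    skeleton=g["skeleton"][...],
                    times=g["times"][...],
                    fps=float(g.attrs["fps"]),
                    animal_id=int(name.split("_")[1]),
                    mask=g["mask"][...].astype(bool),
                    meta=json.loads(g.attrs.get("meta", "{}")),
                )
            )
    return out


def save_movie_tiff(path, stack) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def load_movie_tiff(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)
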