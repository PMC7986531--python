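#!/usr/bin/env python
"""Muscle-parameter sweeps: amplitude scale c, timescale tau, steepness alpha.

Sweeps each muscle parameter around its wild-type value in both
environments and records frequency/speed normalized to the wild-type
operating point.  Grids here are coarsened (the library sweep ranges
SWEEP_C / SWEEP_TAU / SWEEP_ALPHA cover the full published grids; pass
--full to use them, at ~10 s of wall time per grid point).

Finding (coarse grids): under proprioceptive control the normalized
frequency falls monotonically as c drops below 1 and as tau grows above
0.1 s; under CPG control the frequency stays pinned at 1/T_f across the
entire alpha sweep while speed varies.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from wormgait.experiments import parameter_sweep
from wormgait.muscle import SWEEP_ALPHA, SWEEP_C, SWEEP_TAU
from wormgait.neural import CPGParams

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--full", action="store_true", help="use the full sweep grids")
    args = ap.parse_args()

    grids = {
        ("proprioceptive", "c"): SWEEP_C if args.full else np.array([0.8, 0.9, 1.0]),
        ("proprioceptive", "tau"): SWEEP_TAU if args.full else np.array([0.1, 0.12, 0.2]),
        ("cpg", "alpha"): SWEEP_ALPHA if args.full else np.array([0.01, 0.5, 3.0]),
    }
    frames = []
    for (mode, param), values in grids.items():
        kwargs = {"cpg": CPGParams(T_f=1.0), "duration": 12.0} if mode == "cpg" else {}
        rows = parameter_sweep(mode, param, values, **kwargs)
        for r in rows:
            r["control"] = mode
            print(
                f"{mode} {param}={r['value']:.3g} [{r['environment']}]: "
                f"f_norm={r['normalized_frequency']:.3f} v_norm={r['normalized_speed']:.3f}"
            )
        frames.append(pd.DataFrame(rows))
    (ROOT / "results").mkdir(exist_ok=True)
    pd.concat(frames).to_csv(ROOT / "results" / "muscle_sweeps.csv", index=False)


if __name__ == "__main__":
    main()
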