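"""YAML simulation configs.

A config file has sections ``body``, ``environment``, ``control``,
``muscle``, ``perturbation`` and ``run``; every field falls back to the
calibrated wild-type default, so a minimal config is valid.  Example::

    environment: {label: agar_like}
    control: {mode: proprioceptive, theta0: 1.8, w: 0.9, delta: 0.5}
    muscle: {tau_m: 0.1, beta0: 10.0, alpha: 3.0}
    perturbation: {hypothesis: "1", magnitude: 0.2}
    run: {duration: 22.0, transient: 2.0, dt: 0.001, n_points: 48}
"""

from __future__ import annotations

import yaml

from .biomechanics import MechParams
from .muscle import PerturbationSpec
from .neural import CPGParams, ProprioParams
from .experiments import (
    ExperimentSpec,
    THETA0_DEFAULT,
    W_INHIBITION_DEFAULT,
)

__all__ = ["spec_from_dict", "load_config", "save_config", "spec_to_dict"]


def spec_from_dict(cfg: dict) -> ExperimentSpec:
    body = cfg.get("body", {})
    env = cfg.get("environment", {})
    control = cfg.get("control", {})
    musc = cfg.get("muscle", {})
    pert = cfg.get("perturbation", {})
    run = cfg.get("run", {})

    mech = MechParams(
        L=body.get("L", 1.0),
        E=body.get("E", 1.0e5),
        radius_max=body.get("radius_max", 0.04),
    )
    mode = control.get("mode", "proprioceptive")
    cpg = CPGParams(
        T_f=control.get("T_f", 2.0),
        lambda_f=control.get("lambda_f", 0.65),
        L=mech.L,
    )
    proprio = ProprioParams.collapsed(
        theta0=control.get("theta0", THETA0_DEFAULT),
        w=control.get("w", W_INHIBITION_DEFAULT),
        delta=control.get("delta", 0.5),
        backward=control.get("backward", False),
    )
    perturbation = None
    if pert.get("hypothesis", "none") != "none":
        perturbation = PerturbationSpec(
            hypothesis=str(pert["hypothesis"]),
            magnitude=pert.get("magnitude", 0.2),
            allow_above_cap=pert.get("allow_above_cap", False),
        )
    return ExperimentSpec(
        control_mode=mode,
        environment=env.get("label", "agar_like"),
        perturbation=perturbation,
        duration=run.get("duration", 22.0),
        transient=run.get("transient", 2.0),
        dt=run.get("dt", 1.0e-3),
        n_points=run.get("n_points", 48),
        output_stride=run.get("output_stride", 5),
        seed=run.get("seed", 0),
        mech=mech,
        cpg=cpg,
        proprio=proprio,
        tau_m=musc.get("tau_m", 0.1),
        beta0=musc.get("beta0", 10.0),
        alpha=musc.get("alpha", 3.0),
        env_scale=env.get("scale"),
    )


def spec_to_dict(spec: ExperimentSpec) -> dict:
    pert = spec.perturbation
    return {
        "body": {"L": spec.mech.L, "E": spec.mech.E, "radius_max": spec.mech.radius_max},
        "environment": {"label": spec.environment, "scale": spec.env_scale},
        "control": {
            "mode": spec.control_mode,
            "T_f": spec.cpg.T_f,
            "lambda_f": spec.cpg.lambda_f,
            "theta0": spec.proprio.theta_D_on,
            "w": spec.proprio.w,
            "delta": spec.proprio.delta,
            "backward": spec.proprio.backward,
        },
        "muscle": {"tau_m": spec.tau_m, "beta0": spec.beta0, "alpha": spec.alpha},
        "perturbation": {
            "hypothesis": pert.hypothesis if pert else "none",
            "magnitude": pert.magnitude if pert else 0.0,
        },
        "run": {
            "duration": spec.duration,
            "transient": spec.transient,
            "dt": spec.dt,
            "n_points": spec.n_points,
            "output_stride": spec.output_stride,
            "seed": spec.seed,
        },
    }


def load_config(path) -> ExperimentSpec:
    with open(path) as f:
        return spec_from_dict(yaml.safe_load(f) or {})


def save_config(path, spec: ExperimentSpec) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(spec_to_dict(spec), f)
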