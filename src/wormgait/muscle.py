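"""Muscle dynamics: neural activation -> preferred-curvature field beta(u, t).

Under proprioceptive control the body-wall muscles are a leaky integrator,

    tau_m dbeta/dt = -beta + beta0 A(u, t),

with wild-type timescale tau_m = 0.1 s and curvature amplitude
beta0 = 10 mm^-1.  Under CPG control the muscle response is the static
sigmoid beta = beta0 tanh(alpha A) / tanh(alpha) with wild-type steepness
alpha = 3 (a sharp upstroke attributed to disinhibition).

The inhibition-knockout hypotheses map onto these dynamics as:

* hypothesis 1 (no muscle cross-inhibition): beta -> c beta, c = 0.8 default;
* hypothesis 2 (no muscle disinhibition): proprioceptive mode uses a slower
  timescale 1.2 tau_m; CPG mode drops the sigmoid (beta = beta0 A);
* hypothesis 3 (no VD->VB neural inhibition): handled in the neural module;
  no muscle change, and only meaningful under proprioceptive control;
* combined: hypotheses 1 and 2 together.

Perturbation magnitudes are capped at 20% — the physiological bound on
muscle-length change — unless explicitly overridden for parameter sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MuscleField",
    "PerturbationSpec",
    "HYP2_TIMESCALE_FACTOR",
    "PERTURBATION_CAP",
    "muscle_step",
    "cpg_muscle_activation",
    "apply_perturbation",
]

HYP2_TIMESCALE_FACTOR = 1.2
PERTURBATION_CAP = 0.2

# sweep ranges bracketing all quoted operating points
SWEEP_C = np.round(np.arange(0.6, 1.0 + 1e-9, 0.02), 2)
SWEEP_TAU = np.linspace(0.05, 0.3, 11)
SWEEP_ALPHA = np.logspace(-2, np.log10(3.0), 10)


@dataclass(frozen=True)
class PerturbationSpec:
    """Which inhibition knockout to apply and how strongly.

    hypothesis in {"none", "1", "2", "3", "1+2"}; magnitude is the fractional
    perturbation strength (0.2 -> c = 0.8 and tau factor 1.2).
    """

    hypothesis: str = "none"
    magnitude: float = PERTURBATION_CAP
    allow_above_cap: bool = False

    def __post_init__(self) -> None:
        if self.hypothesis not in {"none", "1", "2", "3", "1+2"}:
            raise ValueError(f"unknown hypothesis {self.hypothesis!r}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be non-negative")
        if self.magnitude > PERTURBATION_CAP and not self.allow_above_cap:
            raise ValueError(
                f"perturbation magnitude {self.magnitude} exceeds the 20% cap; "
                "set allow_above_cap=True for sweeps"
            )

    @property
    def c(self) -> float:
        """Hypothesis-1 amplitude scale (1 when hyp1 not active)."""
        return 1.0 - self.magnitude if self.hypothesis in {"1", "1+2"} else 1.0

    @property
    def tau_factor(self) -> float:
        """Hypothesis-2 timescale factor (1 when hyp2 not active)."""
        return 1.0 + self.magnitude if self.hypothesis in {"2", "1+2"} else 1.0

    @property
    def hyp3(self) -> bool:
        return self.hypothesis == "3"


@dataclass
class MuscleField:
    """Preferred-curvature state beta (mm^-1) with its dynamical parameters.

    tau_m : wild-type muscle timescale (s).
    beta0 : curvature amplitude (mm^-1).
    alpha : sigmoid steepness for CPG control (dimensionless).
    c : hypothesis-1 amplitude scale, 1 in the wild type.
    tau_factor : hypothesis-2 timescale multiplier, 1 in the wild type.
    """

    beta: np.ndarray
    tau_m: float = 0.1
    beta0: float = 10.0
    alpha: float = 3.0
    c: float = 1.0
    tau_factor: float = 1.0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.tau_m <= 0:
            raise ValueError("muscle timescale must be positive")
        if not (0.0 < self.c <= 1.0):
            raise ValueError("hypothesis-1 scale c must be in (0, 1]")

    @property
    def tau_effective(self) -> float:
        return self.tau_m * self.tau_factor


def muscle_step(mf: MuscleField, A: np.ndarray, dt: float) -> MuscleField:
    """Advance the leaky muscle integrator one step (exact for constant A).

    Integrates tau dbeta/dt = -beta + c beta0 A over dt with the exponential
    integrator beta <- target + (beta - target) exp(-dt/tau), so the update
    is dt-robust and matches the closed form to machine precision for
    piecewise-constant activation.  The hypothesis-1 scale c multiplies the
    drive, which by linearity equals scaling the whole beta trajectory.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    A = np.asarray(A, dtype=float)
    target = mf.c * mf.beta0 * A
    decay = np.exp(-dt / mf.tau_effective)
    beta_new = target + (mf.beta - target) * decay
    return replace(mf, beta=beta_new)


def cpg_muscle_activation(A: np.ndarray, beta0: float = 10.0, alpha: float = 3.0):
    """Static sigmoidal muscle response beta = beta0 tanh(alpha A)/tanh(alpha).

    Odd and monotone in A, saturating at +-beta0 for A = +-1.  The alpha -> 0
    limit is the linear response beta0 A (used for the hypothesis-2 CPG
    variant); alpha below 1e-8 is evaluated by that limit to avoid 0/0.
    """
    if alpha < 0:
        raise ValueError("steepness alpha must be non-negative")
    A = np.asarray(A, dtype=float)
    if alpha < 1e-8:
        return beta0 * A
    return beta0 * np.tanh(alpha * A) / np.tanh(alpha)


def apply_perturbation(mf: MuscleField, spec: PerturbationSpec | None) -> MuscleField:
    """Return a muscle field with the perturbation folded into its parameters.

    hyp1 scales the beta field (and its drive) by c; hyp2 slows the effective
    timescale; hyp3 is purely neural (the flag is forwarded by the simulation
    loop, not here) and is rejected for CPG-style static muscle by the
    simulation, which only explores it under proprioceptive control.
    """
    if spec is None or spec.hypothesis == "none":
        return mf
    return replace(
        mf,
        beta=spec.c * mf.beta,
        c=spec.c * mf.c,
        tau_factor=spec.tau_factor * mf.tau_factor,
    )
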