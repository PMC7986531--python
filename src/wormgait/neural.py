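"""Neural control of the model worm: feedforward CPG or proprioceptive switches.

Two control paradigms produce the neural activation field A(u, t) that drives
the muscles:

* **CPG** — a retrograde traveling sine wave of unit amplitude with period
  ``T_f`` and wavelength ``lambda_f``; frequency is imposed, not emergent.
* **Proprioceptive** — ventral and dorsal B-type excitatory motoneurons are
  bistable on/off switches distributed along the body.  Each senses the mean
  signed curvature over a posterior receptive field (half the body length in
  the wild type) and flips when that input crosses hysteretic thresholds.
  D-type GABAergic motoneurons (VD/DD) respond instantaneously to the B-type
  neuron of the opposite side: VD mirrors DB and DD mirrors VB.  VD inhibits
  VB with strength ``w`` (the "inhibitory reset"); setting this input to zero
  at all times is the hypothesis-3 perturbation.

Curvature (and hence proprioceptive current and thresholds) is measured in
mm^-1 with the dorsal-positive sign convention; the descending AVB drive is
absorbed into the thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .biomechanics import BodyState

__all__ = [
    "CPGParams",
    "ProprioParams",
    "NeuralState",
    "cpg_activation",
    "proprioceptive_current",
    "update_switches",
    "neural_activation",
]


@dataclass(frozen=True)
class CPGParams:
    """Feedforward wave parameters: period T_f (s), neural wavelength
    lambda_f (mm), body length L (mm)."""

    T_f: float = 2.0
    lambda_f: float = 0.65
    L: float = 1.0

    def __post_init__(self) -> None:
        if self.T_f <= 0 or self.lambda_f <= 0:
            raise ValueError("period and wavelength must be positive")


def cpg_activation(u, t: float, p: CPGParams) -> np.ndarray:
    """A(u, t) = sin(2 pi u L / lambda_f - 2 pi t / T_f); unit amplitude."""
    u = np.asarray(u, dtype=float)
    return np.sin(2.0 * np.pi * u * p.L / p.lambda_f - 2.0 * np.pi * t / p.T_f)


@dataclass(frozen=True)
class ProprioParams:
    """Bistable-switch thresholds and inhibition for proprioceptive control.

    Thresholds are in curvature units (mm^-1) with the AVB descending drive
    absorbed; each side needs OFF < ON for hysteresis.  ``w`` is the VD-to-VB
    inhibition strength and ``delta`` the proprioceptive range as a fraction
    of body length (wild type +0.5, i.e. posterior half).

    The wild-type convention follows the collapse rule: with VD active the VB
    thresholds shift by ``w`` so that the VB/DB pair behaves as a single
    bistable switch.  :meth:`collapsed` builds such a parameter set from a
    single threshold scale theta0.
    """

    theta_D_on: float
    theta_D_off: float
    theta_V_on: float
    theta_V_off: float
    w: float
    I_AVB: float = 0.0
    delta: float = 0.5
    backward: bool = False

    def __post_init__(self) -> None:
        if not (self.theta_D_off < self.theta_D_on):
            raise ValueError("dorsal hysteresis requires OFF < ON threshold")
        if not (self.theta_V_off < self.theta_V_on):
            raise ValueError("ventral hysteresis requires OFF < ON threshold")
        if self.delta == 0.0:
            raise ValueError("proprioceptive range must be nonzero")

    @classmethod
    def collapsed(
        cls,
        theta0: float,
        w: float,
        delta: float = 0.5,
        backward: bool = False,
    ) -> "ProprioParams":
        """Wild-type thresholds obeying the collapse rule.

        The dorsal switch is symmetric (+-theta0).  The ventral ON threshold
        is lowered to theta0 - w: VB is intrinsically more excitable, and it
        is the VD-to-VB inhibition (active exactly while DB is on) that holds
        VB off until the dorsal phase ends, so the wild-type pair behaves as
        one bistable switch with transitions at +-theta0.  Removing the
        inhibitory input (hypothesis 3) lets VB activate while DB is still
        on, opening a dorsoventral coactivation window of width w.
        """
        return cls(
            theta_D_on=theta0,
            theta_D_off=-theta0,
            theta_V_on=theta0 - w,
            theta_V_off=-theta0,
            w=w,
            delta=delta,
            backward=backward,
        )


@dataclass
class NeuralState:
    """Binary B-type states per grid point; D-type states are derived.

    The instantaneous-inhibition rule makes V_VD = V_DB and V_DD = V_VB at
    all times, so only the B-type states are stored.
    """

    V_VB: np.ndarray
    V_DB: np.ndarray

    def __post_init__(self) -> None:
        self.V_VB = np.asarray(self.V_VB, dtype=np.int8)
        self.V_DB = np.asarray(self.V_DB, dtype=np.int8)
        if self.V_VB.shape != self.V_DB.shape:
            raise ValueError("VB and DB state fields must share a grid")

    @property
    def V_VD(self) -> np.ndarray:
        return self.V_DB

    @property
    def V_DD(self) -> np.ndarray:
        return self.V_VB

    @classmethod
    def from_curvature(cls, kappa: np.ndarray) -> "NeuralState":
        """Start with DB on where the posterior body is ventrally bent."""
        kappa = np.asarray(kappa)
        return cls(V_VB=(kappa > 0).astype(np.int8), V_DB=(kappa < 0).astype(np.int8))


def _junction_kappa(state: BodyState) -> np.ndarray:
    h = state.segment_length
    return np.diff(state.theta) / h


def proprioceptive_current(state: BodyState, u, delta: float = 0.5) -> np.ndarray:
    """Arclength-weighted mean of signed curvature over the receptive field.

    For forward control (delta > 0) the field of the neuron at u spans
    [u, u + delta], truncated at the tail (the normalization shrinks with it,
    making posterior neurons more sensitive per unit range).  delta < 0 gives
    the anterior field used for backward locomotion.  At the exact body end
    (zero range) the current is the local curvature, by continuity.
    """
    kappa_j = _junction_kappa(state)
    u_j = state.u_grid[1:-1]
    u = np.atleast_1d(np.asarray(u, dtype=float))
    out = np.empty(u.shape)
    for i, ui in enumerate(u):
        if delta > 0:
            lo, hi = ui, min(ui + delta, 1.0)
        else:
            lo, hi = max(ui + delta, 0.0), ui
        sel = (u_j >= lo - 1e-12) & (u_j <= hi + 1e-12)
        if not np.any(sel):
            # zero range at the body end: local curvature by continuity
            out[i] = kappa_j[-1] if delta > 0 else kappa_j[0]
        else:
            out[i] = kappa_j[sel].mean()
    return out if out.size > 1 else out[0]


def proprioceptive_current_field(
    kappa_j: np.ndarray, delta: float = 0.5
) -> np.ndarray:
    """Vectorized proprioceptive current on the junction grid itself.

    ``kappa_j`` are curvatures at the M interior junctions, assumed uniformly
    spaced in arclength (exactly true for the inextensible solver).  Returns
    I_kappa at each junction.  Used by the closed-loop simulation.
    """
    m = len(kappa_j)
    n_seg = m + 1  # junctions at i/(m+1), i=1..m
    cs = np.concatenate([[0.0], np.cumsum(kappa_j)])
    out = np.empty(m)
    span = abs(delta) * n_seg
    for i in range(m):
        if delta > 0:
            j_hi = min(int(np.floor(i + span)), m - 1)
            j_lo = i
        else:
            j_lo = max(int(np.ceil(i - span)), 0)
            j_hi = i
        out[i] = (cs[j_hi + 1] - cs[j_lo]) / (j_hi - j_lo + 1)
    return out


def update_switches(
    ns: NeuralState,
    I_kappa: np.ndarray,
    p: ProprioParams,
    hyp3: bool = False,
) -> NeuralState:
    """One synchronous threshold update of the bistable B-type switches.

    The dorsal input is I_AVB - I_kappa; the ventral input is
    I_AVB + I_kappa - I_VD with I_VD = w V_VD (dropped entirely under the
    hypothesis-3 perturbation).  DB is updated first, VD rederived, and VB
    then sees the current-step VD — the instantaneous-inhibition ordering.
    Inputs between the OFF and ON thresholds leave a state unchanged
    (hysteresis).
    """
    I_kappa = np.asarray(I_kappa, dtype=float)
    if I_kappa.shape != ns.V_DB.shape:
        raise ValueError("proprioceptive current must live on the neural grid")

    dorsal_in = p.I_AVB - I_kappa
    V_DB = ns.V_DB.copy()
    V_DB[dorsal_in > p.theta_D_on] = 1
    V_DB[dorsal_in < p.theta_D_off] = 0

    I_VD = np.zeros_like(I_kappa) if hyp3 else p.w * V_DB.astype(float)
    ventral_in = p.I_AVB + I_kappa - I_VD
    V_VB = ns.V_VB.copy()
    V_VB[ventral_in > p.theta_V_on] = 1
    V_VB[ventral_in < p.theta_V_off] = 0

    return NeuralState(V_VB=V_VB, V_DB=V_DB)


def neural_activation(
    ns: NeuralState, w_nmj_exc: float = 0.8, w_nmj_inh: float = 0.2
) -> np.ndarray:
    """A = w_exc (V_DB - V_VB) - w_inh (V_DD - V_VD) per grid point.

    With the instantaneous D-type rule this reduces to
    (w_exc + w_inh)(V_DB - V_VB): cross-inhibition adds w_inh of headroom to
    the dorsoventral difference.  Zeroing the inhibitory junction weight is
    exactly the hypothesis-1 amplitude scaling with
    c = w_exc / (w_exc + w_inh).
    """
    db = ns.V_DB.astype(float)
    vb = ns.V_VB.astype(float)
    return w_nmj_exc * (db - vb) - w_nmj_inh * (ns.V_DD.astype(float) - ns.V_VD.astype(float))
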