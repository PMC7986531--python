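"""Continuum viscoelastic body of the model worm.

The body is an inextensible planar elastic rod ("midline") of length ``L``
discretized into ``N`` material points.  Muscles enter as a preferred
curvature field beta(u, t): the elastic energy penalizes deviations of the
realized curvature kappa(u, t) from beta.  The surrounding medium exerts
anisotropic resistive-force-theory drag with tangential and normal
coefficients ``K_tau`` and ``K_nu``; locomotion is possible only because
K_nu != K_tau.  Inertia is negligible (low Reynolds number), so the dynamics
are a force balance between drag, line tension, and bending moments, with
zero force and torque at the free ends.

Units throughout: lengths in mm, time in s, forces in uN.  With these units
1 kPa = 1e3 uN/mm^2 and a drag coefficient quoted in N s m^-2 is numerically
identical in uN s mm^-2.

Numerical scheme
----------------
The rod is parametrized by the position of the head node and the angles of
the N-1 inter-node segments, which makes segment lengths exactly constant
(inextensibility holds to machine precision by construction; the line
tension is the constraint force and can be recovered from the nodal force
balance).  The bending energy is quadratic in the segment angles, so the
elastic term is treated fully implicitly; the drag metric is evaluated at
the current configuration (semi-implicit Euler).  Each step solves one
symmetric positive-definite (N+1) x (N+1) system.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "BodyState",
    "MechParams",
    "Environment",
    "DegenerateGeometryError",
    "SolverError",
    "curvature_from_coords",
    "drag_force",
    "step_body",
    "body_from_curvature_wave",
    "straight_body",
    "internal_tension",
    "bending_energy",
]


class DegenerateGeometryError(ValueError):
    """Raised when the midline geometry is unusable (e.g. repeated points)."""


class SolverError(RuntimeError):
    """Raised when a mechanics step fails; carries the offending residual."""


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class MechParams:
    """Passive mechanical parameters of the body.

    L : body length (mm).
    E : effective Young's modulus (uN/mm^2; 1e5 uN/mm^2 = 100 kPa, the
        wild-type body stiffness).
    radius_max : mid-body radius of the spindle-shaped cross-section profile
        (mm).  The radius is fixed in time.
    radius_floor : lower bound on the radius profile, as a fraction of
        ``radius_max``; keeps the tapered ends from becoming numerically
        floppy.
    internal_viscosity : body damping in response to bending; neglected
        (kept at 0) in the model.
    """

    L: float = 1.0
    E: float = 1.0e5
    radius_max: float = 0.04
    radius_floor: float = 0.1
    internal_viscosity: float = 0.0

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("Young's modulus must be positive")
        if self.radius_max <= 0:
            raise ValueError("body radius must be positive")

    def radius_profile(self, u: np.ndarray) -> np.ndarray:
        """Spindle radius r(u): an ellipse of revolution with a floor."""
        u = np.asarray(u, dtype=float)
        r = self.radius_max * 2.0 * np.sqrt(np.clip(u * (1.0 - u), 0.0, None))
        return np.maximum(r, self.radius_floor * self.radius_max)

    def I2_profile(self, u: np.ndarray) -> np.ndarray:
        """Second moment of area I2(u) = pi r^4 / 4 (mm^4)."""
        return np.pi * self.radius_profile(u) ** 4 / 4.0


@dataclass(frozen=True)
class Environment:
    """Resistive-force-theory drag environment.

    ``K_tau`` and ``K_nu`` are tangential and normal drag coefficients per
    unit body length (uN s mm^-2, numerically equal to N s m^-2).  Agar-like
    media have a large K_nu/K_tau ratio (strong lateral anchoring); water-like
    media are nearly isotropic.
    """

    K_tau: float
    K_nu: float
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.K_tau <= 0:
            raise ValueError("K_tau must be positive")
        if self.K_nu < self.K_tau:
            raise ValueError("K_nu must be >= K_tau")

    @classmethod
    def agar_like(cls, scale: float = 1.0) -> "Environment":
        # Calibrated so the proprioceptive wild type crawls in the reported
        # 0.3-0.9 Hz band; the 40x anisotropy ratio follows the
        # resistive-force-theory literature for crawling on agar.
        return cls(K_tau=scale * 3.2, K_nu=scale * 128.0, label="agar_like")

    @classmethod
    def water_like(cls, scale: float = 1.0) -> "Environment":
        return cls(K_tau=scale * 3.5e-6, K_nu=scale * 5.2e-6, label="water_like")


@dataclass
class BodyState:
    """Discretized midline at one instant.

    t : time (s).
    u_grid : N material coordinates in [0, 1], head at u=0.
    x : (N, 2) lab-frame midline coordinates (mm).
    theta : (N-1,) segment angles (rad); x is the head point plus the
        cumulative sum of unit segments, so segment lengths are exactly
        L/(N-1).
    kappa : (N,) signed curvature per node (mm^-1); positive = dorsal bend
        (left turn when walking head to tail).
    tension : (N-1,) internal line tension per segment (uN); zeros unless
        recovered via :func:`internal_tension`.
    """

    t: float
    u_grid: np.ndarray
    x: np.ndarray
    theta: np.ndarray
    kappa: np.ndarray
    tension: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.u_grid)
        if n < 3:
            raise ValueError("need at least 3 midline points")
        if self.x.shape != (n, 2) or self.theta.shape != (n - 1,):
            raise ValueError("inconsistent state array shapes")
        if self.tension is None:
            self.tension = np.zeros(n - 1)

    @property
    def n_points(self) -> int:
        return len(self.u_grid)

    @property
    def segment_length(self) -> float:
        return float(np.linalg.norm(self.x[1] - self.x[0]))

    @property
    def arclength(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.x, axis=0), axis=1)))

    def centroid(self) -> np.ndarray:
        return self.x.mean(axis=0)


# ---------------------------------------------------------------------------
# geometry


def curvature_from_coords(x: np.ndarray) -> np.ndarray:
    """Signed curvature per point from midline coordinates.

    Interior points use the circumscribed-circle (Menger) curvature of each
    consecutive triplet, signed by the turn direction (positive = dorsal by
    the left-turn convention); end points copy their interior neighbor.
    Collinear triplets give exactly 0.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2 or x.shape[0] < 3:
        raise DegenerateGeometryError("need an (N>=3, 2) coordinate array")
    e = np.diff(x, axis=0)
    le = np.linalg.norm(e, axis=1)
    if np.any(le == 0.0):
        raise DegenerateGeometryError("repeated midline points (zero-length segment)")
    a, b = e[:-1], e[1:]
    chord = np.linalg.norm(x[2:] - x[:-2], axis=1)
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    denom = le[:-1] * le[1:] * chord
    interior = np.where(denom > 0.0, 2.0 * cross / np.where(denom == 0.0, 1.0, denom), 0.0)
    kappa = np.empty(x.shape[0])
    kappa[1:-1] = interior
    kappa[0] = interior[0]
    kappa[-1] = interior[-1]
    return kappa


def _tangents_normals(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit tangents (head-to-tail) and left normals at each node."""
    e = np.diff(x, axis=0)
    le = np.linalg.norm(e, axis=1, keepdims=True)
    if np.any(le == 0.0):
        raise DegenerateGeometryError("zero-length segment")
    d = e / le
    t = np.empty_like(x)
    t[0], t[-1] = d[0], d[-1]
    mid = d[:-1] + d[1:]
    norm = np.linalg.norm(mid, axis=1, keepdims=True)
    t[1:-1] = mid / np.where(norm == 0.0, 1.0, norm)
    n = np.stack([-t[:, 1], t[:, 0]], axis=1)
    return t, n


def drag_force(state: BodyState, env: Environment, velocity: np.ndarray) -> np.ndarray:
    """Resistive force per unit length at each node (uN/mm).

    F = -(K_tau v_tau tau_hat + K_nu v_nu nu_hat): linear in the local
    velocity and opposing it, so the power F.v is never positive.
    """
    velocity = np.asarray(velocity, dtype=float)
    if velocity.shape != state.x.shape:
        raise ValueError("velocity must match the midline grid")
    t, n = _tangents_normals(state.x)
    v_tau = np.sum(velocity * t, axis=1, keepdims=True)
    v_nu = np.sum(velocity * n, axis=1, keepdims=True)
    return -(env.K_tau * v_tau * t + env.K_nu * v_nu * n)


# ---------------------------------------------------------------------------
# construction helpers


def _state_from_theta(t: float, x0: np.ndarray, theta: np.ndarray, L: float) -> BodyState:
    n = len(theta) + 1
    h = L / (n - 1)
    d = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    x = np.empty((n, 2))
    x[0] = x0
    np.cumsum(h * d, axis=0, out=x[1:])
    x[1:] += x0
    kappa = np.empty(n)
    kappa[1:-1] = np.diff(theta) / h
    kappa[0], kappa[-1] = kappa[1], kappa[-2]
    return BodyState(t=t, u_grid=np.linspace(0.0, 1.0, n), x=x, theta=theta, kappa=kappa)


def straight_body(n_points: int = 48, mech: MechParams = MechParams()) -> BodyState:
    """Straight body along +x, head at the origin."""
    return _state_from_theta(0.0, np.zeros(2), np.zeros(n_points - 1), mech.L)


def body_from_curvature(kappa_junctions: np.ndarray, mech: MechParams = MechParams()) -> BodyState:
    """Body whose junction curvatures equal the given (N-2,) profile."""
    kappa_junctions = np.asarray(kappa_junctions, dtype=float)
    n = len(kappa_junctions) + 2
    h = mech.L / (n - 1)
    theta = np.concatenate([[0.0], np.cumsum(kappa_junctions * h)])
    return _state_from_theta(0.0, np.zeros(2), theta, mech.L)


def body_from_curvature_wave(
    n_points: int = 48,
    mech: MechParams = MechParams(),
    amplitude: float = 5.0,
    wavelength: float = 0.65,
    phase: float = 0.0,
) -> BodyState:
    """Body laid along one period of a curvature wave kappa = A sin(2 pi u L / lambda + phase).

    Used as the initial condition so that simulations start on (rather than
    far from) the target waveform; the first seconds are discarded as a
    transient anyway.
    """
    n = n_points
    h = mech.L / (n - 1)
    u_seg = (np.arange(n - 1) + 0.5) * h / mech.L
    kappa = amplitude * np.sin(2.0 * np.pi * u_seg * mech.L / wavelength + phase)
    theta = np.concatenate([[0.0], np.cumsum(kappa[:-1] * h)])
    return _state_from_theta(0.0, np.zeros(2), theta, mech.L)


# ---------------------------------------------------------------------------
# elastic operators


def _junction_grid(n_points: int) -> np.ndarray:
    """Material coordinates of the N-2 interior junctions where curvature,
    muscle drive, and neural fields live."""
    return np.arange(1, n_points - 1) / (n_points - 1)


def _bending_stiffness(n_points: int, mech: MechParams) -> np.ndarray:
    """E I2 at each interior junction (uN mm^2)."""
    return mech.E * mech.I2_profile(_junction_grid(n_points))


def bending_energy(state: BodyState, beta: np.ndarray, mech: MechParams) -> float:
    """Total elastic energy 1/2 integral E I2 (kappa - beta)^2 du (uN mm)."""
    n = state.n_points
    h = mech.L / (n - 1)
    k = _bending_stiffness(n, mech)
    kappa_j = np.diff(state.theta) / h
    return float(0.5 * np.sum(k * (kappa_j - np.asarray(beta)) ** 2) * h)


_STEP_CACHE: dict = {}


def _step_constants(n: int, mech: MechParams):
    """Per-(grid, body) constants reused every step: elastic Hessian,
    junction stiffness, drag weights and the Jacobian support mask."""
    key = (n, mech)
    hit = _STEP_CACHE.get(key)
    if hit is not None:
        return hit
    h = mech.L / (n - 1)
    p = n + 1
    k = _bending_stiffness(n, mech)
    A = np.zeros((p, p))
    main = np.zeros(n - 1)
    main[:-1] += k / h
    main[1:] += k / h
    idx = np.arange(n - 1)
    A[2 + idx, 2 + idx] = main
    A[2 + idx[:-1], 2 + idx[1:]] = -k / h
    A[2 + idx[1:], 2 + idx[:-1]] = -k / h
    w = np.full(n, h)
    w[0] = w[-1] = 0.5 * h
    mask = (np.arange(n)[:, None] > np.arange(n - 1)[None, :]).astype(float)
    out = (h, k, A, w, mask)
    _STEP_CACHE[key] = out
    return out


def step_body(
    state: BodyState,
    beta: np.ndarray,
    mech: MechParams,
    env: Environment,
    dt: float,
    with_tension: bool = False,
) -> BodyState:
    """Advance the body by one time step under preferred-curvature drive.

    ``beta`` is the preferred-curvature field on the N-2 interior junctions
    (mm^-1).  Zero force and torque at the free ends are natural boundary
    conditions of the energy formulation, which is equivalent to beta = kappa
    at u = 0, 1.  Deterministic: identical inputs give bit-identical output.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = state.n_points
    m = n - 2
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (m,):
        raise ValueError(f"beta must live on the {m} interior junctions")
    h, k, A, w, mask = _step_constants(n, mech)
    theta = state.theta
    p = n + 1

    # drag metric at the current configuration, contracted directly into the
    # generalized-coordinate space: R = K_tau J't w t'J + K_nu J'n w n'J
    t_hat, n_hat = _tangents_normals(state.x)
    J = np.zeros((n, 2, p))
    J[:, 0, 0] = 1.0
    J[:, 1, 1] = 1.0
    d = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    J[:, 0, 2:] = -h * d[:, 1] * mask  # d x_i/d theta_j = h * perp(d_j)
    J[:, 1, 2:] = h * d[:, 0] * mask
    tJ = t_hat[:, 0, None] * J[:, 0, :] + t_hat[:, 1, None] * J[:, 1, :]
    nJ = n_hat[:, 0, None] * J[:, 0, :] + n_hat[:, 1, None] * J[:, 1, :]
    R = env.K_tau * (tJ.T @ (w[:, None] * tJ)) + env.K_nu * (nJ.T @ (w[:, None] * nJ))

    # elastic gradient at the current angles
    moments = k * (np.diff(theta) / h - beta)  # bending moment (uN mm)
    grad_theta = np.zeros(n - 1)
    grad_theta[:-1] -= moments
    grad_theta[1:] += moments

    # semi-implicit Euler: (R/dt + A) q_new = R/dt q + (b - A q + A q) ...
    # elastic force is -grad E = -(A_theta theta - L^T K beta); write the
    # implicit system in increments dq: (R/dt + A) dq = -grad E(theta)
    lhs = R / dt + A
    rhs = np.zeros(p)
    rhs[2:] = -grad_theta
    try:
        cf = cho_factor(lhs, check_finite=False)
        dq = cho_solve(cf, rhs, check_finite=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise SolverError(f"mechanics solve failed: {exc}") from exc
    if not np.all(np.isfinite(dq)):
        raise SolverError("mechanics solve produced non-finite increment")
    if np.max(np.abs(dq[2:])) > 0.5 * np.pi:
        raise SolverError(
            "dt too large: segment rotation "
            f"{np.max(np.abs(dq[2:])):.3g} rad in one step (residual norm "
            f"{np.linalg.norm(rhs):.3g} uN mm)"
        )

    x0_new = state.x[0] + dq[:2]
    theta_new = theta + dq[2:]
    new = _state_from_theta(state.t + dt, x0_new, theta_new, mech.L)
    if with_tension:
        new.tension = internal_tension(state, new, beta, mech, env, dt)
    return new


def internal_tension(
    prev: BodyState,
    new: BodyState,
    beta: np.ndarray,
    mech: MechParams,
    env: Environment,
    dt: float,
) -> np.ndarray:
    """Recover the line tension p per segment from the nodal force balance.

    The tension is the Lagrange-multiplier force enforcing inextensibility:
    drag - bending = divergence of (p tau_hat).  Solved in the least-squares
    sense over the 2N nodal balance equations.
    """
    n = prev.n_points
    h = mech.L / (n - 1)
    v = (new.x - prev.x) / dt
    f_drag = drag_force(prev, env, v) * np.where(
        np.arange(n)[:, None] % (n - 1) == 0, 0.5 * h, h
    )
    # nodal bending forces at the new configuration: -dE/dx via angle gradients
    k = _bending_stiffness(n, mech)
    moments = k * (np.diff(new.theta) / h - np.asarray(beta))
    e = np.diff(new.x, axis=0)
    le2 = np.sum(e * e, axis=1)
    # gradient of segment orientation alpha_i wrt endpoints
    g = np.stack([-e[:, 1], e[:, 0]], axis=1) / le2[:, None]
    f_bend = np.zeros_like(new.x)
    for j, mom in enumerate(moments):
        i = j + 1  # junction between segments i-1 and i
        # turning angle phi_j = alpha_i - alpha_{i-1}; f = -m dphi/dx
        f_bend[i + 1] -= mom * g[i]
        f_bend[i] += mom * (g[i] + g[i - 1])
        f_bend[i - 1] -= mom * g[i - 1]
    residual = -(f_drag + f_bend)  # = div(p tau)
    d = e / np.sqrt(le2)[:, None]
    # build divergence operator D: (2n, n-1), residual = D p
    D = np.zeros((2 * n, n - 1))
    for i in range(n - 1):
        D[2 * i : 2 * i + 2, i] -= d[i]
        D[2 * (i + 1) : 2 * (i + 1) + 2, i] += d[i]
    p, *_ = np.linalg.lstsq(D, residual.reshape(-1), rcond=None)
    return -p
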