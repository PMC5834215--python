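"""Coupled two-oscillator central pattern generator (CPG) for vocal production.

The model couples a slow respiratory oscillator (subglottal pressure) and a
fast laryngeal oscillator (vocal-fold tension).  Each CPG is a planar system

    dx/dt = y
    dy/dt = gamma^2 * a - gamma^2 * x + gamma * y - gamma * x^2 * y
            + gamma^2 * alpha_ji * y_j

whose only fixed point sits at (x, y) = (a, 0).  The drive ``a`` moves the
fixed point; for |a| < 1 the fixed point is unstable and the oscillator runs
on a limit cycle (Hopf bifurcations at a = -1 and a = +1), while |a| > 1
gives a stable fixed point.  ``gamma`` sets the oscillation rate (angular
frequency ~ gamma near the Hopf boundary).  Both oscillators receive a
common relative drive I in [0, 1], each linearly rescaled into its own drive
range, so a single arousal-like input steers the whole system through its
dynamical regimes.

Oscillator outputs are squashed into physiological ranges: subglottal
pressure p = p0 * tanh(x1) in (-p0, p0) and laryngeal tension
k = k0 / (1 + exp(-(x2 - x20))) in (0, k0).

Time is in seconds throughout; ``gamma`` carries implicit units of 1/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "OscillatorParams",
    "CPGParams",
    "CPGState",
    "DriveSchedule",
    "SimTrace",
    "StabilityReport",
    "IntegrationError",
    "drive_from_relative",
    "ramp_drive",
    "constant_drive",
    "cpg_vector_field",
    "integrate_cpg",
    "output_transforms",
    "linear_stability",
]


class IntegrationError(RuntimeError):
    """Raised when the state becomes non-finite during integration."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"non-finite state at integration step {step}")


@dataclass(frozen=True)
class OscillatorParams:
    """One planar CPG oscillator.

    Parameters
    ----------
    gamma : float
        Time constant (1/s); larger gamma means faster oscillation.
    a_min, a_max : float
        Bounds of the drive range; the relative drive I in [0, 1] is mapped
        linearly onto [a_min, a_max].
    coupling_in : float
        Coupling strength alpha_ji multiplying the *other* oscillator's
        velocity y_j in this oscillator's acceleration equation.
    """

    gamma: float
    a_min: float
    a_max: float
    coupling_in: float = 0.0

    def __post_init__(self):
        if not self.gamma > 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if not self.a_min < self.a_max:
            raise ValueError(f"need a_min < a_max, got [{self.a_min}, {self.a_max}]")


@dataclass(frozen=True)
class CPGParams:
    """Full coupled-CPG parameter set.

    Defaults are the published operating point: respiratory oscillator
    gamma1 = 2.5 (nominal, within the 2-3 developmental range) with drive
    range [-0.1, 0.1] and incoming laryngeal coupling alpha21 = 4;
    laryngeal oscillator gamma2 = 25 with drive range [-1, 1] and incoming
    respiratory coupling alpha12 = 0.015.  Output scales p0 = 0.1 (pressure),
    k0 = 32 and x20 = 5 (tension sigmoid).

    The laryngeal->respiratory coupling is the strong one: the fast
    laryngeal limit cycle must be able to break respiration into
    "minibreaths", while the reverse influence is weak.
    """

    resp: OscillatorParams = field(
        default_factory=lambda: OscillatorParams(
            gamma=2.5, a_min=-0.1, a_max=0.1, coupling_in=4.0
        )
    )
    lar: OscillatorParams = field(
        default_factory=lambda: OscillatorParams(
            gamma=25.0, a_min=-1.0, a_max=1.0, coupling_in=0.015
        )
    )
    p0: float = 0.1
    k0: float = 32.0
    x20: float = 5.0

    def __post_init__(self):
        if not self.p0 > 0:
            raise ValueError("p0 must be positive")
        if not self.k0 > 0:
            raise ValueError("k0 must be positive")

    def with_gamma1(self, gamma1: float) -> "CPGParams":
        """Copy of the parameter set with the respiratory time constant replaced."""
        return replace(self, resp=replace(self.resp, gamma=gamma1))


@dataclass(frozen=True)
class CPGState:
    """Instantaneous state (x1, y1) respiratory, (x2, y2) laryngeal."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self):
        if not np.all(np.isfinite([self.x1, self.y1, self.x2, self.y2])):
            raise ValueError("state must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.y1, self.x2, self.y2], dtype=float)


class DriveSchedule:
    """Sampled relative-drive profile t -> I(t), linearly interpolated.

    I must stay in [0, 1]; t must be strictly increasing.  Evaluation
    outside the sampled span clamps to the endpoint values.
    """

    def __init__(self, t: np.ndarray, I: np.ndarray):
        t = np.asarray(t, dtype=float)
        I = np.asarray(I, dtype=float)
        if t.ndim != 1 or t.shape != I.shape:
            raise ValueError("t and I must be 1-D arrays of equal length")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(I)):
            raise ValueError("schedule values must be finite")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("t must be strictly increasing")
        if np.any(I < 0) or np.any(I > 1):
            raise ValueError("relative drive I must lie in [0, 1]")
        self.t = t
        self.I = I

    def __call__(self, t):
        return np.interp(t, self.t, self.I)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


def ramp_drive(duration_s: float, I_start: float, I_end: float, dt: float) -> DriveSchedule:
    """Linear ramp of the relative drive, sampled at ``dt``.

    The published demonstration ramps I from 0 to 1 over 6 s, traversing
    immature contact -> trill/twitter -> mature contact regimes.
    """
    vals = [duration_s, I_start, I_end, dt]
    if not np.all(np.isfinite(vals)):
        raise ValueError("ramp inputs must be finite")
    if duration_s <= 0 or dt <= 0:
        raise ValueError("duration_s and dt must be positive")
    n = int(round(duration_s / dt))
    t = np.linspace(0.0, duration_s, n + 1)
    I = np.linspace(I_start, I_end, n + 1)
    return DriveSchedule(t, I)


def constant_drive(I: float, duration_s: float) -> DriveSchedule:
    """Constant relative drive, as used for one cell of a regime sweep."""
    return DriveSchedule(np.array([0.0, duration_s]), np.array([I, I]))


def drive_from_relative(I, osc: OscillatorParams):
    """Map relative drive I in [0, 1] onto the oscillator's own drive range.

    a = a_min + I * (a_max - a_min).  Both CPGs receive the same I, each
    scaled to its own range.  Accepts scalars or arrays.
    """
    I = np.asarray(I, dtype=float)
    if np.any(I < 0) or np.any(I > 1):
        raise ValueError("relative drive I must lie in [0, 1]")
    a = osc.a_min + I * (osc.a_max - osc.a_min)
    return float(a) if a.ndim == 0 else a


def _field_arrays(x1, y1, x2, y2, a1, a2, params: CPGParams):
    """Vector field, broadcasting over array-valued states/drives."""
    g1 = params.resp.gamma
    g2 = params.lar.gamma
    a21 = params.resp.coupling_in
    a12 = params.lar.coupling_in
    dx1 = y1
    dy1 = g1 * g1 * (a1 - x1 + a21 * y2) + g1 * y1 * (1.0 - x1 * x1)
    dx2 = y2
    dy2 = g2 * g2 * (a2 - x2 + a12 * y1) + g2 * y2 * (1.0 - x2 * x2)
    return dx1, dy1, dx2, dy2


def cpg_vector_field(state: CPGState, a1: float, a2: float, params: CPGParams):
    """Time derivative of the coupled system at ``state`` under drives (a1, a2).

    Implements, for each oscillator i with partner j:

        dx_i/dt = y_i
        dy_i/dt = gamma_i^2 a_i - gamma_i^2 x_i + gamma_i y_i
                  - gamma_i x_i^2 y_i + gamma_i^2 alpha_ji y_j

    (a1, 0, a2, 0) is an exact fixed point for every parameter choice since
    the coupling vanishes with the partner's velocity.
    """
    d = _field_arrays(state.x1, state.y1, state.x2, state.y2, a1, a2, params)
    return tuple(float(v) for v in d)


@dataclass
class SimTrace:
    """Post-burn-in trajectory with derived pressure and tension.

    Arrays share one length; ``p`` is bounded by (-p0, p0) and ``k`` by
    (0, k0) by construction of the saturating output transforms.
    """

    t: np.ndarray
    x1: np.ndarray
    y1: np.ndarray
    x2: np.ndarray
    y2: np.ndarray
    I: np.ndarray
    p: np.ndarray
    k: np.ndarray
    dt: float
    burn_in_steps: int

    def __post_init__(self):
        n = len(self.t)
        for name in ("x1", "y1", "x2", "y2", "I", "p", "k"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"array {name!r} length mismatch")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "x1": self.x1,
                "y1": self.y1,
                "x2": self.x2,
                "y2": self.y2,
                "I": self.I,
                "p": self.p,
                "k": self.k,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def output_transforms(x1: np.ndarray, x2: np.ndarray, params: CPGParams):
    """Saturate raw oscillator amplitudes into pressure and tension.

    p = p0 * tanh(x1);  k = k0 / (1 + exp(-(x2 - x20))).
    """
    p = params.p0 * np.tanh(np.asarray(x1, dtype=float))
    k = params.k0 / (1.0 + np.exp(-(np.asarray(x2, dtype=float) - params.x20)))
    return p, k


def integrate_cpg(
    params: CPGParams,
    schedule: DriveSchedule,
    dt: float = 0.01,
    n_burn: int = 500,
    n_keep: int = 2000,
    init: CPGState | None = None,
    perturbation: float = 1e-3,
    seed: int | None = None,
) -> SimTrace:
    """Integrate the coupled CPG with classic fixed-step 4th-order Runge-Kutta.

    ``n_burn`` leading steps are discarded and ``n_keep`` retained, matching
    the sweep protocol (500 discarded + 2000 kept at dt = 0.01).  The drive
    follows ``schedule`` (constant for regime sweeps, a ramp for
    demonstration runs).  The default initial condition is the instantaneous
    fixed point (a1(0), 0, a2(0), 0) nudged by ``perturbation`` on x1 and x2
    so limit cycles are entered from rest.

    ``seed`` is accepted for interface uniformity with the stochastic stages
    of the pipeline but is unused: the model is deterministic.

    Raises
    ------
    IntegrationError
        If the state blows up (non-finite), naming the step index.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    if n_burn < 0:
        raise ValueError("n_burn must be >= 0")

    n_total = n_burn + n_keep
    t_grid = np.arange(n_total + 1) * dt
    I_grid = schedule(t_grid)
    I_half = schedule(t_grid[:-1] + 0.5 * dt)
    a1_grid = drive_from_relative(I_grid, params.resp)
    a2_grid = drive_from_relative(I_grid, params.lar)
    a1_half = drive_from_relative(I_half, params.resp)
    a2_half = drive_from_relative(I_half, params.lar)

    if init is None:
        init = CPGState(
            a1_grid[0] + perturbation, 0.0, a2_grid[0] + perturbation, 0.0
        )
    state = init.as_array()

    out = np.empty((n_total + 1, 4), dtype=float)
    out[0] = state
    with np.errstate(over="ignore", invalid="ignore"):  # blow-ups caught below
        for i in range(n_total):
            state = _rk4_step(
                state,
                dt,
                (a1_grid[i], a2_grid[i]),
                (a1_half[i], a2_half[i]),
                (a1_grid[i + 1], a2_grid[i + 1]),
                params,
            )
            if not np.all(np.isfinite(state)):
                raise IntegrationError(i + 1)
            out[i + 1] = state

    keep = slice(n_burn + 1, n_total + 1)
    x1, y1, x2, y2 = out[keep].T
    p, k = output_transforms(x1, x2, params)
    return SimTrace(
        t=t_grid[keep].copy(),
        x1=x1.copy(),
        y1=y1.copy(),
        x2=x2.copy(),
        y2=y2.copy(),
        I=I_grid[keep].copy(),
        p=p,
        k=k,
        dt=dt,
        burn_in_steps=n_burn,
    )


def _rk4_step(state, dt, a_t, a_half, a_next, params: CPGParams):
    """One classic RK4 step; drives evaluated at t, t + dt/2 and t + dt."""

    def f(s, drives):
        return np.array(_field_arrays(s[0], s[1], s[2], s[3], drives[0], drives[1], params))

    k1 = f(state, a_t)
    k2 = f(state + 0.5 * dt * k1, a_half)
    k3 = f(state + 0.5 * dt * k2, a_half)
    k4 = f(state + dt * k3, a_next)
    return state + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def rk4_batch(
    a1: np.ndarray,
    a2: np.ndarray,
    gamma1: np.ndarray,
    gamma2: float,
    alpha21: float,
    alpha12: float,
    dt: float = 0.01,
    n_burn: int = 500,
    n_keep: int = 2000,
    perturbation: float = 1e-3,
):
    """Vectorised constant-drive RK4 over a batch of (a1, a2, gamma1) cells.

    All inputs broadcast to a common batch shape.  Returns post-burn-in
    (x1, x2) arrays of shape (n_cells, n_keep) plus the y2 history needed
    nowhere downstream (dropped to bound memory).  Used by the regime sweep,
    where thousands of constant-drive cells integrate in lock-step.
    """
    a1, a2, g1 = np.broadcast_arrays(
        np.asarray(a1, float), np.asarray(a2, float), np.asarray(gamma1, float)
    )
    shape = a1.shape
    a1 = a1.ravel()
    a2 = a2.ravel()
    g1 = g1.ravel()
    n = a1.size
    g2 = float(gamma2)

    x1 = a1 + perturbation
    y1 = np.zeros(n)
    x2 = a2 + perturbation
    y2 = np.zeros(n)
    state = np.stack([x1, y1, x2, y2])

    def f(s):
        x1, y1, x2, y2 = s
        return np.stack(
            [
                y1,
                g1 * g1 * (a1 - x1 + alpha21 * y2) + g1 * y1 * (1.0 - x1 * x1),
                y2,
                g2 * g2 * (a2 - x2 + alpha12 * y1) + g2 * y2 * (1.0 - x2 * x2),
            ]
        )

    keep_x1 = np.empty((n, n_keep))
    keep_x2 = np.empty((n, n_keep))
    with np.errstate(over="ignore", invalid="ignore"):  # bad cells flagged below
        for i in range(n_burn + n_keep):
            k1 = f(state)
            k2 = f(state + 0.5 * dt * k1)
            k3 = f(state + 0.5 * dt * k2)
            k4 = f(state + dt * k3)
            state = state + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            if i >= n_burn:
                j = i - n_burn
                keep_x1[:, j] = state[0]
                keep_x2[:, j] = state[2]
    bad = ~np.all(np.isfinite(state), axis=0)
    return keep_x1.reshape(*shape, n_keep), keep_x2.reshape(*shape, n_keep), bad.reshape(shape)


@dataclass(frozen=True)
class StabilityReport:
    """Linear stability of one uncoupled oscillator at its fixed point (a, 0).

    The Jacobian is [[0, 1], [-gamma^2, gamma(1 - a^2)]]: trace
    T = gamma(1 - a^2), determinant D = gamma^2 > 0.  The trace changes
    sign exactly at |a| = 1, the Hopf boundary.
    """

    fixed_point: tuple
    trace: float
    det: float
    eigenvalues: tuple
    classification: str


def linear_stability(a: float, gamma: float, boundary_tol: float = 1e-9) -> StabilityReport:
    """Classify the uncoupled oscillator's fixed point at drive ``a``.

    |a| < 1: unstable (a stable limit cycle surrounds the fixed point);
    |a| > 1: stable node or spiral depending on the discriminant;
    |a| = 1: Hopf boundary (trace zero).
    """
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    T = gamma * (1.0 - a * a)
    D = gamma * gamma
    disc = T * T - 4.0 * D
    if disc >= 0:
        root = np.sqrt(disc)
        eig = ((T + root) / 2.0 + 0j, (T - root) / 2.0 + 0j)
    else:
        root = np.sqrt(-disc)
        eig = (complex(T / 2.0, root / 2.0), complex(T / 2.0, -root / 2.0))
    if abs(T) <= boundary_tol:
        cls = "hopf-boundary"
    elif T > 0:
        cls = "unstable"
    elif disc < 0:
        cls = "stable-spiral"
    else:
        cls = "stable-node"
    return StabilityReport(
        fixed_point=(a, 0.0), trace=T, det=D, eigenvalues=eig, classification=cls
    )
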