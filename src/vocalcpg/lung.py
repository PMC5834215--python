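"""Wilson-Cowan respiratory network coupled to lung mechanics.

This module backs the modelling assumption that heavier lungs breathe more
slowly.  An excitatory-inhibitory rate network (time constant ``tau_wc``)
drives the lung, modelled as a damped mass-spring element, and the lung
volume feeds back *negatively* on the excitatory population — the
architecture used for birdsong air-sac respiration.  The network equations
are the standard two-population Wilson-Cowan sigmoid-rate system:

    tau_wc * dE/dt = -E + S(c_ee*E - c_ei*I + E1 - k_wc*V)
    tau_wc * dI/dt = -I + S(c_ie*E - c_ii*I + E2)
    mass * d2V/dt2 = -damping*dV/dt - stiffness*V + mu_wc*E

with S(x) = 1/(1+exp(-x)).  Biases, neural time constant, feedback gain
and motor coefficient follow the published values (E1 = E2 = -2,
tau = 0.31, k = 5, mu = 1); the within-network weights and the mechanical
constants are this package's own architecture-level choices (the source
gives the architecture, not the full functional forms), so the implemented
system is an architecture-faithful stand-in.  The claim it exists to
check — oscillation period strictly increasing with lung mass — is a
property of the architecture, not of a particular weight setting.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "LungModelParams",
    "LungTrace",
    "NoOscillationError",
    "wc_lung_vector_field",
    "simulate_lung_cycle",
    "cycle_period",
]


class NoOscillationError(RuntimeError):
    """The lung-volume trace shows no detectable oscillation.

    Distinct from a numerical failure: the integration succeeded but the
    system settled to a fixed point (or never produced >= 3 cycles).
    """


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class LungModelParams:
    """Parameters of the neural-mechanical respiratory loop.

    E1, E2 : input biases to the excitatory/inhibitory populations (-2, -2).
    tau_wc : neural time constant in seconds (0.31).
    k_wc : gain of the negative volume feedback onto the excitatory unit (5).
    mu_wc : motor coefficient converting excitatory rate to driving force (1).
    mass : lung mass in arbitrary units; the swept quantity.
    damping, stiffness : mechanical constants of the lung element.  The
        defaults (stiffness 0.5, damping 0.3) are deliberately underdamped
        and compliant so that the slow mechanical recoil — not the neural
        time constant — paces the loop; that is what makes the rhythm
        inherit the lung's inertia and the period grow with mass.
    c_ee, c_ei, c_ie, c_ii : within-network connection weights.  Weak
        resting inhibition (c_ei = 4) keeps the excitatory unit excitable
        at the subthreshold bias E1 = -2, so the volume feedback can
        switch it on and off once per breath.
    """

    E1: float = -2.0
    E2: float = -2.0
    tau_wc: float = 0.31
    k_wc: float = 5.0
    mu_wc: float = 1.0
    mass: float = 1.0
    damping: float = 0.3
    stiffness: float = 0.5
    c_ee: float = 16.0
    c_ei: float = 4.0
    c_ie: float = 10.0
    c_ii: float = 3.0

    def __post_init__(self):
        if not self.tau_wc > 0:
            raise ValueError("tau_wc must be positive")
        if not self.mass > 0:
            raise ValueError("mass must be positive")

    def with_mass(self, mass: float) -> "LungModelParams":
        return replace(self, mass=mass)


def wc_lung_vector_field(state, params: LungModelParams):
    """Derivative (dE, dI, dV, dW) at state (E, I, V, W) with W = dV/dt.

    The volume enters the excitatory input with a strictly negative
    coefficient -k_wc (sensory feedback opposing inflation).
    """
    E, I, V, W = state
    p = params
    dE = (-E + _sigmoid(p.c_ee * E - p.c_ei * I + p.E1 - p.k_wc * V)) / p.tau_wc
    dI = (-I + _sigmoid(p.c_ie * E - p.c_ii * I + p.E2)) / p.tau_wc
    dV = W
    dW = (-p.damping * W - p.stiffness * V + p.mu_wc * E) / p.mass
    return (dE, dI, dV, dW)


@dataclass
class LungTrace:
    """Simulated loop activity; ``transient_end`` indexes the first sample
    past the initial transient (first 20% of the run)."""

    t: np.ndarray
    excitatory: np.ndarray
    inhibitory: np.ndarray
    volume: np.ndarray
    volume_velocity: np.ndarray
    dt: float
    transient_end: int

    def steady(self) -> "LungTrace":
        """View of the trace with the transient removed."""
        s = slice(self.transient_end, None)
        return LungTrace(
            self.t[s], self.excitatory[s], self.inhibitory[s],
            self.volume[s], self.volume_velocity[s], self.dt, 0,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "excitatory": self.excitatory,
                "inhibitory": self.inhibitory,
                "volume": self.volume,
                "volume_velocity": self.volume_velocity,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def simulate_lung_cycle(
    params: LungModelParams,
    duration: float = 60.0,
    dt: float = 0.01,
    init=(0.1, 0.1, 0.0, 0.0),
) -> LungTrace:
    """Integrate the loop with fixed-step RK4.

    The first 20% of the run is flagged as transient.  Blow-up raises a
    RuntimeError naming the step.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    n = int(round(duration / dt))
    state = np.asarray(init, dtype=float)
    out = np.empty((n + 1, 4))
    out[0] = state

    def f(s):
        return np.asarray(wc_lung_vector_field(s, params))

    for i in range(n):
        k1 = f(state)
        k2 = f(state + 0.5 * dt * k1)
        k3 = f(state + 0.5 * dt * k2)
        k4 = f(state + dt * k3)
        state = state + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(state)):
            raise RuntimeError(f"lung model blew up at step {i + 1}")
        out[i + 1] = state
    t = np.arange(n + 1) * dt
    return LungTrace(
        t=t,
        excitatory=out[:, 0],
        inhibitory=out[:, 1],
        volume=out[:, 2],
        volume_velocity=out[:, 3],
        dt=dt,
        transient_end=int(0.2 * (n + 1)),
    )


def cycle_period(trace: LungTrace, min_prominence_frac: float = 0.1) -> float:
    """Mean inter-peak interval (s) of the post-transient lung volume.

    Raises :class:`NoOscillationError` when fewer than 3 complete cycles
    are present or the volume excursion is negligible.
    """
    steady = trace.steady()
    v = steady.volume
    pp = float(np.ptp(v))
    scale = max(abs(float(np.max(np.abs(v)))), 1e-12)
    if pp < 1e-6 * scale or pp == 0.0:
        raise NoOscillationError("lung volume is constant after the transient")
    peaks, _ = find_peaks(v, prominence=min_prominence_frac * pp)
    if peaks.size < 4:  # < 3 complete inter-peak cycles
        raise NoOscillationError(
            f"only {max(peaks.size - 1, 0)} complete cycles detected; need >= 3"
        )
    return float(np.mean(np.diff(peaks)) * steady.dt)
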