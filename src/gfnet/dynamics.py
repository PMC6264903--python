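"""Output-layer dynamics: leaky activations, firing rates, memory traces.

Each output neuron carries an internal activation h (leaky integration of
its synaptic drive), an instantaneous firing rate v obtained by passing h
through a sigmoid whose threshold floats with the population's pi-th
activation percentile (implicit lateral inhibition), and a memory trace q
(low-pass of v).  All ODEs are integrated with Forward Euler at a fixed
step dt, by default one tenth of the activation time constant.

Delayed learning rules read q and v from a ring buffer spanning the largest
delay in use; reads earlier than the start of the simulation return zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DynamicsParams",
    "NetworkState",
    "init_state",
    "percentile_threshold",
    "firing_rates",
    "step_activation",
    "step_trace",
    "read_delayed",
]

_EXP_CLIP = 700.0


@dataclass(frozen=True)
class DynamicsParams:
    tau_h: float = 100.0  # activation time constant (ms)
    tau_q: float = 400.0  # trace time constant (ms)
    phi: float = 4.5  # response sigmoid slope
    theta: float = 0.4  # response sigmoid threshold
    pi_pct: float = 80.0  # competition percentile in [0, 100]
    dt: float | None = None  # solver step (ms); default tau_h / 10

    def __post_init__(self) -> None:
        if self.tau_h <= 0 or self.tau_q <= 0:
            raise ValueError("time constants must be positive")
        if not 0.0 <= self.pi_pct <= 100.0:
            raise ValueError("pi_pct must lie in [0, 100]")
        if self.dt is None:
            object.__setattr__(self, "dt", self.tau_h / 10.0)
        if self.dt <= 0 or self.dt >= min(self.tau_h, self.tau_q):
            raise ValueError("dt must satisfy 0 < dt < min(tau_h, tau_q)")


@dataclass
class NetworkState:
    """Dynamic state of the output layer at simulation time ``t`` (ms)."""

    h: np.ndarray
    q: np.ndarray
    v: np.ndarray
    t: float = 0.0
    step: int = 0
    # ring buffers of past q and v, depth >= ceil(max delay / dt)
    buf_q: np.ndarray = field(default=None, repr=False)
    buf_v: np.ndarray = field(default=None, repr=False)

    @property
    def buffer_depth(self) -> int:
        return 0 if self.buf_q is None else self.buf_q.shape[0]

    def push_history(self) -> None:
        """Record the current q and v as the values for step ``self.step``."""
        if self.buf_q is not None:
            k = self.step % self.buffer_depth
            self.buf_q[k] = self.q
            self.buf_v[k] = self.v


def init_state(N: int, params: DynamicsParams, buffer_depth: int = 0) -> NetworkState:
    """Zero rest state: h = q = 0, v from h through the response sigmoid,
    delay buffers (if any) prefilled with zeros."""
    if N <= 0:
        raise ValueError("N must be positive")
    h = np.zeros(N)
    q = np.zeros(N)
    p_pi = percentile_threshold(h, params.pi_pct)
    v = firing_rates(h, p_pi, params.phi, params.theta)
    buf_q = buf_v = None
    if buffer_depth > 0:
        buf_q = np.zeros((buffer_depth, N))
        buf_v = np.zeros((buffer_depth, N))
    state = NetworkState(h=h, q=q, v=v, buf_q=buf_q, buf_v=buf_v)
    state.push_history()
    return state


def percentile_threshold(h: np.ndarray, pi_pct: float) -> float:
    """pi_pct-th percentile of the activation distribution (linear
    interpolation between order statistics)."""
    if h.size == 0:
        raise ValueError("empty activation vector")
    return float(np.percentile(h, pi_pct))


def firing_rates(h: np.ndarray, p_pi: float, phi: float, theta: float) -> np.ndarray:
    """Sigmoidal response 1 / (1 + exp(-2 phi (h - p_pi - theta)))."""
    x = np.clip(-2.0 * phi * (h - p_pi - theta), -_EXP_CLIP, _EXP_CLIP)
    return 1.0 / (1.0 + np.exp(x))


def step_activation(h: np.ndarray, drive: np.ndarray, tau_h: float, dt: float) -> np.ndarray:
    """One Forward-Euler step of tau_h dh/dt = -h + drive."""
    return h + (dt / tau_h) * (drive - h)


def step_trace(q: np.ndarray, v: np.ndarray, tau_q: float, dt: float) -> np.ndarray:
    """One Forward-Euler step of tau_q dq/dt = -q + v."""
    return q + (dt / tau_q) * (v - q)


def read_delayed(state: NetworkState, which: str, delta_T: float, dt: float) -> np.ndarray:
    """Value of q or v at time t - delta_T.

    delta_T must be a nonnegative integer multiple of dt not exceeding the
    buffer span; reads from before t = 0 return zeros.
    """
    if which not in ("q", "v"):
        raise ValueError("which must be 'q' or 'v'")
    steps = delta_T / dt
    if abs(steps - round(steps)) > 1e-9:
        raise ValueError("delta_T must be an integer multiple of dt")
    d = int(round(steps))
    if d < 0:
        raise ValueError("delta_T must be nonnegative")
    if d == 0:
        return state.q if which == "q" else state.v
    if state.buf_q is None or d >= state.buffer_depth:
        raise ValueError("delay exceeds buffer capacity")
    past = state.step - d
    if past < 0:
        return np.zeros_like(state.h)
    buf = state.buf_q if which == "q" else state.buf_v
    return buf[past % state.buffer_depth]
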