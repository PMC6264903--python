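"""Synaptic learning rules and weight normalisation.

Every rule in the model factorises as dw_ij/dt = g_i * v_j, where v_j is
the presynaptic input rate and g_i is a per-output-neuron postsynaptic
factor built from the neuron's firing rate y_i, its memory trace q_i, and
optionally their time-delayed values:

========================  =============================================
rule                      postsynaptic factor g_i
========================  =============================================
standard_trace            rho * q_i(t)
hebbian                   rho * y_i(t)
delayed_trace_antihebb    alpha * (beta * q_i(t - dT) - y_i(t))
delayed_rate_antihebb     alpha * (beta * y_i(t - dT) - y_i(t))
current_trace_antihebb    alpha * (beta * q_i(t) - y_i(t))
delayed_trace_only        alpha * q_i(t - dT)
========================  =============================================

After every Euler step of the weight ODE, negative weights are clipped to
zero (synapses stay excitatory) and each output neuron's weight vector is
renormalised to unit Euclidean length, which bounds weight growth and
supplies the competition between a neuron's afferents.

The weight ODE is integrated with the step expressed in seconds (learning
rates are per-second), while the neural ODEs use milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RULES",
    "LearningRuleSpec",
    "SynapseSet",
    "make_rule",
    "sample_connectivity",
    "init_weights",
    "weight_derivative",
    "apply_update",
    "renormalise",
]

#: rule name -> (needs_beta, needs_delay, default_beta, default_delta_T_ms)
RULES: dict[str, tuple[bool, bool, float | None, float | None]] = {
    "standard_trace": (False, False, None, None),
    "hebbian": (False, False, None, None),
    "delayed_trace_antihebb": (True, True, 2.2, 50.0),
    "delayed_rate_antihebb": (True, True, 2.4, 500.0),
    "current_trace_antihebb": (True, False, 2.2, None),
    "delayed_trace_only": (False, True, None, 30.0),
}


@dataclass(frozen=True)
class LearningRuleSpec:
    """A learning rule with its hyperparameters.

    ``beta`` and ``delta_T`` default to the tuned values for rules that use
    them and must be absent otherwise.  ``learning_rate`` is per second.
    """

    rule: str = "standard_trace"
    learning_rate: float = 0.05
    beta: float | None = None
    delta_T: float | None = None  # ms

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}; one of {sorted(RULES)}")
        needs_beta, needs_delay, def_beta, def_dT = RULES[self.rule]
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if needs_beta and self.beta is None:
            object.__setattr__(self, "beta", def_beta)
        if needs_delay and self.delta_T is None:
            object.__setattr__(self, "delta_T", def_dT)
        if needs_beta and (self.beta is None or self.beta <= 0):
            raise ValueError(f"rule {self.rule} requires beta > 0")
        if needs_delay and (self.delta_T is None or self.delta_T < 0):
            raise ValueError(f"rule {self.rule} requires delta_T >= 0")
        if not needs_beta and self.beta is not None:
            raise ValueError(f"rule {self.rule} takes no beta")
        if not needs_delay and self.delta_T is not None:
            raise ValueError(f"rule {self.rule} takes no delta_T")

    @property
    def needs_delay(self) -> bool:
        return RULES[self.rule][1]

    def postsynaptic_factor(
        self,
        q: np.ndarray,
        y: np.ndarray,
        q_del: np.ndarray | None = None,
        y_del: np.ndarray | None = None,
    ) -> np.ndarray:
        """Per-output-neuron factor g such that dw_ij/dt = g_i * v_j."""
        a = self.learning_rate
        if self.rule == "standard_trace":
            return a * q
        if self.rule == "hebbian":
            return a * y
        if self.rule == "delayed_trace_antihebb":
            return a * (self.beta * q_del - y)
        if self.rule == "delayed_rate_antihebb":
            return a * (self.beta * y_del - y)
        if self.rule == "current_trace_antihebb":
            return a * (self.beta * q - y)
        # delayed_trace_only
        return a * q_del


def make_rule(spec: LearningRuleSpec | dict | str) -> LearningRuleSpec:
    """Coerce a rule name / mapping into a validated LearningRuleSpec."""
    if isinstance(spec, LearningRuleSpec):
        return spec
    if isinstance(spec, str):
        return LearningRuleSpec(rule=spec)
    return LearningRuleSpec(**spec)


@dataclass
class SynapseSet:
    """Sparse feedforward connectivity with dense per-neuron storage.

    Every output neuron receives the same number K = round(phi * N_I) of
    afferents from its own randomly drawn subset of the input population, so
    the synapses are stored as (N, K) arrays: ``pre_index[i]`` holds the
    presynaptic input indices of output neuron i and ``weights[i]`` the
    aligned nonnegative weights (unit Euclidean norm per row after any
    normalisation).
    """

    pre_index: np.ndarray  # (N, K) int32
    weights: np.ndarray  # (N, K) float64
    phi: float
    n_inputs: int
    seed: int

    @property
    def n_output(self) -> int:
        return self.pre_index.shape[0]

    @property
    def n_afferents(self) -> int:
        return self.pre_index.shape[1]

    def row_norms(self) -> np.ndarray:
        return np.linalg.norm(self.weights, axis=1)


def sample_connectivity(
    N: int, n_inputs: int, phi: float, seed: int
) -> SynapseSet:
    """Draw each output neuron's afferent subset (weights start at zero)."""
    if not 0.0 < phi <= 1.0:
        raise ValueError("connectivity fraction phi must lie in (0, 1]")
    K = int(round(phi * n_inputs))
    if K < 1:
        raise ValueError("connectivity fraction gives zero afferents")
    rng = np.random.default_rng(seed)
    pre = np.empty((N, K), dtype=np.int32)
    for i in range(N):
        pre[i] = rng.choice(n_inputs, size=K, replace=False)
    return SynapseSet(pre_index=pre, weights=np.zeros((N, K)), phi=phi,
                      n_inputs=n_inputs, seed=seed)


def init_weights(synapses: SynapseSet, seed: int) -> SynapseSet:
    """Random initial weights, i.i.d. uniform on [0, 1], then unit-norm."""
    rng = np.random.default_rng(seed)
    synapses.weights = rng.random(synapses.pre_index.shape)
    renormalise(synapses.weights)
    return synapses


def weight_derivative(
    rule: LearningRuleSpec,
    q: np.ndarray,
    y: np.ndarray,
    q_del: np.ndarray | None,
    y_del: np.ndarray | None,
    v_in: np.ndarray,
    synapses: SynapseSet,
) -> np.ndarray:
    """dw/dt for every stored synapse, shaped like ``synapses.weights``."""
    g = rule.postsynaptic_factor(q, y, q_del, y_del)
    return g[:, None] * v_in[synapses.pre_index]


def renormalise(weights: np.ndarray) -> None:
    """In-place per-row unit Euclidean normalisation."""
    norms = np.linalg.norm(weights, axis=1)
    if np.any(norms == 0.0):
        raise FloatingPointError(
            "all-zero weight vector after clipping; learning rate or beta "
            "settings are pathological"
        )
    weights /= norms[:, None]


def apply_update(synapses: SynapseSet, derivative: np.ndarray, dt_ms: float) -> SynapseSet:
    """Euler step of the weight ODE (dt in ms, converted to seconds), clip
    negative weights to zero, then renormalise each row to unit norm."""
    synapses.weights += (dt_ms / 1000.0) * derivative
    np.clip(synapses.weights, 0.0, None, out=synapses.weights)
    renormalise(synapses.weights)
    return synapses
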