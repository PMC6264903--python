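"""Training/testing orchestration for the gain-field network.

A :class:`Model` couples an input population, a sparse synapse set and the
output-layer dynamics.  Training integrates the activation/trace/weight
ODEs with Forward Euler at dt = tau_h / 10 along a saccade-fixation gaze
trajectory, applying the selected learning rule and weight renormalisation
at every step; the dynamic state (activations, traces, delay buffers)
carries over between epochs.  Testing disables learning, runs the
deterministic test schedule and records the instantaneous output rates at
the end of every 330 ms dwell, yielding one E x T response matrix per
output neuron.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels
from .analysis import analyse_responses, population_summary
from .dynamics import (DynamicsParams, firing_rates, init_state,
                       percentile_threshold, read_delayed, step_activation,
                       step_trace)
from .learning import LearningRuleSpec, SynapseSet, init_weights, make_rule, sample_connectivity
from .population import InputPopulation, PopulationConfig, build_input_population
from .protocols import GazeTrajectory, ProtocolConfig, testing_schedule, training_trajectory

__all__ = [
    "Seeds",
    "ModelConfig",
    "Model",
    "Responses",
    "EpochStats",
    "run_training",
    "run_testing",
    "epoch_statistics",
    "sweep_sigmoid_rate",
]


@dataclass(frozen=True)
class Seeds:
    """Named seeds for every source of randomness in a run."""

    connectivity: int = 11
    weights: int = 22
    trajectory: int = 33
    population: int = 44

    def shifted(self, offset: int) -> "Seeds":
        return Seeds(*(s + offset for s in
                       (self.connectivity, self.weights, self.trajectory, self.population)))


@dataclass(frozen=True)
class ModelConfig:
    population: PopulationConfig = field(default_factory=PopulationConfig)
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)
    learning: LearningRuleSpec = field(default_factory=LearningRuleSpec)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    n_output: int = 900
    connectivity: float = 0.05
    epochs: int = 20
    seeds: Seeds = field(default_factory=Seeds)

    def __post_init__(self) -> None:
        if self.n_output <= 0:
            raise ValueError("n_output must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be nonnegative")


@dataclass
class Responses:
    """Test responses for all output neurons: values[n, i, j] is the firing
    rate of neuron n at the i-th eye position and j-th target location."""

    values: np.ndarray  # (N, E, T)
    eye_positions: np.ndarray  # (E,) ascending
    target_locations: np.ndarray  # (T,) ascending

    def matrix(self, neuron: int) -> np.ndarray:
        return self.values[neuron]


@dataclass(frozen=True)
class EpochStats:
    epoch: int
    head_centred_rate: float
    mean_head_centredness: float  # NaN when no head-centred neurons exist
    mean_eye_centredness: float


class Model:
    """An input population wired to a competitive output layer."""

    def __init__(self, config: ModelConfig, population: InputPopulation,
                 synapses: SynapseSet):
        self.config = config
        self.population = population
        self.synapses = synapses
        self.rule = make_rule(config.learning)
        #: clamp weights at zero after each update (Dale's law); settable to
        #: False to study signed-weight variants of the anti-Hebbian rules
        self.clip_negative = True
        self.epochs_trained = 0
        self.state = init_state(config.n_output, config.dynamics,
                                buffer_depth=self._buffer_depth())

    @classmethod
    def from_config(cls, config: ModelConfig) -> "Model":
        pop = build_input_population(config.population, config.seeds.population)
        syn = sample_connectivity(config.n_output, pop.size, config.connectivity,
                                  config.seeds.connectivity)
        init_weights(syn, config.seeds.weights)
        return cls(config, pop, syn)

    def _buffer_depth(self) -> int:
        rule = make_rule(self.config.learning)
        if not rule.needs_delay:
            return 0
        return int(round(rule.delta_T / self.config.dynamics.dt)) + 1

    def reset_state(self) -> None:
        self.state = init_state(self.config.n_output, self.config.dynamics,
                                buffer_depth=self._buffer_depth())

    # -- integration -----------------------------------------------------

    def _train_along(self, traj: GazeTrajectory) -> None:
        p = self.config.dynamics
        dt, dt_s = p.dt, p.dt / 1000.0
        rule, state = self.rule, self.state
        w, pre = self.synapses.weights, self.synapses.pre_index
        drive = np.empty(self.config.n_output)
        n_steps = int(round(traj.duration / dt))
        last_re = (np.nan, np.nan)
        v_in = None
        t0 = state.t
        for s in range(n_steps):
            e, target = traj.sample(state.t - t0)
            r = target - e
            if (r, e) != last_re:
                v_in = self.population.rates(r, e)
                last_re = (r, e)
            q_del = read_delayed(state, "q", rule.delta_T, dt) if rule.needs_delay else None
            v_del = read_delayed(state, "v", rule.delta_T, dt) if rule.needs_delay else None
            g = rule.postsynaptic_factor(state.q, state.v, q_del, v_del) * dt_s
            bad = _kernels.train_step(w, pre, v_in, g, drive,
                                      self.clip_negative)
            if bad >= 0:
                raise FloatingPointError(
                    f"weight vector of output neuron {bad} clipped to zero; "
                    "pathological learning-rate/beta settings")
            h_new = step_activation(state.h, drive, p.tau_h, dt)
            p_pi = percentile_threshold(h_new, p.pi_pct)
            v_new = firing_rates(h_new, p_pi, p.phi, p.theta)
            state.q = step_trace(state.q, state.v, p.tau_q, dt)
            state.h, state.v = h_new, v_new
            state.t += dt
            state.step += 1
            state.push_history()
            if not np.isfinite(state.h).all():
                raise FloatingPointError("non-finite activation; bad parameters")

    def epoch_trajectory(self, epoch: int) -> GazeTrajectory:
        """The training trajectory for a given epoch (fresh saccade draws)."""
        return training_trajectory(config=self.config.protocol,
                                   seed=self.config.seeds.trajectory + epoch)


def run_training(model: Model, epochs: int | None = None) -> Model:
    """Train for ``epochs`` epochs (default: the configured count), one
    fresh trajectory per epoch; state carries over between epochs."""
    if epochs is None:
        epochs = model.config.epochs
    for _ in range(epochs):
        traj = model.epoch_trajectory(model.epochs_trained)
        model._train_along(traj)
        model.epochs_trained += 1
    return model


def run_testing(model: Model, schedule: GazeTrajectory | None = None) -> Responses:
    """Record the E x T response matrix of every output neuron.

    Learning is disabled.  The dynamic state is reset at the start of each
    eye-position sweep and evolves continuously within a sweep; within each
    dwell the input pattern is constant, so the synaptic drive is computed
    once per dwell and the (cheap) rate dynamics are stepped at dt.  The
    model's own training state is left untouched.
    """
    cfg = model.config
    p = cfg.dynamics
    if schedule is None:
        schedule = testing_schedule(config=cfg.protocol)
    dwell = float(schedule.record_marks[0] - schedule.times[0])
    marks_per_sweep = len(schedule.record_marks) // max(len(schedule.sweep_starts), 1)
    eyes, targets = [], []
    n_sub = int(round(dwell / p.dt))
    w, pre = model.synapses.weights, model.synapses.pre_index
    drive = np.empty(cfg.n_output)
    E = len(schedule.sweep_starts)
    T = marks_per_sweep
    values = np.empty((cfg.n_output, E, T))
    for i in range(E):
        state = init_state(cfg.n_output, p)
        sweep_marks = schedule.record_marks[i * T : (i + 1) * T]
        sweep_targets = []
        for j, mark in enumerate(sweep_marks):
            e, target = schedule.sample(mark - dwell / 2.0)
            sweep_targets.append(target)
            v_in = model.population.rates(target - e, e)
            _kernels.compute_drive(w, pre, v_in, drive)
            for _ in range(n_sub):
                h_new = step_activation(state.h, drive, p.tau_h, p.dt)
                p_pi = percentile_threshold(h_new, p.pi_pct)
                v_new = firing_rates(h_new, p_pi, p.phi, p.theta)
                state.q = step_trace(state.q, state.v, p.tau_q, p.dt)
                state.h, state.v = h_new, v_new
            values[:, i, j] = state.v
        eyes.append(e)
        targets = sweep_targets
    return Responses(values=values,
                     eye_positions=np.asarray(eyes),
                     target_locations=np.asarray(targets))


def epoch_statistics(responses: Responses, epoch: int = 0, **analysis_kwargs) -> EpochStats:
    """Classify every analysable neuron and summarise the population."""
    table = analyse_responses(responses, **analysis_kwargs)
    s = population_summary(table, n_total=responses.values.shape[0])
    return EpochStats(epoch=epoch,
                      head_centred_rate=s["head_centred_rate"],
                      mean_head_centredness=s["mean_head_centredness"],
                      mean_eye_centredness=s["mean_eye_centredness"])


def sweep_sigmoid_rate(
    base_config: ModelConfig,
    p_values,
    seeds: Seeds | None = None,
    **analysis_kwargs,
) -> pd.DataFrame:
    """Mixed-population sweep: for each sigmoid modulation rate p, evaluate
    the untrained and trained model and tabulate the population statistics.
    """
    seeds = seeds if seeds is not None else base_config.seeds
    rows = []
    for pv in p_values:
        if not 0.0 <= pv <= 1.0:
            raise ValueError("sigmoid rates must lie in [0, 1]")
        pop_cfg = replace(base_config.population, gain_form="mixed", sigmoid_rate=pv)
        cfg = replace(base_config, population=pop_cfg, seeds=seeds)
        model = Model.from_config(cfg)
        for phase in ("untrained", "trained"):
            if phase == "trained":
                run_training(model)
            stats = epoch_statistics(run_testing(model), **analysis_kwargs)
            rows.append({"p": pv, "phase": phase,
                         "head_centred_rate": stats.head_centred_rate,
                         "mean_head_centredness": stats.mean_head_centredness,
                         "mean_eye_centredness": stats.mean_eye_centredness})
    return pd.DataFrame(rows)
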