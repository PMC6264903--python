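"""Experiment recipes, configuration I/O and reduced-scale fixtures.

Each recipe names one of the study's experiments and expands to a full
:class:`~gfnet.engine.ModelConfig`:

=============================== ============================================
peaked_standard                 peaked gain fields, standard trace rule
sigmoid_standard                pure sigmoid gain fields, standard trace rule
hebbian_control                 Hebbian rule, 200 random (eye, retina)
                                patterns, tau_h = 30 ms (no trace effect)
prewired_plasticity             manually prewired sigmoid model, then
                                standard-trace plasticity
mixed_sweep                     mixed populations over a range of sigmoid
                                rates p
rule_delayed_trace_antihebb     delayed postsynaptic trace + anti-Hebbian
                                (dT = 50 ms, beta = 2.2)
rule_delayed_rate_antihebb      delayed postsynaptic rate + anti-Hebbian
                                (dT = 500 ms, beta = 2.4)
rule_current_trace_antihebb     current postsynaptic trace + anti-Hebbian
                                (beta = 2.2)
rule_delayed_trace_only         delayed postsynaptic trace only (dT = 30 ms)
rule_delayed_trace_only_mixed50 the same rule with a 50:50 peaked/sigmoid
                                mix
=============================== ============================================

``scale='full'`` uses the published parameter tables; ``scale='reduced'``
shrinks only the output count, epoch count and preference-grid resolution
(never the rate equations or rule forms) for quick runs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analysis import analyse_responses, population_summary
from .dynamics import DynamicsParams
from .engine import Model, ModelConfig, Responses, Seeds, run_testing, run_training
from .learning import LearningRuleSpec
from .population import PopulationConfig
from .protocols import GazeTrajectory, ProtocolConfig
from .structure import PrewiringSpec, prewire

__all__ = [
    "RECIPE_NAMES",
    "ExperimentRecipe",
    "recipe_config",
    "run_recipe",
    "make_fixture",
    "pattern_trajectory",
    "config_to_dict",
    "config_from_dict",
    "load_config",
    "save_config",
    "save_responses",
    "load_responses",
    "save_weights",
    "load_weights",
]

_PEAKED_DYN = DynamicsParams(tau_h=100.0, tau_q=400.0, phi=4.5, theta=0.4, pi_pct=80.0)
_SIGMOID_DYN = DynamicsParams(tau_h=100.0, tau_q=400.0, phi=4.5, theta=0.0, pi_pct=90.0)
_PREWIRED_DYN = DynamicsParams(tau_h=100.0, tau_q=400.0, phi=4.0, theta=0.0, pi_pct=90.0)

RECIPE_NAMES = (
    "peaked_standard", "sigmoid_standard", "hebbian_control",
    "prewired_plasticity", "mixed_sweep", "rule_delayed_trace_antihebb", "rule_delayed_rate_antihebb",
    "rule_current_trace_antihebb", "rule_delayed_trace_only", "rule_delayed_trace_only_mixed50",
)


@dataclass(frozen=True)
class ExperimentRecipe:
    name: str
    scale: str = "full"  # full | reduced
    overrides: dict = dataclasses.field(default_factory=dict)
    seeds: Seeds = dataclasses.field(default_factory=Seeds)

    def __post_init__(self) -> None:
        if self.name not in RECIPE_NAMES:
            raise ValueError(f"unknown recipe {self.name!r}")
        if self.scale not in ("full", "reduced"):
            raise ValueError("scale must be 'full' or 'reduced'")


def recipe_config(recipe: ExperimentRecipe | str, scale: str = "full",
                  seeds: Seeds | None = None) -> ModelConfig:
    """Expand a recipe into a full model configuration."""
    if isinstance(recipe, str):
        recipe = ExperimentRecipe(recipe, scale=scale,
                                  seeds=seeds if seeds is not None else Seeds())
    name = recipe.name
    peaked_pop = PopulationConfig(gain_form="peaked")
    sigmoid_pop = PopulationConfig(gain_form="sigmoid")
    if name == "peaked_standard":
        cfg = ModelConfig(population=peaked_pop, dynamics=_PEAKED_DYN,
                          learning=LearningRuleSpec("standard_trace"))
    elif name == "sigmoid_standard":
        cfg = ModelConfig(population=sigmoid_pop, dynamics=_SIGMOID_DYN,
                          learning=LearningRuleSpec("standard_trace"))
    elif name == "hebbian_control":
        cfg = ModelConfig(population=peaked_pop,
                          dynamics=replace(_PEAKED_DYN, tau_h=30.0, dt=3.0),
                          learning=LearningRuleSpec("hebbian"), epochs=1)
    elif name == "prewired_plasticity":
        cfg = ModelConfig(population=sigmoid_pop, dynamics=_PREWIRED_DYN,
                          learning=LearningRuleSpec("standard_trace"),
                          connectivity=0.0816, epochs=10)
    elif name == "mixed_sweep":
        cfg = ModelConfig(population=replace(peaked_pop, gain_form="mixed"),
                          dynamics=_PEAKED_DYN,
                          learning=LearningRuleSpec("standard_trace"))
    elif name == "rule_delayed_trace_antihebb":
        cfg = ModelConfig(population=sigmoid_pop, dynamics=_SIGMOID_DYN,
                          learning=LearningRuleSpec("delayed_trace_antihebb"))
    elif name == "rule_delayed_rate_antihebb":
        cfg = ModelConfig(population=sigmoid_pop, dynamics=_SIGMOID_DYN,
                          learning=LearningRuleSpec("delayed_rate_antihebb"))
    elif name == "rule_current_trace_antihebb":
        cfg = ModelConfig(population=sigmoid_pop, dynamics=_SIGMOID_DYN,
                          learning=LearningRuleSpec("current_trace_antihebb"))
    elif name == "rule_delayed_trace_only":
        cfg = ModelConfig(population=sigmoid_pop, dynamics=_SIGMOID_DYN,
                          learning=LearningRuleSpec("delayed_trace_only"))
    else:  # rule_delayed_trace_only_mixed50
        cfg = ModelConfig(
            population=replace(peaked_pop, gain_form="mixed", sigmoid_rate=0.5),
            dynamics=_SIGMOID_DYN, learning=LearningRuleSpec("delayed_trace_only"))
    cfg = replace(cfg, seeds=recipe.seeds)
    if recipe.scale == "reduced":
        pop = replace(cfg.population, retinal_step=2.0, eye_step=2.0)
        cfg = replace(cfg, population=pop, n_output=200,
                      epochs=min(cfg.epochs, 5))
    if recipe.overrides:
        cfg = config_from_dict(_deep_update(config_to_dict(cfg), recipe.overrides))
    return cfg


def pattern_trajectory(
    n_patterns: int = 200,
    eye_range: tuple[float, float] = (-24.0, 24.0),
    retinal_range: tuple[float, float] = (-63.0, 63.0),
    duration_ms: float = 100.0,
    seed: int = 0,
) -> GazeTrajectory:
    """Discrete-pattern schedule for the Hebbian control: random
    (eye position, retinal location) pairs presented back to back with
    instantaneous transitions (no saccades)."""
    rng = np.random.default_rng(seed)
    eyes = rng.uniform(*eye_range, size=n_patterns)
    rets = rng.uniform(*retinal_range, size=n_patterns)
    times = [0.0]
    eye = []
    target = []
    labels = []
    t = 0.0
    for k in range(n_patterns):
        eye.append(eyes[k])
        t += duration_ms
        times.append(t)
        eye.append(eyes[k])
        target.append(rets[k] + eyes[k])
        labels.append("fixation")
        if k + 1 < n_patterns:
            times.append(t)
            target.append(rets[k + 1] + eyes[k + 1])
            labels.append("fixation")
    return GazeTrajectory(times=np.asarray(times), eye=np.asarray(eye),
                          target_h=np.asarray(target), labels=np.asarray(labels))


def run_recipe(
    recipe: ExperimentRecipe | str,
    scale: str = "full",
    seeds: Seeds | None = None,
    out_dir: str | Path | None = None,
    p_values=(0.0, 0.1, 0.2, 0.5),
    analysis_kwargs: dict | None = None,
) -> dict:
    """Execute build -> (prewire | init) -> train -> test -> analyse.

    Returns a bundle with the model, untrained/trained analysis tables and
    population summaries; writes responses (HDF5), classification tables and
    epoch statistics (CSV) plus a manifest (JSON) when ``out_dir`` is given.
    ``mixed_sweep`` instead returns/writes the per-p summary table.
    """
    if isinstance(recipe, str):
        recipe = ExperimentRecipe(recipe, scale=scale,
                                  seeds=seeds if seeds is not None else Seeds())
    cfg = recipe_config(recipe)
    akw = analysis_kwargs or {}
    bundle: dict = {"recipe": recipe.name, "scale": recipe.scale, "config": cfg}

    if recipe.name == "mixed_sweep":
        from .engine import sweep_sigmoid_rate
        table = sweep_sigmoid_rate(cfg, p_values, **akw)
        bundle["sweep"] = table
    else:
        model = Model.from_config(cfg)
        if recipe.name == "prewired_plasticity":
            syn, assigned = prewire(model.population, cfg.n_output,
                                    PrewiringSpec(), cfg.connectivity,
                                    cfg.seeds.connectivity)
            model.synapses = syn
            bundle["assigned_locations"] = assigned
        phases = {}
        for phase in ("untrained", "trained"):
            if phase == "trained":
                if cfg.epochs == 0:
                    break
                if recipe.name == "hebbian_control":
                    traj = pattern_trajectory(seed=cfg.seeds.trajectory)
                    model._train_along(traj)
                    model.epochs_trained += 1
                else:
                    run_training(model)
            resp = run_testing(model)
            table = analyse_responses(resp, **akw)
            phases[phase] = {
                "responses": resp,
                "table": table,
                "summary": population_summary(table, cfg.n_output),
            }
        bundle["model"] = model
        bundle["phases"] = phases

    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "recipe": bundle["recipe"],
        "scale": bundle["scale"],
        "config": config_to_dict(bundle["config"]),
    }
    if "sweep" in bundle:
        bundle["sweep"].to_csv(out_dir / "sweep.csv", index=False)
    else:
        stats_rows = []
        for phase, data in bundle["phases"].items():
            save_responses(data["responses"], out_dir / f"responses_{phase}.h5")
            data["table"].to_csv(out_dir / f"classification_{phase}.csv", index=False)
            stats_rows.append({"phase": phase, **data["summary"]})
        pd.DataFrame(stats_rows).to_csv(out_dir / "population_stats.csv", index=False)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def make_fixture(seed: int = 0, epochs: int = 2) -> ModelConfig:
    """A miniature configuration for tests and quick demos: ~200 input
    neurons on a coarse 21 x 10 preference grid, 50 output neurons, short
    training (runs in seconds)."""
    return ModelConfig(
        population=PopulationConfig(
            gain_form="peaked",
            retinal_span=(-40.0, 40.0), retinal_step=4.0,
            eye_span=(-18.0, 18.0), eye_step=4.0,
        ),
        dynamics=_PEAKED_DYN,
        learning=LearningRuleSpec("standard_trace"),
        protocol=ProtocolConfig(
            training_locations=(-36.0, -12.0, 12.0, 36.0),
            fixations_per_location=5,
            test_target_span=(-39.0, 39.0),
            test_target_count=40,
        ),
        n_output=50,
        connectivity=0.2,
        epochs=epochs,
        seeds=Seeds().shifted(seed),
    )


# -- configuration serialisation ----------------------------------------


def config_to_dict(cfg: ModelConfig) -> dict:
    d = dataclasses.asdict(cfg)

    def _clean(x):
        if isinstance(x, dict):
            return {k: _clean(v) for k, v in x.items()}
        if isinstance(x, tuple):
            return [_clean(v) for v in x]
        return x

    return _clean(d)


def _deep_update(base: dict, overrides: dict) -> dict:
    out = dict(base)
    for k, v in overrides.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def _tupled(d: dict, keys) -> dict:
    return {k: (tuple(v) if k in keys and v is not None else v) for k, v in d.items()}


def config_from_dict(d: dict) -> ModelConfig:
    pop = PopulationConfig(**_tupled(d["population"], {"retinal_span", "eye_span"}))
    dyn = DynamicsParams(**d["dynamics"])
    rule = LearningRuleSpec(**d["learning"])
    proto = ProtocolConfig(**_tupled(
        d["protocol"],
        {"training_locations", "eye_range", "test_eye_positions", "test_target_span"}))
    seeds = Seeds(**d["seeds"])
    return ModelConfig(population=pop, dynamics=dyn, learning=rule, protocol=proto,
                       n_output=d["n_output"], connectivity=d["connectivity"],
                       epochs=d["epochs"], seeds=seeds)


def save_config(cfg: ModelConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))


def load_config(path: str | Path) -> ModelConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


# -- response matrix I/O -------------------------------------------------


def save_responses(responses: Responses, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=responses.values, compression="gzip")
        f.create_dataset("eye_positions", data=responses.eye_positions)
        f.create_dataset("target_locations", data=responses.target_locations)


def load_responses(path: str | Path) -> Responses:
    import h5py

    with h5py.File(path, "r") as f:
        return Responses(values=f["values"][()],
                         eye_positions=f["eye_positions"][()],
                         target_locations=f["target_locations"][()])


def save_weights(synapses, path: str | Path) -> None:
    """Weight snapshot as sparse triplets (output index, input index, weight)."""
    import h5py

    N, K = synapses.pre_index.shape
    out_idx = np.repeat(np.arange(N, dtype=np.int32), K)
    with h5py.File(path, "w") as f:
        f.create_dataset("output_index", data=out_idx, compression="gzip")
        f.create_dataset("input_index", data=synapses.pre_index.ravel(),
                         compression="gzip")
        f.create_dataset("weight", data=synapses.weights.ravel(),
                         compression="gzip")
        f.attrs["phi"] = synapses.phi
        f.attrs["n_inputs"] = synapses.n_inputs
        f.attrs["seed"] = synapses.seed


def load_weights(path: str | Path):
    from .learning import SynapseSet

    import h5py

    with h5py.File(path, "r") as f:
        out_idx = f["output_index"][()]
        in_idx = f["input_index"][()]
        w = f["weight"][()]
        N = int(out_idx.max()) + 1
        K = out_idx.size // N
        return SynapseSet(pre_index=in_idx.reshape(N, K).astype(np.int32),
                          weights=w.reshape(N, K),
                          phi=float(f.attrs["phi"]),
                          n_inputs=int(f.attrs["n_inputs"]),
                          seed=int(f.attrs["seed"]))
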