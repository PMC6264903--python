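"""Gain-modulated visual input population.

The input layer models retinotopic visual neurons whose Gaussian retinal
tuning is multiplicatively gain-modulated by eye position.  Two gain forms
are supported:

* ``peaked`` — a Gaussian of eye position centred on the neuron's preferred
  eye position ``beta`` with width ``rho``.
* ``sigmoid`` — a saturating sigmoid of eye position with inflection point
  ``beta`` and signed slope parameter ``kappa`` (positive ``kappa`` means the
  gain exceeds 0.5 for eye positions left of ``beta``).

A population covers the (retinal preference x eye-position preference) grid
in even steps; pure sigmoid populations carry both gain signs at every grid
point, and mixed populations convert each grid neuron to sigmoid
independently with probability ``sigmoid_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "PopulationConfig",
    "InputNeuronSpec",
    "InputPopulation",
    "build_input_population",
    "peaked_response",
    "sigmoid_response",
    "population_rates",
]

GainForm = Literal["peaked", "sigmoid", "mixed"]


def _grid(span: tuple[float, float], step: float) -> np.ndarray:
    lo, hi = span
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


@dataclass(frozen=True)
class PopulationConfig:
    """Geometry and tuning of the input layer.

    Defaults reproduce the standard population: 201 retinal preferences in
    [-100, 100] deg and 61 eye-position preferences in [-30, 30] deg at 1 deg
    spacing, giving 12,261 peaked neurons or 24,522 sigmoid neurons.  The
    retinal span is widened 10 deg beyond the nominal +/-90 deg visual space
    so that the preference counts (and hence connectivity fractions) match
    the 201 x 61 layout; the marginal neurons are effectively silent.
    """

    gain_form: GainForm = "peaked"
    sigmoid_rate: float = 0.0
    retinal_span: tuple[float, float] = (-100.0, 100.0)
    retinal_step: float = 1.0
    eye_span: tuple[float, float] = (-30.0, 30.0)
    eye_step: float = 1.0
    sigma: float = 6.0
    rho: float = 6.0
    kappa_abs: float = 0.0625

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.gain_form in ("peaked", "mixed") and self.rho <= 0:
            raise ValueError("rho must be positive for peaked gain fields")
        if self.gain_form in ("sigmoid", "mixed") and self.kappa_abs == 0:
            raise ValueError("kappa_abs must be nonzero for sigmoid gain fields")
        if not 0.0 <= self.sigmoid_rate <= 1.0:
            raise ValueError("sigmoid_rate must lie in [0, 1]")
        if self.retinal_step <= 0 or self.eye_step <= 0:
            raise ValueError("grid steps must be positive")


@dataclass(frozen=True)
class InputNeuronSpec:
    """Tuning of a single input neuron."""

    alpha: float  # preferred retinal location (deg)
    beta: float  # preferred eye position / sigmoid inflection (deg)
    gain_form: Literal["peaked", "sigmoid"]
    sigma: float  # retinal tuning width (deg)
    rho: float | None = None  # eye tuning width (deg, peaked only)
    kappa: float | None = None  # signed sigmoid slope parameter (sigmoid only)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.gain_form == "peaked":
            if self.rho is None or self.rho <= 0:
                raise ValueError("peaked neurons need rho > 0")
        else:
            if self.kappa is None or self.kappa == 0:
                raise ValueError("sigmoid neurons need kappa != 0")

    def response(self, r: float, e: float) -> float:
        if self.gain_form == "peaked":
            return peaked_response(self, r, e)
        return sigmoid_response(self, r, e)


@dataclass(frozen=True)
class InputPopulation:
    """Vectorised input population.

    Per-neuron tuning is held in parallel arrays; ``spec(j)`` materialises a
    single :class:`InputNeuronSpec`.  Neuron order is deterministic given the
    configuration and seed: the (alpha, beta) grid is traversed with alpha
    slowest, and for pure sigmoid populations the positive-gain neuron at
    each grid point precedes the negative-gain one.
    """

    config: PopulationConfig
    seed: int
    alpha: np.ndarray
    beta: np.ndarray
    kappa: np.ndarray  # signed kappa; 0 marks a peaked neuron
    retinal_grid: np.ndarray = field(repr=False, default=None)
    eye_grid: np.ndarray = field(repr=False, default=None)

    @property
    def size(self) -> int:
        return self.alpha.size

    @property
    def is_sigmoid(self) -> np.ndarray:
        return self.kappa != 0.0

    @property
    def sigma(self) -> float:
        return self.config.sigma

    @property
    def rho(self) -> float:
        return self.config.rho

    def spec(self, j: int) -> InputNeuronSpec:
        if self.kappa[j] != 0.0:
            return InputNeuronSpec(
                alpha=float(self.alpha[j]), beta=float(self.beta[j]),
                gain_form="sigmoid", sigma=self.sigma, kappa=float(self.kappa[j]),
            )
        return InputNeuronSpec(
            alpha=float(self.alpha[j]), beta=float(self.beta[j]),
            gain_form="peaked", sigma=self.sigma, rho=self.rho,
        )

    def rates(self, r: float, e: float) -> np.ndarray:
        return population_rates(self, r, e)


def build_input_population(config: PopulationConfig, seed: int = 0) -> InputPopulation:
    """Construct the full input population for the given configuration.

    For ``mixed`` populations each grid neuron is independently converted to
    sigmoid with probability ``config.sigmoid_rate`` and its gain sign drawn
    +/-1 equiprobably, both from ``seed``.
    """
    r_grid = _grid(config.retinal_span, config.retinal_step)
    e_grid = _grid(config.eye_span, config.eye_step)
    a, b = np.meshgrid(r_grid, e_grid, indexing="ij")
    alpha, beta = a.ravel(), b.ravel()

    if config.gain_form == "peaked":
        kappa = np.zeros_like(alpha)
    elif config.gain_form == "sigmoid":
        alpha = np.repeat(alpha, 2)
        beta = np.repeat(beta, 2)
        kappa = np.tile([config.kappa_abs, -config.kappa_abs], alpha.size // 2)
    else:  # mixed
        rng = np.random.default_rng(seed)
        to_sigmoid = rng.random(alpha.size) < config.sigmoid_rate
        sign = np.where(rng.random(alpha.size) < 0.5, 1.0, -1.0)
        kappa = np.where(to_sigmoid, sign * config.kappa_abs, 0.0)

    return InputPopulation(
        config=config, seed=seed,
        alpha=alpha, beta=beta, kappa=kappa,
        retinal_grid=r_grid, eye_grid=e_grid,
    )


def peaked_response(neuron: InputNeuronSpec, r: float, e: float) -> float:
    """Gaussian retinal tuning with a peaked (Gaussian) eye-position gain."""
    if neuron.gain_form != "peaked":
        raise ValueError("neuron does not have a peaked gain field")
    gain = np.exp(-((e - neuron.beta) ** 2) / (2.0 * neuron.rho**2))
    return float(gain * np.exp(-((r - neuron.alpha) ** 2) / (2.0 * neuron.sigma**2)))


def sigmoid_response(neuron: InputNeuronSpec, r: float, e: float) -> float:
    """Gaussian retinal tuning with a sigmoidal eye-position gain."""
    if neuron.gain_form != "sigmoid":
        raise ValueError("neuron does not have a sigmoid gain field")
    x = np.clip(neuron.kappa * (e - neuron.beta), -700.0, 700.0)
    gain = 1.0 / (1.0 + np.exp(x))
    return float(gain * np.exp(-((r - neuron.alpha) ** 2) / (2.0 * neuron.sigma**2)))


def population_rates(pop: InputPopulation, r: float, e: float) -> np.ndarray:
    """Firing rates of every input neuron for target retinal location ``r``
    and eye position ``e``; values lie in [0, 1]."""
    retinal = np.exp(-((r - pop.alpha) ** 2) / (2.0 * pop.sigma**2))
    sig = pop.is_sigmoid
    gain = np.empty(pop.size)
    if sig.any():
        x = np.clip(pop.kappa[sig] * (e - pop.beta[sig]), -700.0, 700.0)
        gain[sig] = 1.0 / (1.0 + np.exp(x))
    pk = ~sig
    if pk.any():
        gain[pk] = np.exp(-((e - pop.beta[pk]) ** 2) / (2.0 * pop.rho**2))
    return gain * retinal
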