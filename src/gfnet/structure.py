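"""Input-structure tools: covariance maps, prewired weights, weight maps.

The covariance between two gain-modulated input neurons over the whole
(retinal location x eye position) stimulus space predicts what a purely
Hebbian competitive network would wire onto its output neurons.  Because
every input neuron's response factorises into a retinal profile times an
eye-position gain, the grid covariance is computed from separable 1-D
sums; a brute-force double loop over grid points gives the same numbers
and serves as the test oracle.

The prewiring construction places a head-centred receptive field at one of
nine assigned locations on each output neuron by elevating (weight 10)
every sampled synapse whose presynaptic neuron responds strongly, at some
eye position, to a target near the assigned head-centred location, and
depressing (weight 1) the rest, followed by unit-norm renormalisation.
For a positive-gain presynaptic neuron (responding for eye positions left
of its inflection beta) the elevated region is h - beta <= alpha <= h + W/2;
for negative gain it is h - W/2 <= alpha <= h - beta, with W = 60 deg the
size of the eye-position dimension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .learning import SynapseSet, renormalise, sample_connectivity
from .population import InputNeuronSpec, InputPopulation

__all__ = [
    "CovarianceMap",
    "PrewiringSpec",
    "input_mean_response",
    "covariance_map",
    "prewire",
    "export_weight_map",
]


def _response_profiles(pop: InputPopulation, r_grid: np.ndarray, e_grid: np.ndarray):
    """Separable per-neuron profiles: retinal (Npop, Gr) and gain (Npop, Ge)."""
    F = np.exp(-((r_grid[None, :] - pop.alpha[:, None]) ** 2) / (2.0 * pop.sigma**2))
    G = np.empty((pop.size, e_grid.size))
    sig = pop.is_sigmoid
    if sig.any():
        x = np.clip(pop.kappa[sig][:, None] * (e_grid[None, :] - pop.beta[sig][:, None]),
                    -700.0, 700.0)
        G[sig] = 1.0 / (1.0 + np.exp(x))
    pk = ~sig
    if pk.any():
        G[pk] = np.exp(-((e_grid[None, :] - pop.beta[pk][:, None]) ** 2) / (2.0 * pop.rho**2))
    return F, G


def _neuron_profiles(neuron: InputNeuronSpec, r_grid: np.ndarray, e_grid: np.ndarray):
    f = np.exp(-((r_grid - neuron.alpha) ** 2) / (2.0 * neuron.sigma**2))
    if neuron.gain_form == "sigmoid":
        x = np.clip(neuron.kappa * (e_grid - neuron.beta), -700.0, 700.0)
        g = 1.0 / (1.0 + np.exp(x))
    else:
        g = np.exp(-((e_grid - neuron.beta) ** 2) / (2.0 * neuron.rho**2))
    return f, g


def default_domain(step: float = 1.0):
    """The represented stimulus space: r in [-90, 90], e in [-30, 30] deg."""
    r = np.arange(-90.0, 90.0 + 1e-9, step)
    e = np.arange(-30.0, 30.0 + 1e-9, step)
    return r, e


def input_mean_response(neuron: InputNeuronSpec, r_grid: np.ndarray,
                        e_grid: np.ndarray) -> float:
    """Mean response of a neuron over the discrete stimulus grid."""
    if r_grid.size == 0 or e_grid.size == 0:
        raise ValueError("empty stimulus grid")
    f, g = _neuron_profiles(neuron, np.asarray(r_grid, float), np.asarray(e_grid, float))
    return float(np.mean(f) * np.mean(g))


@dataclass(frozen=True)
class CovarianceMap:
    """Topographic covariance between a reference input neuron and the rest
    of the population.  ``values`` is (n_alpha, n_beta) for a pure-peaked
    population and (n_alpha, n_beta, 2) for sigmoid populations, with plane
    0 = positive gain and plane 1 = negative gain; cells without a neuron
    hold NaN."""

    reference: InputNeuronSpec
    values: np.ndarray
    alpha_grid: np.ndarray
    beta_grid: np.ndarray


def covariance_map(
    reference: InputNeuronSpec,
    pop: InputPopulation,
    r_grid: np.ndarray | None = None,
    e_grid: np.ndarray | None = None,
) -> CovarianceMap:
    """Grid covariance between ``reference`` and every population neuron.

    cov(a, b) = mean_grid(Ra * Rb) - mean_grid(Ra) * mean_grid(Rb),
    evaluated by separable 1-D sums over the stimulus grid.
    """
    if r_grid is None or e_grid is None:
        r_grid, e_grid = default_domain()
    r_grid = np.asarray(r_grid, float)
    e_grid = np.asarray(e_grid, float)
    F, G = _response_profiles(pop, r_grid, e_grid)
    fr, gr = _neuron_profiles(reference, r_grid, e_grid)
    cross = (F @ fr) * (G @ gr) / (r_grid.size * e_grid.size)
    means = F.mean(axis=1) * G.mean(axis=1)
    mean_ref = fr.mean() * gr.mean()
    cov = cross - means * mean_ref

    a_grid, b_grid = pop.retinal_grid, pop.eye_grid
    ai = np.rint((pop.alpha - a_grid[0]) / (a_grid[1] - a_grid[0])).astype(int)
    bi = np.rint((pop.beta - b_grid[0]) / (b_grid[1] - b_grid[0])).astype(int)
    if pop.is_sigmoid.any():
        values = np.full((a_grid.size, b_grid.size, 2), np.nan)
        plane = np.where(pop.kappa > 0, 0, 1)
        values[ai, bi, plane] = cov
        if (~pop.is_sigmoid).any():
            # mixed population: peaked neurons share plane 0 cells that have
            # no positive-gain sigmoid occupant
            pk = ~pop.is_sigmoid
            values[ai[pk], bi[pk], 0] = cov[pk]
    else:
        values = np.full((a_grid.size, b_grid.size), np.nan)
        values[ai, bi] = cov
    return CovarianceMap(reference=reference, values=values,
                         alpha_grid=a_grid, beta_grid=b_grid)


@dataclass(frozen=True)
class PrewiringSpec:
    """Parameters of the manual head-centred wiring."""

    assigned_locations: tuple[float, ...] = (
        -68.0, -51.0, -34.0, -17.0, 0.0, 17.0, 34.0, 51.0, 68.0)
    elevated: float = 10.0
    depressed: float = 1.0
    W: float = 60.0  # size of the eye-position dimension (deg)

    def __post_init__(self) -> None:
        if not self.elevated > self.depressed > 0:
            raise ValueError("need elevated > depressed > 0")


def prewire(
    pop: InputPopulation,
    N: int,
    spec: PrewiringSpec | None = None,
    phi: float = 0.0816,
    seed: int = 0,
) -> tuple[SynapseSet, np.ndarray]:
    """Manually prewired synapse set plus per-output-neuron assigned
    head-centred location (balanced across the listed locations)."""
    if spec is None:
        spec = PrewiringSpec()
    if not pop.is_sigmoid.all():
        raise ValueError("prewiring is defined for sigmoid populations")
    syn = sample_connectivity(N, pop.size, phi, seed)
    locations = np.asarray(spec.assigned_locations)
    assigned = locations[np.arange(N) % locations.size]
    for i in range(N):
        pre = syn.pre_index[i]
        a, b, k = pop.alpha[pre], pop.beta[pre], pop.kappa[pre]
        h = assigned[i]
        pos = (h - b <= a) & (a <= h + spec.W / 2.0)
        neg = (h - spec.W / 2.0 <= a) & (a <= h - b)
        elev = np.where(k > 0, pos, neg)
        syn.weights[i] = np.where(elev, spec.elevated, spec.depressed)
    renormalise(syn.weights)
    return syn, assigned


def export_weight_map(
    neuron_weights: np.ndarray,
    pre_index: np.ndarray,
    pop: InputPopulation,
) -> np.ndarray:
    """Topographic map of one output neuron's afferent weights.

    Returns (n_alpha, n_beta) for pure-peaked populations and
    (n_alpha, n_beta, 2) (gain-split) otherwise; unconnected preference
    cells hold NaN.
    """
    a_grid, b_grid = pop.retinal_grid, pop.eye_grid
    a = pop.alpha[pre_index]
    b = pop.beta[pre_index]
    k = pop.kappa[pre_index]
    ai = np.rint((a - a_grid[0]) / (a_grid[1] - a_grid[0])).astype(int)
    bi = np.rint((b - b_grid[0]) / (b_grid[1] - b_grid[0])).astype(int)
    if pop.is_sigmoid.any():
        out = np.full((a_grid.size, b_grid.size, 2), np.nan)
        plane = np.where(k > 0, 0, 1)
        out[ai, bi, plane] = neuron_weights
        pk = k == 0
        if pk.any():
            out[ai[pk], bi[pk], 0] = neuron_weights[pk]
    else:
        out = np.full((a_grid.size, b_grid.size), np.nan)
        out[ai, bi] = neuron_weights
    return out
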