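"""Reference-frame analysis of output-neuron test responses.

Given a neuron's E x T response matrix R (rows = ascending eye positions,
columns = ascending head-centred target locations), two metrics summarise
the reference frame of its response:

* head-centredness (Pi): the mean Pearson correlation between full response
  rows across all eye-position pairs — 1 when the head-centred response
  profile is identical at every eye position.
* eye-centredness (Omega): the same pairwise-correlation average, but over
  windowed subvectors of the rows chosen so that every window covers the
  same range of *retinal* locations — 1 when the response is a fixed
  function of retinal position.

The window algebra: with targets t_j = t_1 + dh (j - 1) and eye positions
e_i = e_1 + de (i - 1), de an integer multiple of dh, the retinal ranges
seen at the different eye positions intersect in [t_1 - e_1, t_T - e_E].
The first included column of row i is f_i = (de/dh)(i - 1) + 1 (1-based)
and the common window length is V = T - (de/dh)(E - 1), so the last is
l_i = f_i + V - 1.  These satisfy the defining alignment identities
t_{f_i} - e_i = t_1 - e_1 and t_{l_i} - e_i = t_T - e_E, which are asserted
for every constructed window.

A neuron is classified head-centred if Pi > 0 and Pi > Omega, eye-centred
if Omega > 0 and Omega > Pi, and unclassified otherwise; neurons failing
the response-presence criterion are excluded from analysis.

Two windowing variants and two presence-filter readings are provided.  The
pipeline defaults (``variant='printed'``, ``presence='all'``: windows of
length T - (de/dh)(E + 1) and exclusion of any neuron lacking a response
at some eye position) reproduce the published population
statistics; the ``'constraint'`` variant uses the exact retinal
intersection (V = T - (de/dh)(E - 1), satisfying the alignment identities)
and ``presence='any'`` only excludes fully silent neurons.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import isnan

import numpy as np
import pandas as pd

__all__ = [
    "WindowSpec",
    "ReferenceFrameResult",
    "head_centredness",
    "window_indices",
    "eye_centredness",
    "presence_filter",
    "classify",
    "analyse_matrix",
    "analyse_responses",
    "population_summary",
]

#: default "no response" threshold on the within-window response range;
#: the response sigmoid never reaches exactly zero, so presence is defined
#: as a deviation of at least this much above the row minimum.
DEFAULT_EPS = 0.01


@dataclass(frozen=True)
class WindowSpec:
    """Retinal-intersection windows for the eye-centredness analysis.

    ``first`` holds the 0-based first included column per eye position
    (the 1-based algebra f_i = (de/dh)(i-1) + 1 converted at this boundary);
    ``V`` is the common window length.
    """

    first: np.ndarray  # (E,) 0-based first included column
    V: int
    delta_e: float
    delta_h: float

    @property
    def last(self) -> np.ndarray:
        """0-based last included column per eye position."""
        return self.first + self.V - 1


def window_indices(
    T: int,
    E: int,
    delta_e: float,
    delta_h: float,
    *,
    variant: str = "constraint",
) -> WindowSpec:
    """Build the retinal-intersection windows.

    ``variant='constraint'`` (default) uses the alignment-consistent window
    length V = T - (de/dh)(E - 1); ``variant='printed'`` uses the published
    closed form V = T - (de/dh)(E + 1) with the same first columns, i.e.
    windows 2(de/dh) columns short of the exact retinal intersection.
    """
    if delta_h <= 0:
        raise ValueError("delta_h must be positive")
    if delta_e < 0:
        raise ValueError("delta_e must be nonnegative")
    ratio = delta_e / delta_h
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("delta_e must be an integer multiple of delta_h")
    m = int(round(ratio))
    first = m * np.arange(E)  # 0-based: f_i - 1
    if variant == "constraint":
        V = T - m * (E - 1)
    elif variant == "printed":
        # the published closed form: same f_i, V = T - (de/dh)(E + 1),
        # i.e. windows 2(de/dh) columns shorter than the exact retinal
        # intersection (they do not satisfy the alignment identities)
        V = T - m * (E + 1)
    else:
        raise ValueError("variant must be 'constraint' or 'printed'")
    if V < 2:
        raise ValueError("window length V < 2; protocol incompatible with windowing")
    spec = WindowSpec(first=first, V=V, delta_e=delta_e, delta_h=delta_h)
    if variant == "constraint":
        # alignment identities: t_{f_i} - e_i = t_1 - e_1,
        #                       t_{l_i} - e_i = t_T - e_E  (1-based algebra)
        f1, li = spec.first + 1, spec.last + 1
        assert np.allclose(delta_h * (f1 - 1) - delta_e * np.arange(E), 0.0)
        assert np.allclose(
            delta_h * (li - 1) - delta_e * np.arange(E),
            delta_h * (T - 1) - delta_e * (E - 1),
        )
    if np.any(spec.last > T - 1):
        raise ValueError("window exceeds the response matrix width")
    return spec


def _pairwise_mean_correlation(rows: list[np.ndarray]) -> float:
    """Mean Pearson correlation over all pairs of the given vectors;
    NaN when no pair has well-defined correlations."""
    vals = []
    n = len(rows)
    for i in range(n):
        xi = rows[i]
        si = xi.std()
        if si == 0.0:
            continue
        for j in range(i + 1, n):
            xj = rows[j]
            if xj.std() == 0.0:
                continue
            vals.append(float(np.corrcoef(xi, xj)[0, 1]))
    return float(np.mean(vals)) if vals else float("nan")


def head_centredness(R: np.ndarray) -> float:
    """Pi: mean pairwise Pearson correlation between full response rows.

    Rows with zero variance are dropped from the pair average; NaN if no
    valid pair remains.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] < 2:
        raise ValueError("need an E x T matrix with E >= 2")
    return _pairwise_mean_correlation([R[i] for i in range(R.shape[0])])


def eye_centredness(
    R: np.ndarray,
    w: WindowSpec,
    eps: float = DEFAULT_EPS,
) -> float:
    """Omega: mean pairwise Pearson correlation between retinally aligned
    windowed subvectors.

    Windowed subvectors with no response (range below ``eps``) or zero
    variance are dropped from the pair average; NaN if no valid pair.
    """
    R = np.asarray(R, dtype=float)
    E = R.shape[0]
    if w.first.shape[0] != E:
        raise ValueError("window spec does not match the matrix")
    rows = []
    for i in range(E):
        sub = R[i, w.first[i] : w.first[i] + w.V]
        if sub.max() - sub.min() < eps:
            continue
        rows.append(sub)
    return _pairwise_mean_correlation(rows)


def presence_filter(
    R: np.ndarray,
    w: WindowSpec,
    eps: float = DEFAULT_EPS,
    mode: str = "any",
) -> bool:
    """Response-presence criterion; True means the neuron is analysed.

    ``mode='any'``: keep the neuron if at least one eye position shows a
    response (within-window range >= eps) — exclude only fully silent
    neurons.  ``mode='all'``: require a response at every eye position.
    """
    R = np.asarray(R, dtype=float)
    present = []
    for i in range(R.shape[0]):
        sub = R[i, w.first[i] : w.first[i] + w.V]
        present.append(sub.max() - sub.min() >= eps)
    if mode == "any":
        return bool(np.any(present))
    if mode == "all":
        return bool(np.all(present))
    raise ValueError("mode must be 'any' or 'all'")


def classify(pi: float, omega: float) -> str:
    """Label from the metric pair; an undefined (NaN) metric makes its
    comparisons fail, so e.g. Pi = NaN can never yield head_centred."""
    pi_ok = pi is not None and not isnan(pi)
    om_ok = omega is not None and not isnan(omega)
    if pi_ok and pi > 0 and (not om_ok or pi > omega):
        return "head_centred"
    if om_ok and omega > 0 and (not pi_ok or omega > pi):
        return "eye_centred"
    return "unclassified"


@dataclass(frozen=True)
class ReferenceFrameResult:
    pi: float  # head-centredness, NaN if undefined
    omega: float  # eye-centredness, NaN if undefined
    label: str  # head_centred | eye_centred | unclassified | excluded


def analyse_matrix(
    R: np.ndarray,
    w: WindowSpec,
    eps: float = DEFAULT_EPS,
    presence: str = "all",
) -> ReferenceFrameResult:
    """Full per-neuron analysis: presence filter, Pi, Omega, label."""
    if not presence_filter(R, w, eps, mode=presence):
        return ReferenceFrameResult(float("nan"), float("nan"), "excluded")
    pi = head_centredness(R)
    omega = eye_centredness(R, w, eps)
    return ReferenceFrameResult(pi, omega, classify(pi, omega))


def analyse_responses(
    responses,
    eps: float = DEFAULT_EPS,
    presence: str = "all",
    variant: str = "printed",
) -> pd.DataFrame:
    """Analyse every output neuron of a test run.

    ``responses`` is a :class:`gfnet.engine.Responses` bundle (or anything
    with ``values`` (N, E, T), ``eye_positions`` and ``target_locations``).
    Returns a DataFrame with columns neuron, pi, omega, label.
    """
    eyes = np.asarray(responses.eye_positions, dtype=float)
    targets = np.asarray(responses.target_locations, dtype=float)
    delta_e = float(eyes[1] - eyes[0]) if eyes.size > 1 else 0.0
    delta_h = float(targets[1] - targets[0])
    w = window_indices(targets.size, eyes.size, delta_e, delta_h, variant=variant)
    rows = []
    for n in range(responses.values.shape[0]):
        res = analyse_matrix(responses.values[n], w, eps, presence)
        rows.append((n, res.pi, res.omega, res.label))
    return pd.DataFrame(rows, columns=["neuron", "pi", "omega", "label"])


def population_summary(table: pd.DataFrame, n_total: int | None = None) -> dict:
    """Population statistics from a per-neuron analysis table.

    head_centred_rate is the head-centred fraction of the whole output
    population; mean_head_centredness averages Pi over head-centred neurons
    (NaN when none exist); mean_eye_centredness averages Omega over all
    analysed neurons with a defined Omega.
    """
    if n_total is None:
        n_total = len(table)
    head = table[table["label"] == "head_centred"]
    analysed = table[table["label"] != "excluded"]
    return {
        "n_total": int(n_total),
        "n_analysed": int(len(analysed)),
        "n_head_centred": int(len(head)),
        "head_centred_rate": len(head) / n_total if n_total else float("nan"),
        "mean_head_centredness": float(head["pi"].mean()) if len(head) else float("nan"),
        "mean_eye_centredness": float(analysed["omega"].mean()),
    }
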