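"""Fused inner-loop kernels (numba).

The per-step training work — synaptic drive, Euler weight update, clipping
and per-row renormalisation over all stored synapses — is fused into a
single pass so each weight is touched once per step.  The drive is
accumulated from the pre-update weights, matching the simultaneous
Forward-Euler update of all state variables.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["train_step", "compute_drive"]


@njit(cache=True, fastmath=True)
def train_step(weights, pre_index, v_in, post_dt, drive, clip_negative=True):
    """One fused training step.

    Parameters
    ----------
    weights : (N, K) float64, modified in place
    pre_index : (N, K) int32 presynaptic indices
    v_in : (N_I,) input rates at the current step
    post_dt : (N,) postsynaptic rule factor times the step in seconds
    drive : (N,) output, synaptic drive from the *pre-update* weights
    clip_negative : clamp weights at zero before renormalising

    Returns the index of the first output neuron whose weight vector was
    entirely zero after the update (cannot be renormalised), or -1 if none.
    """
    N, K = weights.shape
    for i in range(N):
        c = post_dt[i]
        s = 0.0
        nrm = 0.0
        row_w = weights[i]
        row_p = pre_index[i]
        for k in range(K):
            vv = v_in[row_p[k]]
            w = row_w[k]
            s += w * vv
            w += c * vv
            if clip_negative and w < 0.0:
                w = 0.0
            row_w[k] = w
            nrm += w * w
        drive[i] = s
        if nrm <= 0.0:
            return i
        inv = 1.0 / np.sqrt(nrm)
        for k in range(K):
            row_w[k] *= inv
    return -1


@njit(cache=True, fastmath=True)
def compute_drive(weights, pre_index, v_in, drive):
    """Synaptic drive only (testing / learning disabled)."""
    N, K = weights.shape
    for i in range(N):
        s = 0.0
        row_w = weights[i]
        row_p = pre_index[i]
        for k in range(K):
            s += row_w[k] * v_in[row_p[k]]
        drive[i] = s
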