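"""Numba kernels for first-order Markov sequence emission.

Randomness comes in as pre-drawn uniforms from a seeded numpy Generator, so
sequences are reproducible and independent of the JIT backend's own RNG.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def markov_states(cum_rows, start, u):
    """Walk a 4-state chain: emit one state per uniform in ``u``.

    cum_rows: (4, 4) row-wise cumulative transition probabilities.
    start: state preceding the first emission (not emitted).
    """
    n = u.shape[0]
    out = np.empty(n, dtype=np.uint8)
    s = start
    for i in range(n):
        ui = u[i]
        if ui < cum_rows[s, 0]:
            s = 0
        elif ui < cum_rows[s, 1]:
            s = 1
        elif ui < cum_rows[s, 2]:
            s = 2
        else:
            s = 3
        out[i] = s
    return out


@njit(cache=False)
def markov_states_mixture(P_edge, P_center, w, start, u):
    """Chain with per-position transition matrix w*P_edge + (1-w)*P_center.

    P_edge / P_center: (4, 4) row-stochastic (NOT cumulative); w: per-
    position edge-model weight in [0, 1], same length as u.
    """
    n = u.shape[0]
    out = np.empty(n, dtype=np.uint8)
    s = start
    for i in range(n):
        wi = w[i]
        vi = 1.0 - wi
        ui = u[i]
        p = s  # freeze the current row while choosing the next state
        c0 = wi * P_edge[p, 0] + vi * P_center[p, 0]
        if ui < c0:
            s = 0
        else:
            c1 = c0 + wi * P_edge[p, 1] + vi * P_center[p, 1]
            if ui < c1:
                s = 1
            else:
                c2 = c1 + wi * P_edge[p, 2] + vi * P_center[p, 2]
                s = 2 if ui < c2 else 3
        out[i] = s
    return out
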