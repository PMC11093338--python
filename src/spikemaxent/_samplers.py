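"""Numba kernels for Gibbs (heat-bath) sampling of pairwise models.

Single-site heat-bath updates with a random scan: one sweep performs N updates
at uniformly random sites. Kernels are deterministic given the seed passed to
``np.random.seed`` inside the jitted function.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["gibbs_sample", "gibbs_persistent_sweep"]


@njit(cache=True)
def _gibbs_core(h, J, n_keep, burn_in, thin, seed, state):
    np.random.seed(seed)
    n = h.shape[0]
    out = np.empty((n_keep, n), dtype=np.int8)
    # local fields maintained incrementally
    local = h + J @ state
    total_sweeps = burn_in + n_keep * thin
    kept = 0
    for sweep in range(total_sweeps):
        for _ in range(n):
            i = np.random.randint(n)
            p_plus = 1.0 / (1.0 + np.exp(-2.0 * local[i]))
            new = 1.0 if np.random.random() < p_plus else -1.0
            if new != state[i]:
                delta = new - state[i]
                state[i] = new
                for j in range(n):
                    local[j] += J[j, i] * delta
                local[i] -= J[i, i] * delta  # J_ii = 0, no-op kept for clarity
        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            for j in range(n):
                out[kept, j] = np.int8(state[j])
            kept += 1
            if kept == n_keep:
                break
    return out, state


def gibbs_sample(h: np.ndarray, J: np.ndarray, n_samples: int, burn_in: int,
                 thin: int, seed: int, init: np.ndarray | None = None):
    """Draw `n_samples` states (rows) from the pairwise model by Gibbs sampling.

    Discards `burn_in` full sweeps, then keeps every `thin`-th sweep. Returns
    (samples, final_state) so chains can be persisted.
    """
    h = np.ascontiguousarray(h, dtype=np.float64)
    J = np.ascontiguousarray(J, dtype=np.float64)
    n = h.shape[0]
    if init is None:
        state = -np.ones(n, dtype=np.float64)  # silent state, the typical one
    else:
        state = np.ascontiguousarray(init, dtype=np.float64)
    return _gibbs_core(h, J, int(n_samples), int(burn_in), int(thin),
                       int(seed) & 0x7FFFFFFF, state)


@njit(cache=True)
def gibbs_persistent_sweep(h, J, states, n_sweeps, seed):
    """One (or more) random-scan sweeps applied to every persistent chain in place.

    `states` is an (M, N) float64 array of ±1 chain states, updated in place.
    """
    np.random.seed(seed)
    m, n = states.shape
    for c in range(m):
        local = h + J @ states[c]
        for _ in range(n_sweeps):
            for _ in range(n):
                i = np.random.randint(n)
                p_plus = 1.0 / (1.0 + np.exp(-2.0 * local[i]))
                new = 1.0 if np.random.random() < p_plus else -1.0
                if new != states[c, i]:
                    delta = new - states[c, i]
                    states[c, i] = new
                    for j in range(n):
                        local[j] += J[j, i] * delta
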