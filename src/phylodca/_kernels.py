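"""Numba hot loops for Metropolis-Hastings Potts sampling.

The proposal picks a site uniformly, then one of the q - 1 *other* states
uniformly; the move is accepted with probability min(1, exp(-dH)), where dH
is computed incrementally from the fields and the couplings incident to the
mutated site.  Seeding is explicit per call so runs are bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def delta_energy(fields, couplings, x, i, b):
    """Energy change of mutating site ``i`` from ``x[i]`` to ``b``."""
    a = x[i]
    dH = -(fields[i, b] - fields[i, a])
    L = x.shape[0]
    for j in range(L):
        if j != i:
            dH -= couplings[i, j, b, x[j]] - couplings[i, j, a, x[j]]
    return dH


@njit(cache=True)
def run_chain(fields, couplings, x, n_steps, seed):
    """Advance one chain in place by ``n_steps`` proposals; return acceptances."""
    np.random.seed(seed)
    L, q = fields.shape
    accepted = 0
    for _ in range(n_steps):
        i = np.random.randint(0, L)
        b = np.random.randint(0, q - 1)
        if b >= x[i]:
            b += 1
        dH = delta_energy(fields, couplings, x, i, b)
        if dH <= 0.0 or np.random.random() < np.exp(-dH):
            x[i] = b
            accepted += 1
    return accepted


@njit(cache=True)
def run_chain_until_accepted(fields, couplings, x, n_accept, max_proposals, seed):
    """Propose until ``n_accept`` moves are accepted; return proposals used.

    Returns -1 if the quota is not reached within ``max_proposals``.
    """
    np.random.seed(seed)
    L, q = fields.shape
    accepted = 0
    proposals = 0
    while accepted < n_accept:
        if proposals >= max_proposals:
            return -1
        i = np.random.randint(0, L)
        b = np.random.randint(0, q - 1)
        if b >= x[i]:
            b += 1
        dH = delta_energy(fields, couplings, x, i, b)
        if dH <= 0.0 or np.random.random() < np.exp(-dH):
            x[i] = b
            accepted += 1
        proposals += 1
    return proposals


@njit(cache=True)
def run_ensemble(fields, couplings, X, n_steps, seeds):
    """Advance each row of ``X`` independently by ``n_steps`` proposals."""
    for m in range(X.shape[0]):
        run_chain(fields, couplings, X[m], n_steps, seeds[m])
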