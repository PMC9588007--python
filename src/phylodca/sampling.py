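"""Metropolis-Hastings sampling of sequences from a Potts model.

Two regimes:

* :func:`sample_equilibrium` — M independent chains from uniform random
  starts, each advanced by a fixed number of proposed mutations; suitable
  when sequences should be equilibrium-independent.
* :func:`sample_along_tree` — an equilibrium root sequence is evolved down
  a phylogeny by duplication at branchings and, along each branch of length
  ``b``, exactly ``round(b * L)`` *accepted* mutations (half-up rounding).
  Because the root is an equilibrium draw and Metropolis dynamics satisfy
  detailed balance, every sequence in the tree is an equilibrium sequence
  and the procedure is invariant to root placement.

Per-chain / per-branch seeds are derived from a single ``numpy``
``SeedSequence``, so identical inputs give byte-identical alignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .msa import DEFAULT_ALPHABET, Msa
from .potts import PottsModel, hamiltonian
from .trees import Phylogeny


@dataclass
class McmcConfig:
    """Sampler settings.

    ``n_steps`` is the number of proposed mutations per equilibrium chain;
    if ``None`` it defaults to ``50 * L * q``, a conservative equilibration
    budget for the desk-scale models used here.  ``cap_per_accept`` bounds
    the proposals spent per unit of accepted-mutation quota on a branch,
    turning pathological non-acceptance into an error instead of a hang.
    """

    n_steps: int | None = None
    cap_per_accept: int = 1000
    seed: int = 0

    def resolve_steps(self, model: PottsModel) -> int:
        if self.n_steps is not None:
            if self.n_steps < 0:
                raise ValueError("n_steps must be >= 0")
            return self.n_steps
        return 50 * model.length * model.q


def _alphabet_for(model: PottsModel) -> str:
    if model.q > len(DEFAULT_ALPHABET):
        raise ValueError(f"q={model.q} exceeds supported alphabet size")
    if model.q == len(DEFAULT_ALPHABET):
        return DEFAULT_ALPHABET
    return DEFAULT_ALPHABET[: model.q]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    ss = np.random.SeedSequence(seed)
    return np.array([s.generate_state(1)[0] % (2**31) for s in ss.spawn(n)],
                    dtype=np.int64)


def metropolis_step(
    model: PottsModel, x: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """One proposal on a copy of ``x``; returns (new sequence, accepted).

    Site uniform on L; proposed state uniform on the q - 1 other states;
    acceptance probability ``min(1, exp(-dH))``.
    """
    x = np.asarray(x, dtype=np.int8)
    L, q = model.length, model.q
    if x.shape != (L,) or x.min() < 0 or x.max() >= q:
        raise ValueError("sequence does not match model dimensions")
    i = int(rng.integers(L))
    b = int(rng.integers(q - 1))
    if b >= x[i]:
        b += 1
    dH = _kernels.delta_energy(model.fields, model.couplings, x, i, np.int8(b))
    y = x.copy()
    if dH <= 0 or rng.random() < math.exp(-dH):
        y[i] = b
        return y, True
    return y, False


def sample_equilibrium(
    model: PottsModel, depth: int, config: McmcConfig | None = None
) -> Msa:
    """Draw ``depth`` sequences by independent Metropolis chains.

    Each chain starts from a uniformly random sequence and makes exactly
    ``config.n_steps`` proposals.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    config = config or McmcConfig()
    n_steps = config.resolve_steps(model)
    seeds = _child_seeds(config.seed, depth + 1)
    init_rng = np.random.Generator(np.random.PCG64(seeds[0]))
    X = init_rng.integers(0, model.q, size=(depth, model.length), dtype=np.int8)
    _kernels.run_ensemble(model.fields, model.couplings, X, n_steps, seeds[1:])
    ids = [f"seq{m}" for m in range(depth)]
    return Msa(ids=ids, matrix=X, alphabet=_alphabet_for(model))


def energy_trace(
    model: PottsModel,
    n_steps: int,
    n_checkpoints: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Hamiltonian of one chain at evenly spaced checkpoints.

    A flat tail (after the initial relaxation from the uniform random
    start) is a quick heuristic check that the proposal budget of
    :func:`sample_equilibrium` suffices for equilibration.
    """
    if n_checkpoints < 1 or n_steps < n_checkpoints:
        raise ValueError("need 1 <= n_checkpoints <= n_steps")
    seeds = _child_seeds(seed, n_checkpoints + 1)
    rng = np.random.Generator(np.random.PCG64(seeds[0]))
    x = rng.integers(0, model.q, size=model.length, dtype=np.int8)
    chunk = n_steps // n_checkpoints
    energies = np.empty(n_checkpoints)
    for k in range(n_checkpoints):
        _kernels.run_chain(model.fields, model.couplings, x, chunk, seeds[k + 1])
        energies[k] = hamiltonian(model, x)
    return energies


def mutation_quota(branch_length: float, L: int) -> int:
    """Accepted mutations on a branch: integer closest to ``b * L``.

    Exact .5 ties round up (half-up), for determinism.
    """
    return int(math.floor(branch_length * L + 0.5))


def sample_along_tree(
    model: PottsModel, tree: Phylogeny, config: McmcConfig | None = None
) -> Msa:
    """Evolve an equilibrium root sequence down ``tree``; leaves form the MSA.

    At each branching the current sequence is duplicated; along each branch
    of length ``b`` proposals are made until ``round(b * L)`` are accepted.
    Rows appear in the tree's stated leaf order.
    """
    if tree.n_leaves < 1:
        raise ValueError("tree must have at least one leaf")
    config = config or McmcConfig()
    L = model.length

    root_msa = sample_equilibrium(model, 1, config)
    root_seq = root_msa.matrix[0].copy()

    nodes = list(tree.dendropy_tree.preorder_node_iter())
    seeds = _child_seeds(config.seed + 1, len(nodes))
    seqs: dict[int, np.ndarray] = {id(nodes[0]): root_seq}
    leaves: dict[str, np.ndarray] = {}

    for k, node in enumerate(nodes):
        if node.parent_node is None:
            seq = seqs[id(node)]
        else:
            seq = seqs[id(node.parent_node)].copy()  # duplication event
            b = node.edge.length or 0.0
            quota = mutation_quota(b, L)
            if quota > 0:
                cap = config.cap_per_accept * quota
                used = _kernels.run_chain_until_accepted(
                    model.fields, model.couplings, seq, quota, cap, seeds[k]
                )
                if used < 0:
                    raise RuntimeError(
                        f"branch into node {k} (length {b}): quota of {quota} "
                        f"accepted mutations not reached within {cap} proposals"
                    )
            seqs[id(node)] = seq
        if node.is_leaf():
            leaves[node.taxon.label] = seq

    names = tree.leaf_names
    X = np.vstack([leaves[n] for n in names])
    return Msa(ids=list(names), matrix=X, alphabet=_alphabet_for(model))
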