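"""Potts models: Hamiltonian, exact Boltzmann law, gauge and contact scores.

A Potts model over sequences of ``L`` sites with ``q`` states has energy

    H(x) = - sum_i h_i(x_i) - sum_{i<j} e_ij(x_i, x_j)

and Boltzmann distribution ``P(x) = exp(-H(x)) / Z``.  Couplings are stored
as a dense ``(L, L, q, q)`` array with ``J[j, i] = J[i, j].T`` and zero
diagonal blocks, so symmetric access is by construction.

Contact scoring follows the standard DCA pipeline: transform to the
zero-sum gauge, take per-pair Frobenius norms, then apply the average
product correction (APC).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

_EXACT_LIMIT = 10**6


@dataclass
class PottsModel:
    """Fields ``h_i(a)`` and pairwise couplings ``e_ij(a, b)``."""

    fields: np.ndarray  # (L, q)
    couplings: np.ndarray  # (L, L, q, q); J[j, i] == J[i, j].T; zero diagonal

    def __post_init__(self) -> None:
        self.fields = np.asarray(self.fields, dtype=float)
        self.couplings = np.asarray(self.couplings, dtype=float)
        L, q = self.fields.shape
        if self.couplings.shape != (L, L, q, q):
            raise ValueError("couplings must have shape (L, L, q, q)")
        if not (np.isfinite(self.fields).all() and np.isfinite(self.couplings).all()):
            raise ValueError("parameters must be finite")

    @property
    def length(self) -> int:
        return self.fields.shape[0]

    @property
    def q(self) -> int:
        return self.fields.shape[1]

    @classmethod
    def zeros(cls, L: int, q: int) -> "PottsModel":
        return cls(np.zeros((L, q)), np.zeros((L, L, q, q)))

    @classmethod
    def from_pair_blocks(
        cls, L: int, q: int, fields: np.ndarray | None, blocks: dict
    ) -> "PottsModel":
        """Build a model from a sparse ``{(i, j): (q, q) block}`` mapping, i < j."""
        J = np.zeros((L, L, q, q))
        for (i, j), e in blocks.items():
            if not 0 <= i < j < L:
                raise ValueError(f"pair ({i}, {j}) must satisfy 0 <= i < j < L")
            e = np.asarray(e, dtype=float)
            J[i, j] = e
            J[j, i] = e.T
        h = np.zeros((L, q)) if fields is None else np.asarray(fields, float)
        return cls(h, J)


@dataclass
class CouplingScoreMatrix:
    """Symmetric ``(L, L)`` coupling scores with zero diagonal."""

    scores: np.ndarray
    gauge: str = "zero-sum"
    apc_applied: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("scores must be square")
        if not np.allclose(s, s.T, atol=1e-9):
            raise ValueError("scores must be symmetric")
        np.fill_diagonal(s, 0.0)
        self.scores = s

    @property
    def length(self) -> int:
        return self.scores.shape[0]


def hamiltonian(model: PottsModel, x: np.ndarray) -> float:
    """Exact Potts energy of one encoded sequence."""
    x = np.asarray(x)
    L, q = model.length, model.q
    if x.shape != (L,):
        raise ValueError(f"sequence length {x.shape} does not match L={L}")
    if x.min() < 0 or x.max() >= q:
        raise ValueError("sequence codes out of range for model alphabet")
    h = model.fields[np.arange(L), x].sum()
    iu, ju = np.triu_indices(L, k=1)
    e = model.couplings[iu, ju, x[iu], x[ju]].sum()
    return float(-h - e)


def enumerate_states(L: int, q: int) -> np.ndarray:
    """All ``q**L`` sequences as a ``(q**L, L)`` array, lexicographic order."""
    return np.array(list(itertools.product(range(q), repeat=L)), dtype=np.int8)


def exact_distribution(model: PottsModel, limit: int = _EXACT_LIMIT) -> np.ndarray:
    """Exact Boltzmann probabilities over all ``q**L`` states.

    States are ordered lexicographically (see :func:`enumerate_states`).
    Raises if the state space exceeds ``limit``; use the MCMC sampler then.
    """
    n = model.q**model.length
    if n > limit:
        raise ValueError(
            f"state space {n} exceeds limit {limit}; use sampling.sample_equilibrium"
        )
    states = enumerate_states(model.length, model.q)
    energies = np.array([hamiltonian(model, s) for s in states])
    w = np.exp(-(energies - energies.min()))
    return w / w.sum()


def zero_sum_gauge(model: PottsModel) -> PottsModel:
    """Re-express the model so every coupling block has zero row/column means.

    The removed block means are absorbed into the fields, so the Boltzmann
    distribution is unchanged; fields are additionally centred per site.
    """
    L, q = model.length, model.q
    J = model.couplings
    row = J.mean(axis=3, keepdims=True)  # mean over b
    col = J.mean(axis=2, keepdims=True)  # mean over a
    tot = J.mean(axis=(2, 3), keepdims=True)
    J2 = J - row - col + tot
    # field correction: h'_i(a) += sum_{j != i} (mean_b e_ij(a, b) - mean_ab e_ij)
    h2 = model.fields + (row - tot)[:, :, :, 0].sum(axis=1)
    h2 = h2 - h2.mean(axis=1, keepdims=True)
    return PottsModel(h2, J2)


def frobenius_scores(model: PottsModel) -> CouplingScoreMatrix:
    """Per-pair Frobenius norms of the zero-sum-gauge coupling blocks.

    The norm runs over all ``q`` states, the gap included.
    """
    g = zero_sum_gauge(model)
    F = np.sqrt((g.couplings**2).sum(axis=(2, 3)))
    np.fill_diagonal(F, 0.0)
    return CouplingScoreMatrix(scores=F, gauge="zero-sum", apc_applied=False)


def apc(scores: CouplingScoreMatrix) -> CouplingScoreMatrix:
    """Average product correction: ``E_ij = F_ij - F_i. F_.j / F_..``.

    Row and grand means exclude the diagonal.  An all-zero input maps to an
    all-zero output.
    """
    F = scores.scores
    L = F.shape[0]
    if L < 2:
        raise ValueError("APC needs at least two sites")
    row_mean = F.sum(axis=1) / (L - 1)
    grand_mean = F.sum() / (L * (L - 1))
    if grand_mean == 0.0:
        E = np.zeros_like(F)
    else:
        E = F - np.outer(row_mean, row_mean) / grand_mean
    np.fill_diagonal(E, 0.0)
    E = (E + E.T) / 2.0
    return CouplingScoreMatrix(
        scores=E, gauge=scores.gauge, apc_applied=True, metadata=dict(scores.metadata)
    )


def eligible_pairs(L: int, min_separation: int = 4) -> list[tuple[int, int]]:
    """Unordered site pairs with ``|i - j| > min_separation``, lexicographic."""
    return [
        (i, j)
        for i in range(L)
        for j in range(i + 1, L)
        if j - i > min_separation
    ]


def top_pairs(
    scores: CouplingScoreMatrix, k: int, min_separation: int = 4
) -> list[tuple[int, int]]:
    """The ``k`` highest-scoring eligible pairs.

    Ties are broken lexicographically on ``(i, j)`` so cutoff lists are
    reproducible.
    """
    pairs = eligible_pairs(scores.length, min_separation)
    if k > len(pairs):
        raise ValueError(f"k={k} exceeds {len(pairs)} eligible pairs")
    ranked = sorted(pairs, key=lambda p: (-scores.scores[p], p))
    return ranked[:k]


def save_model(model: PottsModel, path, alphabet: str | None = None) -> None:
    """Serialize to an HDF5 container (datasets ``fields``, ``couplings``)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("fields", data=model.fields)
        f.create_dataset("couplings", data=model.couplings)
        f.attrs["L"] = model.length
        f.attrs["q"] = model.q
        if alphabet is not None:
            f.attrs["alphabet"] = alphabet


def load_model(path) -> PottsModel:
    import h5py

    with h5py.File(path, "r") as f:
        return PottsModel(f["fields"][...], f["couplings"][...])
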