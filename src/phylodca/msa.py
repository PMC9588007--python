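"""Multiple sequence alignments: encoding, Hamming distances, reweighting.

An alignment is held as an M x L integer matrix over a fixed alphabet of
q = 21 states (20 amino acids plus the alignment gap, encoded last).  All
downstream statistics — normalized Hamming distances, phylogenetic sequence
weights ``w_i``, the effective depth ``M_eff`` and per-column Shannon
entropies — operate on this encoding.  The gap is treated as an ordinary
21st state throughout, so a gap aligned to a gap counts as a match.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

#: Canonical residue ordering; the gap is the last state, code ``q - 1``.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
DEFAULT_ALPHABET = AMINO_ACIDS + GAP

#: Non-standard residue codes silently coerced to the gap state on input.
_AMBIGUOUS = set("BZXUO.")

#: Similarity threshold delta used for sequence reweighting.
DEFAULT_DELTA = 0.2


@dataclass
class Msa:
    """Integer-encoded multiple sequence alignment.

    Parameters
    ----------
    ids
        Unique sequence identifiers, one per row.
    matrix
        ``(M, L)`` integer array with entries in ``[0, q)``.
    alphabet
        Ordered symbol string; its length defines ``q``.
    """

    ids: list[str]
    matrix: np.ndarray
    alphabet: str = DEFAULT_ALPHABET

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2 or self.matrix.size == 0:
            raise ValueError("alignment matrix must be 2-D and non-empty")
        if len(self.ids) != self.matrix.shape[0]:
            raise ValueError("number of ids must equal number of rows")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sequence identifiers must be unique")
        if self.matrix.min() < 0 or self.matrix.max() >= self.q:
            raise ValueError(f"codes must lie in [0, {self.q})")

    @property
    def depth(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def q(self) -> int:
        return len(self.alphabet)

    def sequences(self) -> list[str]:
        """Decode rows back to symbol strings."""
        lut = np.frombuffer(self.alphabet.encode(), dtype=np.uint8)
        return [lut[row].tobytes().decode() for row in self.matrix]


@dataclass
class WeightVector:
    """Per-sequence phylogenetic weights ``w_i`` at threshold ``delta``.

    Each weight is the reciprocal of the number of alignment rows (the row
    itself included) closer than ``delta`` in normalized Hamming distance;
    their sum is the effective depth ``M_eff``.
    """

    weights: np.ndarray
    delta: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)

    @property
    def m_eff(self) -> float:
        return float(self.weights.sum())


def encode_sequence(seq: str, alphabet: str = DEFAULT_ALPHABET) -> np.ndarray:
    """Encode a symbol string to integer codes, coercing ambiguity codes to gap."""
    seq = seq.upper()
    cleaned = []
    for c in seq:
        if c in alphabet:
            cleaned.append(c)
        elif c in _AMBIGUOUS:
            warnings.warn(
                f"non-standard residue {c!r} mapped to gap", stacklevel=2
            )
            cleaned.append(GAP if GAP in alphabet else alphabet[-1])
        else:
            raise ValueError(f"unknown residue {c!r}")
    idx = {c: i for i, c in enumerate(alphabet)}
    return np.array([idx[c] for c in cleaned], dtype=np.int8)


def hamming_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Normalized Hamming distance: fraction of sites whose states differ.

    Gap/gap positions count as matches (the gap is an ordinary state).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(np.mean(x != y))


def distance_matrix(msa: Msa) -> np.ndarray:
    """All pairwise normalized Hamming distances, ``(M, M)`` symmetric."""
    return squareform(pdist(msa.matrix, metric="hamming"))


def sequence_weights(msa: Msa, delta: float = DEFAULT_DELTA) -> WeightVector:
    """Reweight sequences by local redundancy.

    ``w_i = 1 / |{i' : d_H(x_i, x_i') < delta}|``; the neighbour set always
    contains ``i`` itself, so ``delta`` must be positive.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0 (neighbour set must contain i)")
    d = distance_matrix(msa)
    counts = (d < delta).sum(axis=1)
    return WeightVector(weights=1.0 / counts, delta=delta)


def effective_depth(msa: Msa, delta: float = DEFAULT_DELTA) -> float:
    """Effective depth ``M_eff = sum_i w_i`` at threshold ``delta``."""
    return sequence_weights(msa, delta).m_eff


def column_entropy(msa: Msa, j: int) -> float:
    """Shannon entropy (nats) of the empirical state distribution of column j."""
    if not 0 <= j < msa.length:
        raise IndexError(f"column {j} out of range [0, {msa.length})")
    counts = np.bincount(msa.matrix[:, j], minlength=msa.q).astype(float)
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def column_entropies(msa: Msa) -> np.ndarray:
    return np.array([column_entropy(msa, j) for j in range(msa.length)])


def read_fasta(path, alphabet: str = DEFAULT_ALPHABET) -> Msa:
    """Read an aligned FASTA file into an :class:`Msa`.

    Records must all have the same length; lowercase residues are
    uppercased, ambiguity codes become gaps.
    """
    from Bio import SeqIO

    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(encode_sequence(str(rec.seq), alphabet))
    if not rows:
        raise ValueError(f"no FASTA records found in {path}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: record lengths {sorted(lengths)}")
    return Msa(ids=ids, matrix=np.vstack(rows), alphabet=alphabet)


def write_fasta(msa: Msa, path) -> None:
    """Write an :class:`Msa` as aligned FASTA (one line per sequence)."""
    with open(path, "w") as fh:
        for name, seq in zip(msa.ids, msa.sequences()):
            fh.write(f">{name}\n{seq}\n")
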