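"""Synthetic generators: planted Potts models, random trees, surrogate attentions.

These give every pipeline stage a self-contained test surface:

* :func:`planted_potts` — a Potts model whose only nonzero couplings sit on
  ``n_contacts`` randomly chosen well-separated pairs, each block scaled to
  a prescribed Frobenius norm after zero-sum projection.  The planted pairs
  are, by construction, exactly the generator's top coupling scores, so
  they serve as unambiguous proxy contacts.
* :func:`random_tree` — Yule (pure-birth) or balanced binary phylogenies
  with controllable height, standing in for trees inferred from natural
  alignments.
* :func:`surrogate_attentions` — row-stochastic per-column attention maps
  in which designated (layer, head) slices carry a planted monotone signal
  of pairwise sequence similarity: pre-softmax logits are
  ``gamma_lh * match_j(i, i') + noise`` where ``match_j`` indicates equal
  states at column ``j``.  Averaged over columns, the match indicator
  equals ``1 - d_H``, so the planted link between attentions and Hamming
  distance is linear on the logit scale.  Heads with negative ``gamma``
  attend to *similar* sequences; the BOS column is pure noise.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .msa import DEFAULT_ALPHABET, Msa
from .potts import PottsModel
from .attention import ColumnAttentionSet
from .trees import Phylogeny


@dataclass
class PlantedSpec:
    """Conditions for a planted-contact Potts model."""

    L: int = 30
    q: int = 8
    n_contacts: int = 10
    coupling_scale: float = 3.0  # Frobenius norm per planted block
    field_scale: float = 0.3
    min_separation: int = 5  # planted pairs satisfy |i - j| >= 5, i.e. > 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coupling_scale < 0 or self.field_scale < 0:
            raise ValueError("scales must be >= 0")


def _zero_sum_block(block: np.ndarray) -> np.ndarray:
    row = block.mean(axis=1, keepdims=True)
    col = block.mean(axis=0, keepdims=True)
    return block - row - col + block.mean()


def planted_potts(spec: PlantedSpec) -> tuple[PottsModel, list[tuple[int, int]]]:
    """Draw a planted model; returns (model, sorted planted pair list)."""
    rng = np.random.default_rng(spec.seed)
    candidates = [
        (i, j)
        for i in range(spec.L)
        for j in range(i + 1, spec.L)
        if j - i >= spec.min_separation
    ]
    if spec.n_contacts > len(candidates):
        raise ValueError(
            f"{spec.n_contacts} contacts infeasible: only {len(candidates)} "
            f"pairs with separation >= {spec.min_separation}"
        )
    chosen = rng.choice(len(candidates), size=spec.n_contacts, replace=False)
    pairs = sorted(candidates[c] for c in chosen)

    blocks = {}
    for p in pairs:
        e = _zero_sum_block(rng.standard_normal((spec.q, spec.q)))
        norm = np.sqrt((e**2).sum())
        if norm > 0 and spec.coupling_scale > 0:
            e = e * (spec.coupling_scale / norm)
        else:
            e = np.zeros_like(e)
        blocks[p] = e
    fields = spec.field_scale * rng.standard_normal((spec.L, spec.q))
    model = PottsModel.from_pair_blocks(spec.L, spec.q, fields, blocks)
    return model, pairs


def random_tree(
    n_leaves: int,
    kind: str = "yule",
    height: float | None = None,
    birth_rate: float = 1.0,
    branch_length: float = 0.1,
    seed: int = 0,
) -> Phylogeny:
    """Random binary phylogeny, seed-deterministic.

    ``yule`` draws a pure-birth tree (birth rate ``birth_rate``, no
    extinction); ``balanced`` builds a complete binary topology with
    uniform ``branch_length`` (ultrametric), requiring a power-of-two leaf
    count.  If ``height`` is given, branch lengths are rescaled so the
    maximum root-to-leaf path equals it.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    if kind == "yule":
        tree = dendropy.model.birthdeath.birth_death_tree(
            birth_rate=birth_rate,
            death_rate=0.0,
            num_extant_tips=n_leaves,
            rng=random.Random(seed),
        )
        for k, leaf in enumerate(tree.leaf_node_iter()):
            leaf.taxon.label = f"t{k}"
        phylo = Phylogeny(tree)
    elif kind == "balanced":
        if n_leaves & (n_leaves - 1) != 0:
            raise ValueError("balanced trees need a power-of-two leaf count")
        taxa = dendropy.TaxonNamespace([f"t{k}" for k in range(n_leaves)])
        tree = dendropy.Tree(taxon_namespace=taxa)

        def grow(node, n, offset):
            if n == 1:
                node.taxon = taxa.get_taxon(f"t{offset}")
                return
            for half in range(2):
                child = node.new_child(edge_length=branch_length)
                grow(child, n // 2, offset + half * (n // 2))

        grow(tree.seed_node, n_leaves, 0)
        phylo = Phylogeny(tree)
    else:
        raise ValueError(f"unknown tree kind {kind!r}")
    if height is not None:
        h = phylo.height()
        if h <= 0:
            raise ValueError("cannot rescale a zero-height tree")
        phylo = phylo.scale(height / h)
    return phylo


@dataclass
class SurrogateSpec:
    """Conditions for surrogate column-attention tensors.

    ``signal`` maps ``(layer, head)`` to the logit gain ``gamma``; heads
    absent from the map are pure noise.  Defaults plant six signal heads in
    the early layers with gains of both signs, echoing the empirical
    pattern that distance-encoding heads concentrate early and some attend
    to similar (negative gain) rather than dissimilar sequences.
    """

    n_layers: int = 12
    n_heads: int = 12
    signal: dict[tuple[int, int], float] = field(
        default_factory=lambda: {
            (0, 4): 3.0,
            (0, 7): -3.0,
            (1, 2): 3.0,
            (1, 9): -3.0,
            (2, 5): 3.0,
            (3, 1): -3.0,
        }
    )
    noise_scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for (l, h) in self.signal:
            if not (0 <= l < self.n_layers and 0 <= h < self.n_heads):
                raise ValueError(f"signal head ({l}, {h}) out of range")


def _row_softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def surrogate_attentions(msa: Msa, spec: SurrogateSpec) -> ColumnAttentionSet:
    """Column-attention tensor with a planted Hamming-distance signal.

    Shape ``(n_layers, n_heads, L + 1, M, M)``; column 0 (BOS) carries
    noise only.
    """
    rng = np.random.default_rng(spec.seed)
    M, L = msa.depth, msa.length
    shape = (spec.n_layers, spec.n_heads, L + 1, M, M)
    logits = rng.standard_normal(shape).astype(np.float32) * spec.noise_scale
    if spec.signal:
        X = msa.matrix
        # match[j, i, i'] = 1 where sequences i and i' agree at column j
        match = (X.T[:, :, None] == X.T[:, None, :]).astype(np.float32)
        for (l, h), gamma in spec.signal.items():
            logits[l, h, 1:] += np.float32(gamma) * match
    tensor = _row_softmax(logits.astype(np.float64))
    return ColumnAttentionSet(tensor=tensor)


def fixture_suite() -> dict:
    """Deterministic tiny objects shared by tests and examples.

    Contents: a 6 x 8 MSA with known pairwise distances, an enumerable
    L = 6 / q = 3 Potts model (729 states), a 4-leaf tree, and a 2-layer /
    2-head surrogate attention tensor for the MSA.
    """
    seqs = [
        "ACDEFGHI",
        "ACDEFGHI",
        "ACDEFGHK",
        "AMDEFGHI",
        "KKKKKKKK",
        "ACDEWWWW",
    ]
    ids = [f"fx{k}" for k in range(len(seqs))]
    idx = {c: i for i, c in enumerate(DEFAULT_ALPHABET)}
    matrix = np.array([[idx[c] for c in s] for s in seqs], dtype=np.int8)
    msa = Msa(ids=ids, matrix=matrix)

    rng = np.random.default_rng(20231)
    L, q = 6, 3
    fields = 0.5 * rng.standard_normal((L, q))
    blocks = {
        (0, 3): _zero_sum_block(rng.standard_normal((q, q))),
        (1, 5): _zero_sum_block(rng.standard_normal((q, q))),
    }
    model = PottsModel.from_pair_blocks(L, q, fields, blocks)

    tree = Phylogeny.from_newick("((A:0.1,B:0.2):0.05,(C:0.3,D:0.1):0.15);")

    small = Msa(ids=ids, matrix=matrix % 8, alphabet=DEFAULT_ALPHABET[:8])
    attn = surrogate_attentions(
        small,
        SurrogateSpec(
            n_layers=2, n_heads=2, signal={(0, 1): 2.0}, noise_scale=0.1, seed=7
        ),
    )
    return {"msa": msa, "model": model, "tree": tree, "attentions": attn}
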