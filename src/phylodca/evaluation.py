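"""Contact-recovery evaluation under phylogenetic noise.

The central statistic is the relative drop in contact-recovery ROC-AUC
caused by generating an alignment along a phylogeny instead of
independently at equilibrium,

    Delta = (A_eq - A_tree) / A_eq,

where ground-truth "proxy contacts" are the top APC-corrected coupling
scores of the generating Potts model itself.  ROC-AUC uses the rank-sum
(Mann-Whitney) formulation with midranks for ties: the probability that a
uniformly chosen truth pair outscores a uniformly chosen non-truth pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .msa import Msa
from .plm import PlmConfig, coupling_scores
from .potts import (
    CouplingScoreMatrix,
    PottsModel,
    apc,
    eligible_pairs,
    frobenius_scores,
    top_pairs,
)
from .sampling import McmcConfig, sample_along_tree, sample_equilibrium
from .trees import Phylogeny

logger = logging.getLogger(__name__)

MIN_SEPARATION = 4  # |i - j| <= 4 pairs are excluded from truth and candidates


@dataclass
class ContactEvalResult:
    """ROC-AUCs of one equilibrium/tree comparison at one truth cutoff."""

    auc_eq: float
    auc_tree: float
    delta: float
    cutoff: int
    n_eligible: int

    def __post_init__(self) -> None:
        if self.auc_eq > 0:
            expected = (self.auc_eq - self.auc_tree) / self.auc_eq
            if abs(self.delta - expected) > 1e-12:
                raise ValueError("delta inconsistent with its AUCs")


def roc_auc(
    scores: CouplingScoreMatrix,
    truth: set | list,
    eligible: list | None = None,
    min_separation: int = MIN_SEPARATION,
) -> float:
    """Rank-sum ROC-AUC of the truth pairs among the eligible pairs.

    Ties count one half (midrank convention).
    """
    if eligible is None:
        eligible = eligible_pairs(scores.length, min_separation)
    truth = {tuple(sorted(p)) for p in truth}
    eligible = [tuple(sorted(p)) for p in eligible]
    if not truth.issubset(set(eligible)):
        raise ValueError("truth pairs must be a subset of eligible pairs")
    n_pos = len(truth)
    n_neg = len(eligible) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one truth and one non-truth pair")
    vals = np.array([scores.scores[p] for p in eligible])
    is_pos = np.array([p in truth for p in eligible])
    ranks = rankdata(vals)  # midranks
    u = ranks[is_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def phylogeny_impact(auc_eq: float, auc_tree: float) -> float:
    """Relative AUC drop ``(A_eq - A_tree) / A_eq``; may be negative."""
    if auc_eq <= 0:
        raise ValueError("auc_eq must be positive")
    return (auc_eq - auc_tree) / auc_eq


def ground_truth_pairs(
    generator: PottsModel, k: int, min_separation: int = MIN_SEPARATION
) -> list[tuple[int, int]]:
    """Top-k APC-corrected Frobenius pairs of the generating model itself."""
    return top_pairs(apc(frobenius_scores(generator)), k, min_separation)


def default_subsample_size(depth: int) -> int:
    """Default subsample depth: 500, reduced to ``floor(0.8 M)`` for shallow MSAs."""
    return 500 if depth >= 500 else int(np.floor(0.8 * depth))


def subsample_average_scores(
    msa: Msa,
    scorer,
    n_sub: int = 10,
    m_sub: int | None = None,
    rng: np.random.Generator | None = None,
) -> CouplingScoreMatrix:
    """Score ``n_sub`` random row-subsamples of depth ``m_sub`` and average.

    Mirrors the deep-alignment protocol of scoring memory-bounded
    subsamples and averaging the resulting matrices; rows are drawn
    uniformly without replacement within each subsample.  ``m_sub``
    defaults to :func:`default_subsample_size`.
    """
    if m_sub is None:
        m_sub = default_subsample_size(msa.depth)
    if m_sub > msa.depth:
        raise ValueError(f"m_sub={m_sub} exceeds MSA depth {msa.depth}")
    rng = rng if rng is not None else np.random.default_rng(0)
    mats, index_sets = [], []
    for _ in range(n_sub):
        rows = np.sort(rng.choice(msa.depth, size=m_sub, replace=False))
        index_sets.append(rows)
        sub = Msa(
            ids=[msa.ids[r] for r in rows],
            matrix=msa.matrix[rows],
            alphabet=msa.alphabet,
        )
        mats.append(scorer(sub).scores)
        logger.info("subsample %d/%d: rows %s...", len(mats), n_sub, rows[:5])
    mean = np.mean(mats, axis=0)
    return CouplingScoreMatrix(
        scores=mean,
        apc_applied=True,
        metadata={"subsample_indices": index_sets, "per_subsample": mats},
    )


def distance_matrix_correlation(d1: np.ndarray, d2: np.ndarray) -> float:
    """Pearson correlation of two distance matrices over strict upper triangles."""
    d1 = np.asarray(d1, float)
    d2 = np.asarray(d2, float)
    if d1.shape != d2.shape or d1.ndim != 2 or d1.shape[0] != d1.shape[1]:
        raise ValueError("need two square matrices of the same shape")
    iu = np.triu_indices(d1.shape[0], k=1)
    a, b = d1[iu], d2[iu]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant upper triangle: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class DisentangleConfig:
    """Inputs of one equilibrium-vs-tree comparison."""

    depth: int
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    plm: PlmConfig = field(default_factory=PlmConfig)
    truth_cutoff: int | None = None  # None -> number of planted/top pairs = 2L
    use_subsampling: bool = False
    n_sub: int = 10
    m_sub: int | None = None  # None -> default_subsample_size(depth)


def run_disentangling_experiment(
    generator: PottsModel,
    tree: Phylogeny,
    config: DisentangleConfig,
    cutoffs: dict[str, int] | None = None,
) -> dict[str, ContactEvalResult]:
    """Equilibrium and along-tree MSAs of equal depth, scored and compared.

    Returns one :class:`ContactEvalResult` per truth cutoff (by default the
    planted-count cutoff is the caller's ``truth_cutoff`` and ``2L`` the
    second).  Fully deterministic given the seeds in ``config``.
    """
    L = generator.length
    if cutoffs is None:
        n_top = config.truth_cutoff or 2 * L
        cutoffs = {"top": n_top, "2L": 2 * L}

    msa_eq = sample_equilibrium(generator, config.depth, config.mcmc)
    msa_tree = sample_along_tree(generator, tree, config.mcmc)
    if msa_tree.depth != config.depth:
        logger.warning(
            "tree has %d leaves but depth %d requested", msa_tree.depth, config.depth
        )

    def scorer(m: Msa) -> CouplingScoreMatrix:
        return coupling_scores(m, config.plm)

    if config.use_subsampling:
        rng_eq = np.random.default_rng(config.mcmc.seed + 7)
        rng_tr = np.random.default_rng(config.mcmc.seed + 13)
        scores_eq = subsample_average_scores(
            msa_eq, scorer, config.n_sub, config.m_sub, rng_eq
        )
        scores_tree = subsample_average_scores(
            msa_tree, scorer, config.n_sub, config.m_sub, rng_tr
        )
    else:
        scores_eq = scorer(msa_eq)
        scores_tree = scorer(msa_tree)

    results = {}
    n_eligible = len(eligible_pairs(L, MIN_SEPARATION))
    for name, k in cutoffs.items():
        truth = ground_truth_pairs(generator, k)
        a_eq = roc_auc(scores_eq, truth)
        a_tree = roc_auc(scores_tree, truth)
        results[name] = ContactEvalResult(
            auc_eq=a_eq,
            auc_tree=a_tree,
            delta=phylogeny_impact(a_eq, a_tree),
            cutoff=k,
            n_eligible=n_eligible,
        )
        logger.info(
            "cutoff %s (k=%d): auc_eq=%.3f auc_tree=%.3f delta=%.3f",
            name, k, a_eq, a_tree, results[name].delta,
        )
    return results
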