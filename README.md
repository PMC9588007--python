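# phylodca

Correlations between the columns of a multiple sequence alignment (MSA)
have two sources: *coevolution* of residues under structural and
functional constraints, and *phylogeny* — the historical relatedness of
the sequences themselves. Disentangling the two is a central difficulty
for coevolution-based contact prediction. `phylodca` provides a
controlled, fully synthetic laboratory for studying it, plus the
regression machinery for the complementary question of how well pairwise
sequence distances can be read out of column-attention features.

The package is aimed at computational biologists who want to

* generate benchmark MSAs from Potts models with *known* couplings, either
  as independent equilibrium samples or evolved along a phylogeny;
* score couplings from an MSA with a self-contained pseudo-likelihood DCA
  implementation and measure how phylogeny degrades contact recovery;
* regress pairwise Hamming distances on column-attention tensors with a
  fractional-logit model and quantify prediction quality.

## The models at the core

**Potts / DCA.** Sequences `x = (x_1, ..., x_L)` over `q = 21` states are
modelled by `H(x) = -Σ_i h_i(x_i) - Σ_{i<j} e_ij(x_i, x_j)` with Boltzmann
law `P(x) ∝ exp(-H(x))`. Contact scores are the APC-corrected Frobenius
norms of the zero-sum-gauge coupling blocks. Inference is per-site
pseudo-likelihood with l2 penalties (`λ = 10⁻²`) and sequence reweighting
at distance threshold `δ = 0.2`.

**Sequence generation.** Metropolis–Hastings dynamics under `H`: a site
is picked uniformly, a different state proposed uniformly, and the move
accepted with probability `min(1, exp(-ΔH))`. Equilibrium MSAs are
independent chains; phylogenetic MSAs evolve an equilibrium root sequence
down a tree by duplication at branchings and exactly `round(bL)` accepted
mutations along each branch of length `b`.

**Phylogeny impact.** With proxy contacts defined as the generator's own
top coupling scores, contact recovery is summarised by the rank-sum
ROC-AUC, and the cost of phylogeny by `Δ = (A_eq - A_tree) / A_eq`.

**Distance regression.** Column-attention tensors `A_j^(l,h)` (one
row-stochastic `M × M` map per layer, head and column, the BOS column
`j = 0` included) are aggregated as
`A^(l,h) = 1/(2(L+1)) Σ_j (A_j + A_jᵀ)`; the entries at `(i, i′)` feed a
fractional logit `E[y | a] = σ(β₀ + aβᵀ)` for the normalized Hamming
distance `y`, fitted by Bernoulli quasi-maximum-likelihood.

## Worked example

```python
import numpy as np
import phylodca as pd
from phylodca.synthetic import PlantedSpec, planted_potts, random_tree

# a Potts model with 10 strong planted couplings (L=30, q=8)
model, contacts = planted_potts(PlantedSpec(seed=100))

# equilibrium MSA vs MSA evolved along a Yule tree of the same depth
msa_eq = pd.sample_equilibrium(model, 2000, pd.McmcConfig(seed=1000))
tree = random_tree(2000, kind="yule", height=0.4, seed=2000)
msa_tree = pd.sample_along_tree(model, tree, pd.McmcConfig(seed=3000))

a_eq = pd.roc_auc(pd.coupling_scores(msa_eq), contacts)
a_tree = pd.roc_auc(pd.coupling_scores(msa_tree), contacts)
print(f"AUC eq   {a_eq:.3f}")
print(f"AUC tree {a_tree:.3f}")
print(f"delta    {pd.phylogeny_impact(a_eq, a_tree):+.3f}")
```

Output:

```
AUC eq   1.000
AUC tree 0.465
delta    +0.535
```

Read: from 2000 independent equilibrium sequences, pseudo-likelihood DCA
ranks all 10 planted pairs above every background pair (AUC 1.0). The
*same* model, the *same* number of sequences, but related by a short-branch
phylogeny: recovery collapses to chance level, a relative drop Δ of ~0.5.
Nothing changed except the historical contingency in the data — this is
phylogenetic noise, isolated.

A console script wraps the common steps:

```bash
phylodca stats alignment.fasta            # M, L, M_eff, column entropies
phylodca sample eq --model m.h5 --depth 500 --seed 1 -o out.fasta
phylodca score alignment.fasta -o scores.tsv
phylodca disentangle --depth 500 --seed 3
```

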