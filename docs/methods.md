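# Methods

`phylodca` is a desk-scale pipeline for studying how phylogenetic
correlations contaminate coevolution-based contact inference, and for
regressing pairwise sequence distances on column-attention features. This
note records the models, the numerical choices, and what the synthetic
generators do and do not emulate.

## Alignments and reweighting

An alignment is an `M x L` integer matrix over `q = 21` states — the 20
amino acids in the fixed order `ACDEFGHIKLMNPQRSTVWY` followed by the gap,
which is treated as an ordinary 21st state everywhere (in particular,
gap aligned to gap counts as a match in the normalized Hamming distance
`d_H`). Non-standard residue codes (`B Z X U O .`) are coerced to the gap
on input with a warning; the choice is conventional, made once for
deterministic encoding.

Sequence weights follow the standard phylogenetic reweighting
`w_i = 1 / |{i' : d_H(x_i, x_i') < delta}|` with `delta = 0.2` by default;
`M_eff = sum_i w_i`. The neighbour set contains `i` itself, so `delta`
must be positive; `M_eff` is non-increasing in `delta`.

## Potts model, gauge and contact scores

The Hamiltonian is `H(x) = -sum_i h_i(x_i) - sum_{i<j} e_ij(x_i, x_j)`
with Boltzmann law `P(x) = exp(-H(x)) / Z`. Couplings are stored densely,
`(L, L, q, q)`, with symmetric access enforced by construction. Exact
enumeration of `P` is available up to `q^L <= 1e6` states and serves as the
oracle for the sampler and gauge tests.

Contact scores follow the standard DCA recipe: zero-sum gauge (every
coupling block has zero row and column means; removed means are absorbed
into the fields, leaving `P` unchanged; fields are additionally centred
per site), Frobenius norm per pair over all `q` states including the gap,
then the average product correction `E_ij = F_ij - F_i. F_.j / F_..` with
row and grand means excluding the diagonal. Two consequences of that
(standard) mean convention are worth recording: a constant off-diagonal
matrix is annihilated exactly, but a general rank-one matrix `u u^T` is
only suppressed approximately — the residual is second order in the
coefficient of variation of `u` (about 7% of the maximum score for
cv ~ 0.3). Cutoff lists (`top_pairs`) exclude pairs with `|i - j| <= 4`
and break score ties lexicographically on `(i, j)` so ranked lists are
reproducible. The same `|i - j| > 4` restriction is applied both to the
candidate set and to the proxy-contact truth set.

## Pseudo-likelihood inference

`PlmDCA` minimises, independently per site,

    f_i = -(1/M_eff) sum_m w_m log P(x_mi | x_m,-i)
          + lambda_h ||h_i||^2 + lambda_J sum_{j!=i} ||J_ij||^2

with `lambda_h = lambda_J = 1e-2` and reweighting at `delta = 0.2` (a fixed
threshold; no automatic estimation). Each per-site problem is strictly
convex; it is solved by L-BFGS-B with an analytic gradient from a zero
initialization, declared converged when the gradient infinity-norm falls
below `tol = 1e-5` (a small numerical margin of 3x is tolerated when the
optimizer halts on its relative-decrease test first); otherwise a
`ConvergenceError` carries the final gradient norm. The self-coupling
block is pinned at zero by zeroing its gradient, which an optimizer
started at zero provably never moves. The two per-site estimates of each
coupling block are averaged (`e_ij(a,b) = (J_i[j](a,b) + J_j[i](b,a))/2`);
regularization acts on the asymmetric parameters before symmetrisation.
No pseudocounts are used — the conditional-likelihood objective does not
need them.

## Sequence generation

Metropolis–Hastings proposals pick a site uniformly and one of the `q - 1`
*other* states uniformly; acceptance probability is `min(1, exp(-dH))`
with `dH` computed incrementally (verified against full recomputation).

*Equilibrium*: `M` independent chains from uniform random starts, each
advanced a fixed number of proposals; the default budget `50 * L * q`
proposals per chain is a conservative equilibration allowance for the
small, moderately coupled models used here (an external equilibration-time
estimate is not available for planted models), and can be overridden.

*Along a tree*: an equilibrium draw is placed at the root; the sequence is
duplicated at each branching and, along each branch of length `b`
(expected substitutions per site), proposals continue until exactly
`round(b * L)` are accepted, with half-up rounding of exact `.5` ties. A
cap of `1000` proposals per unit of accepted quota converts pathological
non-acceptance (deep energy wells) into an error naming the branch.
Because the root is an equilibrium sample and the dynamics satisfy
detailed balance, every sequence in the tree is marginally an equilibrium
sequence and ensemble observables are invariant to root placement — a
property the test suite checks by re-rooting a fixed topology. Unrooted
input trees are therefore rooted harmlessly at an arbitrary internal node.
All randomness is derived from one `SeedSequence`, so identical inputs
give byte-identical alignments.

## Attention regression

Raw column attentions form a `(layer, head, column, M, M)` tensor of
row-stochastic slices, with column 0 the beginning-of-sentence (BOS)
column. Aggregation averages the symmetrised slices over all `L + 1`
columns, BOS included. The per-pair feature vector is the `(i, i')` entry
of each of the `n_layers x n_heads` aggregated maps, in a fixed
layer-major raster order.

The response — normalized Hamming distance in `[0, 1]` — is modelled as
`E[y | a] = sigma(beta_0 + a beta^T)` and fitted by maximising the summed
Bernoulli quasi-log-likelihood (a binomial-family GLM with logit link, fit
by IRLS through statsmodels). Responses exactly 0 (duplicate sequences)
are legal and included. Perfect collinearity of features is an error, not
a silent pseudo-inverse. No regularization by default; an optional ridge
(`alpha`) exists but is off. The per-MSA protocol splits rows 70/30 and
forms pairs strictly within each side; the cross-MSA protocol pools
within-MSA pairs of several alignments into one fit and evaluates R^2,
Pearson r and the slope of truth-on-prediction on held-out alignments.
Per-column prediction uses the symmetrised single-column maps without the
`1/(2(L+1))` aggregation factor; the scale is absorbed by the
coefficients, so per-column predictions are comparable only within that
convention.

## Synthetic generators and what they (do not) show

`planted_potts` draws `n_contacts` site pairs uniformly among pairs with
`|i - j| >= 5` and gives each a random coupling block projected to the
zero-sum gauge and scaled to Frobenius norm `coupling_scale` (default 3.0,
a strong, unambiguous contact signal); all other couplings are zero and
fields are i.i.d. normal with scale 0.3. The planted pairs are therefore
exactly the generator's top APC scores, giving a noiseless proxy-contact
truth set.

For the disentangling benchmark the phylogeny is a Yule (pure-birth) tree
rescaled to height 0.4 expected substitutions per site. That height is
chosen to emulate the strong redundancy of large natural alignments
(observed `M_eff / M` down to ~0.06; the tree-generated alignments here
have `M_eff / M ~ 0.15`), which is the regime in which phylogenetic
correlations visibly contaminate coupling inference. At the package's
study scale (`L = 30`, `q = 8`, 10 contacts, `M = 2000`) equilibrium
alignments give pseudo-likelihood ROC-AUC ~1 and tree alignments a
substantial positive Delta; only this direction, not the magnitudes of
any published per-family table, is meaningful at desk scale, because the
published values depend on family-specific generative models fitted to
deep natural MSAs, inferred trees, and a pretrained attention scorer.

`surrogate_attentions` plants a distance signal in designated heads:
pre-softmax logits are `gamma_lh * match_j(i, i') + noise`, where
`match_j` indicates equal states at column `j`. Averaged over columns the
match indicator equals `1 - d_H` exactly, so the planted link is linear on
the logit scale; the BOS column is pure noise. Default conditions: 12x12
heads, six signal heads in early layers with gains +-3 (negative gains
model heads that attend to *similar* sequences), noise scale 0.1. The
regression-recovery study uses tree-generated MSAs (`M = 150`, tree height
0.8): equilibrium MSAs concentrate all pairwise distances near saturation
and are not representative of the wide distance spread (and block
structure) of curated seed alignments, which is what makes distance
regression well-posed. Under these conditions held-out R^2 is ~0.92-0.95
for signal tensors and within +-0.05 of zero for pure-noise tensors, and
fully conserved columns yield per-column prediction errors with markedly
smaller standard deviation than typical columns — conserved columns
contribute a constant feature, so their predictions cannot chase
pair-specific noise.

What the surrogates do *not* emulate: trained-transformer attention
statistics (head correlations, sparsity, value-dependent structure),
insertion/gap patterns of real alignments, or any row-attention/contact
signal. Passing tests therefore show that the pipeline recovers planted
structure under realistic alignment geometry — not that any particular
language model encodes distances.

## Evaluation

ROC-AUC uses the rank-sum (Mann–Whitney) formulation with midranks for
ties, over candidate pairs with `|i - j| > 4`; it is checked against an
independent trapezoidal implementation in the tests. The phylogeny impact
is `Delta = (A_eq - A_tree) / A_eq`, which may be negative. The
subsample-and-average protocol scores `n_sub = 10` uniform row-subsamples
of size `m_sub = 500` (capped at `0.8 M` for shallow alignments) and
averages the matrices; the subsample index sets and per-subsample matrices
are kept in the result metadata.

## Problem sizes used by the shipped checks

The acceptance script and end-to-end tests use: sampler-law comparison on
an enumerable `L = 3, q = 3` model (`10^4` chains x `10^5` proposals; the
model is concentrated enough that the finite-sample total-variation floor
~0.013 sits below the asserted 0.02); the disentangling benchmark at
`L = 30, q = 8, M = 2000` (10 seeds in the tests, 3 in the script);
regression recovery at `M = 150, L = 15` with 12x12 heads; root-placement
invariance with 200 runs per rooting on a 16-leaf tree. These sizes were
chosen so the whole pipeline re-runs from scratch on a single CPU in a few
minutes while keeping every statistical assertion well-powered.

## Known limitations

* The pseudo-likelihood fit materialises a dense one-hot design
  (`M x Lq`); fine for desk scale, wasteful beyond `M ~ 10^4` or `L`ong
  alignments.
* The along-tree sampler handles substitutions only — no indels, rate
  heterogeneity, or site-specific clocks.
* `exact_distribution` enumerates `q^L` states and is a test oracle, not
  an inference tool.
* The fractional logit is fitted without regularization; with many heads
  and few pairs it will overfit (visible as a mildly negative noise-floor
  R^2), which is why the shipped protocols keep `n_pairs >> n_features`.
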