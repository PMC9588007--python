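"""Predicting pairwise Hamming distances from column-attention tensors.

A column-attention tensor holds, for each layer ``l``, head ``h`` and MSA
column ``j`` (``j = 0`` being the beginning-of-sentence column), a
row-stochastic ``M x M`` map.  Averaging the symmetrised per-column maps,

    A^(l,h) = 1 / (2 (L + 1)) * sum_{j=0..L} (A_j^(l,h) + A_j^(l,h)^T),

gives one symmetric matrix per head; its entries at ``(i, i')`` are the
regression features for the sequence pair ``(i, i')``.  The response — the
normalized Hamming distance ``y in [0, 1]`` — is modelled as a fractional
logit, ``E[y | a] = sigma(beta_0 + a beta^T)``, fitted by maximising the
Bernoulli quasi-log-likelihood (a GLM with binomial family and logit link).

Coefficients are stored in a fixed layer-major raster order
``(l=0 h=0), (l=0 h=1), ...`` so heatmaps and cross-model comparisons are
stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.special import expit
from sklearn.base import BaseEstimator, RegressorMixin

from .msa import Msa, distance_matrix


# ---------------------------------------------------------------------------
# containers


@dataclass
class ColumnAttentionSet:
    """Raw per-column attentions, ``(n_layers, n_heads, L + 1, M, M)``.

    Every row of every ``M x M`` slice must sum to one (row-stochastic);
    slice ``j = 0`` is the BOS column.
    """

    tensor: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.tensor)
        if t.ndim != 5 or t.shape[3] != t.shape[4]:
            raise ValueError("tensor must be (layers, heads, L + 1, M, M)")
        if t.shape[2] < 2:
            raise ValueError("tensor must include the BOS column (j = 0)")
        if t.min() < 0:
            raise ValueError("attention entries must be non-negative")
        sums = t.sum(axis=4)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("attention rows must sum to 1 (row-stochastic)")
        self.tensor = t

    @property
    def n_layers(self) -> int:
        return self.tensor.shape[0]

    @property
    def n_heads(self) -> int:
        return self.tensor.shape[1]

    @property
    def length(self) -> int:
        return self.tensor.shape[2] - 1

    @property
    def depth(self) -> int:
        return self.tensor.shape[3]


@dataclass
class AttentionStack:
    """Column-averaged symmetric attention maps, ``(n_layers, n_heads, M, M)``."""

    matrices: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrices)
        if m.ndim != 4 or m.shape[2] != m.shape[3]:
            raise ValueError("matrices must be (layers, heads, M, M)")
        if not np.allclose(m, m.transpose(0, 1, 3, 2), atol=1e-9):
            raise ValueError("stack matrices must be symmetric")
        self.matrices = m

    @property
    def n_layers(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_heads(self) -> int:
        return self.matrices.shape[1]

    @property
    def depth(self) -> int:
        return self.matrices.shape[2]

    @property
    def n_features(self) -> int:
        return self.n_layers * self.n_heads


def aggregate_attentions(raw: ColumnAttentionSet) -> AttentionStack:
    """Average the symmetrised per-column maps over all columns, BOS included."""
    t = raw.tensor
    sym = (t + t.transpose(0, 1, 2, 4, 3)) / 2.0
    return AttentionStack(matrices=sym.mean(axis=2))


def pair_features(stack: AttentionStack, i: int, ip: int) -> np.ndarray:
    """Length ``n_layers * n_heads`` feature vector for sequence pair (i, i')."""
    if i == ip:
        raise ValueError("self-pairs are not regression rows")
    return stack.matrices[:, :, i, ip].ravel()


def _pairs_upper(indices: np.ndarray) -> list[tuple[int, int]]:
    idx = sorted(int(v) for v in indices)
    return [(a, b) for k, a in enumerate(idx) for b in idx[k + 1 :]]


def build_design(
    stack: AttentionStack, dmat: np.ndarray, pairs: list[tuple[int, int]]
) -> tuple[np.ndarray, np.ndarray]:
    """Feature table and responses for a list of unordered row pairs."""
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    X = stack.matrices[:, :, ii, jj].reshape(stack.n_features, -1).T
    y = dmat[ii, jj]
    return X, y


# ---------------------------------------------------------------------------
# the fractional logit estimator


class FractionalLogitRegressor(RegressorMixin, BaseEstimator):
    """Quasi-MLE logistic-link regression for responses in [0, 1].

    Maximises the Bernoulli quasi-log-likelihood
    ``y log G + (1 - y) log(1 - G)`` with ``G = sigma(b0 + x b^T)`` — a GLM
    with binomial family and logit link, valid for fractional responses.
    Perfectly collinear features raise rather than silently falling back to
    a pseudo-inverse.  An optional ridge penalty ``alpha`` exists but
    defaults to 0 (plain quasi-MLE).

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray of shape (n_features,)
    """

    def __init__(self, alpha: float = 0.0, max_iter: int = 500, tol: float = 1e-10):
        self.alpha = alpha
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_pairs, n_features) matching y")
        if X.shape[0] < X.shape[1] + 1:
            raise ValueError("need at least n_features + 1 observations")
        if not np.isfinite(X).all():
            raise ValueError("features must be finite")
        if y.min() < 0 or y.max() > 1:
            raise ValueError("responses must lie in [0, 1]")
        design = sm.add_constant(X, has_constant="add")
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("perfectly collinear features; drop redundant heads")
        model = sm.GLM(y, design, family=sm.families.Binomial())
        if self.alpha > 0:
            # do not penalize the intercept
            pen = np.r_[0.0, np.full(X.shape[1], self.alpha)]
            res = model.fit_regularized(alpha=pen, L1_wt=0.0)
            params = res.params
        else:
            res = model.fit(maxiter=self.max_iter, tol=self.tol)
            params = res.params
        self.intercept_ = float(params[0])
        self.coef_ = np.asarray(params[1:], dtype=float)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return expit(self.intercept_ + X @ self.coef_)

    def coefficient_grid(self, n_layers: int, n_heads: int) -> np.ndarray:
        """Coefficients reshaped to the (layer, head) raster."""
        return self.coef_.reshape(n_layers, n_heads)


@dataclass
class FractionalLogitModel:
    """Plain record of a fitted model: intercept and raster-ordered betas."""

    intercept: float
    coef: np.ndarray
    n_layers: int | None = None
    n_heads: int | None = None

    @classmethod
    def from_estimator(
        cls, est: FractionalLogitRegressor, n_layers=None, n_heads=None
    ) -> "FractionalLogitModel":
        return cls(est.intercept_, est.coef_.copy(), n_layers, n_heads)

    def as_estimator(self) -> FractionalLogitRegressor:
        est = FractionalLogitRegressor()
        est.intercept_ = self.intercept
        est.coef_ = np.asarray(self.coef, dtype=float)
        est.n_features_in_ = est.coef_.size
        return est


def fit_fractional_logit(X, y) -> FractionalLogitModel:
    """Functional wrapper over :class:`FractionalLogitRegressor`."""
    est = FractionalLogitRegressor().fit(X, y)
    return FractionalLogitModel.from_estimator(est)


def predict_distances(model: FractionalLogitModel, stack: AttentionStack) -> np.ndarray:
    """Symmetric ``M x M`` matrix of predicted distances; zero diagonal."""
    if model.coef.size != stack.n_features:
        raise ValueError(
            f"model has {model.coef.size} coefficients, stack provides "
            f"{stack.n_features} features"
        )
    est = model.as_estimator()
    M = stack.depth
    feats = stack.matrices.reshape(stack.n_features, M * M).T
    pred = est.predict(feats).reshape(M, M)
    pred = (pred + pred.T) / 2.0
    np.fill_diagonal(pred, 0.0)
    return pred


# ---------------------------------------------------------------------------
# protocols and diagnostics


def split_protocol(
    msa: Msa, frac: float = 0.7, rng: np.random.Generator | None = None
):
    """Partition rows into train/test; pairs never straddle the partition.

    Returns ``(train_rows, test_rows, train_pairs, test_pairs)``.
    """
    if msa.depth < 4:
        raise ValueError("need at least 4 sequences to split")
    rng = rng if rng is not None else np.random.default_rng(0)
    M = msa.depth
    n_train = int(round(frac * M))
    perm = rng.permutation(M)
    train, test = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    if len(train) < 2 or len(test) < 2:
        raise ValueError(f"split {frac} leaves fewer than 2 rows on one side")
    return train, test, _pairs_upper(train), _pairs_upper(test)


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination ``1 - SS_res / SS_tot``."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("need equal-length arrays of size >= 2")
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("constant ground truth: R^2 undefined")
    ss_res = float(((y_true - y_pred) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def slope_diagnostic(y_true, y_pred) -> float:
    """OLS slope of the ground truth regressed on the predictions.

    A slope away from 1 flags a systematic compression/expansion bias of
    the predictions.
    """
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.size < 2:
        raise ValueError("need at least 2 pairs")
    var = y_pred.var()
    if var == 0:
        raise ValueError("constant predictions: slope undefined")
    cov = np.mean((y_pred - y_pred.mean()) * (y_true - y_true.mean()))
    return float(cov / var)


def fit_on_msa(
    msa: Msa,
    stack: AttentionStack,
    frac: float = 0.7,
    rng: np.random.Generator | None = None,
):
    """Per-MSA protocol: 70/30 row split, fit on train pairs, eval on test.

    Returns ``(model, metrics)`` where metrics holds train/test R^2,
    Pearson r and the slope diagnostic on the test pairs.
    """
    dmat = distance_matrix(msa)
    train, test, train_pairs, test_pairs = split_protocol(msa, frac, rng)
    Xtr, ytr = build_design(stack, dmat, train_pairs)
    Xte, yte = build_design(stack, dmat, test_pairs)
    est = FractionalLogitRegressor().fit(Xtr, ytr)
    model = FractionalLogitModel.from_estimator(
        est, stack.n_layers, stack.n_heads
    )
    pred_tr, pred_te = est.predict(Xtr), est.predict(Xte)
    metrics = {
        "r2_train": r_squared(ytr, pred_tr),
        "r2_test": r_squared(yte, pred_te),
        "pearson_r_test": float(np.corrcoef(yte, pred_te)[0, 1]),
        "slope_test": slope_diagnostic(yte, pred_te),
    }
    return model, metrics


def cross_msa_fit(msas, stacks) -> FractionalLogitModel:
    """Pool all within-MSA pairs of several MSAs into one fit.

    Pairs never span two MSAs.  All stacks must share (n_layers, n_heads).
    """
    if len(msas) == 0 or len(msas) != len(stacks):
        raise ValueError("need one stack per MSA, at least one of each")
    shapes = {(s.n_layers, s.n_heads) for s in stacks}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent (n_layers, n_heads) across stacks: {shapes}")
    Xs, ys = [], []
    for msa, stack in zip(msas, stacks):
        dmat = distance_matrix(msa)
        pairs = _pairs_upper(np.arange(msa.depth))
        X, y = build_design(stack, dmat, pairs)
        Xs.append(X)
        ys.append(y)
    est = FractionalLogitRegressor().fit(np.vstack(Xs), np.concatenate(ys))
    nl, nh = shapes.pop()
    return FractionalLogitModel.from_estimator(est, nl, nh)


def evaluate_on_msa(model: FractionalLogitModel, msa: Msa, stack: AttentionStack):
    """Held-out evaluation over all within-MSA pairs: R^2, Pearson r, slope."""
    dmat = distance_matrix(msa)
    pairs = _pairs_upper(np.arange(msa.depth))
    X, y = build_design(stack, dmat, pairs)
    pred = model.as_estimator().predict(X)
    return {
        "r2": r_squared(y, pred),
        "pearson_r": float(np.corrcoef(y, pred)[0, 1]),
        "slope": slope_diagnostic(y, pred),
    }


def column_stack(raw: ColumnAttentionSet, j: int) -> AttentionStack:
    """Symmetrised single-column maps ``(A_j + A_j^T) / 2`` as a stack."""
    if not 0 <= j <= raw.length:
        raise IndexError(f"column {j} out of range [0, {raw.length}]")
    t = raw.tensor[:, :, j]
    return AttentionStack(matrices=(t + t.transpose(0, 1, 3, 2)) / 2.0)


def per_column_predict(
    model: FractionalLogitModel, raw: ColumnAttentionSet, j: int
) -> np.ndarray:
    """Predict the distance matrix using features from column ``j`` only."""
    return predict_distances(model, column_stack(raw, j))


def error_std_by_column(
    model: FractionalLogitModel,
    raw: ColumnAttentionSet,
    truth: np.ndarray,
    pairs: list[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Std of (prediction - truth) per attention column, over given pairs.

    Column 0 is the BOS column; column ``j >= 1`` corresponds to MSA site
    ``j - 1``.  Defaults to all unordered pairs.
    """
    M = raw.depth
    if pairs is None:
        pairs = _pairs_upper(np.arange(M))
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    out = np.empty(raw.length + 1)
    for j in range(raw.length + 1):
        pred = per_column_predict(model, raw, j)
        out[j] = float(np.std(pred[ii, jj] - truth[ii, jj]))
    return out


# ---------------------------------------------------------------------------
# HDF5 I/O


def save_attentions(raw: ColumnAttentionSet, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("column_attentions", data=raw.tensor)
        d.attrs["dims"] = "layer,head,column,row,row"
        f.attrs["n_layers"] = raw.n_layers
        f.attrs["n_heads"] = raw.n_heads
        f.attrs["L"] = raw.length
        f.attrs["M"] = raw.depth


def load_attentions(path) -> ColumnAttentionSet:
    import h5py

    with h5py.File(path, "r") as f:
        return ColumnAttentionSet(tensor=f["column_attentions"][...])


def save_logit_model(model: FractionalLogitModel, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("coef", data=model.coef)
        f.attrs["intercept"] = model.intercept
        f.attrs["order"] = "layer-major raster (l, h)"
        if model.n_layers is not None:
            f.attrs["n_layers"] = model.n_layers
            f.attrs["n_heads"] = model.n_heads


def load_logit_model(path) -> FractionalLogitModel:
    import h5py

    with h5py.File(path, "r") as f:
        nl = int(f.attrs["n_layers"]) if "n_layers" in f.attrs else None
        nh = int(f.attrs["n_heads"]) if "n_heads" in f.attrs else None
        return FractionalLogitModel(
            intercept=float(f.attrs["intercept"]), coef=f["coef"][...],
            n_layers=nl, n_heads=nh,
        )
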