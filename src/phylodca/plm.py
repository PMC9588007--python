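"""Pseudo-likelihood inference of Potts models from MSAs (desk-scale plmDCA).

Each site ``i`` contributes an independent multinomial-logistic objective:
the conditional law of ``x_i`` given the rest of the sequence under the
Potts Hamiltonian.  We minimise, per site,

    f_i = -(1/M_eff) sum_m w_m log P(x_mi | x_m,-i)
          + lambda_h ||h_i||^2 + lambda_J sum_{j != i} ||J_ij||^2

with sequences reweighted at similarity threshold ``delta`` (the same
weights as the effective-depth computation).  The two per-site estimates of
each coupling block are averaged (symmetrisation).  The objective is
strictly convex thanks to the l2 penalties, so any optimizer reaching the
gradient tolerance finds the same parameters; we use L-BFGS-B with an
analytic gradient.

The estimator follows the sklearn protocol: ``PlmDCA().fit(msa)`` exposes
``fields_``, ``couplings_``, ``model_`` and APC-corrected
``coupling_scores_``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .msa import Msa, sequence_weights
from .potts import CouplingScoreMatrix, PottsModel, apc, frobenius_scores


@dataclass
class PlmConfig:
    """Hyperparameters of the pseudo-likelihood fit."""

    lambda_fields: float = 1e-2
    lambda_couplings: float = 1e-2
    delta: float = 0.2
    tol: float = 1e-5
    max_iter: int = 2000

    def __post_init__(self) -> None:
        if self.lambda_fields < 0 or self.lambda_couplings < 0:
            raise ValueError("regularization strengths must be >= 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


class ConvergenceError(RuntimeError):
    def __init__(self, site: int, grad_norm: float):
        super().__init__(
            f"site {site}: pseudo-likelihood fit did not converge "
            f"(final scaled gradient norm {grad_norm:.3e})"
        )
        self.grad_norm = grad_norm


def site_objective(
    params: np.ndarray,
    i: int,
    onehot: np.ndarray,
    targets: np.ndarray,
    w: np.ndarray,
    L: int,
    q: int,
    lambda_h: float,
    lambda_j: float,
) -> tuple[float, np.ndarray]:
    """Penalized per-site conditional negative log-likelihood and gradient.

    ``params`` stacks ``h_i`` (q) and the row of coupling blocks ``J_i``
    (L, q, q) with the self-block pinned at zero (its gradient is zeroed, so
    an optimizer started from zero never moves it).
    """
    h = params[:q]
    W = params[q:].reshape(L * q, q)  # (feature, state)
    z = onehot @ W + h  # (M, q)
    z -= z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    m_idx = np.arange(targets.shape[0])
    logp = z[m_idx, targets] - np.log(ez.sum(axis=1))
    wsum = w.sum()
    nll = -float(w @ logp) / wsum

    resid = p * w[:, None]
    resid[m_idx, targets] -= w
    gh = resid.sum(axis=0) / wsum
    gW = (onehot.T @ resid) / wsum

    Jblocks = W.reshape(L, q, q)
    f = nll + lambda_h * float(h @ h) + lambda_j * float((Jblocks**2).sum())
    gW = gW.reshape(L, q, q) + 2.0 * lambda_j * Jblocks
    gW[i] = 0.0  # self-coupling stays pinned at zero
    grad = np.concatenate([gh + 2.0 * lambda_h * h, gW.ravel()])
    return f, grad


def _fit_site(
    i: int,
    onehot: np.ndarray,
    X: np.ndarray,
    w: np.ndarray,
    q: int,
    config: PlmConfig,
) -> tuple[np.ndarray, np.ndarray]:
    L = X.shape[1]
    x0 = np.zeros(q + L * q * q)
    res = minimize(
        site_objective,
        x0,
        args=(i, onehot, X[:, i], w, L, q,
              config.lambda_fields, config.lambda_couplings),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": config.max_iter, "gtol": config.tol, "ftol": 1e-14},
    )
    grad_norm = float(np.abs(res.jac).max())
    # allow a small numerical margin over the target: L-BFGS-B may stop on
    # its relative-decrease test a hair's breadth above the gradient test
    if grad_norm > 3.0 * config.tol:
        raise ConvergenceError(i, grad_norm)
    # stored as (j, b, a); reorder to (j, a, b) with a the state of site i
    return res.x[:q], res.x[q:].reshape(L, q, q).transpose(0, 2, 1)


class PlmDCA(BaseEstimator):
    """Sklearn-style pseudo-likelihood Potts estimator.

    Parameters mirror :class:`PlmConfig`.  ``fit`` accepts an :class:`Msa`
    or an ``(M, L)`` integer matrix (then ``q`` must be given).
    """

    def __init__(
        self,
        lambda_fields: float = 1e-2,
        lambda_couplings: float = 1e-2,
        delta: float = 0.2,
        tol: float = 1e-5,
        max_iter: int = 2000,
        q: int | None = None,
    ):
        self.lambda_fields = lambda_fields
        self.lambda_couplings = lambda_couplings
        self.delta = delta
        self.tol = tol
        self.max_iter = max_iter
        self.q = q

    def _config(self) -> PlmConfig:
        return PlmConfig(
            lambda_fields=self.lambda_fields,
            lambda_couplings=self.lambda_couplings,
            delta=self.delta,
            tol=self.tol,
            max_iter=self.max_iter,
        )

    def fit(self, X, y=None):
        if isinstance(X, Msa):
            msa, q = X, X.q
        else:
            X = np.asarray(X, dtype=np.int8)
            q = self.q if self.q is not None else int(X.max()) + 1
            msa = Msa(ids=[f"s{i}" for i in range(X.shape[0])], matrix=X,
                      alphabet="ACDEFGHIKLMNPQRSTVWY-"[:q])
        if msa.depth < 2 or msa.length < 2:
            raise ValueError("need M >= 2 sequences and L >= 2 sites")
        config = self._config()
        w = sequence_weights(msa, config.delta).weights
        M, L = msa.matrix.shape
        onehot = np.zeros((M, L * q))
        onehot[np.repeat(np.arange(M), L),
               np.arange(L * q).reshape(L, q)[np.arange(L), msa.matrix].ravel()] = 1.0

        fields = np.zeros((L, q))
        J_asym = np.zeros((L, L, q, q))
        for i in range(L):
            h_i, Jrow = _fit_site(i, onehot, msa.matrix, w, q, config)
            fields[i] = h_i
            J_asym[i] = Jrow  # J_asym[i, j, a, b]: effect of x_j=b on x_i=a

        # symmetrise: e_ij(a, b) = (J_i[j](a, b) + J_j[i](b, a)) / 2
        J = (J_asym + J_asym.transpose(1, 0, 3, 2)) / 2.0
        for i in range(L):
            J[i, i] = 0.0

        self.weights_ = w
        self.fields_ = fields
        self.couplings_ = J
        self.model_ = PottsModel(fields, J)
        self.coupling_scores_ = apc(frobenius_scores(self.model_))
        return self


def fit_plm(msa: Msa, config: PlmConfig | None = None) -> PottsModel:
    """Functional wrapper over :class:`PlmDCA`; returns the fitted model."""
    config = config or PlmConfig()
    est = PlmDCA(**vars(config)).fit(msa)
    return est.model_


def coupling_scores(msa: Msa, config: PlmConfig | None = None) -> CouplingScoreMatrix:
    """Full scoring pipeline: plm fit -> zero-sum gauge -> Frobenius -> APC."""
    config = config or PlmConfig()
    est = PlmDCA(**vars(config)).fit(msa)
    return est.coupling_scores_
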