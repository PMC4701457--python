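"""Sparse Bayesian kernel regression (relevance vector regression).

The model places an individual Gaussian prior ``w_i ~ N(0, 1/alpha_i)`` on
each basis weight and estimates the precisions ``alpha`` and the noise
precision ``beta`` by type-II maximum likelihood.  With a linear kernel the
design is ``Phi = [1 | K]`` where ``K = Xc Xc^T`` over training-mean-centered
features; bases whose precision diverges are pruned, and the training
samples that survive are the relevance vectors.

Re-estimation iterates

    Sigma = (A + beta Phi^T Phi)^-1
    mu    = beta Sigma Phi^T y
    gamma_i = 1 - alpha_i Sigma_ii
    alpha_i <- gamma_i / mu_i^2
    1/beta  <- ||y - Phi mu||^2 / (n - sum gamma)

until the largest change in log alpha falls below ``tol``.  Targets are
centered internally and the training mean is restored at prediction, so the
model is well behaved on raw 0-30 questionnaire scales.

Kernel ridge regression is provided as a closed-form baseline.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.linalg.lapack import dpotrf, dtrtri

_LOG2PI = np.log(2.0 * np.pi)


@dataclasses.dataclass
class KernelMatrix:
    """A (cross-)kernel together with the training feature means used."""

    K: np.ndarray
    centering_mean: np.ndarray

    def __post_init__(self):
        self.K = np.asarray(self.K, dtype=np.float64)
        self.centering_mean = np.asarray(self.centering_mean, dtype=np.float64)


def linear_kernel(
    X_train: np.ndarray,
    X_other: np.ndarray | None = None,
    centering_mean: np.ndarray | None = None,
) -> KernelMatrix:
    """Linear kernel on training-mean-centered features.

    Returns the train Gram matrix when ``X_other`` is None, otherwise the
    cross kernel rows=other, cols=train.
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    if centering_mean is None:
        centering_mean = X_train.mean(axis=0)
    centering_mean = np.asarray(centering_mean, dtype=np.float64)
    if centering_mean.shape != (X_train.shape[1],):
        raise ValueError("centering_mean length does not match feature count")
    Xc = X_train - centering_mean
    if X_other is None:
        return KernelMatrix(K=Xc @ Xc.T, centering_mean=centering_mean)
    X_other = np.asarray(X_other, dtype=np.float64)
    if X_other.shape[1] != X_train.shape[1]:
        raise ValueError("feature counts of X_other and X_train differ")
    return KernelMatrix(K=(X_other - centering_mean) @ Xc.T,
                        centering_mean=centering_mean)


@dataclasses.dataclass
class RVRModel:
    """Fitted relevance vector regression state.

    ``active_idx`` indexes columns of the design ``[1 | K]``: 0 is the bias,
    ``i >= 1`` is training sample ``i - 1``.  ``alpha``, ``mu`` and
    ``Sigma_diag`` are aligned with ``active_idx``.
    """

    alpha: np.ndarray
    beta: float
    mu: np.ndarray
    Sigma_diag: np.ndarray
    active_idx: np.ndarray
    y_offset: float
    n_train: int
    n_iter: int
    converged: bool
    evidence: np.ndarray

    @property
    def relevance_idx(self) -> np.ndarray:
        """Training-sample indices of the retained relevance vectors."""
        samp = self.active_idx[self.active_idx >= 1] - 1
        return samp.astype(np.int64)

    @property
    def all_pruned(self) -> bool:
        return self.active_idx.size == 0

    def save(self, path) -> None:
        np.savez(
            path,
            alpha=self.alpha, beta=self.beta, mu=self.mu,
            Sigma_diag=self.Sigma_diag, active_idx=self.active_idx,
            y_offset=self.y_offset, n_train=self.n_train,
            n_iter=self.n_iter, converged=self.converged,
            evidence=self.evidence,
        )

    @classmethod
    def load(cls, path) -> "RVRModel":
        with np.load(path) as z:
            return cls(
                alpha=z["alpha"], beta=float(z["beta"]), mu=z["mu"],
                Sigma_diag=z["Sigma_diag"],
                active_idx=z["active_idx"].astype(np.int64),
                y_offset=float(z["y_offset"]), n_train=int(z["n_train"]),
                n_iter=int(z["n_iter"]), converged=bool(z["converged"]),
                evidence=z["evidence"],
            )


def _as_kernel_array(K) -> np.ndarray:
    if isinstance(K, KernelMatrix):
        return K.K
    return np.asarray(K, dtype=np.float64)


def _posterior(PhiTPhi_a, PhiTy_a, alpha, beta):
    """Posterior (Sigma, mu, logdet) for the active design; jittered retry.

    Uses raw LAPACK Cholesky (dpotrf) and triangular inverse (dtrtri):
    this loop runs ~1e5 times in a permutation test, so wrapper overhead
    matters.
    """
    m = PhiTPhi_a.shape[0]
    H = beta * PhiTPhi_a
    H.flat[:: m + 1] += alpha
    c, info = dpotrf(H, lower=1)
    if info != 0:
        jitter = 1e-8 * max(np.trace(H) / m, 1.0)
        H.flat[:: m + 1] += jitter
        c, info = dpotrf(H, lower=1)
        if info != 0:
            raise np.linalg.LinAlgError(
                "posterior precision matrix is not positive definite"
            )
    linv, _ = dtrtri(c, lower=1)
    Sigma = linv.T @ linv
    mu = beta * (Sigma @ PhiTy_a)
    logdetH = 2.0 * np.log(c.diagonal()).sum()
    return Sigma, mu, logdetH


def _log_evidence(n, yty, PhiTy_a, mu, alpha, beta, logdetH):
    # log |C| and y^T C^-1 y via the Woodbury identities
    logdetC = -n * np.log(beta) - np.log(alpha).sum() + logdetH
    quad = beta * (yty - PhiTy_a @ mu)
    return -0.5 * (n * _LOG2PI + logdetC + quad)


def _offset_only(y_mean, n, n_iter, converged) -> RVRModel:
    return RVRModel(
        alpha=np.empty(0), beta=1.0, mu=np.empty(0), Sigma_diag=np.empty(0),
        active_idx=np.empty(0, dtype=np.int64), y_offset=float(y_mean),
        n_train=n, n_iter=n_iter, converged=converged,
        evidence=np.empty(0),
    )


def fit_rvr(
    K_train,
    y: np.ndarray,
    max_iter: int = 1000,
    tol: float = 1e-3,
    prune_alpha: float = 1e9,
    alpha_init: float | np.ndarray | None = None,
    beta_init: float | None = None,
) -> RVRModel:
    """Fit relevance vector regression on a precomputed train kernel.

    ``max_iter`` counts hyperparameter re-estimation steps; with
    ``max_iter=0`` and explicit ``alpha_init``/``beta_init`` the fit reduces
    to the fixed-hyperparameter Bayesian linear regression posterior.
    """
    K = _as_kernel_array(K_train)
    n = K.shape[0]
    if K.shape != (n, n):
        raise ValueError("training kernel must be square")
    y = np.asarray(y, dtype=np.float64)
    if y.shape != (n,):
        raise ValueError("y length does not match kernel size")
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    if n < 3:
        raise ValueError("need at least 3 training subjects")

    y_mean = y.mean()
    yc = y - y_mean
    var_y = yc.var()
    if var_y <= 0:
        # constant target: nothing to learn, predict the offset
        return _offset_only(y_mean, n, 0, True)

    Phi = np.concatenate([np.ones((n, 1)), K], axis=1)
    PhiTPhi = Phi.T @ Phi
    PhiTy = Phi.T @ yc
    yty = yc @ yc

    m_full = n + 1
    active = np.arange(m_full)
    if alpha_init is None:
        alpha = np.full(m_full, 1.0 / n**2)
    else:
        alpha = np.broadcast_to(np.asarray(alpha_init, dtype=np.float64),
                                (m_full,)).copy()
    beta = float(beta_init) if beta_init is not None else 1.0 / var_y

    evidence = []
    converged = False
    n_iter = 0
    Sigma = mu = None
    err_state = np.seterr(divide="ignore", invalid="ignore")
    try:
        # active-set submatrices are cached and rebuilt only after pruning
        PhiTPhi_a = PhiTPhi
        Phi_a = Phi
        PhiTy_a = PhiTy
        for it in range(max_iter + 1):
            Sigma, mu, logdetH = _posterior(PhiTPhi_a, PhiTy_a, alpha, beta)
            evidence.append(
                _log_evidence(n, yty, PhiTy_a, mu, alpha, beta, logdetH))
            if it == max_iter:
                break
            n_iter = it + 1

            gamma = 1.0 - alpha * Sigma.diagonal()
            mu2 = mu * mu
            new_alpha = np.where(mu2 > 0, gamma / mu2, np.inf)
            new_alpha = np.maximum(new_alpha, 1e-12)

            resid = yc - Phi_a @ mu
            denom = n - gamma.sum()
            degenerate = denom <= 0
            denom = max(denom, 1e-10)
            # relative floor on the residual keeps beta finite in the
            # noiseless/interpolation limit (noise variance is never
            # estimated below 1e-10 of the target variance)
            beta = denom / max(resid @ resid, 1e-10 * n * var_y)

            keep = new_alpha <= prune_alpha
            if not keep.any():
                return _offset_only(y_mean, n, n_iter, True)
            delta = np.abs(np.log(new_alpha[keep]) - np.log(alpha[keep])).max()
            alpha = new_alpha[keep]
            active = active[keep]
            if not keep.all():
                PhiTPhi_a = PhiTPhi_a[np.ix_(keep, keep)]
                Phi_a = Phi_a[:, keep]
                PhiTy_a = PhiTy_a[keep]
            elif delta < tol and not degenerate:
                converged = True
                # one final posterior evaluation with converged parameters
                Sigma, mu, logdetH = _posterior(PhiTPhi_a, PhiTy_a, alpha, beta)
                evidence.append(
                    _log_evidence(n, yty, PhiTy_a, mu, alpha, beta, logdetH))
                break
    finally:
        np.seterr(**err_state)

    return RVRModel(
        alpha=alpha, beta=float(beta), mu=mu, Sigma_diag=np.diag(Sigma).copy(),
        active_idx=active.astype(np.int64), y_offset=float(y_mean),
        n_train=n, n_iter=n_iter, converged=converged,
        evidence=np.asarray(evidence),
    )


def predict_rvr(model: RVRModel, K_cross) -> np.ndarray:
    """Predict targets: ``y_offset + [1 | K_cross][:, active] mu``."""
    Kx = _as_kernel_array(K_cross)
    Kx = np.atleast_2d(Kx)
    if Kx.shape[1] != model.n_train:
        raise ValueError(
            f"cross kernel has {Kx.shape[1]} columns, expected {model.n_train}"
        )
    if model.all_pruned:
        return np.full(Kx.shape[0], model.y_offset)
    Phi = np.concatenate([np.ones((Kx.shape[0], 1)), Kx], axis=1)
    return model.y_offset + Phi[:, model.active_idx] @ model.mu


def primal_weights(model: RVRModel, X_train_centered: np.ndarray) -> np.ndarray:
    """Voxel-space weights of a linear-kernel fit.

    ``w = sum_i mu_i x_i`` over retained relevance vectors, with
    ``X_train_centered`` the centered (and residualized, if applicable)
    training matrix the kernel was built from.  Satisfies
    ``yhat - y_offset = xc_test @ w + mu_bias`` exactly.
    """
    X_train_centered = np.asarray(X_train_centered, dtype=np.float64)
    if X_train_centered.shape[0] != model.n_train:
        raise ValueError("X_train_centered rows do not match the fit")
    w = np.zeros(X_train_centered.shape[1])
    samp = model.relevance_idx
    if samp.size:
        mu_samp = model.mu[model.active_idx >= 1]
        w = mu_samp @ X_train_centered[samp]
    return w


@dataclasses.dataclass
class KRRModel:
    dual_coef: np.ndarray
    y_offset: float
    ridge_lambda: float
    n_train: int


def fit_krr(K_train, y: np.ndarray, ridge_lambda: float) -> KRRModel:
    """Kernel ridge regression baseline: ``(K + lambda I)^-1 yc``."""
    if ridge_lambda <= 0:
        raise ValueError("ridge_lambda must be positive")
    K = _as_kernel_array(K_train)
    y = np.asarray(y, dtype=np.float64)
    n = K.shape[0]
    if y.shape != (n,):
        raise ValueError("y length does not match kernel size")
    y_mean = y.mean()
    dual = np.linalg.solve(K + ridge_lambda * np.eye(n), y - y_mean)
    return KRRModel(dual_coef=dual, y_offset=float(y_mean),
                    ridge_lambda=float(ridge_lambda), n_train=n)


def predict_krr(model: KRRModel, K_cross) -> np.ndarray:
    Kx = np.atleast_2d(_as_kernel_array(K_cross))
    if Kx.shape[1] != model.n_train:
        raise ValueError("cross kernel columns do not match training size")
    return model.y_offset + Kx @ model.dual_coef
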