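"""Binary-confound control via the residual-forming-matrix framework.

Removing a confound design ``C`` from data ``X`` multiplies by the
projector ``R = I - C (C^T C)^+ C^T`` (equivalent to dummy-variable
regression / ANCOVA).  To avoid train/test leakage the per-voxel confound
coefficients are estimated on the training fold only and applied frozen to
held-out subjects; whole-sample residualization is available for
replication of analyses that residualize before cross-validation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats


def _design(c: np.ndarray, with_intercept: bool) -> np.ndarray:
    c = np.asarray(c, dtype=np.float64).reshape(-1, 1)
    if with_intercept:
        return np.concatenate([np.ones_like(c), c], axis=1)
    return c


def residual_forming_matrix(C: np.ndarray) -> np.ndarray:
    """R = I - C (C^T C)^+ C^T (pseudo-inverse handles rank deficiency)."""
    C = np.atleast_2d(np.asarray(C, dtype=np.float64))
    if C.ndim != 2:
        raise ValueError("C must be an n x q matrix")
    if C.shape[0] <= C.shape[1]:
        raise ValueError("need more observations than confound columns")
    n = C.shape[0]
    return np.eye(n) - C @ np.linalg.pinv(C.T @ C) @ C.T


@dataclasses.dataclass
class ConfoundModel:
    """Per-voxel confound regression estimated on a training set."""

    coef: np.ndarray  # (q [+1 intercept]) x V
    with_intercept: bool

    @property
    def n_features(self) -> int:
        return self.coef.shape[1]


def fit_confound(
    X_train: np.ndarray, c_train: np.ndarray, with_intercept: bool = True
) -> ConfoundModel:
    """Estimate confound coefficients ``(C^T C)^+ C^T X`` on training data."""
    X_train = np.asarray(X_train, dtype=np.float64)
    c_train = np.asarray(c_train)
    if not np.all(np.isin(c_train, [0, 1])):
        raise ValueError("confound must be binary 0/1")
    if with_intercept and len(np.unique(c_train)) < 2:
        raise ValueError(
            "confound has a single class in this training set; "
            "coefficients are unidentifiable"
        )
    C = _design(c_train, with_intercept)
    coef = np.linalg.pinv(C.T @ C) @ C.T @ X_train
    return ConfoundModel(coef=coef, with_intercept=with_intercept)


def apply_confound(model: ConfoundModel, X: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Residualize ``X`` using coefficients frozen from training."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != model.n_features:
        raise ValueError("feature count does not match the fitted model")
    C = _design(c, model.with_intercept)
    if C.shape[1] != model.coef.shape[0]:
        raise ValueError("confound design does not match the fitted model")
    return X - C @ model.coef


def residualize_whole_sample(dataset, with_intercept: bool = True):
    """Residualize every subject's features against the confound at once.

    This is the replication-mode alternative to per-training-fold
    residualization: coefficients are estimated on the full sample before
    any cross-validation, as some published analyses do.  Note that this
    lets test subjects influence the confound fit; the per-fold route
    (``control_confound=True`` in the decoding loop) avoids that.
    """
    import dataclasses

    model = fit_confound(dataset.X, dataset.confound, with_intercept)
    X_res = apply_confound(model, dataset.X, dataset.confound)
    return dataclasses.replace(dataset, X=X_res)


def confound_score_ttest(scores: np.ndarray, c: np.ndarray):
    """Two-sample equal-variance t-test of scores between confound classes.

    Returns ``(t, p, (mean0, mean1), (sd0, sd1))`` with SDs computed with
    ddof=1.  Groups of identical constant value give t=0, p=1; zero pooled
    variance with differing means is degenerate and raises.
    """
    scores = np.asarray(scores, dtype=np.float64)
    c = np.asarray(c)
    g0 = scores[c == 0]
    g1 = scores[c == 1]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("each confound class needs at least 2 subjects")
    means = (g0.mean(), g1.mean())
    sds = (g0.std(ddof=1), g1.std(ddof=1))
    if sds[0] == 0 and sds[1] == 0:
        if means[0] == means[1]:
            return 0.0, 1.0, means, sds
        raise ValueError("zero within-group variance with differing means; "
                         "t statistic is degenerate")
    t, p = stats.ttest_ind(g0, g1, equal_var=True)
    return float(t), float(p), means, sds
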