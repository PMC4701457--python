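"""Cross-validated decoding: fold schemes, the train/test loop and metrics.

Per fold, features are centered by the training mean, optionally
residualized against the binary confound (coefficients estimated on the
training fold and applied frozen to the test fold), a linear kernel is
built, relevance vector regression is fitted, and held-out subjects are
predicted.  Pooled out-of-fold predictions yield Pearson's r and the mean
squared error; the final weight map is the fold-average of the primal
weight vectors divided by its Euclidean norm.

A model is declared significant only when the permutation p-values of both
r and MSE fall below the significance threshold.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import special, stats

from . import confounds, rvm
from .localization import average_weight_map
from .volumes import SubjectDataset


@dataclasses.dataclass
class FoldScheme:
    """A disjoint test-set partition of subjects 0..N-1."""

    kind: str  # "loo" | "kfold"
    folds: list[np.ndarray]
    k: int
    balance_pvalues: np.ndarray | None = None
    attempts_used: int = 0
    seed: int | None = None

    @property
    def n(self) -> int:
        return sum(len(f) for f in self.folds)

    def validate(self, n: int) -> None:
        seen = np.concatenate(self.folds)
        if len(seen) != n or len(np.unique(seen)) != n:
            raise ValueError("folds must partition 0..N-1 disjointly")


def make_loo(n: int) -> FoldScheme:
    """Leave-one-out: n singleton folds in index order."""
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 subjects")
    return FoldScheme(
        kind="loo", folds=[np.array([i]) for i in range(n)], k=n
    )


def _fold_sizes(n: int, k: int) -> list[int]:
    base, rem = divmod(n, k)
    return [base + 1] * rem + [base] * (k - rem)


def _balance_pvalue(fold_scores: np.ndarray, rest_scores: np.ndarray) -> float:
    # equal-variance two-sample t-test, two-sided; direct formula because
    # this runs once per fold per candidate partition per permutation
    n1, n2 = len(fold_scores), len(rest_scores)
    dof = n1 + n2 - 2
    sp2 = (fold_scores.var(ddof=1) * (n1 - 1)
           + rest_scores.var(ddof=1) * (n2 - 1)) / dof
    if sp2 <= 0:  # zero variance everywhere: trivially balanced
        return 1.0
    t = (fold_scores.mean() - rest_scores.mean()) / np.sqrt(
        sp2 * (1.0 / n1 + 1.0 / n2))
    return float(2.0 * special.stdtr(dof, -abs(t)))


def make_kfold(
    scores: np.ndarray,
    k: int,
    seed: int = 0,
    alpha_balance: float = 0.05,
    max_attempts: int = 100,
) -> FoldScheme:
    """Random k-fold partition whose folds are balanced on the target.

    Fold sizes differ by at most one (larger folds first).  Each candidate
    partition is accepted only if, for every fold, a two-sample t-test of
    the fold's scores against all remaining scores has p > alpha_balance;
    otherwise the partition is reshuffled with an incremented seed.
    """
    scores = np.asarray(scores, dtype=np.float64)
    n = len(scores)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < 2 * k:
        raise ValueError("need at least 2k subjects for k folds")
    sizes = _fold_sizes(n, k)
    worst = (1.0, -1)
    for attempt in range(max_attempts):
        rng = np.random.default_rng(seed + attempt)
        perm = rng.permutation(n)
        folds, start = [], 0
        for s in sizes:
            folds.append(np.sort(perm[start:start + s]))
            start += s
        pvals = []
        for f in folds:
            rest = np.setdiff1d(np.arange(n), f)
            pvals.append(_balance_pvalue(scores[f], scores[rest]))
        pvals = np.asarray(pvals)
        if pvals.min() < worst[0]:
            worst = (float(pvals.min()), attempt)
        if np.all(pvals > alpha_balance):
            return FoldScheme(
                kind="kfold", folds=folds, k=k, balance_pvalues=pvals,
                attempts_used=attempt + 1, seed=seed,
            )
    raise RuntimeError(
        f"no balanced {k}-fold partition found in {max_attempts} attempts "
        f"(worst balance p-value {worst[0]:.4g} at attempt {worst[1]})"
    )


def pearson_r(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Product-moment correlation between true and decoded scores."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    if len(y_true) < 3:
        raise ValueError("need at least 3 pairs")
    if y_true.std() == 0 or y_pred.std() == 0:
        raise ValueError(
            "correlation undefined: zero variance (predictions may have "
            "collapsed to a constant)"
        )
    return float(np.corrcoef(y_true, y_pred)[0, 1])


def mse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean of squared differences between decoded and true scores."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    return float(np.mean((y_true - y_pred) ** 2))


def decide_significance(p_r: float, p_mse: float, alpha: float = 0.05) -> bool:
    """Significant only if BOTH metric p-values are below alpha."""
    for p in (p_r, p_mse):
        if not 0.0 <= p <= 1.0:
            raise ValueError("p-values must lie in [0, 1]")
    return (p_r < alpha) and (p_mse < alpha)


@dataclasses.dataclass
class PreparedFold:
    train_idx: np.ndarray
    test_idx: np.ndarray
    K_train: np.ndarray
    K_cross: np.ndarray
    Xc_train: np.ndarray | None  # centered (+residualized) train features


def prepare_folds(
    X: np.ndarray,
    confound: np.ndarray,
    scheme: FoldScheme,
    control_confound: bool,
    keep_train_features: bool = True,
) -> list[PreparedFold]:
    """Precompute per-fold kernels (label-independent, so reusable across
    label permutations)."""
    n = X.shape[0]
    scheme.validate(n)
    all_idx = np.arange(n)
    out = []
    for fi, test_idx in enumerate(scheme.folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        if len(train_idx) < 3:
            raise ValueError(f"fold {fi}: fewer than 3 training subjects")
        means = X[train_idx].mean(axis=0)
        Xtr = X[train_idx] - means
        Xte = X[test_idx] - means
        if control_confound:
            c_tr = confound[train_idx]
            if len(np.unique(c_tr)) < 2:
                raise ValueError(
                    f"fold {fi}: confound has a single class in the "
                    "training set; cannot residualize"
                )
            cmodel = confounds.fit_confound(Xtr, c_tr, with_intercept=True)
            Xtr = confounds.apply_confound(cmodel, Xtr, c_tr)
            Xte = confounds.apply_confound(cmodel, Xte, confound[test_idx])
        out.append(PreparedFold(
            train_idx=train_idx, test_idx=test_idx,
            K_train=Xtr @ Xtr.T, K_cross=Xte @ Xtr.T,
            Xc_train=Xtr if keep_train_features else None,
        ))
    return out


@dataclasses.dataclass
class DecodingResult:
    """Pooled out-of-fold decoding of one score from one fold scheme."""

    y_true: np.ndarray
    y_pred: np.ndarray
    r: float
    mse: float
    per_fold_weights: list[np.ndarray]
    weight_map: np.ndarray | None
    scheme: FoldScheme
    settings: dict

    @property
    def per_fold_r(self) -> list[float]:
        """Within-fold correlations (undefined for singleton folds -> nan)."""
        out = []
        for f in self.scheme.folds:
            if len(f) >= 3 and self.y_true[f].std() > 0 and self.y_pred[f].std() > 0:
                out.append(float(np.corrcoef(self.y_true[f], self.y_pred[f])[0, 1]))
            else:
                out.append(float("nan"))
        return out


def decode_prepared(
    folds: Sequence[PreparedFold],
    scores: np.ndarray,
    rvr_options: dict | None = None,
    compute_weights: bool = True,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Fit/predict over prepared folds; returns pooled predictions and the
    per-fold primal weight vectors (empty when ``compute_weights`` is off)."""
    rvr_options = rvr_options or {}
    n = sum(len(f.test_idx) for f in folds)
    y_pred = np.empty(n)
    per_fold_weights = []
    for f in folds:
        model = rvm.fit_rvr(f.K_train, scores[f.train_idx], **rvr_options)
        y_pred[f.test_idx] = rvm.predict_rvr(model, f.K_cross)
        if compute_weights:
            if f.Xc_train is None:
                raise ValueError("fold was prepared without training features")
            per_fold_weights.append(rvm.primal_weights(model, f.Xc_train))
    return y_pred, per_fold_weights


def run_decoding(
    dataset: SubjectDataset,
    scheme: FoldScheme,
    control_confound: bool = False,
    rvr_options: dict | None = None,
    compute_weights: bool = True,
) -> DecodingResult:
    """Run the full cross-validated decoding loop on a dataset."""
    folds = prepare_folds(
        dataset.X, dataset.confound, scheme, control_confound,
        keep_train_features=compute_weights,
    )
    y_pred, per_fold_weights = decode_prepared(
        folds, dataset.scores, rvr_options, compute_weights
    )
    weight_map = average_weight_map(per_fold_weights) if compute_weights else None
    return DecodingResult(
        y_true=dataset.scores.copy(),
        y_pred=y_pred,
        r=pearson_r(dataset.scores, y_pred),
        mse=mse(dataset.scores, y_pred),
        per_fold_weights=per_fold_weights,
        weight_map=weight_map,
        scheme=scheme,
        settings={
            "control_confound": control_confound,
            "rvr_options": rvr_options or {},
            "score_name": dataset.score_name,
            "scheme_kind": scheme.kind,
            "k": scheme.k,
        },
    )
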