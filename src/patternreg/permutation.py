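"""Label-permutation significance testing of cross-validated decoding.

The entire decoding procedure (fold construction where it depends on the
labels, centering, optional confound residualization, model fitting,
prediction) is re-run with scores shuffled across participants.  The null
count for r is the number of permutations with ``|r_perm| >= |r_obs|``; for
MSE, ``mse_perm <= mse_obs``.  The default p-value is the plain
``count / n_perm`` ratio; a plus-one correction ``(count+1)/(n_perm+1)`` is
available because the plain rule can return exactly zero.

The confound vector stays attached to its participant by default: the test
targets the score-brain association under the observed confound structure.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from . import crossval
from .crossval import FoldScheme, decide_significance
from .volumes import SubjectDataset


@dataclasses.dataclass
class PermutationResult:
    n_perm: int
    observed_r: float
    observed_mse: float
    null_r: np.ndarray
    null_mse: np.ndarray
    count_r: int
    count_mse: int
    p_r: float
    p_mse: float
    seed: int
    plus_one_correction: bool
    n_failed: int = 0


def _resolve_scheme(scheme_spec, scores, seed) -> FoldScheme:
    if isinstance(scheme_spec, FoldScheme):
        return scheme_spec
    spec = dict(scheme_spec)
    kind = spec.pop("kind")
    if kind == "loo":
        return crossval.make_loo(len(scores))
    if kind == "kfold":
        spec.setdefault("seed", seed)
        return crossval.make_kfold(scores, **spec)
    raise ValueError(f"unknown scheme kind {kind!r}")


def permutation_test(
    dataset: SubjectDataset,
    scheme_spec,
    control_confound: bool = False,
    n_perm: int = 1000,
    seed: int = 0,
    rvr_options: dict | None = None,
    plus_one_correction: bool = False,
    permute_confound: bool = False,
) -> PermutationResult:
    """Permutation-test the pooled r and MSE of the full decoding loop.

    ``scheme_spec`` is either a concrete :class:`FoldScheme` (reused for
    every permutation) or a dict like ``{"kind": "loo"}`` /
    ``{"kind": "kfold", "k": 4}``.  For k-fold specs the balanced partition
    is rebuilt against each permuted score vector, because the balance
    t-test references the labels.  Permutations whose decoding fails (e.g.
    zero-variance predictions) are counted as beating the observed
    statistic, a conservative convention.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    scores = dataset.scores
    n = len(scores)

    scheme = _resolve_scheme(scheme_spec, scores, seed)
    label_free_partition = (
        isinstance(scheme_spec, FoldScheme)
        or dict(scheme_spec).get("kind") == "loo"
    )

    observed = crossval.run_decoding(
        dataset, scheme, control_confound, rvr_options, compute_weights=False
    )
    r_obs, mse_obs = observed.r, observed.mse

    # kernels depend only on features/confound, so for a label-independent
    # partition they are computed once and reused across permutations
    folds = None
    if label_free_partition:
        folds = crossval.prepare_folds(
            dataset.X, dataset.confound, scheme, control_confound,
            keep_train_features=False,
        )

    rng = np.random.default_rng(seed)
    null_r = np.empty(n_perm)
    null_mse = np.empty(n_perm)
    n_failed = 0
    for i in range(n_perm):
        perm = rng.permutation(n)
        y_perm = scores[perm]
        conf = dataset.confound[perm] if permute_confound else dataset.confound
        try:
            if label_free_partition and not permute_confound:
                y_pred, _ = crossval.decode_prepared(
                    folds, y_perm, rvr_options, compute_weights=False
                )
            else:
                if label_free_partition:
                    scheme_i = scheme
                else:
                    scheme_i = _resolve_scheme(scheme_spec, y_perm, seed + 1 + i)
                ds_i = dataclasses.replace(dataset, scores=y_perm, confound=conf)
                res = crossval.run_decoding(
                    ds_i, scheme_i, control_confound, rvr_options,
                    compute_weights=False,
                )
                y_pred = res.y_pred
            null_r[i] = crossval.pearson_r(y_perm, y_pred)
            null_mse[i] = crossval.mse(y_perm, y_pred)
        except (ValueError, RuntimeError) as err:
            n_failed += 1
            warnings.warn(
                f"permutation {i} failed ({err}); counted against the "
                "observed statistic"
            )
            null_r[i] = np.inf  # |inf| >= |r_obs| and -inf <= mse_obs
            null_mse[i] = -np.inf

    count_r = int(np.sum(np.abs(null_r) >= abs(r_obs)))
    count_mse = int(np.sum(null_mse <= mse_obs))
    if plus_one_correction:
        p_r = (count_r + 1) / (n_perm + 1)
        p_mse = (count_mse + 1) / (n_perm + 1)
    else:
        p_r = count_r / n_perm
        p_mse = count_mse / n_perm
    return PermutationResult(
        n_perm=n_perm, observed_r=r_obs, observed_mse=mse_obs,
        null_r=null_r, null_mse=null_mse,
        count_r=count_r, count_mse=count_mse,
        p_r=float(p_r), p_mse=float(p_mse), seed=seed,
        plus_one_correction=plus_one_correction, n_failed=n_failed,
    )


def summarize(result: PermutationResult, alpha: float = 0.05) -> dict:
    """Deterministic report record: observed metrics, p-values, null
    quantiles and the joint significance decision."""
    qs = [0.025, 0.25, 0.5, 0.75, 0.975]
    finite_r = result.null_r[np.isfinite(result.null_r)]
    finite_mse = result.null_mse[np.isfinite(result.null_mse)]
    return {
        "n_perm": result.n_perm,
        "observed_r": result.observed_r,
        "observed_mse": result.observed_mse,
        "p_r": result.p_r,
        "p_mse": result.p_mse,
        "count_r": result.count_r,
        "count_mse": result.count_mse,
        "n_failed": result.n_failed,
        "plus_one_correction": result.plus_one_correction,
        "alpha": alpha,
        "significant": decide_significance(result.p_r, result.p_mse, alpha),
        "null_r_quantiles": {
            str(q): float(np.quantile(finite_r, q)) if len(finite_r) else None
            for q in qs
        },
        "null_mse_quantiles": {
            str(q): float(np.quantile(finite_mse, q)) if len(finite_mse) else None
            for q in qs
        },
    }
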