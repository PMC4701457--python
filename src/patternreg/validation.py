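"""End-to-end validation experiments on synthetic studies.

These functions realize the package's standing validation suite: each one
builds a synthetic study under frozen conditions, runs the full pipeline
and returns the measured quantities.  They back both the acceptance tests
and the reproduction script, so the numbers reported in either place come
from the same code path.

Problem sizes are chosen to finish on a single CPU in minutes; the
rationale for each fixture is laid out in the methods note.
"""

from __future__ import annotations

import dataclasses
import time

import numpy as np
from scipy import stats

from . import crossval, localization, permutation, rvm
from .synthetic import GeneratorConfig, generate_dataset


#: recovery fixture: n=200 subjects, V=512 voxels, three broad planted
#: blobs, smooth noise at half the blob amplitude
RECOVERY_CONFIG = dict(
    grid_shape=(16, 16, 2), mask_kind="full", n_subjects=200,
    n_blobs=3, blob_sigma_mm=10.0, noise_sd=0.5,
)

#: localization fixture: a single compact blob planted wholly inside one
#: of four atlas blocks
LOCALIZATION_CONFIG = dict(
    grid_shape=(16, 16, 2), mask_kind="full", n_subjects=200,
    n_blobs=1, blob_sigma_mm=6.0, noise_sd=0.5,
    blob_centers=((4, 4, 1),), blob_signs=(1.0,), atlas_blocks=(2, 2, 1),
)

#: null-calibration fixture: no planted signal at all
NULL_CONFIG = dict(
    grid_shape=(5, 5, 2), mask_kind="full", n_subjects=40,
    n_blobs=0, noise_sd=1.0,
)


def fold_sizes(n: int, k: int, seed: int = 0) -> list[int]:
    """Fold sizes of a balanced k-fold partition of ``n`` subjects."""
    rng = np.random.default_rng(seed)
    scores = np.clip(15.5 + 6.3 * rng.standard_normal(n), 0, 30)
    scheme = crossval.make_kfold(scores, k, seed=seed)
    return sorted((len(f) for f in scheme.folds), reverse=True)


def rvr_closed_form_discrepancy(seed: int = 0) -> float:
    """Largest |mu - closed-form solve| over small fixed-hyperparameter
    toys (alpha=1, beta=100, no re-estimation)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for n, V in [(6, 3), (12, 8), (20, 10)]:
        X = rng.standard_normal((n, V))
        y = 5.0 * rng.standard_normal(n) + 15.0
        km = rvm.linear_kernel(X)
        model = rvm.fit_rvr(km, y, max_iter=0, alpha_init=1.0,
                            beta_init=100.0)
        Phi = np.concatenate([np.ones((n, 1)), km.K], axis=1)
        mu_ref = 100.0 * np.linalg.solve(
            np.eye(n + 1) + 100.0 * (Phi.T @ Phi), Phi.T @ (y - y.mean()))
        worst = max(worst, float(np.max(np.abs(model.mu - mu_ref))))
    return worst


def _planted_region(truth, ds, atlas) -> str:
    """Region holding the largest mean absolute planted weight."""
    w_true = ds.mask.extract(truth.weight_volume)
    nw = localization.region_normalized_weights(w_true, ds.mask, atlas)
    return nw.loc[nw["mean_abs_weight"].idxmax(), "region_name"]


def _block_atlas_for(ds, cfg: GeneratorConfig) -> localization.AtlasLabelMap:
    from .synthetic import make_block_atlas, make_mask
    labels = make_block_atlas(make_mask(cfg), cfg.atlas_blocks)
    present = sorted(int(v) for v in np.unique(labels) if v != 0)
    return localization.AtlasLabelMap(
        label_volume=labels,
        labels={v: f"region_{v:02d}" for v in present})


def recovery_experiment(seed: int = 0) -> dict:
    """Leave-one-out decoding on the recovery fixture: pooled r, MSE and
    the correlation of the final weight map with the planted pattern."""
    cfg = GeneratorConfig(seed=seed, **RECOVERY_CONFIG)
    ds, truth = generate_dataset(cfg)
    res = crossval.run_decoding(ds, crossval.make_loo(ds.n_subjects))
    w_true = ds.mask.extract(truth.weight_volume)
    return {
        "r": res.r,
        "mse": res.mse,
        "weight_corr": float(np.corrcoef(res.weight_map, w_true)[0, 1]),
        "n": ds.n_subjects,
        "V": ds.n_voxels,
    }


def localization_experiment(seed: int = 0) -> dict:
    """Rank of the planted region in the atlas summary of the decoded
    weight map (single compact blob wholly inside one region)."""
    cfg = GeneratorConfig(seed=seed, **LOCALIZATION_CONFIG)
    ds, truth = generate_dataset(cfg)
    atlas = _block_atlas_for(ds, cfg)
    res = crossval.run_decoding(ds, crossval.make_loo(ds.n_subjects))
    nw = localization.region_normalized_weights(res.weight_map, ds.mask,
                                                atlas)
    ranking = localization.rank_regions(nw)
    planted = _planted_region(truth, ds, atlas)
    rank = int(ranking.loc[ranking["region_name"] == planted, "rank"].iloc[0])
    return {
        "planted_region": planted,
        "top_region": str(ranking.iloc[0]["region_name"]),
        "planted_rank": rank,
        "top_pct": float(ranking.iloc[0]["pct_total_nw"]),
        "n": ds.n_subjects,
    }


def null_calibration(
    n_datasets: int = 200, n_perm: int = 99, k: int = 5, seed: int = 0
) -> dict:
    """Permutation p-value calibration under the global null.

    Generates ``n_datasets`` studies with no planted signal (scores and
    features independent), permutation-tests each with balanced k-fold
    decoding, and summarizes the p_r distribution: the empirical rejection
    rate at 0.05 and the Kolmogorov-Smirnov distance from uniformity.
    """
    base = int(np.random.SeedSequence(seed).generate_state(1)[0] % 2**31)
    pvals = np.empty(n_datasets)
    for i in range(n_datasets):
        cfg = GeneratorConfig(seed=(base + i) % 2**31, **NULL_CONFIG)
        ds, _ = generate_dataset(cfg)
        res = permutation.permutation_test(
            ds, {"kind": "kfold", "k": k}, n_perm=n_perm,
            seed=(base + 7919 * i) % 2**31)
        pvals[i] = res.p_r
    ks = stats.kstest(pvals, "uniform").statistic
    return {
        "rejection_rate": float(np.mean(pvals < 0.05)),
        "ks_stat": float(ks),
        "ks_crit_alpha_01": 1.628 / np.sqrt(n_datasets),
        "n_datasets": n_datasets,
        "n_perm": n_perm,
        "pvals": pvals,
    }


def confound_algebra(seed: int = 0) -> dict:
    """Exactness of the residual-forming-matrix algebra on random data."""
    from . import confounds
    rng = np.random.default_rng(seed)
    n, V = 24, 30
    X = rng.standard_normal((n, V))
    c = np.zeros(n, dtype=int)
    c[rng.permutation(n)[: n // 2]] = 1
    C = np.column_stack([np.ones(n), c])
    R = confounds.residual_forming_matrix(C)
    model = confounds.fit_confound(X, c)
    resid = confounds.apply_confound(model, X, c)
    twice = confounds.apply_confound(confounds.fit_confound(resid, c),
                                     resid, c)
    cc = c - c.mean()
    corr = 0.0
    for j in range(V):
        rj = resid[:, j] - resid[:, j].mean()
        denom = np.linalg.norm(rj) * np.linalg.norm(cc)
        corr = max(corr, abs(rj @ cc) / denom)
    return {
        "max_RC": float(np.max(np.abs(R @ C))),
        "max_RR_minus_R": float(np.max(np.abs(R @ R - R))),
        "max_idempotence_gap": float(np.max(np.abs(twice - resid))),
        "max_feature_confound_corr": float(corr),
    }


def scheme_equivalence_gap(seed: int = 0) -> float:
    """Max |pred difference| between LOO and an N-fold singleton scheme."""
    cfg = GeneratorConfig(grid_shape=(6, 6, 3), mask_kind="full",
                          n_subjects=14, n_blobs=1, noise_sd=0.4, seed=seed)
    ds, _ = generate_dataset(cfg)
    loo = crossval.run_decoding(ds, crossval.make_loo(14))
    nfold = crossval.FoldScheme(
        kind="kfold", folds=[np.array([i]) for i in range(14)], k=14)
    alt = crossval.run_decoding(ds, nfold)
    return float(np.max(np.abs(loo.y_pred - alt.y_pred)))


def localization_conservation(seed: int = 0) -> dict:
    """Conservation and scale-invariance of the region percentages, and
    the unit norm of the final weight map."""
    cfg = GeneratorConfig(grid_shape=(8, 8, 4), mask_kind="full",
                          n_subjects=30, n_blobs=2, noise_sd=0.5, seed=seed)
    ds, _ = generate_dataset(cfg)
    atlas = _block_atlas_for(ds, cfg)
    res = crossval.run_decoding(ds, crossval.make_loo(30))
    nw = localization.region_normalized_weights(res.weight_map, ds.mask,
                                                atlas)
    ranking = localization.rank_regions(nw)
    scaled = nw.copy()
    scaled["mean_abs_weight"] *= 123.456
    ranking_scaled = localization.rank_regions(scaled)
    return {
        "pct_sum": float(ranking["pct_total_nw"].sum()),
        "weight_map_norm": float(np.linalg.norm(res.weight_map)),
        "max_scale_invariance_gap": float(np.max(np.abs(
            ranking["pct_total_nw"].to_numpy()
            - ranking_scaled["pct_total_nw"].to_numpy()))),
    }


def study_scale_smoke(seed: int = 0, n_perm: int = 99) -> dict:
    """Full pipeline at study scale: n=57 subjects, ellipsoid mask with
    V~5000 voxels, LOO decoding, permutation test and localization."""
    t0 = time.time()
    cfg = GeneratorConfig(seed=seed)  # study-scale defaults
    ds, truth = generate_dataset(cfg)
    res = crossval.run_decoding(ds, crossval.make_loo(ds.n_subjects))
    perm = permutation.permutation_test(
        ds, crossval.make_loo(ds.n_subjects), n_perm=n_perm, seed=seed)
    atlas = _block_atlas_for(ds, cfg)
    nw = localization.region_normalized_weights(res.weight_map, ds.mask,
                                                atlas)
    ranking = localization.rank_regions(nw)
    return {
        "n": ds.n_subjects,
        "V": ds.n_voxels,
        "r": res.r,
        "mse": res.mse,
        "p_r": perm.p_r,
        "p_mse": perm.p_mse,
        "significant": crossval.decide_significance(perm.p_r, perm.p_mse),
        "n_regions": len(ranking),
        "elapsed_s": time.time() - t0,
    }
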