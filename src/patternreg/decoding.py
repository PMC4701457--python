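"""Model/Results interface for cross-validated pattern regression.

:class:`PatternRegression` is constructed from a subject-by-voxel dataset
(or directly from NIfTI volumes plus a subjects table); ``fit()`` runs the
cross-validated relevance-vector-regression decoding loop and returns a
:class:`DecodingResults` object carrying the pooled out-of-fold
predictions, agreement metrics, per-fold weight vectors and the final
normalized weight map, with ``summary()``, ``permutation_test()``,
``localize()`` and plotting attached.

Example
-------
>>> from patternreg import synthetic, decoding
>>> cfg = synthetic.GeneratorConfig(grid_shape=(8, 8, 4), mask_kind="full",
...                                 n_subjects=30, n_blobs=1, noise_sd=0.2,
...                                 seed=7)
>>> paths, truth = synthetic.generate_study(cfg, "study/")   # doctest: +SKIP
>>> model = decoding.PatternRegression.from_study_dir("study/",
...                                                   "score_screen")  # doctest: +SKIP
>>> res = model.fit(scheme="loo")                            # doctest: +SKIP
>>> print(res.summary())                                     # doctest: +SKIP
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import crossval, localization, permutation, volumes
from .volumes import MaskVolume, SubjectDataset


class PatternRegression:
    """Cross-validated decoding of a continuous score from voxel patterns.

    Parameters
    ----------
    dataset : SubjectDataset
        N x V masked feature matrix with scores and binary confound.
    control_confound : bool
        Residualize features against the confound within each training
        fold (frozen coefficients applied to the test fold).
    rvr_options : dict, optional
        Passed to :func:`patternreg.rvm.fit_rvr` (``max_iter``, ``tol``,
        ``prune_alpha``, ...).
    """

    def __init__(self, dataset: SubjectDataset, control_confound: bool = False,
                 rvr_options: dict | None = None):
        if dataset.n_subjects < 3:
            raise ValueError("need at least 3 subjects to fit")
        self.dataset = dataset
        self.control_confound = control_confound
        self.rvr_options = rvr_options or {}

    # ---------------------------------------------------------------- constructors
    @classmethod
    def from_volumes(
        cls,
        volume_paths,
        subjects_table,
        score_column: str,
        base_mask: np.ndarray | None = None,
        mask: MaskVolume | None = None,
        **kwargs,
    ) -> "PatternRegression":
        """Build the dataset from NIfTI coefficient volumes and a table.

        When no mask is given, the analysis mask is built by the
        NaN-intersection rule (keep voxels finite in every subject,
        optionally within ``base_mask``).
        """
        if not isinstance(subjects_table, pd.DataFrame):
            subjects_table = pd.read_csv(subjects_table)
        if mask is None:
            vols, affines = [], []
            for sid in subjects_table["subject_id"].astype(str):
                data, aff = volumes.load_volume(volume_paths[sid])
                vols.append(data)
                affines.append(aff)
            affine = volumes._check_affines(affines)
            mask = volumes.build_common_mask(vols, base_mask=base_mask,
                                             affine=affine)
        ds = volumes.assemble_dataset(volume_paths, subjects_table,
                                      score_column, mask)
        return cls(ds, **kwargs)

    @classmethod
    def from_study_dir(cls, study_dir, score_column: str,
                       use_mask_file: bool = True, **kwargs) -> "PatternRegression":
        """Convenience constructor for a generated study directory."""
        study_dir = Path(study_dir)
        paths = volumes.find_subject_volumes(study_dir)
        base = None
        if use_mask_file and (study_dir / "mask.nii").exists():
            base = MaskVolume.load(study_dir / "mask.nii").include
        return cls.from_volumes(paths, study_dir / "subjects.csv",
                                score_column, base_mask=base, **kwargs)

    # ---------------------------------------------------------------- fitting
    def make_scheme(self, scheme: str = "loo", k: int = 4, seed: int = 0,
                    alpha_balance: float = 0.05,
                    max_attempts: int = 100) -> crossval.FoldScheme:
        if isinstance(scheme, crossval.FoldScheme):
            return scheme
        if scheme == "loo":
            return crossval.make_loo(self.dataset.n_subjects)
        if scheme == "kfold":
            return crossval.make_kfold(self.dataset.scores, k, seed=seed,
                                       alpha_balance=alpha_balance,
                                       max_attempts=max_attempts)
        raise ValueError(f"unknown scheme {scheme!r}")

    def fit(self, scheme: str = "loo", k: int = 4, seed: int = 0,
            compute_weights: bool = True) -> "DecodingResults":
        fold_scheme = self.make_scheme(scheme, k=k, seed=seed)
        raw = crossval.run_decoding(
            self.dataset, fold_scheme, self.control_confound,
            self.rvr_options, compute_weights=compute_weights,
        )
        return DecodingResults(self, raw)


class DecodingResults:
    """Results of one cross-validated decoding run."""

    def __init__(self, model: PatternRegression, raw: crossval.DecodingResult):
        self.model = model
        self._raw = raw
        self.y_true = raw.y_true
        self.y_pred = raw.y_pred
        self.r = raw.r
        self.mse = raw.mse
        self.per_fold_weights = raw.per_fold_weights
        self.weight_map = raw.weight_map
        self.scheme = raw.scheme
        self.settings = raw.settings
        self.perm_result: permutation.PermutationResult | None = None

    # ---------------------------------------------------------------- inference
    def permutation_test(self, n_perm: int = 1000, seed: int = 0,
                         rebuild_kfold: bool = True,
                         **kwargs) -> permutation.PermutationResult:
        """Re-run the full decoding with shuffled labels to get p-values.

        For k-fold schemes the balanced partition is rebuilt per
        permutation by default; pass ``rebuild_kfold=False`` to reuse the
        observed partition.
        """
        if self.scheme.kind == "kfold" and rebuild_kfold:
            spec = {"kind": "kfold", "k": self.scheme.k,
                    "seed": self.scheme.seed or 0}
        else:
            spec = self.scheme
        self.perm_result = permutation.permutation_test(
            self.model.dataset, spec,
            control_confound=self.model.control_confound,
            n_perm=n_perm, seed=seed,
            rvr_options=self.model.rvr_options, **kwargs,
        )
        return self.perm_result

    @property
    def significant(self) -> bool | None:
        if self.perm_result is None:
            return None
        return crossval.decide_significance(self.perm_result.p_r,
                                            self.perm_result.p_mse)

    # ---------------------------------------------------------------- localization
    def localize(self, atlas: localization.AtlasLabelMap) -> pd.DataFrame:
        """Rank atlas regions by their share of the normalized weights."""
        if self.weight_map is None:
            raise ValueError("fit was run without weight computation")
        nw = localization.region_normalized_weights(
            self.weight_map, self.model.dataset.mask, atlas)
        return localization.rank_regions(nw)

    def weight_volume(self) -> np.ndarray:
        """Final normalized weight map on the 3D grid (zeros outside mask)."""
        if self.weight_map is None:
            raise ValueError("fit was run without weight computation")
        return self.model.dataset.mask.insert(self.weight_map)

    # ---------------------------------------------------------------- reporting
    def predictions_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject_id": self.model.dataset.subject_ids,
            "y_true": self.y_true,
            "y_pred": self.y_pred,
        })

    def summary(self) -> str:
        ds = self.model.dataset
        lines = [
            "Cross-validated pattern regression (RVR)",
            "=" * 44,
            f"score:             {ds.score_name}",
            f"subjects (N):      {ds.n_subjects}",
            f"voxels (V):        {ds.n_voxels}",
            f"scheme:            {self.scheme.kind} (k={self.scheme.k})",
            f"confound control:  {self.model.control_confound}",
            f"pooled Pearson r:  {self.r:.4f}",
            f"pooled MSE:        {self.mse:.4f}",
        ]
        if self.scheme.balance_pvalues is not None:
            lines.append(
                "fold balance p:    "
                + ", ".join(f"{p:.3f}" for p in self.scheme.balance_pvalues)
            )
        if self.perm_result is not None:
            pr = self.perm_result
            verdict = "significant" if self.significant else "not significant"
            lines += [
                f"permutations:      {pr.n_perm}",
                f"p(r):              {pr.p_r:.4g}",
                f"p(MSE):            {pr.p_mse:.4g}",
                f"decision (both<0.05): {verdict}",
            ]
        return "\n".join(lines)

    def plot_predictions(self, ax=None):
        """Scatter of decoded vs true scores with the identity line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.scatter(self.y_true, self.y_pred, s=18, alpha=0.75)
        lo = min(self.y_true.min(), self.y_pred.min())
        hi = max(self.y_true.max(), self.y_pred.max())
        ax.plot([lo, hi], [lo, hi], "k--", lw=0.8)
        ax.set_xlabel(f"true {self.model.dataset.score_name}")
        ax.set_ylabel("decoded score")
        ax.set_title(f"r = {self.r:.3f}, MSE = {self.mse:.2f}")
        return ax

    def save(self, out_dir) -> None:
        """Write predictions CSV, summary JSON and the weight-map NIfTI."""
        import json

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.predictions_frame().to_csv(out_dir / "predictions.csv", index=False)
        payload = {
            "r": self.r, "mse": self.mse,
            "settings": _jsonable(self.settings),
            "scheme": {"kind": self.scheme.kind, "k": self.scheme.k,
                       "attempts_used": self.scheme.attempts_used},
        }
        if self.perm_result is not None:
            payload["permutation"] = _jsonable(
                permutation.summarize(self.perm_result))
        with open(out_dir / "decoding.json", "w") as fh:
            json.dump(payload, fh, indent=2)
        if self.weight_map is not None:
            volumes.save_volume(self.weight_volume(),
                                self.model.dataset.mask.affine,
                                out_dir / "weight_map.nii")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return _jsonable(dataclasses.asdict(obj))
    return obj
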