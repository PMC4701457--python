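"""NIfTI volume I/O, analysis-mask construction and dataset assembly.

The analysis mask follows the NaN-intersection rule: a voxel enters the
feature matrix only if it is finite in *every* subject's coefficient volume
(optionally intersected with a user-supplied base mask).  Masked voxels are
mapped to feature columns by a fixed C-order scan of the grid, so weight
vectors and volumes round-trip deterministically.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

AFFINE_TOL = 1e-4


def _as_array(vol) -> np.ndarray:
    return np.asarray(vol, dtype=np.float64)


@dataclasses.dataclass
class MaskVolume:
    """Boolean analysis mask plus the voxel<->feature-column bijection.

    Feature column ``j`` corresponds to the ``j``-th True voxel of
    ``include`` in C order (last axis fastest); ``coords`` materializes the
    bijection as a (V, 3) integer array.
    """

    include: np.ndarray
    affine: np.ndarray
    n_excluded: int = 0

    def __post_init__(self):
        self.include = np.asarray(self.include, dtype=bool)
        if self.include.ndim != 3:
            raise ValueError("mask must be a 3D volume")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.include.shape

    @property
    def n_voxels(self) -> int:
        return int(self.include.sum())

    @property
    def coords(self) -> np.ndarray:
        return np.argwhere(self.include)

    def extract(self, volume: np.ndarray) -> np.ndarray:
        """Masked voxel values of ``volume`` in feature-column order."""
        volume = _as_array(volume)
        if volume.shape != self.grid_shape:
            raise ValueError(
                f"volume shape {volume.shape} != mask grid {self.grid_shape}"
            )
        return volume[self.include]

    def insert(self, w: np.ndarray) -> np.ndarray:
        """Place a length-V feature vector back on the grid (0 outside)."""
        w = np.asarray(w, dtype=np.float64)
        if w.shape != (self.n_voxels,):
            raise ValueError(
                f"vector length {w.shape} does not match V={self.n_voxels}"
            )
        out = np.zeros(self.grid_shape, dtype=np.float64)
        out[self.include] = w
        return out

    def save(self, path) -> None:
        img = nib.Nifti1Image(self.include.astype(np.uint8), self.affine)
        nib.save(img, str(path))

    @classmethod
    def load(cls, path) -> "MaskVolume":
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata())
        return cls(include=data > 0.5, affine=img.affine)


@dataclasses.dataclass
class SubjectDataset:
    """Subject-by-voxel feature matrix with scores and a binary confound."""

    X: np.ndarray
    scores: np.ndarray
    confound: np.ndarray
    subject_ids: list[str]
    mask: MaskVolume
    score_name: str = "score"

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.confound = np.asarray(self.confound)
        n = self.X.shape[0]
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains NaN/Inf; rebuild the mask")
        if len(self.scores) != n or len(self.confound) != n:
            raise ValueError("scores/confound length does not match X rows")
        if not np.all(np.isin(self.confound, [0, 1])):
            raise ValueError("confound must be binary 0/1")
        self.confound = self.confound.astype(np.int64)
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be numeric and finite")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=np.float64), img.affine


def save_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def _check_affines(affines: Sequence[np.ndarray]) -> np.ndarray:
    ref = np.asarray(affines[0], dtype=np.float64)
    for a in affines[1:]:
        if np.max(np.abs(np.asarray(a) - ref)) > AFFINE_TOL:
            raise ValueError(
                "volume affines differ by more than the tolerance "
                f"({AFFINE_TOL}); volumes are never resampled here"
            )
    return ref


def build_common_mask(
    volumes: Sequence[np.ndarray],
    base_mask: np.ndarray | None = None,
    affine: np.ndarray | None = None,
) -> MaskVolume:
    """Intersect finiteness across subjects: keep a voxel only if it is
    finite in every volume (and inside ``base_mask`` when given).
    """
    if len(volumes) == 0:
        raise ValueError("need at least one volume")
    vols = [_as_array(v) for v in volumes]
    shape = vols[0].shape
    for v in vols[1:]:
        if v.shape != shape:
            raise ValueError("all volumes must share the same grid shape")
    include = np.ones(shape, dtype=bool) if base_mask is None else np.asarray(base_mask, dtype=bool).copy()
    if include.shape != shape:
        raise ValueError("base mask grid does not match the volumes")
    n_base = int(include.sum())
    for v in vols:
        include &= np.isfinite(v)
    if not include.any():
        raise ValueError("common mask is empty: every voxel is NaN in some subject")
    if affine is None:
        affine = np.eye(4)
    return MaskVolume(include=include, affine=np.asarray(affine, dtype=np.float64),
                      n_excluded=n_base - int(include.sum()))


def find_subject_volumes(volumes_dir, pattern: str = "*_beta.nii*") -> dict[str, Path]:
    """Map subject_id -> volume path for files named ``<subject_id>_beta.nii``."""
    out: dict[str, Path] = {}
    for p in sorted(Path(volumes_dir).glob(pattern)):
        sid = p.name.split("_beta")[0]
        out[sid] = p
    return out


def assemble_dataset(
    volume_paths: Mapping[str, "Path | str"],
    subjects_table: "pd.DataFrame | Path | str",
    score_column: str,
    mask: MaskVolume,
    confound_column: str = "confound",
) -> SubjectDataset:
    """Build the N x V dataset; row order follows the subjects table."""
    if not isinstance(subjects_table, pd.DataFrame):
        subjects_table = pd.read_csv(subjects_table)
    if score_column not in subjects_table.columns:
        raise ValueError(f"score column {score_column!r} not in subjects table")
    rows = []
    ids = []
    for sid in subjects_table["subject_id"].astype(str):
        if sid not in volume_paths:
            raise ValueError(f"no coefficient volume for subject {sid!r}")
        data, affine = load_volume(volume_paths[sid])
        _check_affines([mask.affine, affine])
        rows.append(mask.extract(data))
        ids.append(sid)
    scores = pd.to_numeric(subjects_table[score_column], errors="raise").to_numpy()
    confound = subjects_table[confound_column].to_numpy()
    return SubjectDataset(
        X=np.vstack(rows), scores=scores, confound=confound,
        subject_ids=ids, mask=mask, score_name=score_column,
    )


def vector_to_volume(w: np.ndarray, mask: MaskVolume) -> np.ndarray:
    """Voxel-space image of a feature vector (zeros outside the mask)."""
    return mask.insert(w)
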