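"""Synthetic study generator.

Emulates the data structure of a multi-site pediatric reward-task study:
per-subject 3D GLM coefficient volumes whose signal is a planted spatial
weight pattern scaled by a latent symptom severity, plus spatially smooth
noise; a subjects table with a 0-30 mania-scale score at two time points
(screen-like: mean 15.5, SD 6.3; near-scan-like: right-skewed, mean 4.7,
SD 5.4) and a binary medication confound (prevalence 52.6%); a block atlas
and label table; optional NaN voxels to exercise mask building.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage, special, stats

from .volumes import MaskVolume, SubjectDataset, build_common_mask, save_volume

#: isotropic voxel size of the emulated acquisition grid, mm
VOXEL_SIZE_MM = 3.1

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# standard half-normal moments, used to standardize the skewed score preset
_HN_MEAN = np.sqrt(2.0 / np.pi)
_HN_SD = np.sqrt(1.0 - 2.0 / np.pi)

SCORE_PRESETS = {
    "screen_like": (15.5, 6.3),
    "nearscan_like": (4.7, 5.4),
}


@dataclasses.dataclass
class GeneratorConfig:
    grid_shape: tuple[int, int, int] = (23, 23, 18)
    mask_kind: str = "ellipsoid"
    n_subjects: int = 57
    n_blobs: int = 2
    blob_sigma_mm: float = 6.0
    noise_sd: float = 1.0
    noise_smooth_fwhm_mm: float = 8.0
    score_model: str = "screen_like"
    score_loc: float = 15.5
    score_scale: float = 6.3
    score_bounds: tuple[float, float] = (0.0, 30.0)
    integerize_scores: bool = False
    confound_prevalence: float = 0.526
    confound_score_shift: float = 0.0
    confound_pattern_gain: float = 0.0
    nan_rate: float = 0.0
    seed: int = 0
    atlas_blocks: tuple[int, int, int] = (3, 3, 2)
    blob_centers: tuple | None = None  # optional fixed voxel coordinates
    blob_signs: tuple | None = None

    def __post_init__(self):
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if self.mask_kind not in ("full", "ellipsoid"):
            raise ValueError(f"unknown mask_kind {self.mask_kind!r}")
        if self.score_model not in ("screen_like", "nearscan_like", "custom"):
            raise ValueError(f"unknown score_model {self.score_model!r}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.n_blobs < 0:
            raise ValueError("n_blobs must be non-negative")
        if self.blob_sigma_mm <= 0:
            raise ValueError("blob_sigma_mm must be positive")
        if self.noise_sd < 0 or self.noise_smooth_fwhm_mm < 0:
            raise ValueError("noise parameters must be non-negative")
        if not (0.0 <= self.confound_prevalence <= 1.0):
            raise ValueError("confound_prevalence must be in [0, 1]")
        if not (0.0 <= self.nan_rate <= 1.0):
            raise ValueError("nan_rate must be in [0, 1]")
        lo, hi = self.score_bounds
        if not lo < hi:
            raise ValueError("score_bounds must satisfy low < high")
        if self.score_scale < 0:
            raise ValueError("score_scale must be non-negative")


@dataclasses.dataclass
class GroundTruth:
    """What the pipeline should recover from a generated study."""

    weight_volume: np.ndarray
    latent_scores: np.ndarray
    confound_vector: np.ndarray
    confound_weight_volume: np.ndarray | None = None


@dataclasses.dataclass
class StudyPaths:
    out_dir: Path
    volumes: dict[str, Path]
    subjects_csv: Path
    mask: Path
    atlas: Path
    atlas_labels: Path
    true_weights: Path
    ground_truth_csv: Path
    config_yaml: Path


def default_affine() -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = VOXEL_SIZE_MM
    return aff


def make_mask(config: GeneratorConfig) -> np.ndarray:
    shape = config.grid_shape
    if config.mask_kind == "full":
        return np.ones(shape, dtype=bool)
    # ellipsoid inscribed in the grid
    center = [(s - 1) / 2.0 for s in shape]
    semi = [max(s / 2.0, 0.5) for s in shape]
    grids = np.ogrid[[slice(0, s) for s in shape]]
    d2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return d2 <= 1.0


def make_weight_pattern(
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    centers: np.ndarray | None = None,
    signs: np.ndarray | None = None,
) -> np.ndarray:
    """Sum of ``n_blobs`` signed Gaussian bumps inside the mask.

    Blob centers are drawn uniformly over mask voxels unless supplied;
    signs are random +-1 unless supplied.  ``n_blobs = 0`` returns the
    all-zero volume.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mask = make_mask(config)
    vol = np.zeros(config.grid_shape, dtype=np.float64)
    if config.n_blobs == 0:
        return vol
    extent = max(s * VOXEL_SIZE_MM for s in config.grid_shape)
    if extent < 2.0 * config.blob_sigma_mm:
        raise ValueError(
            f"grid extent {extent:.1f} mm is too small for blobs of sigma "
            f"{config.blob_sigma_mm} mm"
        )
    if centers is None and config.blob_centers is not None:
        centers = config.blob_centers
    if signs is None and config.blob_signs is not None:
        signs = config.blob_signs
    coords = np.argwhere(mask)
    if centers is None:
        centers = coords[rng.integers(0, len(coords), size=config.n_blobs)]
    else:
        centers = np.atleast_2d(np.asarray(centers))
        if len(centers) != config.n_blobs:
            raise ValueError("number of centers must equal n_blobs")
    if signs is None:
        signs = rng.choice([-1.0, 1.0], size=config.n_blobs)
    signs = np.asarray(signs, dtype=np.float64)
    sigma_vox = config.blob_sigma_mm / VOXEL_SIZE_MM
    grids = np.ogrid[[slice(0, s) for s in config.grid_shape]]
    for c, s in zip(centers, signs):
        d2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
        vol += s * np.exp(-d2 / (2.0 * sigma_vox**2))
    vol[~mask] = 0.0
    return vol


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def draw_scores(
    config: GeneratorConfig,
    n: int,
    rng: np.random.Generator | None = None,
    score_model: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` observed scores and their latent standardized values.

    ``screen_like``/``custom`` are a clipped affine transform of a standard
    normal z; ``nearscan_like`` pushes the same z through the half-normal
    quantile function (a monotone transform), producing the right-skewed,
    low-value-heavy shape of a symptom score measured near remission.
    Observed scores are clipped to ``score_bounds`` and optionally rounded
    half-away-from-zero to mimic integer questionnaire totals.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    model = config.score_model if score_model is None else score_model
    z = rng.standard_normal(n)
    observed = _scores_from_latent(config, z, model)
    return observed, z


def _scores_from_latent(
    config: GeneratorConfig, z: np.ndarray, model: str, shift: np.ndarray | float = 0.0
) -> np.ndarray:
    if model == "custom":
        loc, scale = config.score_loc, config.score_scale
        raw = loc + scale * z
    elif model == "screen_like":
        loc, scale = SCORE_PRESETS["screen_like"]
        raw = loc + scale * z
    elif model == "nearscan_like":
        loc, scale = SCORE_PRESETS["nearscan_like"]
        u = np.clip(special.ndtr(z), 1e-12, 1 - 1e-12)
        h = stats.halfnorm.ppf(u)
        raw = loc + scale * (h - _HN_MEAN) / _HN_SD
    else:  # pragma: no cover - guarded by config validation
        raise ValueError(model)
    lo, hi = config.score_bounds
    out = np.clip(raw + shift, lo, hi)
    if config.integerize_scores:
        out = _round_half_away(out)
    return out


def _smooth_noise(rng: np.random.Generator, config: GeneratorConfig) -> np.ndarray:
    white = rng.standard_normal(config.grid_shape)
    sigma_vox = config.noise_smooth_fwhm_mm * _FWHM_TO_SIGMA / VOXEL_SIZE_MM
    if sigma_vox > 0:
        white = ndimage.gaussian_filter(white, sigma_vox)
    sd = white.std()
    if sd > 0:
        white = white / sd
    return config.noise_sd * white


def make_block_atlas(mask: np.ndarray, blocks: tuple[int, int, int]) -> np.ndarray:
    """Partition mask voxels into labelled rectangular blocks (0=background)."""
    shape = mask.shape
    edges = [np.linspace(0, s, b + 1) for s, b in zip(shape, blocks)]
    idx = [np.clip(np.digitize(np.arange(s), e) - 1, 0, b - 1)
           for s, e, b in zip(shape, edges, blocks)]
    bx, by, bz = np.meshgrid(idx[0], idx[1], idx[2], indexing="ij")
    labels = 1 + bx * blocks[1] * blocks[2] + by * blocks[2] + bz
    labels = labels.astype(np.int64)
    labels[~mask] = 0
    return labels


def _build_study_arrays(config: GeneratorConfig):
    """Deterministically realize a study in memory.

    Each subject's coefficient volume is ``z_i * w + gain * c_i * w_c +
    smooth noise`` inside the mask and 0 outside, where z_i is the latent
    standardized severity, w the planted pattern and c_i the binary
    confound.  NaNs are injected inside the mask at ``nan_rate`` per
    subject-voxel.
    """
    if config.nan_rate >= 1.0:
        raise ValueError("nan_rate of 1.0 would empty the analysis mask")
    ss = np.random.SeedSequence(config.seed)
    rng_pattern, rng_scores, rng_conf, rng_noise, rng_nan, rng_cpat = (
        np.random.default_rng(c) for c in ss.spawn(6)
    )

    mask = make_mask(config)
    w = make_weight_pattern(config, rng=rng_pattern)
    # the confound's own spatial signature: a single bump elsewhere in the mask
    if config.confound_pattern_gain != 0.0:
        cpat_cfg = dataclasses.replace(
            config, n_blobs=1, blob_centers=None, blob_signs=None)
        w_c = make_weight_pattern(cpat_cfg, rng=rng_cpat)
    else:
        w_c = np.zeros(config.grid_shape)

    n = config.n_subjects
    z = rng_scores.standard_normal(n)
    c = (rng_conf.random(n) < config.confound_prevalence).astype(np.int64)
    shift = config.confound_score_shift * c
    score_screen = _scores_from_latent(config, z, "screen_like", shift)
    score_nearscan = _scores_from_latent(config, z, "nearscan_like", shift)
    if config.score_model == "custom":
        score_screen = _scores_from_latent(config, z, "custom", shift)

    vols = []
    for i in range(n):
        vol = z[i] * w + config.confound_pattern_gain * c[i] * w_c
        if config.noise_sd > 0:
            vol = vol + _smooth_noise(rng_noise, config) * mask
        else:
            vol = vol.copy()
        vol[~mask] = 0.0
        if config.nan_rate > 0:
            drop = (rng_nan.random(config.grid_shape) < config.nan_rate) & mask
            vol[drop] = np.nan
        vols.append(vol)

    truth = GroundTruth(weight_volume=w, latent_scores=z, confound_vector=c,
                        confound_weight_volume=w_c)
    return mask, vols, score_screen, score_nearscan, truth


def generate_dataset(
    config: GeneratorConfig, score: str = "screen"
) -> tuple[SubjectDataset, GroundTruth]:
    """In-memory variant of :func:`generate_study`: same realization for a
    given (config, seed), but assembled directly into a
    :class:`~patternreg.volumes.SubjectDataset` without touching disk."""
    mask, vols, score_screen, score_nearscan, truth = _build_study_arrays(config)
    mv = build_common_mask(vols, base_mask=mask, affine=default_affine())
    scores = {"screen": score_screen, "nearscan": score_nearscan}[score]
    X = np.stack([v[mv.include] for v in vols])
    ds = SubjectDataset(
        X=X, scores=scores, confound=truth.confound_vector,
        subject_ids=[f"sub-{i + 1:03d}" for i in range(config.n_subjects)],
        mask=mv, score_name=f"score_{score}",
    )
    return ds, truth


def generate_study(config: GeneratorConfig, out_dir) -> tuple[StudyPaths, GroundTruth]:
    """Write a complete synthetic study to ``out_dir``.

    See :func:`_build_study_arrays` for the data model; this writes one
    NIfTI coefficient volume per subject plus the subjects CSV, mask,
    block atlas with label TSV, true-weight volume, ground-truth CSV and a
    YAML echo of the configuration.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = default_affine()

    mask, vols, score_screen, score_nearscan, truth = _build_study_arrays(config)
    w, z, c = truth.weight_volume, truth.latent_scores, truth.confound_vector

    n = config.n_subjects
    ids = [f"sub-{i + 1:03d}" for i in range(n)]
    vol_paths: dict[str, Path] = {}
    for sid, vol in zip(ids, vols):
        p = out_dir / f"{sid}_beta.nii"
        save_volume(vol, affine, p)
        vol_paths[sid] = p

    subjects = pd.DataFrame(
        {
            "subject_id": ids,
            "score_screen": score_screen,
            "score_nearscan": score_nearscan,
            "confound": c,
        }
    )
    subjects_csv = out_dir / "subjects.csv"
    subjects.to_csv(subjects_csv, index=False)

    mask_path = out_dir / "mask.nii"
    MaskVolume(include=mask, affine=affine).save(mask_path)

    atlas = make_block_atlas(mask, config.atlas_blocks)
    atlas_path = out_dir / "atlas.nii"
    save_volume(atlas.astype(np.float64), affine, atlas_path)
    labels_present = sorted(int(v) for v in np.unique(atlas) if v != 0)
    labels_tsv = out_dir / "atlas_labels.tsv"
    pd.DataFrame(
        {"label_value": labels_present,
         "region_name": [f"region_{v:02d}" for v in labels_present]}
    ).to_csv(labels_tsv, sep="\t", index=False)

    tw_path = out_dir / "true_weights.nii"
    save_volume(w, affine, tw_path)

    gt_csv = out_dir / "ground_truth.csv"
    pd.DataFrame(
        {"subject_id": ids, "latent_score": z, "confound": c}
    ).to_csv(gt_csv, index=False)

    config_yaml = out_dir / "config.yaml"
    with open(config_yaml, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)

    paths = StudyPaths(
        out_dir=out_dir, volumes=vol_paths, subjects_csv=subjects_csv,
        mask=mask_path, atlas=atlas_path, atlas_labels=labels_tsv,
        true_weights=tw_path, ground_truth_csv=gt_csv, config_yaml=config_yaml,
    )
    return paths, truth
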