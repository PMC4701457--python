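"""Atlas-based pattern localization.

A linear decoding model yields one weight per voxel; because predictions use
the whole pattern, the weight map is reported unthresholded.  The final map
is the across-fold average divided by its Euclidean norm.  To summarize it
anatomically, each atlas region gets the mean of absolute voxel weights over
its masked voxels (NW), expressed as a percentage of the summed NW over all
regions, and regions are ranked by that percentage.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .volumes import MaskVolume, load_volume, _check_affines


@dataclasses.dataclass
class AtlasLabelMap:
    """Integer label volume plus label-value -> region-name lookup."""

    label_volume: np.ndarray
    labels: dict[int, str]
    background_value: int = 0

    def __post_init__(self):
        self.label_volume = np.asarray(self.label_volume)
        if not np.issubdtype(self.label_volume.dtype, np.integer):
            rounded = np.rint(self.label_volume)
            if np.max(np.abs(self.label_volume - rounded)) > 1e-6:
                raise ValueError("atlas volume must be integer-valued")
            self.label_volume = rounded.astype(np.int64)


def average_weight_map(per_fold_weights) -> np.ndarray:
    """Across-fold mean weight vector divided by its Euclidean norm."""
    folds = [np.asarray(w, dtype=np.float64) for w in per_fold_weights]
    if len(folds) == 0:
        raise ValueError("need at least one fold weight vector")
    length = folds[0].shape
    for w in folds[1:]:
        if w.shape != length:
            raise ValueError("fold weight vectors have differing lengths")
    mean = np.mean(folds, axis=0)
    norm = np.linalg.norm(mean)
    if norm == 0:
        warnings.warn("all fold weights are zero; weight map left as zeros")
        return mean
    return mean / norm


def region_normalized_weights(
    weight_map: np.ndarray, mask: MaskVolume, atlas: AtlasLabelMap
) -> pd.DataFrame:
    """Per-region mean of absolute voxel weights over masked voxels.

    Returns columns ``label``, ``region_name``, ``n_voxels``,
    ``mean_abs_weight``; regions with no masked voxels are dropped with a
    warning, voxels outside the mask or with the background label are
    ignored.
    """
    if atlas.label_volume.shape != mask.grid_shape:
        raise ValueError("atlas grid does not match the analysis mask")
    w = np.asarray(weight_map, dtype=np.float64)
    if w.shape != (mask.n_voxels,):
        raise ValueError("weight map length does not match mask voxel count")
    labels_vec = atlas.label_volume[mask.include]
    rows = []
    dropped = []
    for label, name in sorted(atlas.labels.items()):
        if label == atlas.background_value:
            continue
        sel = labels_vec == label
        n_vox = int(sel.sum())
        if n_vox == 0:
            dropped.append(name)
            continue
        rows.append((label, name, n_vox, float(np.abs(w[sel]).mean())))
    if dropped:
        warnings.warn(
            f"{len(dropped)} atlas region(s) empty after mask intersection "
            f"and dropped: {', '.join(dropped)}"
        )
    if not rows:
        raise ValueError("no atlas region overlaps the analysis mask")
    return pd.DataFrame(
        rows, columns=["label", "region_name", "n_voxels", "mean_abs_weight"]
    )


def rank_regions(nw_table: pd.DataFrame) -> pd.DataFrame:
    """Rank regions by their share of the total normalized weights.

    ``pct_total_nw = 100 * NW / sum(NW)``, sorted descending with ties
    broken lexicographically by region name; a cumulative percentage column
    supports top-k share statements.  An all-zero map yields an empty
    ranking with a warning.
    """
    total = nw_table["mean_abs_weight"].sum()
    if total == 0:
        warnings.warn("all region weights are zero; returning empty ranking")
        return pd.DataFrame(
            columns=["rank", "region_name", "n_voxels", "mean_abs_weight",
                     "pct_total_nw", "cumulative_pct"]
        )
    df = nw_table.copy()
    df["pct_total_nw"] = 100.0 * df["mean_abs_weight"] / total
    df = df.sort_values(
        ["pct_total_nw", "region_name"], ascending=[False, True]
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["cumulative_pct"] = df["pct_total_nw"].cumsum()
    return df[["rank", "region_name", "n_voxels", "mean_abs_weight",
               "pct_total_nw", "cumulative_pct"]]


def load_atlas(label_nifti_path, label_tsv_path, mask: MaskVolume) -> AtlasLabelMap:
    """Load a labelled atlas volume and its TSV lookup on the analysis grid.

    The grid must match exactly (no resampling).  Label values present in
    the volume but missing from the TSV are auto-named ``label_<value>``
    with a warning.
    """
    data, affine = load_volume(label_nifti_path)
    if data.shape != mask.grid_shape:
        raise ValueError("atlas grid does not match the analysis mask")
    _check_affines([mask.affine, affine])
    table = pd.read_csv(label_tsv_path, sep="\t")
    labels = {
        int(v): str(n)
        for v, n in zip(table["label_value"], table["region_name"])
    }
    atlas = AtlasLabelMap(label_volume=data, labels=labels)
    present = {int(v) for v in np.unique(atlas.label_volume)} - {atlas.background_value}
    missing = sorted(present - set(labels))
    if missing:
        warnings.warn(
            f"atlas labels missing from TSV, auto-named: {missing}"
        )
        for v in missing:
            labels[v] = f"label_{v}"
    return atlas


def region_pct_volume(
    ranking: pd.DataFrame, mask: MaskVolume, atlas: AtlasLabelMap
) -> np.ndarray:
    """Visualization volume: each masked voxel set to its region's %NW."""
    name_to_pct = dict(zip(ranking["region_name"], ranking["pct_total_nw"]))
    out = np.zeros(mask.grid_shape)
    for label, name in atlas.labels.items():
        if label == atlas.background_value or name not in name_to_pct:
            continue
        sel = (atlas.label_volume == label) & mask.include
        out[sel] = name_to_pct[name]
    return out
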