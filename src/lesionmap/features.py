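"""Regional lesion quantification against brain parcellation atlases.

Converts binary lesion masks plus an integer label atlas into the feature
table used for outcome prediction: the ischemic percentage of each atlas
region (fraction of the region's voxels overlapped by the lesion, x100),
total lesion volume in mL, and hemisphere lateralization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .segmentation import (
    ADCVolume,
    GridMismatchError,
    LesionMask,
    SegmentationParams,
    segment_lesion,
)

REQUIRED_TABLE_COLUMNS = ("id", "name", "hemisphere", "tissue")


class ReconciliationError(ValueError):
    """Imaging and tabular inputs disagree about which subjects/labels exist."""


class UndefinedHemisphereError(ValueError):
    """Hemisphere assignment requested for an empty lesion."""


@dataclass(frozen=True)
class AtlasParcellation:
    """An integer-labeled parcellation volume plus its label table.

    ``labels`` holds one region id per voxel, 0 = background. ``table`` has
    one row per region with columns id, name, hemisphere (left/right/midline)
    and tissue (gm/wm).
    """

    labels: np.ndarray
    table: pd.DataFrame
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError("atlas labels must be 3D")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        missing = [c for c in REQUIRED_TABLE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"label table missing columns: {missing}")
        if self.table["id"].duplicated().any():
            raise ValueError("label table ids must be unique")
        in_grid = set(np.unique(labels)) - {0}
        in_table = set(self.table["id"].tolist())
        orphans = sorted(in_grid - in_table)
        if orphans:
            raise ReconciliationError(
                f"labels present in grid but missing from table: {orphans}"
            )
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def region_ids(self) -> list[int]:
        return sorted(int(i) for i in self.table["id"])

    def hemisphere_of(self) -> dict[int, str]:
        return dict(zip(self.table["id"].astype(int), self.table["hemisphere"]))


def region_percentages(lesion: LesionMask, atlas: AtlasParcellation) -> pd.Series:
    """Percentage of each atlas region's voxels covered by the lesion.

    pct(r) = 100 * |lesion ∩ voxels(r)| / |voxels(r)|. Regions listed in the
    atlas table but absent from the label grid are dropped with a warning,
    not reported as zero. Exact integer identity holds:
    sum_r pct(r) * |voxels(r)| / 100 = |lesion ∩ atlas-covered voxels|.
    """
    if lesion.shape != atlas.shape:
        raise GridMismatchError(
            f"lesion shape {lesion.shape} != atlas shape {atlas.shape}"
        )
    labels = atlas.labels
    nbins = int(labels.max()) + 1
    region_sizes = np.bincount(labels.ravel(), minlength=nbins)
    overlap = np.bincount(labels[lesion.mask].ravel(), minlength=nbins)
    out = {}
    dropped = []
    for rid in atlas.region_ids():
        if rid < nbins and region_sizes[rid] > 0:
            out[rid] = 100.0 * overlap[rid] / region_sizes[rid]
        else:
            dropped.append(rid)
    if dropped:
        warnings.warn(
            f"atlas regions with no voxels in grid dropped: {dropped}",
            stacklevel=2,
        )
    return pd.Series(out, name="pct", dtype=float)


def lesion_volume_ml(lesion: LesionMask) -> float:
    """Lesion volume in mL: voxel count x voxel volume (mm^3) / 1000."""
    return lesion.n_voxels * lesion.voxel_volume_mm3 / 1000.0


def assign_hemisphere(lesion: LesionMask, atlas: AtlasParcellation) -> str:
    """Hemisphere holding the majority of lesion voxels, by atlas labels.

    Voxels on background or midline labels do not vote. Ties break toward
    left with a warning.
    """
    if not lesion.mask.any():
        raise UndefinedHemisphereError("cannot lateralize an empty lesion")
    if lesion.shape != atlas.shape:
        raise GridMismatchError("lesion and atlas grids differ")
    hemi = atlas.hemisphere_of()
    lesion_labels = atlas.labels[lesion.mask]
    counts = {"left": 0, "right": 0}
    nbins = int(atlas.labels.max()) + 1
    votes = np.bincount(lesion_labels.ravel(), minlength=nbins)
    for rid, h in hemi.items():
        if h in counts and rid < nbins:
            counts[h] += int(votes[rid])
    if counts["left"] == counts["right"]:
        warnings.warn("hemisphere tie; assigning left", stacklevel=2)
        return "left"
    return "left" if counts["left"] > counts["right"] else "right"


CLINICAL_COLUMNS = ["patient_id", "age", "nihss", "mrs_binary", "hemisphere"]


def feature_table(
    lesions: dict[str, LesionMask],
    atlas: AtlasParcellation,
    clinical: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the analysis feature table from in-memory objects.

    One row per patient: clinical covariates (age, nihss), outcome, lesion
    volume in mL, hemisphere, then ``pct_<region id>`` columns sorted by
    atlas id. Patient sets in ``lesions`` and ``clinical`` must coincide.
    """
    img_ids = set(lesions)
    clin_ids = set(clinical["patient_id"].astype(str))
    if img_ids != clin_ids:
        raise ReconciliationError(
            f"imaging-only ids: {sorted(img_ids - clin_ids)}; "
            f"clinical-only ids: {sorted(clin_ids - img_ids)}"
        )
    region_ids = atlas.region_ids()
    pct_cols = [f"pct_{r}" for r in region_ids]
    rows = []
    clinical = clinical.copy()
    clinical["patient_id"] = clinical["patient_id"].astype(str)
    clin_by_id = clinical.set_index("patient_id")
    for pid in sorted(lesions):
        lesion = lesions[pid]
        pct = region_percentages(lesion, atlas)
        crow = clin_by_id.loc[pid]
        row = {
            "patient_id": pid,
            "age": float(crow["age"]),
            "nihss": float(crow["nihss"]),
            "mrs_binary": int(crow["mrs_binary"]),
            "volume_ml": lesion_volume_ml(lesion),
        }
        if lesion.mask.any():
            row["hemisphere"] = assign_hemisphere(lesion, atlas)
        else:
            row["hemisphere"] = str(crow.get("hemisphere", "left"))
        for r, c in zip(region_ids, pct_cols):
            row[c] = float(pct.get(r, np.nan))
        rows.append(row)
    cols = ["patient_id", "age", "nihss", "mrs_binary", "volume_ml", "hemisphere"] + pct_cols
    if not rows:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows, columns=cols)
    bad = [c for c in pct_cols if ((df[c] < 0) | (df[c] > 100)).any()]
    assert not bad, f"percentages out of [0, 100] in {bad}"
    return df


def build_feature_table(
    cohort_dir: str | Path,
    params: SegmentationParams | None = None,
) -> pd.DataFrame:
    """Segment every patient in a cohort directory and build the feature table.

    The directory layout is the one written by the synthetic cohort writer:
    ``atlas.nii.gz`` + ``atlas_labels.tsv``, ``brain_mask.nii.gz``,
    ``clinical.csv`` and per-patient ``adc_<id>.nii.gz``.
    """
    from .io import read_atlas, read_clinical, read_mask, read_volume

    cohort_dir = Path(cohort_dir)
    atlas = read_atlas(cohort_dir / "atlas.nii.gz", cohort_dir / "atlas_labels.tsv")
    brain = read_mask(cohort_dir / "brain_mask.nii.gz")
    clinical = read_clinical(cohort_dir / "clinical.csv")
    adc_paths = sorted(cohort_dir.glob("adc_*.nii.gz"))
    lesions: dict[str, LesionMask] = {}
    for path in adc_paths:
        pid = path.name[len("adc_"):-len(".nii.gz")]
        adc = read_volume(path)
        lesions[pid] = segment_lesion(adc, brain.mask, params)
    return feature_table(lesions, atlas, clinical)
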