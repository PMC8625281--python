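"""Seedable synthetic stroke cohorts: atlas, ADC volumes, covariates, outcomes.

The generator emulates the statistical structure the downstream analysis
assumes for an anterior-circulation thrombectomy cohort: ~143 patients with
a single contiguous lesion confined to one hemisphere, lesion volumes
log-normal around a 20 mL median with a wide spread, ADC hypointensity well
below the 615 (1e-6 mm^2/s) ischemia threshold against normal-tissue values
well above it, and a dichotomized 3-month functional outcome drawn from a
logistic model over age, baseline NIHSS and the ischemic percentage of a
planted subset of "eloquent" regions.

Everything is deterministic given (config, seed): per-patient random streams
are spawned from one seed sequence, so cohorts are bit-identical across runs.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .features import AtlasParcellation, region_percentages
from .segmentation import ADCVolume, LesionMask

ADC_ISCHEMIA_THRESHOLD = 615.0

_NEIGHBORS6 = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


class InfeasibleParcellationError(ValueError):
    """More regions requested than voxels available to hold them."""


class ConfigurationError(ValueError):
    """A simulation config references entities that do not exist."""


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation parameters.

    ADC means/SDs are in 1e-6 mm^2/s; the lesion mean must sit below the 615
    ischemia threshold and the normal-tissue mean above it, so thresholding
    separates the tissue classes in expectation. Lesion volumes are drawn
    log-normally (``lesion_volume_log_mean`` is the log of the median volume
    in mL). Outcomes follow a logistic model over standardized age, NIHSS
    and the true ischemic percentages of ``effect_regions``.
    """

    n_patients: int = 143
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    n_gm_regions_per_hemi: int = 16
    n_wm_regions_per_hemi: int = 7
    adc_normal_mean: float = 850.0
    adc_normal_sd: float = 60.0
    adc_lesion_mean: float = 450.0
    adc_lesion_sd: float = 50.0
    lesion_volume_log_mean: float = math.log(20.0)
    lesion_volume_log_sd: float = 1.0
    effect_regions: tuple[int, ...] = ()
    betas_region: tuple[float, ...] = ()
    beta_age: float = 0.5
    beta_nihss: float = 0.8
    intercept: float = -0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.n_gm_regions_per_hemi < 1 or self.n_wm_regions_per_hemi < 1:
            raise ValueError("region counts must be >= 1")
        if self.grid_shape[0] % 2 != 0:
            raise ValueError("first grid axis must be even (mid-sagittal split)")
        if not (self.adc_lesion_mean < ADC_ISCHEMIA_THRESHOLD < self.adc_normal_mean):
            raise ValueError(
                "adc_lesion_mean < 615 < adc_normal_mean required for the "
                "threshold to separate tissue classes"
            )
        if len(self.effect_regions) != len(self.betas_region):
            raise ValueError("effect_regions and betas_region lengths differ")

    @property
    def n_regions(self) -> int:
        return 2 * (self.n_gm_regions_per_hemi + self.n_wm_regions_per_hemi)


def planted_effect_config(
    n_effect: int = 5, beta: float = 2.0, **overrides
) -> SimConfig:
    """Default study config with ``n_effect`` outcome-relevant regions.

    Effect regions are spread over hemispheres and tissue classes; all other
    regions are pure noise with respect to outcome.
    """
    base = SimConfig(**overrides)
    per_hemi = base.n_gm_regions_per_hemi + base.n_wm_regions_per_hemi
    candidates = []
    # alternate left/right, mixing gm and wm ids
    for k in range(n_effect):
        side = k % 2
        rid = 1 + (k * 5) % per_hemi + side * per_hemi
        while rid in candidates:
            rid = rid % (2 * per_hemi) + 1
        candidates.append(rid)
    return replace(
        base,
        effect_regions=tuple(sorted(candidates)),
        betas_region=(beta,) * n_effect,
    )


@dataclass
class PatientTruth:
    """Ground truth for one synthetic patient."""

    patient_id: str
    lesion_mask: LesionMask
    hemisphere: str
    truncated: bool
    age: float
    nihss: int
    outcome: int | None = None  # 1 = poor (mRS 3-6), 0 = favorable
    linear_predictor: float | None = None


@dataclass
class SyntheticCohort:
    atlas: AtlasParcellation
    brain_mask: LesionMask
    volumes: dict[str, ADCVolume]
    truth: list[PatientTruth]
    config: SimConfig

    def clinical_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": [t.patient_id for t in self.truth],
                "age": [t.age for t in self.truth],
                "nihss": [t.nihss for t in self.truth],
                "mrs_binary": [t.outcome for t in self.truth],
                "hemisphere": [t.hemisphere for t in self.truth],
            }
        )

    def truth_features(self) -> pd.DataFrame:
        """Feature table built from the true lesion masks (no segmentation)."""
        from .features import feature_table

        lesions = {t.patient_id: t.lesion_mask for t in self.truth}
        return feature_table(lesions, self.atlas, self.clinical_table())


def _ellipsoid_mask(shape: tuple[int, int, int], scale: float = 0.9) -> np.ndarray:
    # voxel-center coordinates, symmetric about the mid-sagittal plane for
    # an even first axis
    axes = [np.arange(n) - (n - 1) / 2.0 for n in shape]
    semi = [scale * n / 2.0 for n in shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return (
        (xx / semi[0]) ** 2 + (yy / semi[1]) ** 2 + (zz / semi[2]) ** 2
    ) <= 1.0


def _default_affine(
    shape: tuple[int, int, int], voxel_size: tuple[float, float, float]
) -> np.ndarray:
    # diagonal RAS affine centered on the grid: world x < 0 is the left
    # hemisphere, i.e. voxel index i < nx/2
    affine = np.eye(4)
    for a in range(3):
        affine[a, a] = voxel_size[a]
        affine[a, 3] = -voxel_size[a] * (shape[a] - 1) / 2.0
    return affine


def _multi_source_bfs(
    class_mask: np.ndarray, seeds: np.ndarray, labels_out: np.ndarray, label_ids: list[int]
) -> None:
    """Grow all seeds simultaneously (6-connectivity) to partition class_mask."""
    shape = class_mask.shape
    queue: deque = deque()
    for (v, lab) in zip(seeds, label_ids):
        labels_out[tuple(v)] = lab
        queue.append(tuple(v))
    while queue:
        v = queue.popleft()
        lab = labels_out[v]
        for d in _NEIGHBORS6:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if (
                0 <= w[0] < shape[0]
                and 0 <= w[1] < shape[1]
                and 0 <= w[2] < shape[2]
                and class_mask[w]
                and labels_out[w] == 0
            ):
                labels_out[w] = lab
                queue.append(w)
    # attach any voxels BFS could not reach (disconnected slivers) to an
    # adjacent already-labeled voxel of the same class
    remaining = class_mask & (labels_out == 0)
    while remaining.any():
        changed = False
        idx = np.argwhere(remaining)
        for v in idx:
            for d in _NEIGHBORS6:
                w = tuple(v + d)
                if all(0 <= w[a] < shape[a] for a in range(3)) and labels_out[w] != 0 and class_mask[w]:
                    labels_out[tuple(v)] = labels_out[w]
                    remaining[tuple(v)] = False
                    changed = True
                    break
        if not changed:
            # isolated island: give it the first label
            v = tuple(idx[0])
            labels_out[v] = label_ids[0]
            remaining[v] = False


def generate_atlas(
    grid_shape: tuple[int, int, int],
    n_gm: int,
    n_wm: int,
    seed: int,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> AtlasParcellation:
    """Generate a mirrored left/right parcellation of an ellipsoidal brain.

    White matter is an inner ellipsoidal core, gray matter the surrounding
    shell. The left hemisphere is partitioned into contiguous regions by
    multi-source breadth-first growth from random seed voxels and mirrored
    onto the right, giving paired regions with matching shapes. Label 0 is
    background; left regions take ids 1..(n_gm+n_wm), right regions the same
    id + (n_gm+n_wm).
    """
    if grid_shape[0] % 2 != 0:
        raise ValueError("first grid axis must be even")
    if n_gm < 0 or n_wm < 0 or n_gm + n_wm < 1:
        raise ValueError("need at least one region per hemisphere")
    rng = np.random.default_rng(seed)
    brain = _ellipsoid_mask(grid_shape, scale=0.9)
    # white matter is an inner core; with a single tissue class the whole
    # brain belongs to it
    core = _ellipsoid_mask(grid_shape, scale=0.9 * 0.6) if (n_gm and n_wm) else (
        np.zeros(grid_shape, dtype=bool) if n_gm else brain
    )
    nx = grid_shape[0]
    left = np.zeros(grid_shape, dtype=bool)
    left[: nx // 2] = True

    wm_left = core & left
    gm_left = brain & ~core & left
    labels = np.zeros(grid_shape, dtype=np.int32)
    per_hemi = n_gm + n_wm
    for class_mask, n_reg, first_id in ((gm_left, n_gm, 1), (wm_left, n_wm, n_gm + 1)):
        if n_reg == 0:
            continue
        voxels = np.argwhere(class_mask)
        if len(voxels) < n_reg:
            raise InfeasibleParcellationError(
                f"{n_reg} regions requested but only {len(voxels)} voxels available"
            )
        picks = rng.choice(len(voxels), size=n_reg, replace=False)
        _multi_source_bfs(
            class_mask, voxels[picks], labels, list(range(first_id, first_id + n_reg))
        )
    # mirror left labels onto the right hemisphere
    mirrored = labels[::-1, :, :]
    right_sel = mirrored > 0
    labels[right_sel] = mirrored[right_sel] + per_hemi

    rows = []
    for hemi, offset in (("left", 0), ("right", per_hemi)):
        for k in range(1, per_hemi + 1):
            tissue = "gm" if k <= n_gm else "wm"
            idx = k if tissue == "gm" else k - n_gm
            rows.append(
                {
                    "id": k + offset,
                    "name": f"{tissue}_{idx:02d}_{hemi[0].upper()}",
                    "hemisphere": hemi,
                    "tissue": tissue,
                }
            )
    table = pd.DataFrame(rows)
    return AtlasParcellation(
        labels=labels, table=table, affine=_default_affine(grid_shape, voxel_size)
    )


def _grow_lesion(
    brain: np.ndarray,
    hemi_mask: np.ndarray,
    target_voxels: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    """Random region growing: start from a random in-hemisphere voxel and
    repeatedly absorb a uniformly chosen 6-connected boundary voxel."""
    allowed = brain & hemi_mask
    lesion = np.zeros_like(brain, dtype=bool)
    if target_voxels <= 0:
        return lesion, False
    shape = brain.shape
    candidates = np.argwhere(allowed)
    start = tuple(candidates[rng.integers(len(candidates))])
    lesion[start] = True
    frontier: list[tuple[int, int, int]] = []
    in_frontier = np.zeros_like(brain, dtype=bool)

    def push_neighbors(v):
        for d in _NEIGHBORS6:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if (
                0 <= w[0] < shape[0]
                and 0 <= w[1] < shape[1]
                and 0 <= w[2] < shape[2]
                and allowed[w]
                and not lesion[w]
                and not in_frontier[w]
            ):
                in_frontier[w] = True
                frontier.append(w)

    push_neighbors(start)
    n = 1
    while n < target_voxels and frontier:
        i = int(rng.integers(len(frontier)))
        frontier[i], frontier[-1] = frontier[-1], frontier[i]
        v = frontier.pop()
        in_frontier[v] = False
        lesion[v] = True
        n += 1
        push_neighbors(v)
    truncated = n < target_voxels
    return lesion, truncated


def _draw_age(rng: np.random.Generator, mean=64.0, sd=12.0, lo=18.0, hi=80.0) -> float:
    for _ in range(1000):
        a = rng.normal(mean, sd)
        if lo <= a <= hi:
            return float(a)
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def generate_patient(
    config: SimConfig, atlas: AtlasParcellation, seed: int, patient_id: str = "p000"
) -> tuple[ADCVolume, PatientTruth]:
    """Simulate one patient: a contiguous single-hemisphere lesion and its
    ADC map.

    The lesion target volume is drawn log-normally (mL), converted to voxels
    and grown from a random seed voxel; if the target exceeds the hemisphere
    the lesion is truncated and flagged. ADC values follow the lesion
    distribution inside the lesion and the normal distribution elsewhere,
    clipped at zero.
    """
    rng = np.random.default_rng(seed)
    brain = atlas.labels > 0
    nx = config.grid_shape[0]
    hemisphere = "left" if rng.random() < 0.5 else "right"
    hemi_mask = np.zeros(config.grid_shape, dtype=bool)
    if hemisphere == "left":
        hemi_mask[: nx // 2] = True
    else:
        hemi_mask[nx // 2:] = True

    voxel_vol = float(np.prod(config.voxel_size))
    target_ml = float(
        rng.lognormal(config.lesion_volume_log_mean, config.lesion_volume_log_sd)
    )
    target_voxels = int(round(target_ml * 1000.0 / voxel_vol))
    lesion, truncated = _grow_lesion(brain, hemi_mask, target_voxels, rng)

    values = rng.normal(config.adc_normal_mean, config.adc_normal_sd, config.grid_shape)
    n_lesion = int(lesion.sum())
    if n_lesion:
        values[lesion] = rng.normal(config.adc_lesion_mean, config.adc_lesion_sd, n_lesion)
    values = np.clip(values, 0.0, None)

    affine = atlas.affine
    adc = ADCVolume(values=values, affine=affine)
    truth = PatientTruth(
        patient_id=patient_id,
        lesion_mask=LesionMask(mask=lesion, affine=affine),
        hemisphere=hemisphere,
        truncated=truncated,
        age=_draw_age(rng),
        nihss=int(rng.integers(10, 26)),
    )
    return adc, truth


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def generate_outcomes(
    features: pd.DataFrame, config: SimConfig, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw dichotomized outcomes from the logistic model.

    ``features`` must carry ``age``, ``nihss`` and one ``pct_<id>`` column
    per atlas region. Covariates and regional percentages are standardized
    against the generated sample, so the betas are on a common standardized
    scale. Returns (labels, linear predictor); label 1 = poor outcome.
    """
    for rid in config.effect_regions:
        if f"pct_{rid}" not in features.columns:
            raise ConfigurationError(f"effect region {rid} absent from feature table")
    rng = np.random.default_rng(seed)
    lp = np.full(len(features), config.intercept, dtype=float)
    lp += config.beta_age * _zscore(features["age"].to_numpy())
    lp += config.beta_nihss * _zscore(features["nihss"].to_numpy())
    for rid, beta in zip(config.effect_regions, config.betas_region):
        lp += beta * _zscore(features[f"pct_{rid}"].to_numpy())
    p = 1.0 / (1.0 + np.exp(-lp))
    labels = (rng.random(len(features)) < p).astype(int)
    return labels, lp


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a full cohort: atlas, per-patient ADC volumes and truth,
    and outcomes drawn from the configured logistic model."""
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_patients + 2)
    atlas = generate_atlas(
        config.grid_shape,
        config.n_gm_regions_per_hemi,
        config.n_wm_regions_per_hemi,
        int(seeds[0]),
        voxel_size=config.voxel_size,
    )
    brain_mask = LesionMask(mask=atlas.labels > 0, affine=atlas.affine)
    width = max(3, len(str(config.n_patients)))
    volumes: dict[str, ADCVolume] = {}
    truth: list[PatientTruth] = []
    for i in range(config.n_patients):
        pid = f"p{i + 1:0{width}d}"
        adc, rec = generate_patient(config, atlas, int(seeds[2 + i]), pid)
        volumes[pid] = adc
        truth.append(rec)

    # true regional percentages feed the outcome model
    rows = {}
    for rec in truth:
        rows[rec.patient_id] = region_percentages(rec.lesion_mask, atlas)
    pct = pd.DataFrame(rows).T
    pct.columns = [f"pct_{int(c)}" for c in pct.columns]
    feats = pd.DataFrame(
        {
            "age": [t.age for t in truth],
            "nihss": [t.nihss for t in truth],
        },
        index=[t.patient_id for t in truth],
    ).join(pct)
    labels, lp = generate_outcomes(feats, config, int(seeds[1]))
    for rec, y, eta in zip(truth, labels, lp):
        rec.outcome = int(y)
        rec.linear_predictor = float(eta)
    return SyntheticCohort(
        atlas=atlas, brain_mask=brain_mask, volumes=volumes, truth=truth, config=config
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write a cohort directory: NIfTI volumes, label TSV, clinical CSV and
    the config as YAML."""
    import yaml

    from .io import write_mask, write_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_mask(cohort.brain_mask, out / "brain_mask.nii.gz")
    import nibabel as nib

    nib.save(
        nib.Nifti1Image(cohort.atlas.labels.astype(np.int16), cohort.atlas.affine),
        out / "atlas.nii.gz",
    )
    cohort.atlas.table.to_csv(out / "atlas_labels.tsv", sep="\t", index=False)
    for pid, adc in cohort.volumes.items():
        write_volume(adc, out / f"adc_{pid}.nii.gz")
    for rec in cohort.truth:
        write_mask(rec.lesion_mask, out / f"truth_{rec.patient_id}.nii.gz")
    cohort.clinical_table().to_csv(out / "clinical.csv", index=False)
    def _native(v):
        if isinstance(v, (tuple, list)):
            return [_native(x) for x in v]
        if isinstance(v, np.integer):
            return int(v)
        if isinstance(v, np.floating):
            return float(v)
        return v

    cfg = {
        k: _native(getattr(cohort.config, k))
        for k in cohort.config.__dataclass_fields__
    }
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    return out
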