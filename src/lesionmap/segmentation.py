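"""Ischemic lesion segmentation from apparent diffusion coefficient (ADC) maps.

Acutely ischemic tissue shows restricted diffusion, i.e. low ADC. A fixed
quantitative threshold of 615 (in units of 1e-6 mm^2/s) separates ischemic
from normal parenchyma on pretreatment ADC maps; the segmentation here is
that threshold restricted to a brain mask, followed by a small deterministic
connected-component filter standing in for manual mask cleanup.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

#: Published ADC cutoff for acute ischemia, 1e-6 mm^2/s. Voxels strictly
#: below this value are considered ischemic.
DEFAULT_ADC_THRESHOLD = 615.0


class GridMismatchError(ValueError):
    """Two volumes that must share a voxel grid do not."""


class EmptyInputError(ValueError):
    """An operation received an empty mask where voxels are required."""


@dataclass(frozen=True)
class ADCVolume:
    """A 3D ADC map with voxel geometry.

    ``values`` are in 1e-6 mm^2/s and must be non-negative. ``affine`` is the
    4x4 voxel-to-world map; voxel size is derived from it.
    """

    values: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError(f"ADC volume must be 3D, got shape {values.shape}")
        if np.any(values < 0):
            raise ValueError("ADC values must be non-negative")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm, per axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))


@dataclass(frozen=True)
class LesionMask:
    """A binary 3D lesion mask on the same grid as its source volume."""

    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        mask = np.asarray(self.mask)
        if mask.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {mask.shape}")
        object.__setattr__(self, "mask", mask.astype(bool))
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class SegmentationParams:
    """Threshold and cleanup parameters.

    ``adc_threshold`` is strict: a voxel enters the mask iff its ADC value is
    < threshold. ``min_component_voxels`` removes small connected components
    under the given ``connectivity`` (6 = faces only, 26 = faces+edges+corners).
    """

    adc_threshold: float = DEFAULT_ADC_THRESHOLD
    min_component_voxels: int = 5
    connectivity: int = 6

    def __post_init__(self):
        if self.adc_threshold <= 0:
            raise ValueError("adc_threshold must be positive")
        if self.min_component_voxels < 0:
            raise ValueError("min_component_voxels must be >= 0")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)


def segment_lesion(
    adc: ADCVolume,
    brain: np.ndarray,
    params: SegmentationParams | None = None,
) -> LesionMask:
    """Threshold an ADC volume inside the brain mask and clean the result.

    A voxel is ischemic iff it lies inside ``brain`` and its ADC value is
    strictly below ``params.adc_threshold``; components smaller than
    ``params.min_component_voxels`` are then removed.

    Raises
    ------
    GridMismatchError
        If the brain mask is not on the ADC grid.
    EmptyInputError
        If the brain mask contains no voxels.
    """
    params = params or SegmentationParams()
    brain = np.asarray(brain).astype(bool)
    if brain.shape != adc.shape:
        raise GridMismatchError(
            f"brain mask shape {brain.shape} != ADC shape {adc.shape}"
        )
    if not brain.any():
        raise EmptyInputError("brain mask is empty")
    raw = LesionMask(mask=brain & (adc.values < params.adc_threshold), affine=adc.affine)
    return clean_mask(raw, params)


def clean_mask(mask: LesionMask, params: SegmentationParams | None = None) -> LesionMask:
    """Remove connected components smaller than ``min_component_voxels``.

    Idempotent: cleaning an already-cleaned mask is a no-op.
    """
    params = params or SegmentationParams()
    if params.min_component_voxels == 0 or not mask.mask.any():
        return mask
    labeled, n = ndimage.label(mask.mask, structure=_structure(params.connectivity))
    if n == 0:
        return mask
    sizes = np.bincount(labeled.ravel())
    keep = sizes >= params.min_component_voxels
    keep[0] = False
    return replace(mask, mask=keep[labeled])


def resample_mask_nn(
    mask: LesionMask,
    target_shape: tuple[int, int, int],
    voxel_map: np.ndarray,
) -> LesionMask:
    """Nearest-neighbour resampling of a binary mask onto a new grid.

    ``voxel_map`` is a 4x4 homogeneous matrix mapping source voxel indices to
    target voxel indices; it must be invertible. The identity map returns a
    mask equal to the input. Output affine is composed so world coordinates
    are preserved.
    """
    voxel_map = np.asarray(voxel_map, dtype=float)
    if voxel_map.shape != (4, 4):
        raise ValueError("voxel_map must be a 4x4 homogeneous matrix")
    if abs(np.linalg.det(voxel_map[:3, :3])) < 1e-12:
        raise ValueError("voxel_map is singular")
    inv = np.linalg.inv(voxel_map)  # target voxel -> source voxel
    out = ndimage.affine_transform(
        mask.mask.astype(np.float32),
        matrix=inv[:3, :3],
        offset=inv[:3, 3],
        output_shape=tuple(target_shape),
        order=0,
        mode="constant",
        cval=0.0,
    )
    new_affine = mask.affine @ inv
    return LesionMask(mask=out > 0.5, affine=new_affine)
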