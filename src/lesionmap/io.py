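"""NIfTI and tabular readers/writers with a single internal orientation.

All volumes are canonicalized to the closest-to-RAS orientation on read, so
the left hemisphere is consistently at negative world x regardless of how a
file was stored. Masks stored as floats are accepted and binarized, with a
warning when values outside {0, 1} are present. NIfTI headers carry no
intensity units, so ADC maps are paired with a JSON sidecar stating
1e-6 mm^2/s on write.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .features import AtlasParcellation
from .segmentation import ADCVolume, LesionMask

ADC_UNITS = "1e-6 mm^2/s"


class FormatError(ValueError):
    """A file is not a readable 3D NIfTI volume of the expected kind."""


def _load_canonical(path: str | Path):
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as err:  # nibabel raises several types for bad files
        raise FormatError(f"{path}: not a readable NIfTI file ({err})") from err
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return data, np.asarray(img.affine)


def read_volume(path: str | Path) -> ADCVolume:
    """Read an ADC map; values must be non-negative scalars."""
    data, affine = _load_canonical(path)
    return ADCVolume(values=data.astype(float), affine=affine)


def read_mask(path: str | Path) -> LesionMask:
    """Read a binary mask, binarizing float storage with a warning on
    values outside {0, 1}."""
    data, affine = _load_canonical(path)
    uniq = np.unique(data)
    if not np.all(np.isin(uniq, (0, 1))):
        warnings.warn(
            f"{path}: mask has values outside {{0, 1}} "
            f"({uniq[:5].tolist()}...); binarizing at > 0.5"
        )
        data = data > 0.5
    return LesionMask(mask=data.astype(bool), affine=affine)


def read_atlas(volume_path: str | Path, table_path: str | Path) -> AtlasParcellation:
    """Read a label volume plus its TSV label table.

    Labels present in the grid but absent from the table raise a
    reconciliation error (via the AtlasParcellation contract).
    """
    data, affine = _load_canonical(volume_path)
    if not np.allclose(data, np.round(data)):
        raise FormatError(f"{volume_path}: atlas labels must be integers")
    table = pd.read_csv(table_path, sep="\t")
    return AtlasParcellation(labels=data.astype(np.int32), table=table, affine=affine)


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    required = {"patient_id", "age", "nihss", "mrs_binary"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: clinical table missing columns {sorted(missing)}")
    return df


def write_volume(volume: ADCVolume, path: str | Path) -> None:
    path = Path(path)
    nib.save(nib.Nifti1Image(volume.values.astype(np.float32), volume.affine), str(path))
    sidecar = path.with_name(path.name.split(".")[0] + ".json")
    sidecar.write_text(json.dumps({"units": ADC_UNITS}) + "\n")


def write_mask(mask: LesionMask, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8), mask.affine), str(path))


def write_table(df: pd.DataFrame, path: str | Path, header_comment: str = "") -> None:
    """CSV with optional '#'-prefixed provenance header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_comment.splitlines():
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
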