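"""NIfTI-1 readers/writers and cohort-manifest parsing.

Volumes are exchanged as NIfTI-1 (.nii / .nii.gz) via nibabel.  On read,
masks are validated to {0,1} and probability maps to [0,1]; tiny float
excursions of a probability map (within 1e-6 outside the unit interval,
as produced by float32 round-trips of upstream tools) are clamped with a
warning, anything larger is an error.  On write, masks are stored as
unsigned 8-bit and scalar maps as 32-bit float.

A cohort manifest is a CSV with one row per subject pointing at the
per-subject volumes plus scalar covariates; see :class:`CohortManifest`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import BinaryMask, ProbabilityMap, VoxelGrid

__all__ = [
    "FormatError",
    "ValidationError",
    "read_volume",
    "write_volume",
    "read_binary_mask",
    "read_probability_map",
    "CohortManifest",
    "read_manifest",
]

logger = logging.getLogger(__name__)

#: tolerated float excursion of probability maps outside [0, 1]
PROB_CLAMP_TOL = 1e-6

MANIFEST_REQUIRED = ["subject_id", "tract_path", "lesion_path"]
MANIFEST_PATHS = ["tract_path", "lesion_path", "exclusion_path",
                  "ad_path", "rd_path", "md_path", "fa_path"]


class FormatError(ValueError):
    """The file is not a readable NIfTI-1 volume."""


class ValidationError(ValueError):
    """The volume's values violate its declared type contract."""


def read_volume(path: str | Path, space_tag: str = "unspecified") -> VoxelGrid:
    """Read a NIfTI volume as a :class:`VoxelGrid`.

    Voxel dimensions come from the header zooms, the affine from the
    best available NIfTI transform.
    """
    path = Path(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoxelGrid(data, zooms, np.asarray(img.affine), space_tag)


def write_volume(vol: VoxelGrid | BinaryMask | ProbabilityMap, path: str | Path) -> None:
    """Write a volume as NIfTI-1: masks as uint8, scalar maps as float32."""
    path = Path(path)
    if isinstance(vol, BinaryMask):
        data = vol.data.astype(np.uint8)
        grid = vol.grid
    elif isinstance(vol, ProbabilityMap):
        data = vol.data.astype(np.float32)
        grid = vol.grid
    else:
        data = vol.data.astype(np.float32)
        grid = vol
    img = nib.Nifti1Image(data, grid.affine)
    img.header.set_zooms(grid.voxel_dims)
    nib.save(img, path)


def read_binary_mask(path: str | Path, space_tag: str = "unspecified") -> BinaryMask:
    """Read a NIfTI volume as a binary mask; non-{0,1} values are an error."""
    grid = read_volume(path, space_tag)
    vals = grid.data
    if not np.isin(vals, (0.0, 1.0)).all():
        bad = np.unique(vals[~np.isin(vals, (0.0, 1.0))])
        raise ValidationError(
            f"{path}: mask contains values other than 0/1 (e.g. {bad[:3]})"
        )
    return BinaryMask(grid)


def read_probability_map(path: str | Path, space_tag: str = "unspecified") -> ProbabilityMap:
    """Read a NIfTI volume as a probability map.

    Values within ``1e-6`` outside [0, 1] are clamped with a warning
    (float32 round-trip slack); larger excursions raise
    :class:`ValidationError`.
    """
    grid = read_volume(path, space_tag)
    vals = grid.data
    lo, hi = float(np.nanmin(vals)), float(np.nanmax(vals))
    if lo < -PROB_CLAMP_TOL or hi > 1.0 + PROB_CLAMP_TOL:
        raise ValidationError(
            f"{path}: probability values out of [0, 1] beyond tolerance "
            f"(range [{lo}, {hi}])"
        )
    if lo < 0.0 or hi > 1.0:
        warnings.warn(f"{path}: clamping probability values within {PROB_CLAMP_TOL} "
                      "outside [0, 1]", stacklevel=2)
        vals = np.clip(vals, 0.0, 1.0)
        grid = grid.like(vals)
    return ProbabilityMap(grid)


@dataclass(frozen=True)
class CohortManifest:
    """A validated cohort table.

    Required columns: ``subject_id``, ``tract_path``, ``lesion_path``.
    Optional: ``exclusion_path``, ``ad_path``/``rd_path``/``md_path``/
    ``fa_path``, ``brain_volume_ml``, ``scaling_factor`` (default 1.0),
    ``diffusivity_units`` (``"1e-3 mm2/s"``, the default, or ``"mm2/s"``
    — maps in mm^2/s are rescaled by 1000 on load so all internal values
    are in 1e-3 mm^2/s).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"manifest is missing required columns: {missing}")
        if len(self.table) == 0:
            raise ValueError("manifest is empty")
        ids = self.table["subject_id"]
        if ids.duplicated().any():
            raise ValueError(f"duplicate subject_id: {sorted(ids[ids.duplicated()])}")

    def __len__(self) -> int:
        return len(self.table)

    def rows(self):
        for _, row in self.table.iterrows():
            yield row


def has_value(row: pd.Series, col: str) -> bool:
    """True if a manifest row has a usable (non-empty, non-NaN) value."""
    if col not in row.index:
        return False
    v = row[col]
    if isinstance(v, str):
        return v != ""
    return bool(pd.notna(v))


def read_manifest(path: str | Path, check_paths: bool = True) -> CohortManifest:
    """Load and validate a cohort manifest CSV.

    All referenced file paths must exist at load time (relative paths are
    resolved against the manifest's directory).
    """
    path = Path(path)
    table = pd.read_csv(path)
    manifest = CohortManifest(table)
    base = path.parent
    resolved = table.copy()
    for col in MANIFEST_PATHS:
        if col not in table.columns:
            continue
        for i, value in table[col].items():
            if not isinstance(value, str) or value == "":
                continue
            p = Path(value)
            if not p.is_absolute():
                p = base / p
            if check_paths and not p.exists():
                raise FileNotFoundError(
                    f"manifest row {table['subject_id'][i]!r}: {col} {p} does not exist"
                )
            resolved.loc[i, col] = str(p)
    return CohortManifest(resolved)
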