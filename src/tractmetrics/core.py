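"""Grid-aware voxel containers and elementary mask operations.

Every quantity in this package lives on a :class:`VoxelGrid`: a 3D scalar
array with physical voxel dimensions (mm) and a voxel-to-world affine.
Two restricted views are used throughout:

* :class:`BinaryMask` — values in {0, 1}; individual tract reconstructions,
  T2 lesion masks, anatomical exclusion masks.
* :class:`ProbabilityMap` — values in [0, 1]; tract templates and atlases,
  where a voxel's value is the fraction of a reference cohort whose tract
  occupies it.

All arithmetic happens in voxel space.  Registration and resampling are
upstream concerns: inputs are required to share a grid exactly, and any
mismatch raises :class:`GridMismatch` rather than being silently resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridMismatch",
    "EmptyRegion",
    "VoxelGrid",
    "BinaryMask",
    "ProbabilityMap",
    "check_same_grid",
    "require_same_grid",
    "binarize",
    "dice",
    "mask_exclude",
]

#: absolute tolerance on voxel dimensions (mm) when comparing grids
DIM_ATOL = 1e-6
#: absolute tolerance on affine entries when comparing grids
AFFINE_ATOL = 1e-4


class GridMismatch(ValueError):
    """Two volumes that must share a voxel grid do not."""


class EmptyRegion(ValueError):
    """A weighted region has zero total weight; a mean is undefined."""


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D scalar field with voxel dimensions (mm) and a world affine.

    Parameters
    ----------
    data
        3D array of scalars.  Stored as float64 and made read-only.
    voxel_dims
        Edge lengths of one voxel in mm, strictly positive.
    affine
        4x4 voxel-to-world transform.  Carried for I/O round-trips only;
        computation is done in voxel space.
    space_tag
        Free-text label of the coordinate space, e.g. ``"ICBM2009a"`` or
        ``"subject-native"``.
    """

    data: np.ndarray
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    space_tag: str = "unspecified"

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError(f"data must be 3D, got ndim={data.ndim}")
        dims = tuple(float(d) for d in self.voxel_dims)
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise ValueError(f"voxel_dims must be 3 positive lengths, got {self.voxel_dims}")
        affine = np.asarray(self.affine, dtype=np.float64)
        if affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {affine.shape}")
        data = data.copy()
        data.flags.writeable = False
        affine = affine.copy()
        affine.flags.writeable = False
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "voxel_dims", dims)
        object.__setattr__(self, "affine", affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_dims))

    def like(self, data: np.ndarray) -> "VoxelGrid":
        """A new grid with the same geometry and new data."""
        if np.shape(data) != self.shape:
            raise ValueError(f"data shape {np.shape(data)} != grid shape {self.shape}")
        return VoxelGrid(data, self.voxel_dims, self.affine, self.space_tag)


def check_same_grid(a: VoxelGrid, b: VoxelGrid) -> bool:
    """True iff two grids agree in shape, voxel dims, affine and space tag.

    Pure predicate; callers raise :class:`GridMismatch` when it is false.
    Tolerances are absolute: ``1e-6`` mm on voxel dimensions and ``1e-4``
    on affine entries — a mismatch beyond these is a user error, never
    something to resample away.
    """
    if a.shape != b.shape:
        return False
    if not np.allclose(a.voxel_dims, b.voxel_dims, rtol=0.0, atol=DIM_ATOL):
        return False
    if not np.allclose(a.affine, b.affine, rtol=0.0, atol=AFFINE_ATOL):
        return False
    return a.space_tag == b.space_tag


def require_same_grid(a: VoxelGrid, b: VoxelGrid, what: str = "volumes") -> None:
    if not check_same_grid(a, b):
        raise GridMismatch(
            f"{what} are not on the same voxel grid "
            f"(shapes {a.shape} vs {b.shape}, spaces {a.space_tag!r} vs {b.space_tag!r})"
        )


@dataclass(frozen=True)
class BinaryMask:
    """A :class:`VoxelGrid` restricted to values {0, 1}."""

    grid: VoxelGrid

    def __post_init__(self) -> None:
        vals = self.grid.data
        if not np.isin(vals, (0.0, 1.0)).all():
            bad = vals[~np.isin(vals, (0.0, 1.0))]
            raise ValueError(f"BinaryMask values must be 0 or 1; found e.g. {bad.flat[0]!r}")

    @classmethod
    def from_array(cls, data, voxel_dims=(1.0, 1.0, 1.0), affine=None,
                   space_tag: str = "unspecified") -> "BinaryMask":
        if affine is None:
            affine = np.eye(4)
        return cls(VoxelGrid(np.asarray(data, dtype=bool).astype(np.float64),
                             voxel_dims, affine, space_tag))

    @property
    def data(self) -> np.ndarray:
        return self.grid.data

    @property
    def n_voxels(self) -> int:
        """Number of voxels set to 1."""
        return int(self.data.sum())

    @property
    def volume_ml(self) -> float:
        """Mask volume in mL (voxel count x voxel volume / 1000)."""
        return self.n_voxels * self.grid.voxel_volume / 1000.0

    def as_probability(self) -> "ProbabilityMap":
        """View the mask as a degenerate {0,1}-valued probability map."""
        return ProbabilityMap(self.grid)


@dataclass(frozen=True)
class ProbabilityMap:
    """A :class:`VoxelGrid` restricted to values in [0, 1]."""

    grid: VoxelGrid

    def __post_init__(self) -> None:
        vals = self.grid.data
        if vals.size and (np.nanmin(vals) < 0.0 or np.nanmax(vals) > 1.0):
            raise ValueError(
                f"ProbabilityMap values must lie in [0, 1]; "
                f"found range [{np.nanmin(vals)}, {np.nanmax(vals)}]"
            )
        if np.isnan(vals).any():
            raise ValueError("ProbabilityMap values must not be NaN")

    @classmethod
    def from_array(cls, data, voxel_dims=(1.0, 1.0, 1.0), affine=None,
                   space_tag: str = "unspecified") -> "ProbabilityMap":
        if affine is None:
            affine = np.eye(4)
        return cls(VoxelGrid(data, voxel_dims, affine, space_tag))

    @property
    def data(self) -> np.ndarray:
        return self.grid.data

    @property
    def weight_sum(self) -> float:
        """Total probability weight (sum of voxel values)."""
        return float(self.data.sum())

    @property
    def volume_ml(self) -> float:
        """Probability-weighted volume in mL: voxel_volume x sum(w) / 1000."""
        return self.weight_sum * self.grid.voxel_volume / 1000.0


def binarize(p: ProbabilityMap, threshold: float, inclusive: bool = True) -> BinaryMask:
    """Threshold a probability map into a binary mask.

    Voxels *below* the threshold are zeroed; with ``inclusive=True`` (the
    default) a voxel exactly at the threshold survives (rule ``value >= t``).

    Parameters
    ----------
    threshold
        Probability cutoff, strictly inside (0, 1).
    inclusive
        If False, the rule is ``value > t`` instead; exposed for
        sensitivity analysis.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie strictly in (0, 1), got {threshold}")
    if inclusive:
        kept = p.data >= threshold
    else:
        kept = p.data > threshold
    return BinaryMask(p.grid.like(kept.astype(np.float64)))


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|).

    By convention two empty masks are identical and score 1.0.
    """
    require_same_grid(a.grid, b.grid, "masks")
    na, nb = a.n_voxels, b.n_voxels
    if na + nb == 0:
        return 1.0
    inter = int(np.logical_and(a.data > 0, b.data > 0).sum())
    return 2.0 * inter / (na + nb)


def mask_exclude(target: ProbabilityMap, exclusion: BinaryMask) -> ProbabilityMap:
    """Zero the target map wherever the exclusion mask is 1.

    Used to remove anatomy that must not contribute to tract metrics
    (e.g. the thalamus at the anterior end of the optic radiation).
    Idempotent; voxels outside the exclusion are untouched.
    """
    require_same_grid(target.grid, exclusion.grid, "map and exclusion mask")
    out = target.data.copy()
    out[exclusion.data > 0] = 0.0
    return ProbabilityMap(target.grid.like(out))
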