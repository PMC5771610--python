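"""Per-subject probability-weighted tract volumetry and diffusivity means.

The central quantities, for a tract map w (binary or probability-weighted)
and a binarised lesion mask v on the same grid:

* weighted tract volume      V  = r * sum_i w_i            (r = voxel volume, mm^3)
* weighted lesion volume     VL = r * sum_i v_i * w_i
* weighted diffusivity mean  D  = sum_i D_i w_i / sum_i w_i

Tract voxels overlapping the lesion mask form the *lesional* compartment;
the rest is the *non-lesional* (normal-appearing) compartment.  The two
compartments partition the tract's weight exactly, so weighted volumes and
weight sums are conserved and the whole-tract mean is the weight-mixture
of the compartment means.

``r`` in the volume formulas is the voxel *volume* in mm^3 (the only
reading with correct units); outputs are converted to mL.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    BinaryMask,
    EmptyRegion,
    ProbabilityMap,
    VoxelGrid,
    mask_exclude,
    require_same_grid,
)

__all__ = [
    "DiffusivitySet",
    "TractMetrics",
    "weighted_lesion_volume",
    "partition_lesional",
    "weighted_mean_diffusivity",
    "compute_tract_metrics",
    "lesion_frequency_map",
]

logger = logging.getLogger(__name__)

DIFFUSIVITY_METRICS = ("ad", "rd", "md", "fa")
COMPARTMENTS = ("whole", "lesional", "nonlesional")


@dataclass(frozen=True)
class DiffusivitySet:
    """Co-registered AD, RD, MD and FA scalar maps for one subject.

    AD/RD/MD are in units of 1e-3 mm^2/s (the conventional scale for
    white-matter water diffusion at 3T); FA is dimensionless in [0, 1].
    Undefined voxels (background, CSF-masked) are NaN and are excluded
    pairwise from every weighted mean.

    Validated on construction: the four grids must match, FA must lie in
    [0, 1] where defined, and AD >= RD voxel-wise where both are defined
    (the axial eigenvalue bounds the radial average by construction of the
    diffusion tensor).
    """

    ad: VoxelGrid
    rd: VoxelGrid
    md: VoxelGrid
    fa: VoxelGrid

    def __post_init__(self) -> None:
        for name, g in (("rd", self.rd), ("md", self.md), ("fa", self.fa)):
            require_same_grid(self.ad, g, f"ad and {name} maps")
        fa = self.fa.data
        defined = ~np.isnan(fa)
        if defined.any() and (np.nanmin(fa) < 0.0 or np.nanmax(fa) > 1.0):
            raise ValueError("FA must lie in [0, 1] where defined")
        both = ~np.isnan(self.ad.data) & ~np.isnan(self.rd.data)
        if both.any() and np.any(self.ad.data[both] < self.rd.data[both] - 1e-9):
            raise ValueError("AD must be >= RD voxel-wise where both are defined")

    def as_dict(self) -> dict[str, VoxelGrid]:
        return {"ad": self.ad, "rd": self.rd, "md": self.md, "fa": self.fa}


@dataclass(frozen=True)
class TractMetrics:
    """Per-subject tract volumetry and compartment diffusivity summary.

    Volumes are in mL.  ``mean_<metric>_<compartment>`` fields hold the 12
    probability-weighted diffusivity means (4 metrics x whole / lesional /
    non-lesional); a compartment with zero weight (e.g. no lesions) leaves
    its means NaN.  ``normalized_tract_volume_ml`` is tract volume times
    the user-supplied head-size scaling factor; the brain-volume fraction
    is in percent.
    """

    subject_id: str
    tract_volume_ml: float
    lesion_volume_ml: float
    lesional_volume_ml: float
    nonlesional_volume_ml: float
    normalized_tract_volume_ml: float
    tract_volume_fraction_of_brain: float = math.nan
    mean_ad_whole: float = math.nan
    mean_rd_whole: float = math.nan
    mean_md_whole: float = math.nan
    mean_fa_whole: float = math.nan
    mean_ad_lesional: float = math.nan
    mean_rd_lesional: float = math.nan
    mean_md_lesional: float = math.nan
    mean_fa_lesional: float = math.nan
    mean_ad_nonlesional: float = math.nan
    mean_rd_nonlesional: float = math.nan
    mean_md_nonlesional: float = math.nan
    mean_fa_nonlesional: float = math.nan

    def __post_init__(self) -> None:
        for name in ("tract_volume_ml", "lesion_volume_ml",
                     "lesional_volume_ml", "nonlesional_volume_ml",
                     "normalized_tract_volume_ml"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        resid = abs(self.lesional_volume_ml + self.nonlesional_volume_ml - self.tract_volume_ml)
        scale = max(self.tract_volume_ml, 1.0)
        if resid > 1e-9 * scale:
            raise ValueError("lesional + nonlesional volume must equal tract volume")

    def to_dict(self) -> dict[str, object]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def weighted_lesion_volume(lesions: BinaryMask, tract: ProbabilityMap) -> float:
    """Probability-weighted lesion volume within a tract, in mL.

    ``voxel_volume * sum_i (lesion_i * weight_i) / 1000``.  With a binary
    tract map this reduces to the intersection voxel count times the voxel
    volume.
    """
    require_same_grid(lesions.grid, tract.grid, "lesion mask and tract map")
    s = float((lesions.data * tract.data).sum())
    return s * tract.grid.voxel_volume / 1000.0


def partition_lesional(
    tract: ProbabilityMap, lesions: BinaryMask
) -> tuple[ProbabilityMap, ProbabilityMap]:
    """Split a tract map into lesional and non-lesional compartments.

    Tract voxels overlapping the lesion mask keep their weight in the
    lesional output and are zero in the non-lesional output, and vice
    versa; the two outputs sum voxel-wise to the input exactly.
    """
    require_same_grid(tract.grid, lesions.grid, "tract map and lesion mask")
    inside = lesions.data > 0
    les = np.where(inside, tract.data, 0.0)
    nonles = np.where(inside, 0.0, tract.data)
    return (
        ProbabilityMap(tract.grid.like(les)),
        ProbabilityMap(tract.grid.like(nonles)),
    )


def weighted_mean_diffusivity(d: VoxelGrid, tract: ProbabilityMap) -> float:
    """Probability-weighted mean of a scalar map over a tract.

    ``sum_i D_i w_i / sum_i w_i`` over voxels where D is defined (non-NaN);
    NaN voxels are dropped from numerator and denominator alike.  Raises
    :class:`EmptyRegion` if no weight survives the NaN exclusion.
    """
    require_same_grid(d, tract.grid, "scalar map and tract map")
    vals = d.data
    w = tract.data
    defined = ~np.isnan(vals)
    n_dropped = int(((w > 0) & ~defined).sum())
    if n_dropped:
        logger.debug("weighted mean: dropped %d weighted voxels with undefined values", n_dropped)
    wsum = float(w[defined].sum())
    if wsum <= 0.0:
        raise EmptyRegion("tract weight is zero after NaN exclusion; mean undefined")
    return float((vals[defined] * w[defined]).sum() / wsum)


def _compartment_means(
    diffusivity: DiffusivitySet, region: ProbabilityMap
) -> dict[str, float]:
    """Weighted means of the four metrics over one compartment; NaN if empty."""
    out: dict[str, float] = {}
    for name, grid in diffusivity.as_dict().items():
        try:
            out[name] = weighted_mean_diffusivity(grid, region)
        except EmptyRegion:
            out[name] = math.nan
    return out


def compute_tract_metrics(
    subject_id: str,
    tract: ProbabilityMap | BinaryMask,
    lesions: BinaryMask,
    diffusivity: DiffusivitySet | None = None,
    exclusion: BinaryMask | None = None,
    brain_volume_ml: float | None = None,
    scaling_factor: float = 1.0,
) -> TractMetrics:
    """Assemble the full per-subject tract metrics record.

    The exclusion mask (if any) is applied to the tract map before every
    other computation.  Binary tract masks are accepted and treated as
    degenerate {0,1} probability maps, so tractography-derived and
    template-derived tracts flow through identical formulas.

    ``scaling_factor`` is a head-size normalisation (e.g. the SIENAX
    volumetric scaling factor): normalized volume = absolute volume x
    factor.  If ``brain_volume_ml`` is given, the tract volume is also
    expressed as a percentage of (equally normalized) brain volume.

    An empty lesional compartment is not an error: its diffusivity means
    are simply NaN.
    """
    if scaling_factor <= 0:
        raise ValueError(f"scaling_factor must be > 0, got {scaling_factor}")
    if isinstance(tract, BinaryMask):
        tract = tract.as_probability()
    if exclusion is not None:
        tract = mask_exclude(tract, exclusion)
    require_same_grid(tract.grid, lesions.grid, "tract map and lesion mask")

    lesional, nonlesional = partition_lesional(tract, lesions)
    tract_vol = tract.volume_ml
    lesion_vol = weighted_lesion_volume(lesions, tract)
    norm_vol = tract_vol * scaling_factor
    if brain_volume_ml is not None and brain_volume_ml > 0:
        frac = norm_vol / (brain_volume_ml * scaling_factor) * 100.0
    else:
        frac = math.nan

    means: dict[str, float] = {}
    if diffusivity is not None:
        require_same_grid(tract.grid, diffusivity.ad, "tract map and diffusivity maps")
        for comp, region in (
            ("whole", tract),
            ("lesional", lesional),
            ("nonlesional", nonlesional),
        ):
            for name, value in _compartment_means(diffusivity, region).items():
                means[f"mean_{name}_{comp}"] = value

    return TractMetrics(
        subject_id=subject_id,
        tract_volume_ml=tract_vol,
        lesion_volume_ml=lesion_vol,
        lesional_volume_ml=lesional.volume_ml,
        nonlesional_volume_ml=nonlesional.volume_ml,
        normalized_tract_volume_ml=norm_vol,
        tract_volume_fraction_of_brain=frac,
        **means,
    )


def lesion_frequency_map(
    lesion_masks: Sequence[BinaryMask], tract: ProbabilityMap
) -> ProbabilityMap:
    """Voxel-wise lesion frequency across subjects, within the tract support.

    Each voxel holds the fraction of subjects with a lesion there,
    restricted to voxels where the tract weight is positive (zero outside).
    Used to map where along a tract a cohort's lesions concentrate.
    """
    if len(lesion_masks) == 0:
        raise ValueError("need at least one lesion mask")
    for m in lesion_masks:
        require_same_grid(tract.grid, m.grid, "tract map and lesion mask")
    acc = np.zeros(tract.grid.shape, dtype=np.float64)
    for m in lesion_masks:
        acc += m.data
    acc /= len(lesion_masks)
    acc[tract.data <= 0] = 0.0
    return ProbabilityMap(tract.grid.like(acc))
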