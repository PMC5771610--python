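"""Synthetic voxel phantoms with known ground truth.

The phantom emulates the statistical structure of a tract-specific MS
imaging study, not its anatomy:

* a common curved tube (an analytic arc standing in for a white-matter
  bundle running from a "geniculate" anterior point to an "occipital"
  posterior region) defines the reference tract;
* each subject's tract is the tube displaced by smooth random jitter
  (low-order sinusoidal modes plus a global shift), so an ensemble of
  subjects is a set of jittered realizations of one probability map;
* focal lesions are spheres whose centres are drawn along the tube with a
  placement bias toward its middle third — the periventricular segment,
  where MS lesions concentrate;
* diffusivity maps hold a per-subject non-lesional baseline per metric,
  an additive lesional offset inside lesions (AD/RD/MD raised, FA
  lowered), and i.i.d. Gaussian voxel noise; voxels outside the "brain"
  ellipsoid are NaN.

Default diffusivity parameters are realistic 3T white-matter values
(non-lesional AD 1.17, RD 0.63, MD 0.81 x 1e-3 mm^2/s, FA 0.38; lesional
AD 1.46, RD 0.82, MD 1.03, FA 0.37), so phantom outputs land in the range
a real cohort would produce.

Every subject carries a truth record (true volumes, configured
compartment means, the seed), so parameter recovery is checkable to
closed-form tolerances: binary-mask volumetry is exact counting, and a
compartment's weighted mean differs from its configured value only by
averaged voxel noise, i.e. within ~noise_sd/sqrt(n_eff).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import BinaryMask, ProbabilityMap, VoxelGrid
from .metrics import DIFFUSIVITY_METRICS, DiffusivitySet, TractMetrics

__all__ = [
    "PhantomConfig",
    "PhantomSubject",
    "generate_cohort",
    "truth_check",
    "tract_thirds",
]

#: non-lesional (normal-appearing white matter) means, 1e-3 mm^2/s except FA
DEFAULT_NONLESIONAL_MEAN = {"ad": 1.17, "rd": 0.63, "md": 0.81, "fa": 0.38}
#: between-subject SD of the non-lesional baseline
DEFAULT_SUBJECT_SD = {"ad": 0.034, "rd": 0.038, "md": 0.030, "fa": 0.031}
#: additive lesional offset (lesions raise diffusivities, lower FA)
DEFAULT_LESIONAL_OFFSET = {"ad": 0.29, "rd": 0.19, "md": 0.22, "fa": -0.01}


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, lesion model and diffusivity model of a synthetic cohort.

    Attributes
    ----------
    shape, voxel_dims
        Grid size in voxels and voxel edge lengths in mm (default a
        40 x 48 x 40 grid of 2 mm isotropic voxels — a downsampled
        hemisphere, large enough for ~2000-voxel tracts).
    tube_radius_vox
        Tract tube radius in voxels.
    jitter_sd_vox
        SD of the per-subject smooth displacement field, in voxels; 0
        makes every subject's tract identical to the reference tube.
    n_jitter_modes
        Number of sinusoidal displacement modes per axis.
    lesion_rate
        Poisson mean of the per-subject lesion count.
    lesion_radius_vox
        (low, high) of the uniform lesion-radius distribution, voxels.
    lesion_center_beta
        (a, b) of the Beta distribution of the along-tract position of
        lesion centres; the symmetric default (3, 3) concentrates lesions
        in the middle third of the tube.
    lesion_offaxis_sd_vox
        SD of the perpendicular scatter of lesion centres around the
        tube's centerline.
    voxel_noise_sd
        SD of i.i.d. Gaussian voxel noise added to every diffusivity map
        (same units as the map).
    seed
        Cohort RNG seed; one shared stream drives all randomness.
    """

    shape: tuple[int, int, int] = (40, 48, 40)
    voxel_dims: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_subjects: int = 10
    tube_radius_vox: float = 3.0
    jitter_sd_vox: float = 1.0
    n_jitter_modes: int = 3
    lesion_rate: float = 3.0
    lesion_radius_vox: tuple[float, float] = (1.5, 3.0)
    lesion_center_beta: tuple[float, float] = (3.0, 3.0)
    lesion_offaxis_sd_vox: float = 2.0
    nonlesional_mean: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NONLESIONAL_MEAN))
    subject_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SUBJECT_SD))
    lesional_offset: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LESIONAL_OFFSET))
    voxel_noise_sd: float = 0.02
    seed: int = 0
    space_tag: str = "phantom-common"

    def __post_init__(self) -> None:
        if self.tube_radius_vox <= 0:
            raise ValueError("tube radius must be positive")
        if self.jitter_sd_vox < 0 or self.voxel_noise_sd < 0:
            raise ValueError("SDs must be >= 0")
        if any(sd < 0 for sd in self.subject_sd.values()):
            raise ValueError("subject SDs must be >= 0")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        for m in ("ad", "rd", "md"):
            if self.lesional_offset[m] < 0:
                raise ValueError(f"lesional {m.upper()} offset must be >= 0 "
                                 "(lesions raise diffusivity)")
        if self.lesional_offset["fa"] > 0:
            raise ValueError("lesional FA offset must be <= 0 (lesions lower FA)")


@dataclass(frozen=True)
class PhantomSubject:
    """One simulated subject plus its ground-truth record."""

    subject_id: str
    tract: BinaryMask
    lesions: BinaryMask
    diffusivity: DiffusivitySet
    truth: dict[str, float]


def _centerline(config: PhantomConfig, n_samples: int = 240) -> np.ndarray:
    """Reference arc through the grid, (n, 3) in voxel coordinates.

    Runs mostly along the second axis ("anterior -> posterior") with a
    lateral bow, mimicking a bundle sweeping around a ventricle.
    """
    nx, ny, nz = config.shape
    t = np.linspace(0.0, 1.0, n_samples)
    x = 0.30 * nx + 0.12 * nx * np.sin(np.pi * t)
    y = 0.18 * ny + (0.82 - 0.18) * ny * t
    z = 0.50 * nz + 0.06 * nz * np.sin(2 * np.pi * t) * 0.5
    return np.column_stack([x, y, z])


def _smooth_jitter(rng: np.random.Generator, t: np.ndarray, sd: float, n_modes: int) -> np.ndarray:
    """Smooth (n, 3) displacement with per-axis marginal SD ~ sd voxels."""
    if sd == 0:
        return np.zeros((t.size, 3))
    disp = np.zeros((t.size, 3))
    # global shift plus sinusoidal modes, variance split evenly
    per = sd / np.sqrt(n_modes + 1)
    for ax in range(3):
        disp[:, ax] += rng.normal(0.0, per)
        for k in range(1, n_modes + 1):
            # sin(k*pi*t) has mean-square 1/2 over [0,1]; scale keeps SD ~ per
            disp[:, ax] += rng.normal(0.0, per * np.sqrt(2)) * np.sin(k * np.pi * t)
    return disp


def _tube_mask(shape: tuple[int, int, int], points: np.ndarray, radius: float) -> np.ndarray:
    """Boolean mask of voxels within `radius` (voxels) of a polyline."""
    marks = np.zeros(shape, dtype=bool)
    idx = np.round(points).astype(int)
    for ax, n in enumerate(shape):
        idx[:, ax] = np.clip(idx[:, ax], 0, n - 1)
    marks[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    dist = ndimage.distance_transform_edt(~marks)
    return dist <= radius


def _stamp_sphere(mask: np.ndarray, center: np.ndarray, radius: float) -> None:
    """Set voxels within `radius` of `center` (both in voxels), in place."""
    lo = np.maximum(np.floor(center - radius).astype(int), 0)
    hi = np.minimum(np.ceil(center + radius).astype(int) + 1, mask.shape)
    if np.any(lo >= hi):
        return
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    grids = np.ogrid[sl]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    mask[sl] |= d2 <= radius**2


def _brain_region(shape: tuple[int, int, int]) -> np.ndarray:
    """Ellipsoidal 'brain' inside which diffusivity is defined."""
    nx, ny, nz = shape
    x, y, z = np.ogrid[:nx, :ny, :nz]
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    return ((x - cx) / (0.48 * nx)) ** 2 + ((y - cy) / (0.48 * ny)) ** 2 + (
        (z - cz) / (0.48 * nz)) ** 2 <= 1.0


def generate_cohort(config: PhantomConfig) -> list[PhantomSubject]:
    """Generate a deterministic cohort of phantom subjects.

    One RNG stream, seeded from ``config.seed``, drives the whole cohort,
    so identical configs produce bit-identical cohorts.  Each subject's
    truth record stores the seed, the true tract and lesion volumes, and
    the configured compartment means against which recovery is checked.
    """
    rng = np.random.default_rng(config.seed)
    t = np.linspace(0.0, 1.0, 240)
    base_line = _centerline(config)
    brain = _brain_region(config.shape)
    affine = np.diag([*config.voxel_dims, 1.0])
    voxel_vol = float(np.prod(config.voxel_dims))

    subjects: list[PhantomSubject] = []
    for i in range(config.n_subjects):
        line = base_line + _smooth_jitter(rng, t, config.jitter_sd_vox, config.n_jitter_modes)
        tract_arr = _tube_mask(config.shape, line, config.tube_radius_vox) & brain

        lesion_arr = np.zeros(config.shape, dtype=bool)
        n_lesions = int(rng.poisson(config.lesion_rate))
        a, b = config.lesion_center_beta
        for _ in range(n_lesions):
            pos = rng.beta(a, b)
            center = line[int(round(pos * (len(line) - 1)))]
            center = center + rng.normal(0.0, config.lesion_offaxis_sd_vox, size=3)
            radius = rng.uniform(*config.lesion_radius_vox)
            _stamp_sphere(lesion_arr, center, radius)
        lesion_arr &= brain

        lesional_arr = tract_arr & lesion_arr
        baseline = {
            m: rng.normal(config.nonlesional_mean[m], config.subject_sd[m])
            for m in DIFFUSIVITY_METRICS
        }
        maps: dict[str, VoxelGrid] = {}
        for m in DIFFUSIVITY_METRICS:
            arr = np.full(config.shape, np.nan)
            vals = np.full(config.shape, baseline[m])
            vals[lesion_arr] += config.lesional_offset[m]
            vals += rng.normal(0.0, config.voxel_noise_sd, size=config.shape)
            arr[brain] = vals[brain]
            maps[m] = VoxelGrid(arr, config.voxel_dims, affine, config.space_tag)
        # enforce tensor-eigenvalue ordering and FA bounds; with default
        # noise these projections are many sigma away from ever acting
        rd_arr = np.minimum(maps["rd"].data, maps["ad"].data)
        maps["rd"] = maps["rd"].like(rd_arr)
        fa_arr = np.clip(maps["fa"].data, 0.0, 1.0)
        maps["fa"] = maps["fa"].like(fa_arr)

        truth: dict[str, float] = {
            "seed": float(config.seed),
            "tract_voxels": float(tract_arr.sum()),
            "lesional_voxels": float(lesional_arr.sum()),
            "tract_volume_ml": tract_arr.sum() * voxel_vol / 1000.0,
            "lesion_volume_ml": lesional_arr.sum() * voxel_vol / 1000.0,
            "voxel_noise_sd": config.voxel_noise_sd,
        }
        for m in DIFFUSIVITY_METRICS:
            truth[f"true_{m}_nonlesional"] = baseline[m]
            truth[f"true_{m}_lesional"] = baseline[m] + config.lesional_offset[m]

        subjects.append(
            PhantomSubject(
                subject_id=f"sub-{i + 1:03d}",
                tract=BinaryMask(VoxelGrid(tract_arr.astype(float), config.voxel_dims,
                                           affine, config.space_tag)),
                lesions=BinaryMask(VoxelGrid(lesion_arr.astype(float), config.voxel_dims,
                                             affine, config.space_tag)),
                diffusivity=DiffusivitySet(**maps),
                truth=truth,
            )
        )
    return subjects


def tract_thirds(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean voxel masks of the anterior / middle / posterior thirds.

    Thirds are bands of the along-tract axis between the reference
    centerline's endpoints; used to test lesion-placement bias.
    """
    line = _centerline(config)
    y0, y1 = line[0, 1], line[-1, 1]
    edges = np.linspace(y0, y1, 4)
    ny = config.shape[1]
    y = np.arange(ny)
    bands = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        band1d = (y >= lo) & (y < hi) if hi < edges[-1] else (y >= lo) & (y <= hi)
        band = np.zeros(config.shape, dtype=bool)
        band[:, band1d, :] = True
        bands.append(band)
    return tuple(bands)  # type: ignore[return-value]


def truth_check(
    cohort: Sequence[PhantomSubject],
    metrics: Sequence[TractMetrics],
    sigma_multiple: float = 4.0,
) -> pd.DataFrame:
    """Per-subject recovery report: recovered metrics vs ground truth.

    Volumes must match exactly (binary-mask volumetry is counting).  A
    compartment's weighted diffusivity mean is the configured mean plus
    averaged voxel noise, so its tolerance is
    ``sigma_multiple * noise_sd / sqrt(n_voxels)`` for that compartment
    (NaN recovered means in empty compartments are skipped).

    Returns a DataFrame with one row per subject x metric x compartment
    plus volume rows; column ``within_tolerance`` flags each check.
    """
    if len(cohort) != len(metrics):
        raise ValueError("cohort and metrics lists differ in length")
    rows: list[dict[str, object]] = []
    for subj, m in zip(cohort, metrics):
        tr = subj.truth
        rows.append({
            "subject_id": subj.subject_id, "quantity": "tract_volume_ml",
            "recovered": m.tract_volume_ml, "truth": tr["tract_volume_ml"],
            "tolerance": 1e-9 * max(tr["tract_volume_ml"], 1.0),
            "error": m.tract_volume_ml - tr["tract_volume_ml"],
        })
        rows.append({
            "subject_id": subj.subject_id, "quantity": "lesion_volume_ml",
            "recovered": m.lesion_volume_ml, "truth": tr["lesion_volume_ml"],
            "tolerance": 1e-9 * max(tr["lesion_volume_ml"], 1.0),
            "error": m.lesion_volume_ml - tr["lesion_volume_ml"],
        })
        n_les = tr["lesional_voxels"]
        n_nonles = tr["tract_voxels"] - n_les
        for metric in DIFFUSIVITY_METRICS:
            for comp, n_vox in (("lesional", n_les), ("nonlesional", n_nonles)):
                rec = getattr(m, f"mean_{metric}_{comp}")
                if n_vox == 0 or np.isnan(rec):
                    continue
                tol = sigma_multiple * tr["voxel_noise_sd"] / np.sqrt(n_vox)
                rows.append({
                    "subject_id": subj.subject_id,
                    "quantity": f"mean_{metric}_{comp}",
                    "recovered": rec, "truth": tr[f"true_{metric}_{comp}"],
                    "tolerance": tol, "error": rec - tr[f"true_{metric}_{comp}"],
                })
    df = pd.DataFrame(rows)
    df["within_tolerance"] = df["error"].abs() <= df["tolerance"]
    return df
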