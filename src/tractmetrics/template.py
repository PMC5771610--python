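"""Probabilistic tract-template construction and Dice-optimal thresholding.

A cohort of individual binary tract masks, all warped to one reference
space upstream, is averaged voxel-wise into a probability template: voxel
value = fraction of subjects whose tract occupies that voxel.  To obtain a
binary template, the map is thresholded over a grid of cutoffs (default
1%..99% in 1% steps) and the cutoff maximizing the mean Dice similarity
coefficient against the individual masks is selected.

Note the deliberate simplification relative to a full registration
pipeline: the Dice comparison happens in the common space of the inputs.
If per-subject native-space comparison is wanted, warp the masks upstream
and pass the warped set — the procedure is otherwise identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    BinaryMask,
    ProbabilityMap,
    binarize,
    require_same_grid,
)

__all__ = [
    "TemplateBuildResult",
    "default_threshold_grid",
    "build_probability_template",
    "optimize_threshold",
    "template_volume",
]


def default_threshold_grid(lo: float = 0.01, hi: float = 0.99, step: float = 0.01) -> np.ndarray:
    """Threshold grid 1%..99% in 1% increments (configurable)."""
    n = int(round((hi - lo) / step)) + 1
    return np.round(np.linspace(lo, hi, n), 10)


@dataclass(frozen=True)
class TemplateBuildResult:
    """Output of :func:`optimize_threshold`.

    Attributes
    ----------
    probability_template
        The voxel-wise average of the input masks.
    optimal_threshold
        Grid threshold with the largest mean Dice against the individuals;
        ties broken toward the lowest threshold.
    binary_template
        ``binarize(probability_template, optimal_threshold)``.
    per_subject_dsc_at_optimum
        Dice of the binary template against each individual mask.
    dsc_curve
        threshold -> mean Dice over subjects, for the full grid (audit).
    dsc_sd_curve
        threshold -> sample SD of Dice over subjects.
    """

    probability_template: ProbabilityMap
    optimal_threshold: float
    binary_template: BinaryMask
    per_subject_dsc_at_optimum: tuple[float, ...]
    dsc_curve: dict[float, float]
    dsc_sd_curve: dict[float, float]

    @property
    def mean_dsc_at_optimum(self) -> float:
        return self.dsc_curve[self.optimal_threshold]


def build_probability_template(masks: Sequence[BinaryMask]) -> ProbabilityMap:
    """Average binary tract masks voxel-wise into a probability template.

    Each voxel of the result equals (number of masks containing the voxel)
    divided by the number of masks, i.e. 0 means present in no subject and
    1 means present in every subject.
    """
    if len(masks) == 0:
        raise ValueError("cannot build a template from an empty mask list")
    ref = masks[0].grid
    for m in masks[1:]:
        require_same_grid(ref, m.grid, "template input masks")
    acc = np.zeros(ref.shape, dtype=np.float64)
    for m in masks:
        acc += m.data
    acc /= len(masks)
    return ProbabilityMap(ref.like(acc))


def template_volume(template: ProbabilityMap) -> float:
    """Probability-weighted volume of a template in mL.

    voxel_volume (mm^3) x sum of voxel weights, divided by 1000.  For a
    template built by :func:`build_probability_template` this equals the
    mean of the individual binary mask volumes (linearity of the average).
    """
    return template.volume_ml


def _counts_ge(sorted_vals: np.ndarray, thresholds: np.ndarray, inclusive: bool) -> np.ndarray:
    """For each t, number of entries with value >= t (or > t)."""
    side = "left" if inclusive else "right"
    return sorted_vals.size - np.searchsorted(sorted_vals, thresholds, side=side)


def optimize_threshold(
    template: ProbabilityMap,
    masks: Sequence[BinaryMask],
    thresholds: np.ndarray | None = None,
    inclusive: bool = True,
) -> TemplateBuildResult:
    """Select the binarization threshold maximizing mean Dice vs the masks.

    For every threshold on the grid the template is binarized and compared
    with each individual mask by Dice; the threshold with the largest mean
    Dice wins, ties resolved toward the lowest threshold (the more
    inclusive template).  The full mean/SD curve is returned for audit.

    The sweep is computed by sorting template values once per mask: at
    threshold t the binary template has ``#{w >= t}`` voxels and its
    intersection with a mask has ``#{w >= t within the mask}`` voxels,
    both monotone step functions of t.  This is algebraically identical to
    binarizing 99 times and counting.

    Subjects with an empty mask contribute Dice 0 at every threshold where
    the binary template is nonempty (with a warning) rather than being
    dropped.
    """
    if thresholds is None:
        thresholds = default_threshold_grid()
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if thresholds.size == 0:
        raise ValueError("threshold grid is empty")
    if np.any(thresholds <= 0.0) or np.any(thresholds >= 1.0):
        raise ValueError("thresholds must lie strictly in (0, 1)")
    if len(masks) == 0:
        raise ValueError("need at least one mask to optimize against")
    for m in masks:
        require_same_grid(template.grid, m.grid, "template and mask")
    if any(m.n_voxels == 0 for m in masks):
        warnings.warn(
            "one or more input masks are empty; they contribute Dice 0 at "
            "every threshold with a nonempty template",
            stacklevel=2,
        )

    flat = template.data.ravel()
    sorted_all = np.sort(flat)
    n_template = _counts_ge(sorted_all, thresholds, inclusive)  # |T(t)|

    dsc = np.empty((len(masks), thresholds.size), dtype=np.float64)
    for i, m in enumerate(masks):
        inside = np.sort(flat[m.data.ravel() > 0])
        inter = _counts_ge(inside, thresholds, inclusive)  # |T(t) ∩ M|
        denom = n_template + inside.size
        with np.errstate(invalid="ignore", divide="ignore"):
            d = 2.0 * inter / denom
        d[denom == 0] = 1.0  # both empty: identical by convention
        dsc[i] = d

    mean_curve = dsc.mean(axis=0)
    sd_curve = dsc.std(axis=0, ddof=1) if len(masks) > 1 else np.zeros_like(mean_curve)
    best = int(np.argmax(mean_curve))  # first max == lowest threshold on a tie
    t_opt = float(thresholds[best])
    binary = binarize(template, t_opt, inclusive=inclusive)
    return TemplateBuildResult(
        probability_template=template,
        optimal_threshold=t_opt,
        binary_template=binary,
        per_subject_dsc_at_optimum=tuple(float(x) for x in dsc[:, best]),
        dsc_curve={float(t): float(v) for t, v in zip(thresholds, mean_curve)},
        dsc_sd_curve={float(t): float(v) for t, v in zip(thresholds, sd_curve)},
    )
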