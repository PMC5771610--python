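"""Pairwise method-agreement statistics.

When the same per-subject quantity (tract volume, lesion volume, a
compartment diffusivity mean) is measured by two or more segmentation
methods, agreement is summarised by:

* Pearson's product-moment correlation (association),
* Bland-Altman analysis: mean paired difference (bias) and the
  +/- 1.96 SD limits of agreement,
* the inter-subject variability coefficient CV% = sample SD / mean x 100
  per method,
* a paired Wilcoxon signed-rank test and one-way ANOVA with Tukey HSD
  post-hoc comparisons for location differences,
* Dice overlap summaries where the methods also produce masks.

Standard hypothesis tests are delegated to scipy.stats; Bland-Altman,
CV% and the Dice summary have no single-call equivalent and are computed
directly.  Normality is not auto-tested: both the parametric and the
rank-based results are reported and the caller chooses, which is the
convention in method-comparison studies.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import BinaryMask, dice

__all__ = [
    "BlandAltman",
    "PairComparison",
    "AgreementReport",
    "pearson",
    "bland_altman",
    "cv_percent",
    "dice_summary",
    "paired_method_comparison",
]


@dataclass(frozen=True)
class BlandAltman:
    """Bias and limits of agreement of paired differences x - y."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int

    def __post_init__(self) -> None:
        if not (self.loa_low <= self.bias <= self.loa_high):
            raise ValueError("limits of agreement must bracket the bias")


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with two-sided p-value.

    Returns ``(nan, nan)`` when either series has zero variance (the
    coefficient is undefined, not an error).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("series must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (math.nan, math.nan)
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def bland_altman(x: Sequence[float], y: Sequence[float], loa_multiplier: float = 1.96) -> BlandAltman:
    """Bland-Altman agreement of two paired series.

    Differences d = x - y; bias = mean(d); sd_diff = sample SD (n-1
    denominator); limits of agreement = bias +/- 1.96 sd (multiplier
    configurable).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - loa_multiplier * sd,
        loa_high=bias + loa_multiplier * sd,
        n=int(d.size),
    )


def cv_percent(values: Sequence[float]) -> float:
    """Inter-subject variability coefficient: sample SD / mean x 100.

    Undefined (NaN) when the mean is zero.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    m = v.mean()
    if m == 0:
        return math.nan
    return float(v.std(ddof=1) / m * 100.0)


def dice_summary(masks_a: Sequence[BinaryMask], masks_b: Sequence[BinaryMask]) -> dict[str, float]:
    """Mean/SD/min/max of per-subject Dice between two mask series."""
    if len(masks_a) != len(masks_b) or len(masks_a) == 0:
        raise ValueError("need equal-length, nonempty mask lists")
    d = np.array([dice(a, b) for a, b in zip(masks_a, masks_b)])
    return {
        "mean_dsc": float(d.mean()),
        "sd_dsc": float(d.std(ddof=1)) if d.size > 1 else 0.0,
        "min_dsc": float(d.min()),
        "max_dsc": float(d.max()),
    }


def _wilcoxon_p(x: np.ndarray, y: np.ndarray) -> float:
    """Paired Wilcoxon signed-rank p; NaN when all differences are zero."""
    d = x - y
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; Wilcoxon undefined", stacklevel=3)
        return math.nan
    return float(sps.wilcoxon(x, y).pvalue)


@dataclass(frozen=True)
class PairComparison:
    """Agreement statistics for one ordered method pair (a vs b)."""

    method_a: str
    method_b: str
    pearson_r: float
    pearson_p: float
    bland_altman: BlandAltman
    wilcoxon_p: float
    tukey_p: float
    median_a: float
    median_b: float
    dsc: dict[str, float] | None = None


@dataclass(frozen=True)
class AgreementReport:
    """Full agreement battery over >= 2 methods measuring one metric."""

    methods: tuple[str, ...]
    n_subjects: int
    anova_p: float
    cv_percent: dict[str, float]
    pairs: tuple[PairComparison, ...]

    def pair(self, a: str, b: str) -> PairComparison:
        for p in self.pairs:
            if {p.method_a, p.method_b} == {a, b}:
                return p
        raise KeyError(f"no comparison for pair ({a}, {b})")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.pairs:
            row: dict[str, object] = {
                "method_a": p.method_a,
                "method_b": p.method_b,
                "n": self.n_subjects,
                "pearson_r": p.pearson_r,
                "pearson_p": p.pearson_p,
                "ba_bias": p.bland_altman.bias,
                "ba_sd": p.bland_altman.sd_diff,
                "ba_loa_low": p.bland_altman.loa_low,
                "ba_loa_high": p.bland_altman.loa_high,
                "wilcoxon_p": p.wilcoxon_p,
                "anova_p": self.anova_p,
                "tukey_p": p.tukey_p,
                "median_a": p.median_a,
                "median_b": p.median_b,
                "cv_percent_a": self.cv_percent[p.method_a],
                "cv_percent_b": self.cv_percent[p.method_b],
            }
            if p.dsc is not None:
                row.update(p.dsc)
            rows.append(row)
        return pd.DataFrame(rows)


def paired_method_comparison(
    table: pd.DataFrame,
    dsc_masks: dict[str, Sequence[BinaryMask]] | None = None,
) -> AgreementReport:
    """Compare >= 2 methods measured on the same subjects.

    Parameters
    ----------
    table
        subjects x methods; one row per subject, one column per method,
        values of a single metric.  Rows with missing cells are dropped
        with a warning.
    dsc_masks
        Optional method -> list-of-masks mapping (one mask per retained
        subject, same order) from which per-pair Dice summaries are added.

    Returns
    -------
    AgreementReport with per-pair Pearson, Bland-Altman, paired Wilcoxon
    and Tukey-HSD p, plus one-way ANOVA across methods and per-method CV%.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least 2 methods to compare")
    complete = table.dropna(axis=0)
    n_dropped = len(table) - len(complete)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} subjects with missing cells", stacklevel=2)
    if len(complete) < 3:
        raise ValueError("need at least 3 complete subjects")
    methods = tuple(str(c) for c in complete.columns)
    cols = {m: complete[c].to_numpy(dtype=float) for m, c in zip(methods, complete.columns)}

    anova_p = float(sps.f_oneway(*cols.values()).pvalue)
    tukey = sps.tukey_hsd(*cols.values())
    cv = {m: cv_percent(v) if v.mean() != 0 else math.nan for m, v in cols.items()}

    pairs = []
    for (i, a), (j, b) in itertools.combinations(enumerate(methods), 2):
        xa, xb = cols[a], cols[b]
        r, p = pearson(xa, xb) if np.ptp(xa) and np.ptp(xb) else (math.nan, math.nan)
        dsc = None
        if dsc_masks is not None and a in dsc_masks and b in dsc_masks:
            dsc = dice_summary(dsc_masks[a], dsc_masks[b])
        pairs.append(
            PairComparison(
                method_a=a,
                method_b=b,
                pearson_r=r,
                pearson_p=p,
                bland_altman=bland_altman(xa, xb),
                wilcoxon_p=_wilcoxon_p(xa, xb),
                tukey_p=float(tukey.pvalue[i, j]),
                median_a=float(np.median(xa)),
                median_b=float(np.median(xb)),
                dsc=dsc,
            )
        )
    return AgreementReport(
        methods=methods,
        n_subjects=len(complete),
        anova_p=anova_p,
        cv_percent=cv,
        pairs=tuple(pairs),
    )
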