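"""Independent brute-force re-implementations used as test oracles.

These deliberately avoid the library's vectorised code paths: the
threshold sweep literally re-binarizes the template at every threshold
and recomputes Dice by explicit set intersection, and the weighted means
are plain Python loops.
"""

import numpy as np


def bruteforce_dice(a: np.ndarray, b: np.ndarray) -> float:
    sa = {tuple(i) for i in np.argwhere(a > 0)}
    sb = {tuple(i) for i in np.argwhere(b > 0)}
    if not sa and not sb:
        return 1.0
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def bruteforce_threshold_sweep(template: np.ndarray, masks: list[np.ndarray],
                               thresholds: np.ndarray, inclusive: bool = True):
    """Return (best_threshold, mean_dsc_curve) by explicit looping."""
    curve = []
    for t in thresholds:
        binary = (template >= t) if inclusive else (template > t)
        dscs = [bruteforce_dice(binary, m) for m in masks]
        curve.append(sum(dscs) / len(dscs))
    curve = np.asarray(curve)
    best = 0
    for k in range(1, len(thresholds)):
        if curve[k] > curve[best]:  # strict: ties keep the lowest threshold
            best = k
    return float(thresholds[best]), curve


def loop_weighted_mean(values: np.ndarray, weights: np.ndarray) -> float:
    num = den = 0.0
    for v, w in zip(values.ravel(), weights.ravel()):
        if not np.isnan(v):
            num += v * w
            den += w
    return num / den
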