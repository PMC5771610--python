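"""End-to-end orchestration: manifest -> per-subject metrics -> comparison.

Mirrors the order of a tract-specific analysis: apply the anatomical
exclusion mask, overlay the lesion mask on the tract, compute weighted
volumes and compartment diffusivity means, then (given two or more metric
tables) run the method-agreement battery.

Two modes:

* ``individual`` — each subject supplies their own tract mask/map
  (tractography output);
* ``template``  — one tract probability map (a template, already warped
  to each subject's grid upstream) is used for every subject.

Per-subject failures are logged and skipped; the run aborts if more than
half the cohort fails.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .core import GridMismatch, ProbabilityMap, require_same_grid
from .io import (
    CohortManifest,
    has_value,
    read_binary_mask,
    read_probability_map,
    read_volume,
)
from .metrics import DiffusivitySet, compute_tract_metrics

__all__ = ["run_pipeline", "metrics_for_manifest_row"]

logger = logging.getLogger(__name__)

DIFF_COLS = {"ad": "ad_path", "rd": "rd_path", "md": "md_path", "fa": "fa_path"}


def _load_diffusivity(row: pd.Series) -> DiffusivitySet | None:
    if not all(has_value(row, c) for c in DIFF_COLS.values()):
        return None
    scale = 1.0
    if has_value(row, "diffusivity_units"):
        units = str(row["diffusivity_units"]).strip()
        if units in ("mm2/s", "mm^2/s"):
            scale = 1000.0  # normalise to 1e-3 mm^2/s internally
        elif units not in ("1e-3 mm2/s", "1e-3 mm^2/s"):
            raise ValueError(f"unknown diffusivity_units {units!r}")
    grids = {}
    for name, col in DIFF_COLS.items():
        g = read_volume(row[col])
        if scale != 1.0 and name != "fa":
            g = g.like(g.data * scale)
        grids[name] = g
    return DiffusivitySet(**grids)


def metrics_for_manifest_row(row: pd.Series, template: ProbabilityMap | None = None):
    """Compute one subject's :class:`~tractmetrics.metrics.TractMetrics`."""
    subject_id = str(row["subject_id"])
    lesions = read_binary_mask(row["lesion_path"])
    if template is not None:
        if not _grids_match(template, lesions):
            raise GridMismatch(
                f"template grid does not match subject {subject_id!r}"
            )
        tract: ProbabilityMap = template
    else:
        tract = read_probability_map(row["tract_path"])
    exclusion = read_binary_mask(row["exclusion_path"]) if has_value(row, "exclusion_path") else None
    diffusivity = _load_diffusivity(row)
    brain_vol = float(row["brain_volume_ml"]) if has_value(row, "brain_volume_ml") else None
    scaling = float(row["scaling_factor"]) if has_value(row, "scaling_factor") else 1.0
    return compute_tract_metrics(
        subject_id, tract, lesions,
        diffusivity=diffusivity, exclusion=exclusion,
        brain_volume_ml=brain_vol, scaling_factor=scaling,
    )


def _grids_match(template: ProbabilityMap, mask) -> bool:
    try:
        require_same_grid(template.grid, mask.grid)
        return True
    except GridMismatch:
        return False


def run_pipeline(
    manifest: CohortManifest,
    mode: str = "individual",
    template_path: str | Path | None = None,
) -> pd.DataFrame:
    """Run the per-subject metrics stage over a whole manifest.

    Returns a DataFrame with one row per successfully processed subject
    (undefined compartment means are NaN, emitted as empty CSV cells).
    Raises if the manifest is empty, the mode is unknown, a template-mode
    grid mismatch occurs, or more than 50% of subjects fail.
    """
    if mode not in ("individual", "template"):
        raise ValueError(f"mode must be 'individual' or 'template', got {mode!r}")
    template = None
    if mode == "template":
        if template_path is None:
            raise ValueError("template mode requires a template path")
        template = read_probability_map(template_path)
        logger.info("template mode: %s", template_path)

    rows, failures = [], []
    for row in manifest.rows():
        sid = str(row["subject_id"])
        try:
            m = metrics_for_manifest_row(row, template=template)
            rows.append(m.to_dict())
            logger.info("subject %s: tract %.3f mL, lesions %.3f mL",
                        sid, m.tract_volume_ml, m.lesion_volume_ml)
        except GridMismatch:
            raise
        except Exception as exc:
            failures.append(sid)
            logger.error("subject %s failed: %s", sid, exc)
    if len(failures) * 2 > len(manifest):
        raise RuntimeError(
            f"{len(failures)}/{len(manifest)} subjects failed: {failures}"
        )
    return pd.DataFrame(rows)
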