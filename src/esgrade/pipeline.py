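"""End-to-end orchestration: cohort -> normalization -> maps -> ROIs -> CV.

Thin glue over the stage modules so the CLI, the test suite, and scripted
experiments share one code path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classifier import TrainConfig, cross_validate, make_folds
from .envelope import (
    EllipticalWindow,
    EnvelopeImage,
    MOMENT_MAP_WINDOW_MM,
    NORMALIZATION_WINDOW_MM,
    iterative_normalize,
)
from .evaluation import indicator_trend_report, summarize_view_results
from .parametric import build_moment_maps
from .roi import ROISpec, VIEW_KINDS, enumerate_rois, extract_roi_views, sample_case_rois


def process_image(
    image: EnvelopeImage,
    norm_window_mm: tuple[float, float] = NORMALIZATION_WINDOW_MM,
    map_window_mm: tuple[float, float] = MOMENT_MAP_WINDOW_MM,
    threshold_factor: float = 3.0,
):
    """Normalize one envelope frame and form its two moment maps."""
    normalized = iterative_normalize(
        image, EllipticalWindow(norm_window_mm), threshold_factor=threshold_factor
    )
    m1, m4 = build_moment_maps(normalized, EllipticalWindow(map_window_mm))
    return normalized, m1, m4


def process_cohort(
    cohort,
    roi_spec: ROISpec,
    input_size: tuple[int, int] = (32, 32),
    norm_window_mm: tuple[float, float] = NORMALIZATION_WINDOW_MM,
    map_window_mm: tuple[float, float] = MOMENT_MAP_WINDOW_MM,
    log=None,
):
    """Run every case through normalization, maps, and ROI sampling.

    Returns (roi_records, case_summaries): records carry the four rendered
    views; the summary table holds per-case mean M1/M4 (mean over valid
    map pixels, then over the case's images) next to PDFF and any clinical
    indicators, ready for correlation reports.
    """
    records = []
    summary_rows = []
    for case, images in cohort:
        processed = []
        candidates = []
        mean_m1s, mean_m4s = [], []
        for i, img in enumerate(images):
            normalized, m1, m4 = process_image(img, norm_window_mm, map_window_mm)
            image_id = f"img{i:02d}"
            processed.append((image_id, normalized, m1, m4))
            mean_m1s.append(m1.mean())
            mean_m4s.append(m4.mean())
            invalid = ~(m1.valid & m4.valid & normalized.valid)
            for origin, frac in enumerate_rois(
                img.liver_mask, roi_spec, invalid, img.pixel_spacing_um
            ):
                candidates.append((image_id, origin, frac))
            if log is not None:
                log(
                    {"case_id": case.case_id, "image_id": image_id,
                     "excluded_px": int(normalized.excluded.sum()),
                     "iterations": normalized.iterations_run}
                )
        size_px = roi_spec.size_px(images[0].pixel_spacing_um)
        case_records = sample_case_rois(
            candidates, roi_spec, case.case_id, case.grade, size_px
        )
        by_image = {pid: (n, m1, m4) for pid, n, m1, m4 in processed}
        for rec in case_records:
            normalized, m1, m4 = by_image[rec.image_id]
            extract_roi_views(rec, normalized, m1, m4, input_size=input_size)
        records.extend(case_records)
        if log is not None:
            log({"case_id": case.case_id, "n_candidates": len(candidates),
                 "n_rois": len(case_records)})
        summary_rows.append(
            {
                "case_id": case.case_id,
                "grade": case.grade,
                "pdff_percent": case.mri_pdff_percent,
                "cap": case.cap_db_per_m,
                "ati": case.ati_db_cm_mhz,
                "elasticity": case.elasticity_kpa,
                "mean_m1": float(np.mean(mean_m1s)),
                "mean_m4": float(np.mean(mean_m4s)),
            }
        )
    return records, pd.DataFrame(summary_rows)


def run_train_eval(
    records,
    cases,
    config: TrainConfig,
    fold_seed: int = 0,
    views=VIEW_KINDS,
    case_summaries: pd.DataFrame | None = None,
    permute_labels_seed: int | None = None,
) -> dict:
    """Cross-validate every view type and assemble the evaluation report."""
    folds = make_folds(cases, seed=fold_seed)
    cohort_grades = {c.case_id: c.grade for c in cases}
    report = {"views": {}, "folds": folds.groups}
    for view in views:
        cv = cross_validate(
            records, view, folds, config,
            permute_labels_seed=permute_labels_seed,
        )
        report["views"][view] = summarize_view_results(cv, cohort_grades)
        report["views"][view]["_cv"] = cv
    if case_summaries is not None and len(case_summaries) > 2:
        report["indicator_trends"] = indicator_trend_report(case_summaries)
    return report
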