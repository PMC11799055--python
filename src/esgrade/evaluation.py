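"""Accuracy, confusion matrices, indicator correlations, and reporting."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .grading import GRADE_NAMES

_GRADE_IDX = {g: i for i, g in enumerate(GRADE_NAMES)}


def confusion_and_accuracy(truth, predicted) -> tuple[np.ndarray, float]:
    """3x3 confusion matrix (rows = truth, columns = prediction) and accuracy."""
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted) or not truth:
        raise ValueError("truth and prediction must have equal nonzero length")
    mat = np.zeros((len(GRADE_NAMES), len(GRADE_NAMES)), dtype=int)
    for t, p in zip(truth, predicted):
        mat[_GRADE_IDX[t], _GRADE_IDX[p]] += 1
    return mat, float(np.trace(mat) / mat.sum())


def pearson_correlation(x, y, method: str = "pearson") -> tuple[float, int]:
    """Product-moment correlation between paired per-case values.

    Pairs with a missing member are dropped (the count of used pairs is
    returned alongside r).  ``method='spearman'`` switches to the rank
    correlation.  Constant input is an error, not a silent NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    for name, v in (("x", x), ("y", y)):
        if np.ptp(v) == 0:
            raise ValueError(f"variable {name} is constant; correlation undefined")
    if method == "pearson":
        r = float(stats.pearsonr(x, y).statistic)
    elif method == "spearman":
        r = float(stats.spearmanr(x, y).statistic)
    else:
        raise ValueError(f"unknown method {method!r}")
    return r, int(len(x))


def indicator_trend_report(case_summaries: pd.DataFrame,
                           method: str = "pearson") -> dict:
    """Correlate per-case mean moments (and indicators) with PDFF.

    ``case_summaries`` needs columns ``case_id``, ``pdff_percent``,
    ``mean_m1``, ``mean_m4`` and optionally ``cap``, ``ati``,
    ``elasticity``.  Means are per-case over all of a case's images — the
    granularity at which the moments track fat fraction.  Single-case
    input yields correlations reported as undefined rather than an error.
    """
    required = {"case_id", "pdff_percent", "mean_m1", "mean_m4"}
    missing = required - set(case_summaries.columns)
    if missing:
        raise ValueError(f"case summary table lacks columns {sorted(missing)}")
    out = {"n_cases": int(len(case_summaries)), "method": method, "correlations": {}}
    indicators = [c for c in ("cap", "ati", "mean_m1", "mean_m4")
                  if c in case_summaries.columns]
    for against in ("pdff_percent", "elasticity"):
        if against not in case_summaries.columns:
            continue
        block = {}
        for ind in indicators:
            try:
                r, n = pearson_correlation(
                    case_summaries[ind], case_summaries[against], method=method
                )
                block[ind] = {"r": r, "n_pairs": n}
            except ValueError as err:
                block[ind] = {"r": None, "n_pairs": 0, "reason": str(err)}
        out["correlations"][against] = block
    return out


def summarize_view_results(cv_results: dict, cohort_grades: dict) -> dict:
    """ROI- and case-level confusion/accuracy for one view's CV output."""
    roi = cv_results["roi"]
    roi_mat, roi_acc = confusion_and_accuracy(roi["true_grade"], roi["pred_grade"])
    case_truth = [cohort_grades[cid] for cid in sorted(cv_results["votes"])]
    case_pred = [cv_results["votes"][cid].case_grade
                 for cid in sorted(cv_results["votes"])]
    case_mat, case_acc = confusion_and_accuracy(case_truth, case_pred)
    return {
        "roi_confusion": roi_mat.tolist(),
        "roi_accuracy": roi_acc,
        "case_confusion": case_mat.tolist(),
        "case_accuracy": case_acc,
        "n_rois": int(len(roi)),
        "n_cases": len(case_truth),
        "fold_epochs": cv_results["fold_epochs"],
    }


def render_report_markdown(report: dict) -> str:
    """Human-readable summary of a full evaluation report dict."""
    lines = ["# Evaluation report", ""]
    for view, res in report.get("views", {}).items():
        lines.append(f"## View: {view}")
        lines.append(
            f"- ROI-level accuracy: {res['roi_accuracy']:.3f} "
            f"({res['n_rois']} ROIs)"
        )
        lines.append(
            f"- Case-level accuracy (hard voting): {res['case_accuracy']:.3f} "
            f"({res['n_cases']} cases)"
        )
        lines.append(f"- Best epochs per fold: {res['fold_epochs']}")
        lines.append("")
        lines.append("| truth \\ pred | " + " | ".join(GRADE_NAMES) + " |")
        lines.append("|---" * (len(GRADE_NAMES) + 1) + "|")
        for g, row in zip(GRADE_NAMES, res["case_confusion"]):
            lines.append(f"| {g} | " + " | ".join(str(v) for v in row) + " |")
        lines.append("")
    trends = report.get("indicator_trends")
    if trends:
        lines.append("## Indicator correlations")
        for against, block in trends["correlations"].items():
            for ind, res in block.items():
                r = res["r"]
                shown = f"{r:+.3f}" if r is not None else "undefined"
                lines.append(f"- r({ind}, {against}) = {shown} (n={res['n_pairs']})")
        lines.append("")
    return "\n".join(lines)


def write_report(report: dict, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    (outdir / "report.md").write_text(render_report_markdown(report))
    for view, res in report.get("views", {}).items():
        for level in ("roi", "case"):
            pd.DataFrame(
                res[f"{level}_confusion"], index=GRADE_NAMES, columns=GRADE_NAMES
            ).to_csv(outdir / f"confusion_{view}_{level}.csv")
    return outdir


def plot_indicator_scatter(case_summaries: pd.DataFrame, indicator: str,
                           path: str | Path) -> None:
    """Scatter of an indicator against PDFF, points colored by grade."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"G0": "tab:blue", "G1": "tab:green", "G2-3": "tab:red"}
    fig, ax = plt.subplots(figsize=(4, 3.2))
    for grade, grp in case_summaries.groupby("grade"):
        ax.scatter(grp["pdff_percent"], grp[indicator], s=18,
                   color=colors.get(grade, "gray"), label=grade)
    ax.set_xlabel("MRI-PDFF [%]")
    ax.set_ylabel(indicator)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
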