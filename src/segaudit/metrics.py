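"""Axis 1 — diagnostic performance.

Per-patient confusion counts restricted to the brain mask, the eight-metric
panel (Sens, Spec, PPV, NPV, BAcc, Dice, Jaccard, AUROC), dataset-level
confusion percentages, and the per-patient metric table / heat map.

Conventions: pixels are pooled across a patient's slices before computing the
panel (per-patient granularity); hard masks come from thresholding calibrated
probabilities at 0.5 by default; any 0/0 ratio is *undefined* and propagates
as NaN — it is excluded from means, never coerced to 0 or 1.

Note on PPV/NPV: the standard definitions are used — PPV = TP/(TP+FP) is the
probability that a pixel *called tumor* truly is tumor, NPV = TN/(TN+FN) the
probability that a pixel *called benign* truly is benign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .calibration import PlattParams, apply_platt
from .core import Cohort, PatientCase, Predictor, SegAuditError

METRIC_NAMES: tuple[str, ...] = (
    "Sens",
    "Spec",
    "PPV",
    "NPV",
    "BAcc",
    "Dice",
    "JacC",
    "AUROC",
)


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel confusion counts within the brain mask."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise SegAuditError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP,
            self.FP + other.FP,
            self.FN + other.FN,
            self.TN + other.TN,
        )


def confusion_counts(
    pred_mask: np.ndarray, gt_mask: np.ndarray, brain_mask: np.ndarray
) -> ConfusionCounts:
    """Count TP/FP/FN/TN over brain pixels only.

    Predictions outside the brain are ignored entirely; ground truth must be
    a subset of the brain mask.
    """
    pred = np.asarray(pred_mask, dtype=bool)
    gt = np.asarray(gt_mask, dtype=bool)
    brain = np.asarray(brain_mask, dtype=bool)
    if not (pred.shape == gt.shape == brain.shape):
        raise SegAuditError("mask shape mismatch")
    if not brain.any():
        raise SegAuditError("empty brain mask")
    if np.any(gt & ~brain):
        raise SegAuditError("ground truth extends outside brain mask")
    p = pred[brain]
    y = gt[brain]
    return ConfusionCounts(
        TP=int(np.sum(p & y)),
        FP=int(np.sum(p & ~y)),
        FN=int(np.sum(~p & y)),
        TN=int(np.sum(~p & ~y)),
    )


def _ratio(num: int, den: int) -> float:
    """0/0 is undefined (NaN), never 0."""
    return num / den if den > 0 else float("nan")


def auroc(
    prob_map: np.ndarray, gt_mask: np.ndarray, brain_mask: np.ndarray
) -> float:
    """Probability that a random tumor pixel scores above a random benign
    pixel, with ties counted 1/2 (Mann-Whitney / midrank formulation).

    Undefined (NaN) when the brain contains only one class.
    """
    brain = np.asarray(brain_mask, dtype=bool)
    if not brain.any():
        raise SegAuditError("empty brain mask")
    p = np.asarray(prob_map, dtype=float)[brain]
    y = np.asarray(gt_mask, dtype=bool)[brain]
    if y.all() or not y.any():
        return float("nan")
    return float(roc_auc_score(y, p))


def metric_panel(
    counts: ConfusionCounts,
    prob_map: np.ndarray | None = None,
    gt_mask: np.ndarray | None = None,
    brain_mask: np.ndarray | None = None,
) -> dict[str, float]:
    """The eight-metric panel from confusion counts plus (optionally) AUROC
    from the probability map.  Undefined ratios are NaN."""
    sens = _ratio(counts.TP, counts.TP + counts.FN)
    spec = _ratio(counts.TN, counts.TN + counts.FP)
    ppv = _ratio(counts.TP, counts.TP + counts.FP)
    npv = _ratio(counts.TN, counts.TN + counts.FN)
    bacc = (sens + spec) / 2.0  # NaN-propagating by design
    dice = _ratio(2 * counts.TP, 2 * counts.TP + counts.FP + counts.FN)
    jac = _ratio(counts.TP, counts.TP + counts.FP + counts.FN)
    if prob_map is not None:
        if gt_mask is None or brain_mask is None:
            raise SegAuditError("AUROC needs gt_mask and brain_mask")
        au = auroc(prob_map, gt_mask, brain_mask)
    else:
        au = float("nan")
    return {
        "Sens": sens,
        "Spec": spec,
        "PPV": ppv,
        "NPV": npv,
        "BAcc": bacc,
        "Dice": dice,
        "JacC": jac,
        "AUROC": au,
    }


def _patient_probs(
    case: PatientCase, predictor: Predictor, platt: PlattParams | None
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled (probabilities, labels) over all brain pixels of a patient."""
    ps, ys = [], []
    for i in range(case.n_slices):
        m = case.brain_masks[i]
        z = predictor.predict_logits(case.slices[i])
        p = apply_platt(platt, z) if platt is not None else 1.0 / (1.0 + np.exp(-z))
        ps.append(p[m])
        ys.append(case.gt_masks[i][m])
    return np.concatenate(ps), np.concatenate(ys)


def patient_panel(
    case: PatientCase,
    predictor: Predictor,
    threshold: float = 0.5,
    platt: PlattParams | None = None,
) -> dict[str, float]:
    """Eight-metric panel for one patient, pixels pooled across slices."""
    if not (0.0 < threshold < 1.0):
        raise SegAuditError("threshold must lie in (0, 1)")
    p, y = _patient_probs(case, predictor, platt)
    pred = p >= threshold
    counts = ConfusionCounts(
        TP=int(np.sum(pred & y)),
        FP=int(np.sum(pred & ~y)),
        FN=int(np.sum(~pred & y)),
        TN=int(np.sum(~pred & ~y)),
    )
    panel = metric_panel(counts)
    if y.any() and not y.all():
        panel["AUROC"] = float(roc_auc_score(y, p))
    return panel


def cohort_metric_table(
    cohort: Cohort,
    predictor: Predictor,
    threshold: float = 0.5,
    platt: PlattParams | None = None,
) -> pd.DataFrame:
    """Per-patient metric table (one row per patient, eight metric columns)."""
    if len(cohort) == 0:
        raise SegAuditError("empty cohort")
    rows = []
    for case in cohort.cases:
        row = {
            "patient_id": case.patient_id,
            "site_code": case.site_code,
            "grade_group": case.grade_group,
        }
        row.update(patient_panel(case, predictor, threshold, platt))
        rows.append(row)
    return pd.DataFrame(rows)


def confusion_percentages(
    cohort: Cohort,
    predictor: Predictor,
    threshold: float = 0.5,
    platt: PlattParams | None = None,
) -> dict[str, float]:
    """Percentage of all pooled brain pixels in the cohort classified as
    TP / FN / FP / TN.  Sums to 100."""
    if len(cohort) == 0:
        raise SegAuditError("empty cohort")
    total = ConfusionCounts(0, 0, 0, 0)
    for case in cohort.cases:
        p, y = _patient_probs(case, predictor, platt)
        pred = p >= threshold
        total = total + ConfusionCounts(
            TP=int(np.sum(pred & y)),
            FP=int(np.sum(pred & ~y)),
            FN=int(np.sum(~pred & y)),
            TN=int(np.sum(~pred & ~y)),
        )
    n = total.total
    return {
        "%TP": 100.0 * total.TP / n,
        "%FN": 100.0 * total.FN / n,
        "%FP": 100.0 * total.FP / n,
        "%TN": 100.0 * total.TN / n,
    }


def save_metric_heatmap(table: pd.DataFrame, path: str) -> None:
    """Render the per-patient metric table as a heat map PNG (rows =
    patients, columns = metrics)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = table[list(METRIC_NAMES)].to_numpy(dtype=float)
    fig, ax = plt.subplots(
        figsize=(6, max(2.0, 0.3 * len(table) + 1.2)), constrained_layout=True
    )
    im = ax.imshow(data, vmin=0, vmax=1, cmap="RdYlGn", aspect="auto")
    ax.set_xticks(range(len(METRIC_NAMES)), METRIC_NAMES, rotation=45, ha="right")
    ax.set_yticks(range(len(table)), table["patient_id"], fontsize=6)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=120)
    plt.close(fig)
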