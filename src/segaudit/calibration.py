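"""Axis 2a — post-hoc calibration by Platt scaling and its quality metrics.

Platt scaling maps logits z to probabilities p = sigma(a*z + b), with (a, b)
fitted by minimizing the negative log likelihood on validation-cohort pixels.
Calibration quality is reported per patient, then averaged: NLL, Brier score,
and the binned expected / maximum calibration errors as percentages (ECE%,
MCE%).  Binning follows the foreground-probability vs empirical-foreground-
fraction convention over equal-width bins — natural for binary segmentation,
where "confidence of the argmax" would make a p = 0.5 pixel ill-defined.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import optimize

from .core import Cohort, PatientCase, Predictor, SegAuditError

#: Probability clip used inside NLL only.
_NLL_EPS = 1e-7

CALIBRATION_METRICS: tuple[str, ...] = ("NLL", "BS", "ECE_pct", "MCE_pct")


@dataclass(frozen=True)
class PlattParams:
    """Sigmoid recalibration p = sigma(a*z + b)."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and np.isfinite(self.b)):
            raise SegAuditError("Platt parameters must be finite")
        if self.a <= 0:
            warnings.warn(
                "Platt slope a <= 0: calibrated probabilities decrease with the "
                "logit, which indicates a pathological model",
                stacklevel=2,
            )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def fit_platt(
    logits: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    max_pixels: int = 200_000,
) -> PlattParams:
    """Fit (a, b) by NLL minimization (convex two-parameter logistic fit).

    Subsamples at most ``max_pixels`` pixels, stratified by label, before
    fitting — a two-parameter fit does not need full-cohort pixel counts.
    """
    z = np.asarray(logits, dtype=float).ravel()
    y = np.asarray(labels).ravel().astype(float)
    if z.shape != y.shape:
        raise SegAuditError("logits/labels length mismatch")
    if y.min() == y.max():
        raise SegAuditError("Platt fit requires both classes present")
    if len(z) > max_pixels:
        rng = np.random.default_rng(seed)
        keep = []
        for cls in (0.0, 1.0):
            idx = np.nonzero(y == cls)[0]
            n_cls = max(1, int(round(max_pixels * len(idx) / len(y))))
            keep.append(rng.choice(idx, size=min(n_cls, len(idx)), replace=False))
        sel = np.sort(np.concatenate(keep))
        z, y = z[sel], y[sel]

    def nll_and_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        a, b = theta
        p = _sigmoid(a * z + b)
        pc = np.clip(p, _NLL_EPS, 1 - _NLL_EPS)
        nll = -np.mean(y * np.log(pc) + (1 - y) * np.log(1 - pc))
        r = p - y
        return nll, np.array([np.mean(r * z), np.mean(r)])

    res = optimize.minimize(
        nll_and_grad, x0=np.array([1.0, 0.0]), jac=True, method="L-BFGS-B"
    )
    return PlattParams(a=float(res.x[0]), b=float(res.x[1]))


def identity_platt() -> PlattParams:
    """Parameters that leave sigma(z) unchanged (the 'before' condition)."""
    return PlattParams(a=1.0, b=0.0)


def apply_platt(params: PlattParams, logit_map: np.ndarray) -> np.ndarray:
    """Elementwise sigma(a*z + b); strictly increasing in z when a > 0."""
    return _sigmoid(params.a * np.asarray(logit_map, dtype=float) + params.b)


def calibration_metrics(
    prob_map: np.ndarray,
    gt_mask: np.ndarray,
    brain_mask: np.ndarray,
    n_bins: int = 10,
) -> dict[str, float]:
    """NLL, Brier score, ECE% and MCE% for one patient's pooled brain pixels.

    ECE% is the bin-count-weighted mean absolute gap between the mean
    foreground probability and the empirical foreground fraction over
    equal-width probability bins; MCE% is the maximum gap over nonempty bins.
    """
    if n_bins < 2:
        raise SegAuditError("need at least 2 calibration bins")
    brain = np.asarray(brain_mask, dtype=bool)
    if not brain.any():
        raise SegAuditError("empty brain mask")
    p = np.asarray(prob_map, dtype=float)[brain]
    y = np.asarray(gt_mask, dtype=bool)[brain].astype(float)
    if p.min() < 0 or p.max() > 1:
        raise SegAuditError("probabilities outside [0, 1]")

    pc = np.clip(p, _NLL_EPS, 1 - _NLL_EPS)
    nll = float(-np.mean(y * np.log(pc) + (1 - y) * np.log(1 - pc)))
    bs = float(np.mean((p - y) ** 2))

    bins = np.minimum((p * n_bins).astype(int), n_bins - 1)
    ece = 0.0
    mce = 0.0
    n = len(p)
    for b in range(n_bins):
        sel = bins == b
        nb = int(sel.sum())
        if nb == 0:
            continue
        gap = abs(float(p[sel].mean()) - float(y[sel].mean()))
        ece += nb / n * gap
        mce = max(mce, gap)
    return {"NLL": nll, "BS": bs, "ECE_pct": 100.0 * ece, "MCE_pct": 100.0 * mce}


def patient_calibration(
    case: PatientCase,
    predictor: Predictor,
    params: PlattParams | None,
    n_bins: int = 10,
) -> dict[str, float]:
    """Calibration metrics for one patient; ``params=None`` means raw
    sigma(z) probabilities (the before-calibration condition)."""
    ps, ys, ms = [], [], []
    for i in range(case.n_slices):
        z = predictor.predict_logits(case.slices[i])
        p = apply_platt(params, z) if params is not None else _sigmoid(z)
        ps.append(p)
        ys.append(case.gt_masks[i])
        ms.append(case.brain_masks[i])
    return calibration_metrics(np.stack(ps), np.stack(ys), np.stack(ms), n_bins)


def cohort_calibration_report(
    cohort: Cohort,
    predictor: Predictor,
    params: PlattParams,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Per-patient before/after calibration metrics plus the mean aggregate.

    Returns a long DataFrame with columns (patient_id, condition, NLL, BS,
    ECE_pct, MCE_pct); the aggregate rows carry patient_id = "MEAN".
    """
    if len(cohort) == 0:
        raise SegAuditError("empty cohort")
    rows = []
    for case in cohort.cases:
        for cond, prm in (("before", None), ("after", params)):
            row = {"patient_id": case.patient_id, "condition": cond}
            row.update(patient_calibration(case, predictor, prm, n_bins))
            rows.append(row)
    df = pd.DataFrame(rows)
    means = (
        df.groupby("condition", sort=False)[list(CALIBRATION_METRICS)]
        .mean()
        .reset_index()
    )
    means.insert(0, "patient_id", "MEAN")
    return pd.concat([df, means], ignore_index=True)


def validation_logit_sample(
    cohort: Cohort,
    predictor: Predictor,
    seed: int = 0,
    max_pixels: int = 200_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled (logits, labels) over all brain pixels of a cohort, subsampled
    to ``max_pixels`` with label stratification (seeded)."""
    zs, ys = [], []
    for case in cohort.cases:
        for i in range(case.n_slices):
            m = case.brain_masks[i]
            zs.append(predictor.predict_logits(case.slices[i])[m])
            ys.append(case.gt_masks[i][m])
    z = np.concatenate(zs)
    y = np.concatenate(ys)
    if len(z) > max_pixels:
        rng = np.random.default_rng(seed)
        keep = []
        for cls in (False, True):
            idx = np.nonzero(y == cls)[0]
            n_cls = max(1, int(round(max_pixels * len(idx) / len(y))))
            keep.append(rng.choice(idx, size=min(n_cls, len(idx)), replace=False))
        sel = np.sort(np.concatenate(keep))
        z, y = z[sel], y[sel]
    return z, y
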