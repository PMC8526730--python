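"""Axis 3 — adversarial robustness under FGSM epsilon sweeps.

The fast gradient sign method perturbs the input one step in the direction
that increases the model's own training loss: x' = x + eps * sign(grad_x L).
The perturbation is restricted to brain pixels so the skull-stripped
convention (background exactly zero) is never violated; sign(0) = 0, so
pixels with zero gradient are untouched.  The full metric panel is recomputed
at each epsilon and aggregated per patient with Student-t 95% confidence
intervals across patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import PlattParams
from .core import Cohort, PatientCase, Predictor, SegAuditError
from .metrics import METRIC_NAMES, metric_panel, ConfusionCounts
from sklearn.metrics import roc_auc_score

#: Epsilon schedule: dense at the low end to resolve small perturbations.
DEFAULT_EPSILONS: tuple[float, ...] = (0.0, 0.005, 0.01, 0.05, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass(frozen=True)
class AttackConfig:
    epsilons: tuple[float, ...] = DEFAULT_EPSILONS
    clip_to_input_range: bool = False
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        eps = tuple(self.epsilons)
        if len(eps) == 0 or eps[0] != 0.0:
            raise SegAuditError("epsilon schedule must start at 0")
        if any(e < 0 for e in eps) or any(
            eps[i] >= eps[i + 1] for i in range(len(eps) - 1)
        ):
            raise SegAuditError("epsilons must be nonnegative and strictly ascending")


def fgsm_perturb(
    pixels: np.ndarray,
    gt_mask: np.ndarray,
    predictor: Predictor,
    epsilon: float,
    clip_to_input_range: bool = False,
) -> np.ndarray:
    """One FGSM step within the brain mask; eps = 0 returns the input
    bit-identically."""
    if epsilon < 0:
        raise SegAuditError("epsilon must be nonnegative")
    px = np.asarray(pixels, dtype=float)
    if epsilon == 0.0:
        return px.copy()
    grad = predictor.loss_input_gradient(px, gt_mask)
    if grad.shape != px.shape:
        raise SegAuditError("gradient shape mismatch")
    brain = np.any(px != 0, axis=0)
    step = epsilon * np.sign(grad) * brain[None]
    out = px + step
    if clip_to_input_range:
        lo, hi = px.min(), px.max()
        out = np.where(brain[None], np.clip(out, lo, hi), out)
    return out


def _perturbed_patient_panel(
    case: PatientCase,
    predictor: Predictor,
    epsilon: float,
    threshold: float,
    platt: PlattParams | None,
    clip: bool,
) -> dict[str, float]:
    from .calibration import apply_platt

    ps, ys = [], []
    for i in range(case.n_slices):
        xadv = fgsm_perturb(case.slices[i], case.gt_masks[i], predictor, epsilon, clip)
        z = predictor.predict_logits(xadv)
        p = apply_platt(platt, z) if platt is not None else 1.0 / (1.0 + np.exp(-z))
        m = case.brain_masks[i]
        ps.append(p[m])
        ys.append(case.gt_masks[i][m])
    p = np.concatenate(ps)
    y = np.concatenate(ys)
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


def t_confidence_halfwidth(values: np.ndarray, level: float = 0.95) -> float:
    """Student-t CI half-width over per-patient values (NaNs dropped)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 2:
        return float("nan")
    tcrit = stats.t.ppf(0.5 + level / 2.0, df=len(v) - 1)
    return float(tcrit * v.std(ddof=1) / np.sqrt(len(v)))


def epsilon_sweep(
    cohort: Cohort,
    predictor: Predictor,
    attack: AttackConfig | None = None,
    threshold: float = 0.5,
    platt: PlattParams | None = None,
) -> pd.DataFrame:
    """Metric-decay curve: per (metric, epsilon) the per-patient mean and
    95% CI half-width.  The eps = 0 column is the clean evaluation."""
    attack = attack or AttackConfig()
    if len(cohort) == 0:
        raise SegAuditError("empty cohort")
    per_patient: dict[float, list[dict[str, float]]] = {}
    for eps in attack.epsilons:
        per_patient[eps] = [
            _perturbed_patient_panel(
                case, predictor, eps, threshold, platt, attack.clip_to_input_range
            )
            for case in cohort.cases
        ]
    rows = []
    for metric in METRIC_NAMES:
        for eps in attack.epsilons:
            vals = np.array([pp[metric] for pp in per_patient[eps]])
            ok = vals[~np.isnan(vals)]
            half = t_confidence_halfwidth(vals, attack.ci_level)
            mean = float(ok.mean()) if len(ok) else float("nan")
            rows.append(
                {
                    "metric": metric,
                    "epsilon": eps,
                    "mean": mean,
                    "ci_lo": mean - half if len(ok) else float("nan"),
                    "ci_hi": mean + half if len(ok) else float("nan"),
                    "n_patients": int(len(ok)),
                }
            )
    return pd.DataFrame(rows)


def random_sign_perturb(
    pixels: np.ndarray, epsilon: float, seed: int
) -> np.ndarray:
    """Control perturbation: an independent random +/-eps sign field within
    the brain mask, used to verify FGSM is adversarial rather than mere
    noise."""
    px = np.asarray(pixels, dtype=float)
    if epsilon == 0.0:
        return px.copy()
    rng = np.random.default_rng(seed)
    brain = np.any(px != 0, axis=0)
    signs = rng.choice([-1.0, 1.0], size=px.shape)
    return px + epsilon * signs * brain[None]


def save_decay_curves(
    curves: dict[tuple[str, str], pd.DataFrame],
    path: str,
    metrics: tuple[str, ...] = ("AUROC", "Dice", "Sens", "Spec"),
    eps_max: float | None = None,
) -> None:
    """Decay-curve grid PNG: one panel per metric, one line per (model,
    dataset) condition, with CI bands.  ``eps_max`` zooms the epsilon axis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(10, 7), constrained_layout=True)
    for ax, metric in zip(axes.ravel(), metrics):
        for (model, dataset), df in curves.items():
            sub = df[df["metric"] == metric]
            if eps_max is not None:
                sub = sub[sub["epsilon"] <= eps_max]
            ax.plot(sub["epsilon"], sub["mean"], marker="o", ms=3, label=f"{model} on {dataset}")
            ax.fill_between(sub["epsilon"], sub["ci_lo"], sub["ci_hi"], alpha=0.15)
        ax.set_title(metric)
        ax.set_xlabel("epsilon")
        ax.set_ylim(-0.02, 1.02)
    axes.ravel()[0].legend(fontsize=6)
    fig.savefig(path, dpi=120)
    plt.close(fig)
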