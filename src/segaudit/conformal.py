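"""Axis 2b — conformalized quantile regression (CQR) prediction intervals.

Pixelwise prediction intervals around the calibrated foreground probability:
two quantile regressors (levels alpha/2 and 1 - alpha/2) are fitted on
validation summary-slice pixels mapping the raw logit to the Platt-calibrated
probability, then conformalized on a held-out half of those pixels so the
interval [q_lo(z) - Q, q_hi(z) + Q] carries the finite-sample marginal
coverage guarantee of at least 1 - alpha.

The quantile regressors are linear-in-parameters pinball-loss fits on the
basis (1, z, sigma(z)) of the scalar logit.  The sigmoid term makes the
noiseless case — targets exactly sigma(z) — representable with zero residual,
so interval widths genuinely reflect the scatter of calibrated probabilities
around their logit-conditional quantiles, not basis misfit.

The per-patient summary is the average prediction interval (API): the mean
interval width over a region (whole brain, or tumor-only) of the patient's
summary slice.  Wide APIs mean low model confidence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .calibration import PlattParams, apply_platt
from .core import Cohort, Predictor, SegAuditError, summary_slice_index


@dataclass(frozen=True)
class ConformalConfig:
    """CQR configuration.

    alpha : target miscoverage rate (interval coverage is >= 1 - alpha).
    calib_fraction : share of fitting pixels held out for conformalization.
    """

    alpha: float = 0.1
    calib_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise SegAuditError("alpha must lie in (0, 1)")
        if not (0.0 < self.calib_fraction < 1.0):
            raise SegAuditError("calib_fraction must lie in (0, 1)")


def _design(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float).ravel()
    return np.column_stack([np.ones_like(z), z, 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))])


@dataclass
class ConformalIntervalModel:
    """Fitted quantile pair plus conformal offset Q (probability units)."""

    beta_lo: np.ndarray
    beta_hi: np.ndarray
    Q: float
    alpha: float

    def q_lo(self, z: np.ndarray) -> np.ndarray:
        return _design(z) @ self.beta_lo

    def q_hi(self, z: np.ndarray) -> np.ndarray:
        return _design(z) @ self.beta_hi


@dataclass
class IntervalMap:
    """Per-pixel interval bounds (probability units), defined within the
    brain mask; NaN outside."""

    lower: np.ndarray
    upper: np.ndarray
    n_clamped: int = 0

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower


def _pinball_fit(z: np.ndarray, y: np.ndarray, q: float) -> np.ndarray:
    """Linear-in-parameters quantile regression at level q (pinball loss)."""
    X = _design(z)
    with warnings.catch_warnings():
        # QuantReg emits convergence chatter on near-degenerate residuals;
        # the fit itself is deterministic IRLS.
        warnings.simplefilter("ignore")
        model = sm.QuantReg(np.asarray(y, dtype=float).ravel(), X)
        res = model.fit(q=q, max_iter=5000, p_tol=1e-9)
    return np.asarray(res.params, dtype=float)


def conformal_quantile_level(n: int, alpha: float) -> float:
    """Finite-sample-corrected empirical quantile level ceil((1-a)(n+1))/n."""
    return math.ceil((1.0 - alpha) * (n + 1)) / n


def fit_cqr(
    val_logits: np.ndarray,
    val_targets: np.ndarray,
    config: ConformalConfig | None = None,
) -> ConformalIntervalModel:
    """Fit and conformalize the interval model on validation pixels.

    Pixels are shuffled (seeded) and split into a proper-training half (the
    pinball fits) and a calibration half (conformity scores
    E_i = max(q_lo(z_i) - y_i, y_i - q_hi(z_i)), whose finite-sample-corrected
    (1 - alpha) quantile is the offset Q).
    """
    config = config or ConformalConfig()
    z = np.asarray(val_logits, dtype=float).ravel()
    y = np.asarray(val_targets, dtype=float).ravel()
    if z.shape != y.shape:
        raise SegAuditError("logits/targets length mismatch")
    if len(z) < 20:
        raise SegAuditError("need at least 20 pixels to fit CQR")
    if y.min() < 0 or y.max() > 1:
        raise SegAuditError("targets must lie in [0, 1]")
    if np.ptp(z) == 0:
        raise SegAuditError("degenerate constant logits")

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(z))
    n_cal = int(round(len(z) * config.calib_fraction))
    cal_idx, fit_idx = order[:n_cal], order[n_cal:]
    if len(fit_idx) < 10 or len(cal_idx) < 10:
        raise SegAuditError("too few pixels in one of the CQR halves")

    beta_lo = _pinball_fit(z[fit_idx], y[fit_idx], config.alpha / 2.0)
    beta_hi = _pinball_fit(z[fit_idx], y[fit_idx], 1.0 - config.alpha / 2.0)

    Xc = _design(z[cal_idx])
    lo = Xc @ beta_lo
    hi = Xc @ beta_hi
    scores = np.maximum(lo - y[cal_idx], y[cal_idx] - hi)
    level = conformal_quantile_level(len(scores), config.alpha)
    srt = np.sort(scores)
    k = min(len(srt) - 1, math.ceil(level * len(srt)) - 1)
    Q = float(srt[k])
    return ConformalIntervalModel(beta_lo=beta_lo, beta_hi=beta_hi, Q=Q, alpha=config.alpha)


def predict_intervals(
    model: ConformalIntervalModel,
    logit_map: np.ndarray,
    brain_mask: np.ndarray,
) -> IntervalMap:
    """Per-pixel [q_lo(z) - Q, q_hi(z) + Q], clipped to [0, 1], clamped so
    lower <= upper, defined only inside the brain mask."""
    if model.beta_lo is None or model.beta_hi is None:
        raise SegAuditError("unfitted conformal model")
    z = np.asarray(logit_map, dtype=float)
    brain = np.asarray(brain_mask, dtype=bool)
    lo = np.clip(model.q_lo(z.ravel()).reshape(z.shape) - model.Q, 0.0, 1.0)
    hi = np.clip(model.q_hi(z.ravel()).reshape(z.shape) + model.Q, 0.0, 1.0)
    inverted = lo > hi
    n_clamped = int(np.sum(inverted & brain))
    lo2 = np.minimum(lo, hi)
    hi2 = np.maximum(lo, hi)
    lo2 = np.where(brain, lo2, np.nan)
    hi2 = np.where(brain, hi2, np.nan)
    return IntervalMap(lower=lo2, upper=hi2, n_clamped=n_clamped)


def average_prediction_interval(
    interval_map: IntervalMap, region_mask: np.ndarray
) -> float:
    """Mean interval width over a region (API, probability units)."""
    region = np.asarray(region_mask, dtype=bool)
    if not region.any():
        raise SegAuditError("empty region for API")
    w = interval_map.width[region]
    if np.isnan(w).any():
        raise SegAuditError("API region extends outside the brain mask")
    return float(w.mean())


def cohort_api_table(
    cohort: Cohort,
    predictor: Predictor,
    platt: PlattParams,
    model: ConformalIntervalModel,
    model_name: str = "model",
    dataset_name: str | None = None,
) -> pd.DataFrame:
    """Per-patient APIs on summary slices for brain and tumor-only regions."""
    rows = []
    for case in cohort.cases:
        s = summary_slice_index(case)
        z = predictor.predict_logits(case.slices[s])
        im = predict_intervals(model, z, case.brain_masks[s])
        for region_name, region in (
            ("brain", case.brain_masks[s]),
            ("tumor", case.gt_masks[s]),
        ):
            rows.append(
                {
                    "patient_id": case.patient_id,
                    "model": model_name,
                    "dataset": dataset_name or cohort.name,
                    "region": region_name,
                    "api": average_prediction_interval(im, region),
                }
            )
    return pd.DataFrame(rows)


def summary_slice_pixels(
    cohort: Cohort, predictor: Predictor, platt: PlattParams
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled (logits, calibrated probabilities) over brain pixels of every
    patient's summary slice — the CQR fitting sample."""
    zs, ps = [], []
    for case in cohort.cases:
        s = summary_slice_index(case)
        m = case.brain_masks[s]
        z = predictor.predict_logits(case.slices[s])
        zs.append(z[m])
        ps.append(apply_platt(platt, z)[m])
    return np.concatenate(zs), np.concatenate(ps)


def api_summary(api_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Condition-level violin summary: median and quartiles of per-patient
    APIs per (model, dataset, region)."""
    df = pd.concat(api_tables, ignore_index=True)
    out = (
        df.groupby(["model", "dataset", "region"])["api"]
        .agg(
            n="count",
            median="median",
            q1=lambda s: s.quantile(0.25),
            q3=lambda s: s.quantile(0.75),
        )
        .reset_index()
    )
    return out


def save_api_violin(df: pd.DataFrame, path: str, region: str = "tumor") -> None:
    """Violin plot of per-patient APIs by dataset, one violin per model."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = df[df["region"] == region]
    datasets = sorted(sub["dataset"].unique())
    models = sorted(sub["model"].unique())
    fig, ax = plt.subplots(figsize=(7, 4), constrained_layout=True)
    width = 0.8 / max(1, len(models))
    for mi, m in enumerate(models):
        pos, data = [], []
        for di, d in enumerate(datasets):
            vals = sub[(sub["model"] == m) & (sub["dataset"] == d)]["api"].to_numpy()
            if len(vals):
                pos.append(di + (mi - (len(models) - 1) / 2) * width)
                data.append(vals)
        if data:
            parts = ax.violinplot(data, positions=pos, widths=width * 0.9, showmedians=True)
            for pc in parts["bodies"]:
                pc.set_alpha(0.6)
    ax.set_xticks(range(len(datasets)), datasets)
    ax.set_ylabel(f"average prediction interval ({region})")
    fig.savefig(path, dpi=120)
    plt.close(fig)
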