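"""Axis 4 — data-quality features, correlation screening, and batch effects.

Thirteen per-modality image-quality features in the MRQy style are computed
from the *pre-normalization* volumes (foreground = brain mask, background =
its complement).  Each patient also gets a six-entry performance vector per
model (mean calibrated foreground probability over TP/TN/FP/FN pixels, Dice,
AUROC).  Every (feature, modality, performance metric, model) pair is screened
with Spearman correlation under Benjamini-Hochberg FDR control, and the
feature matrix is z-scored and decomposed by PCA with ANOVA plus pairwise
Welch t-tests of the leading components across site codes.

Feature definitions (this package's fixed, testable conventions; F denotes
foreground voxels, B background voxels of one modality's raw volume):

    MEAN  mean(F)                      RNG   max(F) - min(F)
    VAR   population variance of F     CV    sd(F) / mean(F)
    PSNR  10 log10(max(F)^2 / MSE(F, median-filtered F))
    SNR1  mean(F) / sd(B)              SNR2  median(F) / sd(B)
    SNR3  mean(F) / sd(F - local-mean F)   (patch-detrended foreground noise)
    SNR4  mean(F) / MAD(B)             CNR   (mean(F) - mean(B)) / sd(B)
    CVP   sd(patch) / mean(patch) over a window at the brain centroid
    CJV   (sd(F) + sd(B)) / |mean(F) - mean(B)|
    EFC   Shannon entropy of the intensity distribution normalized by the
          maximum-energy bound (scale-invariant focus criterion)

Background-dependent features (PSNR excluded) are *missing* (NaN) when the
background is empty or has zero variance — e.g. on already skull-stripped
raw volumes.  The stochastic embedding coordinates of the full MRQy roster
(TSNEX, TSNEY, UMAPX, UMAPY) are enumerated in the audit grid but never
computed; their cells are reported as explicitly missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .calibration import PlattParams, apply_platt
from .core import CHANNELS, Cohort, PatientCase, Predictor, SegAuditError

logger = logging.getLogger(__name__)

#: Analytic quality features this package computes.
QUALITY_FEATURES: tuple[str, ...] = (
    "MEAN", "RNG", "VAR", "CV", "PSNR", "SNR1", "SNR2", "SNR3", "SNR4",
    "CNR", "CVP", "CJV", "EFC",
)

#: Stochastic embedding coordinates of the full MRQy roster: enumerated in
#: the comparison grid, never computed.
EMBEDDING_FEATURES: tuple[str, ...] = ("TSNEX", "TSNEY", "UMAPX", "UMAPY")

#: Full 17-feature roster used to enumerate the audit grid.
FULL_FEATURE_ROSTER: tuple[str, ...] = QUALITY_FEATURES + EMBEDDING_FEATURES

#: The six performance metrics screened against quality features.
PERFORMANCE_METRICS: tuple[str, ...] = (
    "mean_p_TP", "mean_p_TN", "mean_p_FP", "mean_p_FN", "Dice", "AUROC",
)


def _modality_features(
    volume: np.ndarray, brain: np.ndarray, patch_size: int = 11
) -> dict[str, float]:
    """Thirteen quality features for one modality's raw (S, H, W) volume."""
    F = volume[brain]
    if F.size == 0:
        raise SegAuditError("empty brain mask for quality features")
    B = volume[~brain]
    nan = float("nan")
    mean_f = float(F.mean())
    sd_f = float(F.std())
    out: dict[str, float] = {
        "MEAN": mean_f,
        "RNG": float(F.max() - F.min()),
        "VAR": float(F.var()),
        "CV": sd_f / mean_f if mean_f != 0 else nan,
    }
    # PSNR against a median-filtered (denoised) reference, foreground only.
    med = np.stack([ndimage.median_filter(volume[s], size=5) for s in range(volume.shape[0])])
    mse = float(((volume - med)[brain] ** 2).mean())
    out["PSNR"] = 10.0 * np.log10(F.max() ** 2 / mse) if mse > 0 and F.max() > 0 else nan
    # Patch-detrended foreground noise estimate.
    local = np.stack(
        [ndimage.uniform_filter(volume[s], size=5, mode="nearest") for s in range(volume.shape[0])]
    )
    sd_detrended = float((volume - local)[brain].std())
    out["SNR3"] = mean_f / sd_detrended if sd_detrended > 0 else nan

    # Background-dependent features: missing on empty/degenerate background.
    sd_b = float(B.std()) if B.size else 0.0
    mean_b = float(B.mean()) if B.size else nan
    mad_b = float(np.median(np.abs(B - np.median(B)))) if B.size else 0.0
    if B.size and sd_b > 0:
        out["SNR1"] = mean_f / sd_b
        out["SNR2"] = float(np.median(F)) / sd_b
        out["CNR"] = (mean_f - mean_b) / sd_b
        out["CJV"] = (sd_f + sd_b) / abs(mean_f - mean_b) if mean_f != mean_b else nan
    else:
        out["SNR1"] = out["SNR2"] = out["CNR"] = out["CJV"] = nan
    out["SNR4"] = mean_f / mad_b if B.size and mad_b > 0 else nan

    # Coefficient of variation of a foreground patch at the brain centroid.
    mid = volume.shape[0] // 2
    cy, cx = ndimage.center_of_mass(brain[mid])
    h, w = brain[mid].shape
    half = patch_size // 2
    y0 = int(np.clip(round(cy) - half, 0, h - patch_size))
    x0 = int(np.clip(round(cx) - half, 0, w - patch_size))
    patch = volume[mid, y0 : y0 + patch_size, x0 : x0 + patch_size]
    out["CVP"] = float(patch.std() / patch.mean()) if patch.mean() != 0 else nan

    # Entropy focus criterion over the whole volume, normalized to [0, 1].
    x = np.abs(volume).ravel()
    b = np.sqrt(float((x**2).sum()))
    if b > 0:
        xn = x / b
        nz = xn[xn > 0]
        e = float(-(nz * np.log(nz)).sum())
        n = x.size
        e_max = np.sqrt(n) * np.log(np.sqrt(n))
        out["EFC"] = e / e_max
    else:
        out["EFC"] = nan
    return out


def quality_features(case: PatientCase, patch_size: int = 11) -> pd.Series:
    """Per-modality quality features of one patient's pre-normalization
    volume, indexed by (modality, feature) strings like ``"FLAIR_EFC"``."""
    if case.raw_slices is None:
        raise SegAuditError(
            "quality features require pre-normalization images (raw_slices)"
        )
    vals: dict[str, float] = {}
    for ci, ch in enumerate(CHANNELS):
        feats = _modality_features(case.raw_slices[:, ci], case.brain_masks, patch_size)
        for name, v in feats.items():
            vals[f"{ch}_{name}"] = v
    return pd.Series(vals, name=case.patient_id)


def cohort_quality_features(cohort: Cohort, patch_size: int = 11) -> pd.DataFrame:
    """Feature matrix: one row per patient, one column per
    (modality, feature)."""
    return pd.DataFrame([quality_features(c, patch_size) for c in cohort.cases])


# ---------------------------------------------------------------------------
# Performance vectors
# ---------------------------------------------------------------------------

def mean_probability_by_class(
    prob_map: np.ndarray,
    pred_mask: np.ndarray,
    gt_mask: np.ndarray,
    brain_mask: np.ndarray,
) -> dict[str, float]:
    """Mean foreground probability restricted to the TP / TN / FP / FN pixel
    sets (within the brain); an empty set yields NaN."""
    brain = np.asarray(brain_mask, dtype=bool)
    p = np.asarray(prob_map, dtype=float)[brain]
    pred = np.asarray(pred_mask, dtype=bool)[brain]
    y = np.asarray(gt_mask, dtype=bool)[brain]
    sets = {
        "TP": pred & y,
        "TN": ~pred & ~y,
        "FP": pred & ~y,
        "FN": ~pred & y,
    }
    return {
        k: (float(p[s].mean()) if s.any() else float("nan")) for k, s in sets.items()
    }


def performance_vectors(
    cohort: Cohort,
    predictor: Predictor,
    platt: PlattParams | None = None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-patient six-metric performance vector for one model."""
    from sklearn.metrics import roc_auc_score

    rows = []
    for case in cohort.cases:
        ps, ys = [], []
        for i in range(case.n_slices):
            m = case.brain_masks[i]
            z = predictor.predict_logits(case.slices[i])
            p = apply_platt(platt, z) if platt is not None else 1.0 / (1.0 + np.exp(-z))
            ps.append(p[m])
            ys.append(case.gt_masks[i][m])
        p = np.concatenate(ps)
        y = np.concatenate(ys)
        pred = p >= threshold
        cls = {
            "TP": pred & y,
            "TN": ~pred & ~y,
            "FP": pred & ~y,
            "FN": ~pred & y,
        }
        tp, fp, fn = cls["TP"].sum(), cls["FP"].sum(), cls["FN"].sum()
        dice = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else float("nan")
        au = float(roc_auc_score(y, p)) if (y.any() and not y.all()) else float("nan")
        row = {"patient_id": case.patient_id}
        for k, s in cls.items():
            row[f"mean_p_{k}"] = float(p[s].mean()) if s.any() else float("nan")
        row["Dice"] = float(dice)
        row["AUROC"] = au
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")


# ---------------------------------------------------------------------------
# Correlation audit
# ---------------------------------------------------------------------------

def _exact_spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact permutation p-value for Spearman's rho (small n)."""
    from itertools import permutations

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = float(np.corrcoef(rx, ry)[0, 1])
    count = 0
    total = 0
    for perm in permutations(ry):
        r = float(np.corrcoef(rx, np.asarray(perm))[0, 1])
        count += abs(r) >= abs(obs) - 1e-12
        total += 1
    return obs, count / total

def correlation_audit(
    features: pd.DataFrame,
    performance: dict[str, pd.DataFrame],
    alpha: float = 0.25,
    feature_roster: tuple[str, ...] = FULL_FEATURE_ROSTER,
    min_pairs: int = 3,
    exact_small_n: bool = False,
) -> pd.DataFrame:
    """Spearman screen of every (feature, modality, metric, model) cell with
    BH-FDR control at ``alpha`` across the full comparison grid.

    ``features`` is the patient x (modality_feature) matrix; ``performance``
    maps model name -> patient x metric frame.  Cells whose feature is not
    computed (embedding coordinates) or with fewer than ``min_pairs``
    complete pairs are enumerated but reported missing; BH is applied to the
    non-missing p-values only.

    The default p-values use the large-sample t approximation; with
    ``exact_small_n`` cells with fewer than 10 pairs switch to an exact
    permutation p-value instead.
    """
    rows = []
    for model, perf in performance.items():
        common = features.index.intersection(perf.index)
        for feat in feature_roster:
            for mod in CHANNELS:
                col = f"{mod}_{feat}"
                for metric in PERFORMANCE_METRICS:
                    row = {
                        "feature": feat,
                        "modality": mod,
                        "metric": metric,
                        "model": model,
                        "rho": float("nan"),
                        "p_value": float("nan"),
                        "n": 0,
                        "missing": True,
                    }
                    if col in features.columns:
                        x = features.loc[common, col]
                        yv = perf.loc[common, metric]
                        ok = x.notna() & yv.notna()
                        n = int(ok.sum())
                        row["n"] = n
                        if n >= min_pairs and x[ok].nunique() > 1 and yv[ok].nunique() > 1:
                            if exact_small_n and n < 10:
                                rho, p = _exact_spearman(
                                    x[ok].to_numpy(), yv[ok].to_numpy()
                                )
                            else:
                                rho, p = stats.spearmanr(x[ok], yv[ok])
                            row.update(rho=float(rho), p_value=float(p), missing=False)
                    rows.append(row)
    df = pd.DataFrame(rows)
    n_missing = int(df["missing"].sum())
    if n_missing:
        logger.info(
            "correlation audit: %d of %d comparisons missing (uncomputed "
            "features or too few pairs)", n_missing, len(df)
        )
    df["p_adj"] = np.nan
    df["reject"] = False
    ok = ~df["missing"] & df["p_value"].notna()
    if ok.any():
        rej, p_adj, _, _ = multipletests(
            df.loc[ok, "p_value"], alpha=alpha, method="fdr_bh"
        )
        df.loc[ok, "p_adj"] = p_adj
        df.loc[ok, "reject"] = rej
    return df


# ---------------------------------------------------------------------------
# PCA + site tests
# ---------------------------------------------------------------------------

@dataclass
class SiteTestResult:
    scores: pd.DataFrame  # patient_id, site_code, PC1, PC2
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray  # (n_components, n_features)
    feature_names: list[str]
    anova: pd.DataFrame  # component, F, p
    pairwise: pd.DataFrame  # component, site_a, site_b, t, p
    dropped_columns: list[str]


def pca_site_tests(
    features: pd.DataFrame,
    site_codes: pd.Series | dict[str, str],
    n_components: int = 2,
) -> SiteTestResult:
    """z-score the feature matrix, decompose by PCA, and test the first two
    components for site differences (one-way ANOVA + pairwise Welch t-tests).

    Constant and NaN-containing feature columns are dropped (logged) before
    normalization; PCA on a degenerate (all-identical-rows) matrix is an
    error.
    """
    sites = pd.Series(site_codes)
    X = features.copy()
    dropped = []
    for col in list(X.columns):
        colv = X[col]
        if colv.isna().any() or colv.nunique() <= 1:
            dropped.append(col)
    if dropped:
        logger.info("pca_site_tests: dropping %d degenerate columns", len(dropped))
        X = X.drop(columns=dropped)
    if X.shape[1] < n_components:
        raise SegAuditError("too few usable feature columns for PCA")
    Z = (X - X.mean()) / X.std(ddof=0)
    if not np.isfinite(Z.to_numpy()).all() or np.allclose(Z.to_numpy(), 0.0):
        raise SegAuditError("degenerate feature matrix: PCA undefined")
    n_comp = min(n_components, len(X) - 1, X.shape[1])
    if n_comp < n_components:
        raise SegAuditError("too few patients for the requested components")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Z.to_numpy())
    sdf = pd.DataFrame(
        {
            "patient_id": X.index,
            "site_code": sites.loc[X.index].to_numpy(),
            "PC1": scores[:, 0],
            "PC2": scores[:, 1],
        }
    )
    anova_rows = []
    pair_rows = []
    site_list = sorted(sdf["site_code"].unique())
    if len(site_list) < 2:
        raise SegAuditError("need at least two sites for site tests")
    for comp in ("PC1", "PC2"):
        groups = [sdf.loc[sdf["site_code"] == s, comp].to_numpy() for s in site_list]
        F, p = stats.f_oneway(*groups)
        anova_rows.append({"component": comp, "F": float(F), "p": float(p)})
        for i in range(len(site_list)):
            for j in range(i + 1, len(site_list)):
                a = sdf.loc[sdf["site_code"] == site_list[i], comp]
                b = sdf.loc[sdf["site_code"] == site_list[j], comp]
                t, pp = stats.ttest_ind(a, b, equal_var=False)
                pair_rows.append(
                    {
                        "component": comp,
                        "site_a": site_list[i],
                        "site_b": site_list[j],
                        "t": float(t),
                        "p": float(pp),
                    }
                )
    return SiteTestResult(
        scores=sdf,
        explained_variance_ratio=pca.explained_variance_ratio_,
        loadings=pca.components_,
        feature_names=list(X.columns),
        anova=pd.DataFrame(anova_rows),
        pairwise=pd.DataFrame(pair_rows),
        dropped_columns=dropped,
    )


def save_pca_scatter(result: SiteTestResult, path: str) -> None:
    """PC1/PC2 scatter colored by site code."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5), constrained_layout=True)
    for site in sorted(result.scores["site_code"].unique()):
        sub = result.scores[result.scores["site_code"] == site]
        ax.scatter(sub["PC1"], sub["PC2"], label=site, s=30, alpha=0.8)
    evr = result.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({100 * evr[0]:.1f}% var)")
    ax.set_ylabel(f"PC2 ({100 * evr[1]:.1f}% var)")
    ax.legend(title="site", fontsize=8)
    fig.savefig(path, dpi=120)
    plt.close(fig)
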