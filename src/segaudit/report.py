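"""Orchestration of the full audit: 3 models x 3 test datasets, four axes.

Three segmenters are trained on the GBM, LGG and ALL training cohorts, then
every (model, dataset) condition is evaluated on the enabled axes:

* metrics      — per-patient eight-metric tables and confusion percentages;
* calibration  — per-model Platt scaling on its validation cohort, with the
                 before/after calibration report;
* confidence   — per-model CQR interval model from validation summary slices,
                 per-patient brain/tumor APIs on each test dataset;
* robustness   — FGSM epsilon sweeps with per-patient 95% CIs;
* batcheffects — quality features, the Spearman/BH correlation audit over the
                 full 17 x 4 x 6 x 3 grid, and PCA site tests on the ALL
                 test cohort.

All randomness is seeded from the config; rerunning an identical config
reproduces every CSV byte-for-byte.  A machine-readable manifest records
versions, seeds, input hashes, and per-condition status; any axis failure is
recorded and the audit continues with the remaining conditions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .batcheffects import (
    cohort_quality_features,
    correlation_audit,
    pca_site_tests,
    performance_vectors,
    save_pca_scatter,
)
from .calibration import (
    PlattParams,
    cohort_calibration_report,
    fit_platt,
    validation_logit_sample,
)
from .conformal import (
    ConformalConfig,
    cohort_api_table,
    api_summary,
    fit_cqr,
    save_api_violin,
    summary_slice_pixels,
)
from .core import Cohort, Predictor, SegAuditError
from .metrics import cohort_metric_table, confusion_percentages, save_metric_heatmap
from .robustness import AttackConfig, epsilon_sweep, save_decay_curves
from .synth import SynthConfig, ToyPredictorParams, generate_cohorts, train_toy_predictor

logger = logging.getLogger(__name__)

AXES: tuple[str, ...] = ("metrics", "calibration", "confidence", "robustness", "batcheffects")

MODEL_NAMES: tuple[str, ...] = ("M_GBM", "M_LGG", "M_ALL")
DATASET_NAMES: tuple[str, ...] = ("GBM", "LGG", "ALL")


@dataclass
class AuditConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    toy: ToyPredictorParams = field(default_factory=ToyPredictorParams)
    conformal: ConformalConfig = field(default_factory=ConformalConfig)
    attack: AttackConfig = field(default_factory=AttackConfig)
    axes: tuple[str, ...] = AXES
    threshold: float = 0.5
    n_bins: int = 10
    bh_alpha: float = 0.25
    seed: int = 0
    out_dir: str = "audit_out"
    make_plots: bool = True

    def __post_init__(self) -> None:
        unknown = set(self.axes) - set(AXES)
        if unknown:
            raise SegAuditError(f"unknown axes: {sorted(unknown)}")
        if not (0 < self.threshold < 1):
            raise SegAuditError("threshold must lie in (0, 1)")


@dataclass
class AuditResult:
    manifest: dict
    tables: dict[str, pd.DataFrame]
    n_failures: int


def _hash_cohort(cohort: Cohort) -> str:
    h = hashlib.sha256()
    for case in cohort.cases:
        h.update(case.patient_id.encode())
        h.update(np.ascontiguousarray(case.slices).tobytes())
        h.update(np.ascontiguousarray(case.gt_masks).tobytes())
    return h.hexdigest()[:16]


def _derived_seed(base: int, k: int) -> int:
    return int((base * 1009 + k) % (2**31 - 1))


def run_audit(config: AuditConfig) -> AuditResult:
    """Run the full audit; writes artifacts under ``config.out_dir``."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}

    cohorts = generate_cohorts(config.synth, seed=config.seed)
    test, val, train = cohorts["test"], cohorts["validation"], cohorts["train"]

    # --- models -----------------------------------------------------------
    predictors: dict[str, Predictor] = {}
    platt: dict[str, PlattParams] = {}
    model_train_data = dict(zip(MODEL_NAMES, DATASET_NAMES))
    for mi, mname in enumerate(MODEL_NAMES):
        dname = model_train_data[mname]
        toy_cfg = ToyPredictorParams(
            **{**asdict(config.toy), "seed": _derived_seed(config.seed, mi + 1)}
        )
        predictors[mname] = train_toy_predictor(train[dname], toy_cfg)
        z, y = validation_logit_sample(
            val[dname], predictors[mname], seed=_derived_seed(config.seed, 100 + mi)
        )
        platt[mname] = fit_platt(z, y, seed=_derived_seed(config.seed, 200 + mi))

    conditions = [(m, d) for m in MODEL_NAMES for d in DATASET_NAMES]
    cond_status: dict[str, dict] = {
        f"{m}|{d}": {"model": m, "dataset": d, "axes": {}} for m, d in conditions
    }
    n_failures = 0

    def _run(cond_key: str, axis: str, fn) -> None:
        nonlocal n_failures
        t = time.time()
        try:
            fn()
            cond_status[cond_key]["axes"][axis] = {
                "status": "ok",
                "seconds": round(time.time() - t, 2),
            }
        except Exception as exc:  # failure recorded; audit continues
            logger.exception("axis %s failed for %s", axis, cond_key)
            n_failures += 1
            cond_status[cond_key]["axes"][axis] = {
                "status": f"failed: {exc}",
                "seconds": round(time.time() - t, 2),
            }

    # --- metrics axis ------------------------------------------------------
    if "metrics" in config.axes:
        mdir = out / "metrics"
        mdir.mkdir(exist_ok=True)
        conf_rows = []
        for m, d in conditions:
            def _metrics(m=m, d=d):
                tab = cohort_metric_table(
                    test[d], predictors[m], config.threshold, platt[m]
                )
                tab.insert(0, "model", m)
                tab.insert(1, "dataset", d)
                tables[f"metrics/{m}_{d}"] = tab
                tab.to_csv(mdir / f"{m}_on_{d}_metrics.csv", index=False)
                if config.make_plots:
                    save_metric_heatmap(tab, str(mdir / f"{m}_on_{d}_heatmap.png"))
                pc = confusion_percentages(
                    test[d], predictors[m], config.threshold, platt[m]
                )
                conf_rows.append({"model": m, "dataset": d, **pc})

            _run(f"{m}|{d}", "metrics", _metrics)
        if conf_rows:
            conf = pd.DataFrame(conf_rows)
            tables["confusion_percentages"] = conf
            conf.to_csv(mdir / "confusion_percentages.csv", index=False)

    # --- calibration axis (per model) --------------------------------------
    if "calibration" in config.axes:
        cdir = out / "calibration"
        cdir.mkdir(exist_ok=True)
        reports = []
        for m in MODEL_NAMES:
            d = model_train_data[m]

            def _calib(m=m, d=d):
                rep = cohort_calibration_report(
                    val[d], predictors[m], platt[m], config.n_bins
                )
                rep.insert(0, "model", m)
                reports.append(rep)

            _run(f"{m}|{d}", "calibration", _calib)
        if reports:
            rep = pd.concat(reports, ignore_index=True)
            tables["calibration"] = rep
            rep.to_csv(cdir / "calibration_report.csv", index=False)

    # --- confidence axis ----------------------------------------------------
    if "confidence" in config.axes:
        fdir = out / "confidence"
        fdir.mkdir(exist_ok=True)
        cqr_models = {}
        for mi, m in enumerate(MODEL_NAMES):
            d = model_train_data[m]

            def _fit(m=m, d=d, mi=mi):
                z, p = summary_slice_pixels(val[d], predictors[m], platt[m])
                cfg = ConformalConfig(
                    alpha=config.conformal.alpha,
                    calib_fraction=config.conformal.calib_fraction,
                    seed=_derived_seed(config.seed, 300 + mi),
                )
                cqr_models[m] = fit_cqr(z, p, cfg)

            _run(f"{m}|{d}", "confidence", _fit)
        api_tables = []
        for m, d in conditions:
            if m not in cqr_models:
                continue

            def _api(m=m, d=d):
                api_tables.append(
                    cohort_api_table(
                        test[d], predictors[m], platt[m], cqr_models[m], m, d
                    )
                )

            _run(f"{m}|{d}", "confidence", _api)
        if api_tables:
            api = pd.concat(api_tables, ignore_index=True)
            tables["api"] = api
            api.to_csv(fdir / "api_per_patient.csv", index=False)
            summ = api_summary(api_tables)
            tables["api_summary"] = summ
            summ.to_csv(fdir / "api_summary.csv", index=False)
            if config.make_plots:
                save_api_violin(api, str(fdir / "api_violin_brain.png"), "brain")
                save_api_violin(api, str(fdir / "api_violin_tumor.png"), "tumor")

    # --- robustness axis ----------------------------------------------------
    if "robustness" in config.axes:
        rdir = out / "robustness"
        rdir.mkdir(exist_ok=True)
        curves: dict[tuple[str, str], pd.DataFrame] = {}
        for m, d in conditions:

            def _rob(m=m, d=d):
                curve = epsilon_sweep(
                    test[d], predictors[m], config.attack, config.threshold, platt[m]
                )
                curve.insert(0, "model", m)
                curve.insert(1, "dataset", d)
                curves[(m, d)] = curve
                tables[f"robustness/{m}_{d}"] = curve
                curve.to_csv(rdir / f"{m}_on_{d}_curve.csv", index=False)

            _run(f"{m}|{d}", "robustness", _rob)
        if curves and config.make_plots:
            save_decay_curves(curves, str(rdir / "decay_full.png"))
            save_decay_curves(curves, str(rdir / "decay_zoom.png"), eps_max=0.2)

    # --- batch-effects axis -------------------------------------------------
    if "batcheffects" in config.axes:
        bdir = out / "batcheffects"
        bdir.mkdir(exist_ok=True)

        def _batch():
            feats = cohort_quality_features(test["ALL"])
            tables["quality_features"] = feats
            feats.to_csv(bdir / "quality_features.csv")
            perf = {
                m: performance_vectors(
                    test["ALL"], predictors[m], platt[m], config.threshold
                )
                for m in MODEL_NAMES
            }
            audit = correlation_audit(feats, perf, alpha=config.bh_alpha)
            tables["correlation_audit"] = audit
            audit.to_csv(bdir / "correlation_audit.csv", index=False)
            sites = pd.Series(
                {c.patient_id: c.site_code for c in test["ALL"].cases}
            )
            res = pca_site_tests(feats, sites)
            tables["pca_scores"] = res.scores
            tables["pca_anova"] = res.anova
            tables["pca_pairwise"] = res.pairwise
            res.scores.to_csv(bdir / "pca_scores.csv", index=False)
            res.anova.to_csv(bdir / "pca_anova.csv", index=False)
            res.pairwise.to_csv(bdir / "pca_pairwise_tests.csv", index=False)
            if config.make_plots:
                save_pca_scatter(res, str(bdir / "pca_sites.png"))

        # the batch-effect audit spans all models on the ALL test dataset
        _run("M_ALL|ALL", "batcheffects", _batch)

    # --- manifest and summary ----------------------------------------------
    manifest = {
        "segaudit_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "threshold": config.threshold,
        "alpha_conformal": config.conformal.alpha,
        "bh_alpha": config.bh_alpha,
        "epsilons": list(config.attack.epsilons),
        "axes": list(config.axes),
        "n_conditions": len(conditions),
        "conditions": list(cond_status.values()),
        "input_hashes": {
            f"{split}/{name}": _hash_cohort(c)
            for split, grid in cohorts.items()
            for name, c in grid.items()
        },
        "n_failures": n_failures,
        "wall_seconds": round(time.time() - t0, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    _write_summary(out, config, tables, manifest)
    return AuditResult(manifest=manifest, tables=tables, n_failures=n_failures)


def _write_summary(
    out: Path, config: AuditConfig, tables: dict[str, pd.DataFrame], manifest: dict
) -> None:
    lines = [
        "# Segmentation audit summary",
        "",
        f"- conditions: {manifest['n_conditions']} (3 models x 3 test datasets)",
        f"- seed: {config.seed}; threshold: {config.threshold}",
        f"- failures: {manifest['n_failures']}",
        "",
    ]
    if "confusion_percentages" in tables:
        lines += ["## Confusion percentages (pooled test pixels)", "",
                  tables["confusion_percentages"].round(3).to_markdown(index=False), ""]
    if "calibration" in tables:
        cal = tables["calibration"]
        agg = cal[cal["patient_id"] == "MEAN"]
        lines += ["## Calibration (patient-mean, before vs after Platt)", "",
                  agg.round(5).to_markdown(index=False), ""]
    if "api_summary" in tables:
        lines += ["## Average prediction intervals (median per condition)", "",
                  tables["api_summary"].round(4).to_markdown(index=False), ""]
    if "correlation_audit" in tables:
        audit = tables["correlation_audit"]
        lines += [
            "## Batch-effect correlation screen",
            "",
            f"- comparisons enumerated: {len(audit)}",
            f"- computed (non-missing): {int((~audit['missing']).sum())}",
            f"- BH rejections at alpha={config.bh_alpha}: {int(audit['reject'].sum())}",
            "",
        ]
    if "pca_anova" in tables:
        lines += ["## PCA site ANOVA", "", tables["pca_anova"].round(6).to_markdown(index=False), ""]
    (out / "summary.md").write_text("\n".join(lines))
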