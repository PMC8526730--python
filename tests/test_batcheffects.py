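"""Quality features, class-conditional probabilities, the Spearman/BH
screen, and PCA site tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from statsmodels.stats.multitest import multipletests

from segaudit.batcheffects import (
    EMBEDDING_FEATURES,
    FULL_FEATURE_ROSTER,
    QUALITY_FEATURES,
    cohort_quality_features,
    correlation_audit,
    mean_probability_by_class,
    pca_site_tests,
    performance_vectors,
    quality_features,
)
from segaudit.core import CHANNELS, PatientCase, SegAuditError


def _uniform_case(value=10.0, background=0.0):
    """3-slice patient whose brain intensity is constant."""
    slices = np.zeros((3, 4, 16, 16))
    brain = np.zeros((3, 16, 16), dtype=bool)
    brain[:, 4:12, 4:12] = True
    raw = np.full((3, 4, 16, 16), background)
    raw[:, :, 4:12, 4:12] = value
    slices[:, :, 4:12, 4:12] = 1.0
    gt = np.zeros((3, 16, 16), dtype=bool)
    gt[1, 6:8, 6:8] = True
    return PatientCase("p", "06", "GBM", slices, gt, brain, raw_slices=raw)


class TestQualityFeatures:
    def test_constant_foreground(self):
        f = quality_features(_uniform_case(10.0))
        for ch in CHANNELS:
            assert f[f"{ch}_VAR"] == 0.0
            assert f[f"{ch}_CV"] == 0.0
            assert f[f"{ch}_RNG"] == 0.0

    def test_hand_two_value_foreground(self):
        """Foreground of half 10s, half 20s: MEAN 15, VAR 25, CV 1/3, RNG 10."""
        case = _uniform_case(10.0)
        raw = case.raw_slices.copy()
        raw[:, :, 4:12, 4:8] = 10.0
        raw[:, :, 4:12, 8:12] = 20.0
        case = PatientCase(
            "p", "06", "GBM", case.slices, case.gt_masks, case.brain_masks, raw
        )
        f = quality_features(case)
        assert f["T1_MEAN"] == pytest.approx(15.0)
        assert f["T1_VAR"] == pytest.approx(25.0)
        assert f["T1_CV"] == pytest.approx(5.0 / 15.0)
        assert f["T1_RNG"] == pytest.approx(10.0)

    @pytest.mark.parametrize("k", [2.0, 7.5])
    def test_intensity_scaling_behaviour(self, k, cohorts):
        """Scaling intensities by k > 0 leaves CV, CJV, EFC unchanged and
        scales MEAN and RNG by k (dimensional analysis)."""
        case = cohorts["test"]["GBM"].cases[0]
        f1 = quality_features(case)
        scaled = PatientCase(
            case.patient_id, case.site_code, case.grade_group,
            case.slices, case.gt_masks, case.brain_masks, k * case.raw_slices,
        )
        f2 = quality_features(scaled)
        for ch in CHANNELS:
            for inv in ("CV", "CJV", "EFC"):
                assert f2[f"{ch}_{inv}"] == pytest.approx(f1[f"{ch}_{inv}"], rel=1e-9)
            for lin in ("MEAN", "RNG"):
                assert f2[f"{ch}_{lin}"] == pytest.approx(k * f1[f"{ch}_{lin}"], rel=1e-9)

    def test_degenerate_background_marks_features_missing(self):
        """On already skull-stripped raw volumes (zero background) the
        background-dependent features are missing, the rest computed."""
        f = quality_features(_uniform_case(10.0, background=0.0))
        assert np.isnan(f["T1_SNR1"]) and np.isnan(f["T1_CJV"]) and np.isnan(f["T1_CNR"])
        assert not np.isnan(f["T1_MEAN"])

    def test_missing_raw_slices_error(self, cohorts):
        case = cohorts["test"]["GBM"].cases[0]
        bare = PatientCase(
            case.patient_id, case.site_code, case.grade_group,
            case.slices, case.gt_masks, case.brain_masks,
        )
        with pytest.raises(SegAuditError):
            quality_features(bare)


class TestMeanProbabilityByClass:
    def test_oracle_constant_probability(self):
        gt = np.array([[True, False], [False, False]])
        brain = np.ones((2, 2), bool)
        p = np.full((2, 2), 0.7)
        means = mean_probability_by_class(p, gt, gt, brain)
        assert means["TP"] == pytest.approx(0.7)
        assert np.isnan(means["FP"]) and np.isnan(means["FN"])

    def test_hand_one_pixel_per_class(self):
        probs = np.array([[0.9, 0.6], [0.4, 0.1]])
        pred = np.array([[True, True], [False, False]])
        gt = np.array([[True, False], [True, False]])
        means = mean_probability_by_class(probs, pred, gt, np.ones((2, 2), bool))
        assert (means["TP"], means["TN"], means["FP"], means["FN"]) == (0.9, 0.1, 0.6, 0.4)

    def test_thresholded_tp_mean_above_threshold(self, cohorts, predictor, platt):
        from segaudit.calibration import apply_platt

        case = cohorts["test"]["LGG"].cases[0]
        z = predictor.predict_logits(case.slices[4])
        p = apply_platt(platt, z)
        pred = p >= 0.5
        means = mean_probability_by_class(p, pred, case.gt_masks[4], case.brain_masks[4])
        if not np.isnan(means["TP"]):
            assert means["TP"] >= 0.5


@pytest.fixture(scope="module")
def audit(cohorts, predictor, platt):
    feats = cohort_quality_features(cohorts["test"]["ALL"])
    perf = {
        m: performance_vectors(cohorts["test"]["ALL"], predictor, platt)
        for m in ("M_GBM", "M_LGG", "M_ALL")
    }
    return correlation_audit(feats, perf)


class TestCorrelationAudit:
    def test_grid_enumerates_1224_comparisons(self, audit):
        """17 features x 4 sequences x 6 metrics x 3 models = 1,224."""
        assert len(audit) == 1224
        assert len(FULL_FEATURE_ROSTER) == 17 and len(QUALITY_FEATURES) == 13

    def test_embedding_cells_are_explicitly_missing(self, audit):
        emb = audit[audit.feature.isin(EMBEDDING_FEATURES)]
        assert len(emb) == 4 * 4 * 6 * 3
        assert emb["missing"].all()
        assert not audit[~audit.feature.isin(EMBEDDING_FEATURES)]["missing"].any()

    def test_perfectly_monotone_pair_gives_rho_one(self):
        n = 10
        feats = pd.DataFrame(
            {"T1_MEAN": np.arange(n, dtype=float)},
            index=[f"p{i}" for i in range(n)],
        )
        perf = pd.DataFrame(
            {m: np.arange(n, dtype=float) ** 2 if m == "Dice" else np.zeros(n)
             for m in ("mean_p_TP", "mean_p_TN", "mean_p_FP", "mean_p_FN", "Dice", "AUROC")},
            index=feats.index,
        )
        audit = correlation_audit(feats, {"M": perf}, feature_roster=("MEAN",))
        cell = audit[(audit.modality == "T1") & (audit.metric == "Dice")].iloc[0]
        assert cell["rho"] == pytest.approx(1.0)

    def test_exact_permutation_p_for_small_n(self):
        """Monotone pair with n = 5: only the identity and the reversal of
        the ranks achieve |rho| = 1, so the exact two-sided p is 2/5!."""
        n = 5
        feats = pd.DataFrame(
            {"T1_MEAN": np.arange(n, dtype=float)}, index=[f"p{i}" for i in range(n)]
        )
        perf = pd.DataFrame(
            {m: np.arange(n, dtype=float) for m in
             ("mean_p_TP", "mean_p_TN", "mean_p_FP", "mean_p_FN", "Dice", "AUROC")},
            index=feats.index,
        )
        audit = correlation_audit(
            feats, {"M": perf}, feature_roster=("MEAN",), exact_small_n=True
        )
        cell = audit[(audit.modality == "T1") & (audit.metric == "Dice")].iloc[0]
        assert cell["rho"] == pytest.approx(1.0)
        assert cell["p_value"] == pytest.approx(2 / 120)

    @given(st.integers(0, 999))
    def test_bh_matches_brute_force_definition(self, seed):
        """BH rejects exactly {i : p_(i) <= k* alpha / m} where k* is the
        largest k with p_(k) <= k alpha / m."""
        rng = np.random.default_rng(seed)
        m = int(rng.integers(5, 60))
        p = rng.random(m) ** rng.uniform(0.5, 3.0)
        alpha = 0.25
        rej, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
        order = np.argsort(p)
        ks = [k for k in range(1, m + 1) if p[order[k - 1]] <= k * alpha / m]
        expected = np.zeros(m, dtype=bool)
        if ks:
            expected[order[: max(ks)]] = True
        assert np.array_equal(rej, expected)

    @given(st.integers(0, 200))
    def test_bh_no_less_powerful_than_bonferroni(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(40)
        alpha = 0.25
        bh, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
        bonf = p <= alpha / len(p)
        assert bh.sum() >= bonf.sum()


class TestPcaSiteTests:
    def test_site_shift_detected_on_pc1(self):
        """Two sites differing by a 3-SD mean shift in 3 of 10 features are
        separated on PC1 (Welch t-test p < 0.01, n = 15 per site)."""
        rng = np.random.default_rng(0)
        n = 15
        X = rng.normal(size=(2 * n, 10))
        X[n:, :3] += 3.0
        feats = pd.DataFrame(X, index=[f"p{i}" for i in range(2 * n)])
        feats.columns = [f"f{j}" for j in range(10)]
        sites = pd.Series(
            ["A"] * n + ["B"] * n, index=feats.index
        )
        res = pca_site_tests(feats, sites)
        pc1 = res.pairwise[res.pairwise.component == "PC1"].iloc[0]
        assert pc1["p"] < 0.01
        assert res.anova.set_index("component").loc["PC1", "p"] < 0.01

    def test_pca_properties(self, cohorts):
        feats = cohort_quality_features(cohorts["test"]["ALL"])
        sites = pd.Series({c.patient_id: c.site_code for c in cohorts["test"]["ALL"].cases})
        res = pca_site_tests(feats, sites)
        evr = res.explained_variance_ratio
        assert evr[0] >= evr[1]
        # loadings orthonormal
        G = res.loadings @ res.loadings.T
        assert np.allclose(G, np.eye(len(G)), atol=1e-10)

    def test_full_rank_pca_reconstruction_is_exact(self, rng):
        from sklearn.decomposition import PCA

        X = rng.normal(size=(12, 6))
        Z = (X - X.mean(0)) / X.std(0)
        pca = PCA(n_components=6, svd_solver="full").fit(Z)
        rec = pca.inverse_transform(pca.transform(Z))
        assert np.abs(rec - Z).max() <= 1e-8 * max(1.0, np.abs(Z).max())

    def test_identical_rows_degenerate_error(self):
        feats = pd.DataFrame(np.ones((6, 5)), index=[f"p{i}" for i in range(6)])
        sites = pd.Series(["A", "A", "A", "B", "B", "B"], index=feats.index)
        with pytest.raises(SegAuditError):
            pca_site_tests(feats, sites)

    def test_pre_normalization_separates_sites_more(self, cohorts):
        """Quality features on raw images separate synthetic sites; the same
        features on normalized images separate them less (preprocessing
        homogenizes scans)."""
        cohort = cohorts["test"]["ALL"]
        raw_feats = cohort_quality_features(cohort)
        norm_cases = [
            PatientCase(
                c.patient_id, c.site_code, c.grade_group,
                c.slices, c.gt_masks, c.brain_masks, raw_slices=c.slices,
            )
            for c in cohort.cases
        ]
        from segaudit.core import Cohort

        norm_feats = cohort_quality_features(Cohort("ALL", norm_cases, "test"))
        sites = pd.Series({c.patient_id: c.site_code for c in cohort.cases})

        def pc1_f(feats):
            res = pca_site_tests(feats, sites)
            return res.anova.set_index("component").loc["PC1", "F"]

        assert pc1_f(raw_feats) > pc1_f(norm_feats)
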