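import numpy as np
import pandas as pd
import pytest

import reoxkinetics as rk
from reoxkinetics.reliability import (
    MDC_MULTIPLIER,
    between_cv,
    build_reports,
    icc_2_1,
    icc_band,
    sem_mdc,
    within_cv,
)

# 5x2 toy matrix whose two-way ANOVA was worked by hand (explicit mean-square
# sums) before this module was written; values frozen from that computation.
TOY = np.array([[8, 10], [12, 11], [17, 15], [9, 12], [14, 13]], dtype=float)
TOY_ICC = 0.7668711656441719
TOY_SEM = 1.5329709716755893
TOY_MDC = 4.2491787441810445
TOY_WITHIN_CV = 12.636802373761585


class TestBetweenCV:
    def test_no_spread(self):
        assert between_cv([10.0, 10.0, 10.0]) == 0.0

    def test_hand_computed(self):
        assert between_cv([8.0, 12.0]) == pytest.approx(28.2843, abs=1e-3)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            between_cv([10.0])

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            between_cv([-5.0, 5.0])


class TestICC:
    def test_toy_matrix_matches_anova_oracle(self):
        icc, lo, hi = icc_2_1(TOY)
        assert icc == pytest.approx(TOY_ICC, abs=1e-10)
        assert lo < icc < hi

    def test_duplicated_trials_perfect_agreement(self):
        X = np.column_stack([TOY[:, 0], TOY[:, 0]])
        icc, lo, hi = icc_2_1(X)
        assert icc == pytest.approx(1.0)

    def test_offset_penalized_by_absolute_agreement(self):
        rng = np.random.default_rng(0)
        base = rng.normal(30, 10, 40)
        X = np.column_stack([base, base + 3.0])
        icc, _, _ = icc_2_1(X)
        assert icc < 1.0

    def test_matches_pingouin_cross_check(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        X = rng.normal(0, 3, (12, 2)) + rng.normal(25, 8, (12, 1))
        icc, lo, hi = icc_2_1(X)
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(12), 2),
            "raters": np.tile([1, 2], 12),
            "scores": X.ravel(),
        })
        ref = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="scores")
        row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        assert icc == pytest.approx(row["ICC"], abs=1e-9)
        ref_ci = np.asarray(row[[c for c in ref.columns if c.startswith("CI95")][0]])
        assert np.allclose([lo, hi], ref_ci, atol=5e-3)  # pingouin rounds its CI

    def test_variance_component_recovery(self):
        """On a large simulated matrix with known variance components the ICC
        estimates sigma_b^2 / (sigma_b^2 + sigma_w^2)."""
        rng = np.random.default_rng(123)
        sigma_b, sigma_w = 4.0, 2.0
        n = 500
        X = 30 + rng.normal(0, sigma_b, (n, 1)) + rng.normal(0, sigma_w, (n, 2))
        icc, _, _ = icc_2_1(X)
        expected = sigma_b**2 / (sigma_b**2 + sigma_w**2)
        assert icc == pytest.approx(expected, abs=0.05)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            icc_2_1(TOY[:2])

    def test_listwise_deletion(self):
        X = np.vstack([TOY, [np.nan, 12.0]])
        assert icc_2_1(X)[0] == pytest.approx(TOY_ICC, abs=1e-10)


class TestSemMdc:
    def test_toy_matrix_matches_anova_oracle(self):
        sem, (lo, hi), mdc = sem_mdc(TOY)
        assert sem == pytest.approx(TOY_SEM, abs=1e-10)
        assert mdc == pytest.approx(TOY_MDC, abs=1e-10)
        assert lo < sem < hi

    def test_duplicated_trials_zero_error(self):
        X = np.column_stack([TOY[:, 0], TOY[:, 0]])
        sem, ci, mdc = sem_mdc(X)
        assert sem == 0.0 and mdc == 0.0 and ci == (0.0, 0.0)

    def test_mdc_sem_ratio_exact(self):
        sem, _, mdc = sem_mdc(TOY)
        assert mdc / sem == pytest.approx(1.96 * np.sqrt(2.0), abs=1e-12)
        assert MDC_MULTIPLIER == pytest.approx(1.96 * np.sqrt(2.0))

    def test_paper_style_rounding_consistency(self):
        """An SEM of 12 s implies an MDC of 33.3 s (33 at integer precision)."""
        assert 12.0 * MDC_MULTIPLIER == pytest.approx(33.26, abs=0.01)


class TestWithinCV:
    def test_duplicated_trials(self):
        X = np.column_stack([TOY[:, 0], TOY[:, 0]])
        assert within_cv(X) == 0.0

    def test_single_participant_pair(self):
        assert within_cv(np.array([[8.0, 12.0], [8.0, 12.0]])) == pytest.approx(
            28.2843, abs=1e-3)

    def test_toy_matrix_matches_oracle(self):
        assert within_cv(TOY) == pytest.approx(TOY_WITHIN_CV, abs=1e-10)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            within_cv(np.array([[0.0, 0.0], [5.0, 6.0], [4.0, 4.0]]))


class TestIccBand:
    @pytest.mark.parametrize(
        "icc,band",
        [(0.2, "poor"), (0.5, "moderate"), (0.74, "moderate"),
         (0.75, "good"), (0.9, "good"), (0.95, "excellent")],
    )
    def test_thresholds(self, icc, band):
        assert icc_band(icc) == band


class TestBuildReports:
    def test_layout_12_cells(self, study_bouts):
        table, _ = study_bouts
        desc, rel = build_reports(table)
        assert len(desc) == 12 and len(rel) == 12
        assert set(desc["site"]) == {"VL", "RF", "PS", "DL"}

    def test_noise_free_study_perfect_reliability(self):
        """Zero noise and zero within-trial variance: both trials identical,
        so ICC = 1 and SEM = MDC = 0 in every cell."""
        pop = rk.PopulationConfig(
            n_participants=5, within_sd=0.0, noise_sd_pct=0.0, seed=8)
        study = rk.simulate_study(pop)
        table, _ = rk.extract_all(study.traces, study.schedules)
        _, rel = build_reports(table)
        assert np.allclose(rel["icc"], 1.0)
        assert np.allclose(rel["sem_s"], 0.0) and np.allclose(rel["mdc_s"], 0.0)

    def test_dominant_within_variability_gives_poor_icc(self):
        """When trial-to-trial spread dwarfs participant spread the ICC must
        classify as poor (< 0.5)."""
        pop = rk.PopulationConfig(
            n_participants=12, between_sd=0.02, site_sd=0.0, within_sd=0.6,
            noise_sd_pct=1.0, seed=13)
        study = rk.simulate_study(pop, profiles={"VL": rk.DEFAULT_PROFILES["VL"]})
        table, _ = rk.extract_all(study.traces, study.schedules)
        _, rel = build_reports(table, sites=("VL",))
        assert (rel["icc"] < 0.5).all()
        assert (rel["icc_band"] == "poor").all()

    def test_listwise_deletion_shrinks_reliability_n(self, study):
        """Participants missing one trial still count in descriptives but not
        in the test-retest table."""
        corrupted = rk.inject_missing_bouts(study, 43, seed=7)
        table, _ = rk.extract_all(corrupted.traces, corrupted.schedules)
        desc, rel = build_reports(table)
        merged = desc.merge(rel, on=["site", "pct_target"], suffixes=("_desc", "_rel"))
        assert (merged["n_rel"] <= merged["n_desc"]).all()
        assert (merged["n_rel"] < merged["n_desc"]).any()

    def test_median_invariant_under_row_order(self, study_bouts):
        table, _ = study_bouts
        desc1, _ = build_reports(table)
        desc2, _ = build_reports(table.sample(frac=1.0, random_state=0))
        pd.testing.assert_frame_equal(desc1, desc2)
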