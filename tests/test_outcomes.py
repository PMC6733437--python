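import numpy as np
import pandas as pd
import pytest

from crcrisk.cohort import PROTEINS
from crcrisk.outcomes import (
    HybridRiskScore,
    SingleProteinRisk,
    compute_comb,
    confusion_metrics,
    fit_single_protein_model,
    hybrid_risk_score,
    outcome_report,
    predict_outcome,
    search_clinical_weights,
    subgroup_stratify,
)
from crcrisk.reference import REPORTED_W_STAR
from crcrisk.risk import FixedWeightRiskScore, compute_beta
from crcrisk.survival import binary_cox_hr, stratify_at_cutoff
from crcrisk.synthetic import SyntheticConfig, default_crc_like_config, \
    generate_cohort
from conftest import make_cohort


class TestOutcomePrediction:
    def test_boundary_is_favorable(self):
        np.testing.assert_array_equal(
            predict_outcome([-0.1, 0.0, 0.1]), [0, 1, 1])

    def test_all_positive(self):
        assert predict_outcome([0.5, 1.2]).all()

    def test_perfect_prediction_metrics(self):
        cm = confusion_metrics([1, 1, 0, 0], [1, 1, 0, 0])
        assert cm.sensitivity == cm.specificity == cm.accuracy == 1.0

    def test_counts_consistent_with_study_percentages(self):
        # 70 of 95 favorable predicted favorable; 26 of 39 unfavorable
        # predicted unfavorable: the unique counts giving the published
        # 73.68 / 66.66 / 71.64 percentages on a 95/39 split
        actual = [1] * 95 + [0] * 39
        predicted = [1] * 70 + [0] * 25 + [0] * 26 + [1] * 13
        cm = confusion_metrics(predicted, actual)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (70, 25, 26, 13)
        assert 100 * cm.sensitivity == pytest.approx(73.68, abs=0.005)
        assert 100 * cm.specificity == pytest.approx(66.67, abs=0.005)
        assert 100 * cm.accuracy == pytest.approx(71.64, abs=0.005)

    def test_all_favorable_baseline(self):
        cm = confusion_metrics([1] * 134, [1] * 95 + [0] * 39)
        assert cm.sensitivity == 1.0 and cm.specificity == 0.0
        assert 100 * cm.accuracy == pytest.approx(70.90, abs=0.01)

    def test_accuracy_identity_holds_exactly(self):
        rng = np.random.default_rng(5)
        p = rng.integers(0, 2, 200)
        a = rng.integers(0, 2, 200)
        cm = confusion_metrics(p, a)
        prev = (cm.tp + cm.fn) / cm.n
        assert cm.accuracy == pytest.approx(
            cm.sensitivity * prev + cm.specificity * (1 - prev), abs=1e-15)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_metrics([1], [1, 0])


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(default_crc_like_config(seed=31))


@pytest.fixture(scope="module")
def base(cohort):
    return FixedWeightRiskScore(weights=REPORTED_W_STAR).fit(cohort)


class TestHybrid:
    def test_zero_weights_reduce_to_beta(self, cohort, base):
        beta = compute_beta(cohort, base.w_star_)
        np.testing.assert_array_equal(compute_comb(cohort, beta, {}), beta)
        np.testing.assert_array_equal(
            compute_comb(cohort, beta, {"age": 0.0}), beta)

    def test_single_patient_arithmetic(self):
        cohort = make_cohort([10], [0], age=[60])
        comb = compute_comb(cohort, np.array([5.0]), {"age": -0.2})
        assert comb[0] == pytest.approx(-7.0)

    def test_categorical_level_weights(self):
        cohort = make_cohort([10, 20], [0, 1], gender=["male", "female"])
        comb = compute_comb(cohort, np.zeros(2),
                            {"gender": {"male": 0.1, "female": -1.0}})
        np.testing.assert_allclose(comb, [0.1, -1.0])

    def test_missing_feature_excluded_with_warning(self):
        cohort = make_cohort([10, 20], [0, 1], age=[60, np.nan])
        with pytest.warns(UserWarning, match="excluded"):
            comb = compute_comb(cohort, np.zeros(2), {"age": -0.2})
        assert np.isnan(comb[1]) and comb[0] == pytest.approx(-12.0)

    def test_zero_weight_hybrid_identical_to_plain_rs(self, cohort, base):
        hm = HybridRiskScore(base=base, feature_weights={}).fit(cohort)
        rs_h, fit_mean, _ = hybrid_risk_score(cohort, hm)
        rs = base.transform(cohort)
        np.testing.assert_array_equal(rs_h, rs)
        g = stratify_at_cutoff(rs, rs.mean(), "below")
        plain = binary_cox_hr(cohort["os_time"], cohort["event"], g)
        assert fit_mean.hr == plain.hr and fit_mean.wald_p == plain.wald_p

    def test_null_feature_weight_search_prefers_no_change(self, cohort, base):
        """A feature with no survival association should not beat w=0."""
        rng = np.random.default_rng(17)
        c = cohort.copy()
        c["age"] = rng.normal(64, 10, len(c)).round(1)  # independent redraw
        beta = compute_beta(c, base.w_star_)
        w, obj = search_clinical_weights(c, beta, "age", precision=0.1)
        from crcrisk.risk import fold_objective
        base_obj, _, _ = fold_objective(beta, c["os_time"], c["event"])
        assert obj >= base_obj          # search can only improve in-sample
        assert obj <= base_obj * 2.5    # but not transformatively on noise

    def test_clinical_search_equals_brute_force(self, cohort, base):
        from lifelines import CoxPHFitter

        beta = compute_beta(cohort, base.w_star_)
        w, obj = search_clinical_weights(cohort, beta, "age", precision=0.5)
        best = -np.inf
        best_w = None
        t, e = cohort["os_time"].to_numpy(), cohort["event"].to_numpy()
        age = cohort["age"].to_numpy(float)
        for cand in np.arange(-1, 1.01, 0.5):
            comb = beta + cand * age
            hrs = []
            ok = True
            for cut in (comb.mean(), np.median(comb)):
                g = (comb < cut).astype(int)
                if g.sum() in (0, len(g)):
                    ok = False
                    break
                cph = CoxPHFitter().fit(
                    pd.DataFrame({"t": t, "e": e, "g": g}), "t", "e")
                hrs.append(float(np.exp(cph.params_["g"])))
                ok &= float(cph.summary.loc["g", "p"]) < 0.05
            if ok and min(hrs) > best:
                best, best_w = min(hrs), cand
        assert w == pytest.approx(best_w, abs=1e-12)
        assert obj == pytest.approx(best, rel=1e-3)


class TestSubgroups:
    def test_whole_cohort_predicate_matches_unfiltered(self, crc_like_cohort):
        base = FixedWeightRiskScore(weights=REPORTED_W_STAR).fit(crc_like_cohort)
        rs = base.transform(crc_like_cohort)
        _, lr, fit = subgroup_stratify(
            crc_like_cohort, np.ones(len(crc_like_cohort), bool), rs, 0.0)
        g = stratify_at_cutoff(rs, 0.0, "below")
        direct = binary_cox_hr(crc_like_cohort["os_time"],
                               crc_like_cohort["event"], g)
        assert fit.hr == direct.hr

    def test_complementary_predicates_partition(self, crc_like_cohort):
        base = FixedWeightRiskScore(weights=REPORTED_W_STAR).fit(crc_like_cohort)
        rs = base.transform(crc_like_cohort)
        old = (crc_like_cohort["age"] > 60).to_numpy()
        _, _, fit_old = subgroup_stratify(crc_like_cohort, old, rs, 0.0)
        _, _, fit_young = subgroup_stratify(crc_like_cohort, ~old, rs, 0.0)
        total = fit_old.n_high + fit_old.n_low + fit_young.n_high + fit_young.n_low
        assert total == len(crc_like_cohort)

    def test_one_sided_subgroup_flagged(self, crc_like_cohort):
        rs = np.ones(len(crc_like_cohort))
        with pytest.raises(ValueError, match="one side"):
            subgroup_stratify(crc_like_cohort,
                              np.ones(len(crc_like_cohort), bool), rs, 0.0)


class TestSingleProtein:
    def test_null_association_flat_near_half(self):
        # baseline hazard raised so the null cohort still has spread in OS
        cfg = SyntheticConfig(n=600, seed=37, effect_scale=0.0,
                              hazard_scale=0.01)
        cohort = generate_cohort(cfg)
        m = fit_single_protein_model(cohort, "bclxl", n_bins=10)
        assert abs(m.slope_ * cohort["bclxl"].std()) < 0.15
        mid = float(np.atleast_1d(m.predict(cohort["bclxl"].median()))[0])
        assert 35 < mid < 65  # median OS split => ~50% base rate

    def test_monotone_construction_positive_slope(self):
        # OS decreasing in concentration => high conc = high risk bins
        n = 100
        conc = np.linspace(1, 50, n)
        os_time = 60 - conc + 5
        cohort = make_cohort(os_time, np.ones(n),
                             proteins=np.column_stack([conc] * 5))
        m = fit_single_protein_model(cohort, "bclxl", n_bins=5)
        assert m.slope_ > 0
        assert (np.diff(m.bin_risk_) >= 0).all()

    def test_two_bin_closed_form_least_squares(self):
        conc = np.array([1, 2, 3, 4, 5, 26, 27, 28, 29, 30], dtype=float)
        os_time = np.array([50, 55, 60, 58, 52, 5, 6, 7, 8, 9], dtype=float)
        cohort = make_cohort(os_time, np.ones(10),
                             proteins=np.column_stack([conc] * 5))
        m = fit_single_protein_model(cohort, "bak", n_bins=2)
        x = np.array([3.0, 28.0])     # bin mean concentrations
        y = np.array([0.0, 1.0])      # bin high-risk fractions
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept = y.mean() - slope * x.mean()
        assert m.slope_ == pytest.approx(slope, rel=1e-12)
        assert m.intercept_ == pytest.approx(intercept, rel=1e-12)

    def test_prediction_clamped(self):
        m = SingleProteinRisk()
        m.slope_, m.intercept_ = 0.1, 0.0
        assert float(np.atleast_1d(m.predict(1000.0))[0]) == 100.0
        m.slope_, m.intercept_ = 0.0, 0.5
        assert float(np.atleast_1d(m.predict(3.0))[0]) == 50.0

    def test_negative_concentration_rejected(self):
        m = SingleProteinRisk()
        m.slope_, m.intercept_ = 0.0, 0.5
        with pytest.raises(ValueError):
            m.predict(-1.0)

    def test_too_few_patients_for_bins(self):
        cohort = make_cohort(np.arange(1, 11), np.ones(10))
        with pytest.raises(ValueError, match="bins"):
            fit_single_protein_model(cohort, "bak", n_bins=10)


def test_outcome_report_on_structured_cohort(structured_cohort):
    base = FixedWeightRiskScore(weights=REPORTED_W_STAR).fit(structured_cohort)
    cm = outcome_report(structured_cohort, base.transform(structured_cohort))
    assert cm.n == len(structured_cohort)
    assert cm.accuracy > 0.5  # protective-weight score is informative here
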