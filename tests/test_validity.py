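"""Validity/concordance statistics: frozen known values, oracles, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rxremit import (
    ConfusionTable,
    RemissionAgreement,
    SampleSizeSpec,
    binary_auc,
    cohen_kappa,
    confusion_table,
    cronbach_alpha_binary,
    likelihood_ratios,
    mcnemar_chi2,
    phi_coefficient,
    prevalence_ci,
    sample_size_prevalence,
    validity_measures,
)
from rxremit.validity import Estimate, round_half_away

tables = st.builds(
    ConfusionTable,
    tp=st.integers(1, 200),
    fp=st.integers(1, 150),
    fn=st.integers(1, 150),
    tn=st.integers(1, 200),
)


class TestConfusionTable:
    def test_counts_and_labels_round_trip(self, validation_table):
        assert validation_table.n == 133
        assert validation_table.discordant == 11
        index, reference = validation_table.to_labels()
        assert ConfusionTable.from_labels(index, reference) == validation_table

    def test_from_calls(self):
        from rxremit import classify_cohort, generate_exact_table

        timelines, assessments = generate_exact_table(3, 1, 2, 4, seed=5)
        calls, _ = classify_cohort(timelines)
        assert confusion_table(calls, assessments).counts() == (3, 1, 2, 4)

    def test_missing_assessment_names_patient(self):
        from rxremit import classify_cohort, generate_exact_table

        timelines, assessments = generate_exact_table(1, 0, 0, 1, seed=5)
        calls, _ = classify_cohort(timelines)
        with pytest.raises(KeyError, match=calls[0].patient_id):
            confusion_table(calls, assessments[1:] if assessments[0].patient_id == calls[0].patient_id else assessments[:1])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionTable(-1, 0, 0, 1)


class TestValidityMeasures:
    def test_known_point_estimates(self, validation_table):
        m = validity_measures(validation_table)
        assert m["sensitivity"].pct() == 92.5
        assert m["specificity"].pct() == 90.6
        assert m["ppv"].pct() == 93.7
        assert m["npv"].pct() == 88.9
        assert m["false_positive_rate"].pct() == 7.5
        assert m["false_negative_rate"].pct() == 9.4

    def test_perfect_test(self):
        m = validity_measures(ConfusionTable(10, 0, 0, 10))
        for key in ("sensitivity", "specificity", "ppv", "npv"):
            assert m[key].value == 1.0
            assert m[key].ci_high == 1.0  # clamped
        assert m["false_positive_rate"].value == 0.0

    def test_zero_denominator_is_undefined_not_zero(self):
        m = validity_measures(ConfusionTable(5, 0, 0, 0))
        assert m["specificity"] is None
        assert m["npv"] is None
        assert m["false_negative_rate"] is None
        assert m["sensitivity"].value == 1.0

    def test_standard_intervals_at_least_as_wide_as_published_mode(self, validation_table):
        std = validity_measures(validation_table, "standard")
        pub = validity_measures(validation_table, "as_published")
        for key in ("sensitivity", "specificity", "ppv", "npv"):
            w_std = std[key].ci_high - std[key].ci_low
            w_pub = pub[key].ci_high - pub[key].ci_low
            assert w_std >= w_pub - 1e-12

    @given(tables)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_integer_identity_and_bounds(self, table):
        m = validity_measures(table)
        ppv = m["ppv"].value
        assert ppv * (table.tp + table.fp) == pytest.approx(table.tp, abs=1e-9)
        for est in m.values():
            assert 0.0 <= est.value <= 1.0
            assert 0.0 <= est.ci_low <= est.ci_high <= 1.0

    @given(tables)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bayes_consistency_of_ppv(self, table):
        m = validity_measures(table)
        s, sp = m["sensitivity"].value, m["specificity"].value
        prev = (table.tp + table.fn) / table.n
        bayes = s * prev / (s * prev + (1 - sp) * (1 - prev))
        assert bayes == pytest.approx(m["ppv"].value, abs=1e-12)


class TestLikelihoodRatios:
    def test_known_values(self, validation_table):
        ppr, npr = likelihood_ratios(validation_table)
        assert round_half_away(ppr, 1) == 9.8
        assert round_half_away(npr, 1) == 0.1

    def test_hand_computed_symmetric_table(self):
        ppr, npr = likelihood_ratios(ConfusionTable(9, 1, 1, 9))
        assert round_half_away(ppr, 1) == 9.0
        assert round_half_away(npr, 1) == 0.1

    def test_uninformative_test_has_unit_ppr(self):
        ppr, _ = likelihood_ratios(ConfusionTable(8, 8, 2, 2))  # S = 1 - Sp = 0.8
        assert ppr == pytest.approx(1.0)

    def test_perfect_specificity_gives_infinite_ppr(self):
        ppr, npr = likelihood_ratios(ConfusionTable(9, 0, 1, 10))
        assert math.isinf(ppr)
        assert npr == pytest.approx(0.1)


class TestAgreementStatistics:
    def test_kappa_known_value_and_published_interval(self, validation_table):
        est = cohen_kappa(validation_table, ci_convention="as_published")
        assert est.pct() == 82.8
        assert est.ci_pct() == (73.1, 92.6)

    def test_kappa_perfect_and_independent(self):
        assert cohen_kappa(ConfusionTable(50, 0, 0, 50)).value == pytest.approx(1.0)
        assert cohen_kappa(ConfusionTable(25, 25, 25, 25)).value == pytest.approx(0.0, abs=1e-12)

    def test_phi_known_and_degenerate_values(self, validation_table):
        assert round_half_away(phi_coefficient(validation_table) * 100) == 82.8
        assert phi_coefficient(ConfusionTable(50, 0, 0, 50)) == pytest.approx(1.0)
        assert phi_coefficient(ConfusionTable(25, 25, 25, 25)) == pytest.approx(0.0)
        with pytest.raises(ValueError):
            phi_coefficient(ConfusionTable(10, 0, 5, 0))

    def test_cronbach_alpha_known_and_perfect(self, validation_table):
        assert round_half_away(cronbach_alpha_binary(validation_table) * 100) == 90.6
        assert cronbach_alpha_binary(ConfusionTable(50, 0, 0, 50)) == pytest.approx(1.0)

    @given(st.integers(1, 100), st.integers(1, 100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_alpha_spearman_brown_identity_for_equal_variances(self, a, d):
        # equal item variances: alpha = 2 phi / (1 + phi)
        table = ConfusionTable(a, d, d, a)
        phi = phi_coefficient(table)
        assert cronbach_alpha_binary(table) == pytest.approx(2 * phi / (1 + phi), abs=1e-12)

    @given(tables)
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_label_vector_oracles_agree_to_1e12(self, table):
        """Closed-form kappa/phi/alpha match brute force on expanded label vectors."""
        x, y = table.to_labels()
        po = float(np.mean(x == y))
        pe = float(np.mean(x) * np.mean(y) + (1 - np.mean(x)) * (1 - np.mean(y)))
        kappa_bf = (po - pe) / (1 - pe)
        phi_bf = float(np.corrcoef(x, y)[0, 1])
        v1, v2, vt = np.var(x), np.var(y), np.var(x + y)
        alpha_bf = 2 * (1 - (v1 + v2) / vt)
        assert cohen_kappa(table).value == pytest.approx(kappa_bf, abs=1e-12)
        assert phi_coefficient(table) == pytest.approx(phi_bf, abs=1e-12)
        assert cronbach_alpha_binary(table) == pytest.approx(alpha_bf, abs=1e-12)

    @given(tables)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_third_party_oracles(self, table):
        from sklearn.metrics import cohen_kappa_score
        from statsmodels.stats.inter_rater import cohens_kappa

        x, y = table.to_labels()
        assert cohen_kappa(table).value == pytest.approx(
            cohen_kappa_score(x, y), abs=1e-12
        )
        sm = cohens_kappa([[table.tp, table.fp], [table.fn, table.tn]], return_results=True)
        fleiss = cohen_kappa(table, kappa_se="fleiss")
        assert fleiss.ci_low == pytest.approx(max(-1.0, sm.kappa_low), abs=1e-9)
        assert fleiss.ci_high == pytest.approx(min(1.0, sm.kappa_upp), abs=1e-9)

    @given(st.integers(1, 80), st.integers(1, 60), st.integers(1, 80))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_kappa_equals_phi_when_marginals_match(self, tp, off, tn):
        table = ConfusionTable(tp, off, off, tn)  # fp == fn -> equal marginals
        assert cohen_kappa(table).value == pytest.approx(
            phi_coefficient(table), abs=1e-12
        )

    def test_mcnemar_values(self, validation_table):
        stat, p = mcnemar_chi2(validation_table)
        assert stat == pytest.approx(1 / 11)
        assert p > 0.05
        stat, _ = mcnemar_chi2(ConfusionTable(5, 7, 7, 5))
        assert stat == 0.0
        stat, _ = mcnemar_chi2(ConfusionTable(0, 10, 0, 0), continuity_correction=True)
        assert stat == pytest.approx(8.1)
        assert mcnemar_chi2(ConfusionTable(5, 0, 0, 5)) == (0.0, 1.0)

    def test_auc_values(self, validation_table):
        assert binary_auc(validation_table) == pytest.approx((74 / 80 + 48 / 53) / 2)
        assert binary_auc(ConfusionTable(10, 0, 0, 10)) == 1.0
        assert binary_auc(ConfusionTable(8, 8, 2, 2)) == pytest.approx(0.5)


class TestSampleSizeAndPrevalence:
    def test_design_sample_size(self):
        assert sample_size_prevalence(0.54, 0.085) == 133
        assert sample_size_prevalence(0.5, 0.05) == 385
        assert SampleSizeSpec(0.54, 0.085).required_n() == 133

    def test_limit_behaviour_small_n(self):
        assert sample_size_prevalence(0.5, 0.9) == 2  # ceil(z^2/4/0.81)

    def test_prevalence_ci_values(self):
        est = prevalence_ci(2496, 4572, ci_convention="as_published")
        assert est.pct() == 54.6
        assert est.ci_pct() == (53.2, 56.0)
        est = prevalence_ci(50, 100)
        assert est.ci_pct() == (40.2, 59.8)
        assert prevalence_ci(0, 10).ci_low == 0.0  # clamped

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            sample_size_prevalence(0.0, 0.1)
        with pytest.raises(ValueError):
            prevalence_ci(5, 4)


class TestModelResults:
    def test_fit_collects_every_statistic(self, validation_table):
        results = RemissionAgreement.from_table(validation_table).fit(
            ci_convention="as_published"
        )
        d = results.to_dict()
        assert d["sensitivity"] == {"value": 92.5, "ci": [88.0, 97.0]}
        assert d["kappa"] == {"value": 82.8, "ci": [73.1, 92.6]}
        assert d["phi"] == 82.8
        assert d["cronbach_alpha"] == 90.6
        assert d["ppr"] == 9.8
        assert d["npr"] == 0.1
        assert d["discordant"] == 11

    def test_summary_is_readable(self, validation_table):
        text = RemissionAgreement.from_table(validation_table).fit().summary()
        assert "Sensitivity" in text and "92.5" in text
        assert "Cohen kappa" in text and "82.8" in text

    def test_model_from_labels_matches_table(self, validation_table):
        x, y = validation_table.to_labels()
        model = RemissionAgreement(x, y)
        assert model.table == validation_table


def test_round_half_away():
    assert round_half_away(92.551, 1) == 92.6
    assert round_half_away(92.549, 1) == 92.5
    assert round_half_away(-1.25, 1) == -1.3
    assert round_half_away(0.5459, 3) == 0.546
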