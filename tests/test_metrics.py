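"""Diagnostic-accuracy statistics: confusion tallying, metrics, intervals,
precision and sample-size planning, prevalence transport, subgroups."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import spectrodx as sx
from spectrodx.consensus import PatientPrediction
from spectrodx.errors import (
    ConsistencyError,
    DegenerateInputError,
    InvalidConfigError,
    UndefinedMetricError,
)
from spectrodx.metrics import confusion
from spectrodx.simulate import CANCER, NON_CANCER

# The study's patient-level confusion counts (positive = cancer).
STUDY = dict(tp=54, fp=65, fn=13, tn=253)


def _pred(pid, cls):
    return PatientPrediction(pid, 9, 9 if cls == CANCER else 0, cls, 0.5)


class TestConfusion:
    def test_reconstructed_study_counts(self):
        truth, preds = [], []
        i = 0
        for pred_cls, true_cls, n in [
            (CANCER, CANCER, 54), (CANCER, NON_CANCER, 65),
            (NON_CANCER, CANCER, 13), (NON_CANCER, NON_CANCER, 253),
        ]:
            for _ in range(n):
                pid = f"P{i}"; i += 1
                subtype = "glioblastoma" if true_cls == CANCER else None
                truth.append(sx.PatientRecord(pid, true_cls, subtype))
                preds.append(_pred(pid, pred_cls))
        cm = confusion(preds, truth)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (54, 65, 13, 253)
        assert cm.n_positive_test == 119
        assert cm.n_negative_test == 266
        assert cm.total == 385

    def test_perfect_predictions(self):
        truth = [sx.PatientRecord("A", CANCER, "glioblastoma"),
                 sx.PatientRecord("B", NON_CANCER)]
        cm = confusion([_pred("A", CANCER), _pred("B", NON_CANCER)], truth)
        assert (cm.fp, cm.fn) == (0, 0)

    def test_duplicate_and_missing_patients_named(self):
        truth = [sx.PatientRecord("A", CANCER, "glioblastoma"),
                 sx.PatientRecord("B", NON_CANCER)]
        with pytest.raises(ConsistencyError, match="A"):
            confusion([_pred("A", CANCER), _pred("A", CANCER)], truth)
        with pytest.raises(ConsistencyError, match="B"):
            confusion([_pred("A", CANCER)], truth)

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidConfigError):
            sx.ConfusionMatrix(tp=-1, fp=0, fn=0, tn=10)


class TestMetricsAndIntervals:
    def test_study_panel_reproduced_to_whole_percent(self):
        """All six metrics and CI bounds round to the published panel."""
        res = sx.DiagnosticAccuracy.from_counts(**STUDY).fit()
        table = res.to_frame(percent=True)
        expected = {
            "sensitivity": (81, 71, 90),
            "specificity": (80, 75, 84),
            "prevalence": (17, 14, 21),
            "ppv": (45, 36, 54),
            "npv": (95, 93, 98),
            "accuracy": (80, 76, 84),
        }
        for metric, (pt, lo, hi) in expected.items():
            row = table.loc[metric]
            assert (row["estimate"], row["ci_lower"], row["ci_upper"]) == (pt, lo, hi)

    def test_trivial_perfect_test(self):
        res = sx.DiagnosticAccuracy.from_counts(1, 0, 0, 1).fit()
        assert res.sensitivity == res.specificity == res.ppv == res.npv == 1.0
        assert res.prevalence == 0.5

    @given(
        tp=st.integers(0, 200), fp=st.integers(0, 200),
        fn=st.integers(0, 200), tn=st.integers(1, 200),
    )
    def test_accuracy_conservation_identity(self, tp, fp, fn, tn):
        """accuracy == prevalence*sensitivity + (1-prevalence)*specificity."""
        res = sx.DiagnosticAccuracy.from_counts(tp, fp, fn, tn).fit()
        sens = res.sensitivity if not math.isnan(res.sensitivity) else 0.0
        spec = res.specificity if not math.isnan(res.specificity) else 0.0
        assert res.accuracy == pytest.approx(
            res.prevalence * sens + (1 - res.prevalence) * spec, abs=1e-12
        )

    def test_wald_boundary_zero_width(self):
        assert sx.wald_ci(0.0, 50) == (0.0, 0.0)
        assert sx.wald_ci(1.0, 50) == (1.0, 1.0)

    def test_wald_clipping(self):
        lo, hi = sx.wald_ci(0.98, 20)
        assert 0.0 <= lo and hi <= 1.0

    def test_wilson_option_available_and_sane(self):
        res = sx.DiagnosticAccuracy.from_counts(**STUDY).fit(ci_method="wilson")
        lo, hi = res.conf_int("sensitivity")
        assert 0.0 < lo < res.sensitivity < hi < 1.0
        w_lo, w_hi = sx.wilson_ci(0.5, 10)
        assert (w_lo, w_hi) == pytest.approx((0.2366, 0.7634), abs=2e-4)

    def test_undefined_metric_flagged_not_zero(self):
        res = sx.DiagnosticAccuracy.from_counts(0, 5, 0, 10).fit()
        assert "sensitivity" in res.undefined
        assert math.isnan(res.sensitivity)
        with pytest.raises(UndefinedMetricError):
            res.conf_int("sensitivity")

    def test_ci_covers_point(self):
        res = sx.DiagnosticAccuracy.from_counts(**STUDY).fit()
        for m in ("sensitivity", "specificity", "ppv", "npv", "accuracy", "prevalence"):
            lo, hi = res.conf_int(m)
            assert lo <= res.estimates[m] <= hi


class TestPrecision:
    def test_interim_cohort_precision(self):
        assert round(sx.half_width(54 / 67, 67), 1) == 9.5

    def test_projected_full_cohort_precision(self):
        assert round(sx.half_width(54 / 67, 600 * 67 / 385), 1) == 7.6

    def test_half_width_vanishes_with_n(self):
        widths = [sx.half_width(0.5, n) for n in (10, 100, 10000, 10**8)]
        assert all(a > b for a, b in zip(widths, widths[1:]))
        assert widths[-1] < 0.01

    def test_required_n_inverse_consistency(self):
        p, prev = 54 / 67, 67 / 385
        for n_pos in (30, 67, 150):
            target = sx.half_width(p, n_pos)
            n_total = sx.required_n(p, target, prev)
            assert abs(n_total * prev - n_pos) <= 1.0

    def test_halving_target_quadruples_positives(self):
        p, prev = 0.8, 0.2
        n1 = sx.required_n(p, 10.0, prev)
        n2 = sx.required_n(p, 5.0, prev)
        assert n2 / n1 == pytest.approx(4.0, rel=0.02)

    def test_required_n_matches_grid_search_oracle(self):
        """Brute-force scan over N for the planning example p=0.9375,
        target +-17 points, prevalence 3%."""
        p, target, prev = 0.9375, 17.0, 0.03
        got = sx.required_n(p, target, prev)
        oracle = next(
            n for n in range(1, 100000)
            if sx.half_width(p, n * prev) <= target
        )
        assert got == oracle
        assert sx.half_width(p, got * prev) <= target

    def test_impossible_target_rejected(self):
        with pytest.raises(InvalidConfigError):
            sx.required_n(0.8, 0.0, 0.2)


class TestPrevalenceTransport:
    SENS, SPEC = 54 / 67, 253 / 318

    def test_bayes_low_prevalence_value(self):
        ppv, npv = sx.adjust_predictive_values(
            self.SENS, self.SPEC, sx.PrevalenceScenario(0.03, "bayes"))
        assert ppv == pytest.approx(0.109, abs=5e-4)
        assert npv > 0.99

    def test_linear_rescaling_value(self):
        ppv, npv = sx.adjust_predictive_values(
            self.SENS, self.SPEC, sx.PrevalenceScenario(0.03, "linear"),
            cohort_ppv=54 / 119, cohort_prevalence=67 / 385)
        assert ppv == pytest.approx(0.078, abs=5e-4)
        assert npv is None

    def test_linear_identity_at_cohort_prevalence(self):
        ppv, _ = sx.adjust_predictive_values(
            self.SENS, self.SPEC, sx.PrevalenceScenario(67 / 385, "linear"),
            cohort_ppv=54 / 119, cohort_prevalence=67 / 385)
        assert ppv == pytest.approx(54 / 119)

    def test_perfect_test_invariant(self):
        for pi in (0.01, 0.3, 0.9):
            ppv, npv = sx.adjust_predictive_values(
                1.0, 1.0, sx.PrevalenceScenario(pi, "bayes"))
            assert (ppv, npv) == (1.0, 1.0)

    def test_bayes_ppv_strictly_increasing_in_prevalence(self):
        grid = np.linspace(0.01, 0.99, 25)
        ppvs = [sx.adjust_predictive_values(self.SENS, self.SPEC,
                                            sx.PrevalenceScenario(pi, "bayes"))[0]
                for pi in grid]
        assert all(a < b for a, b in zip(ppvs, ppvs[1:]))

    def test_linear_and_bayes_agree_to_first_order_at_low_prevalence(self):
        """As pi -> 0, bayes_ppv / pi -> sens/(1-spec) and linear_ppv / pi is
        constant; their ratio converges."""
        ratios = []
        for pi in (1e-2, 1e-3, 1e-4):
            b, _ = sx.adjust_predictive_values(
                self.SENS, self.SPEC, sx.PrevalenceScenario(pi, "bayes"))
            l, _ = sx.adjust_predictive_values(
                self.SENS, self.SPEC, sx.PrevalenceScenario(pi, "linear"),
                cohort_ppv=54 / 119, cohort_prevalence=67 / 385)
            ratios.append(b / l)
        assert ratios[1] == pytest.approx(ratios[2], rel=1e-2)

    def test_degenerate_prevalence_rejected(self):
        with pytest.raises(DegenerateInputError):
            sx.PrevalenceScenario(0.0)
        with pytest.raises(DegenerateInputError):
            sx.PrevalenceScenario(1.0)


class TestSubgroupSensitivity:
    def _cohort(self):
        truth, preds = [], []
        # 33 glioblastoma: 30 detected; 34 other cancers: 24 detected; controls.
        for i in range(33):
            pid = f"G{i}"
            truth.append(sx.PatientRecord(pid, CANCER, "glioblastoma"))
            preds.append(_pred(pid, CANCER if i < 30 else NON_CANCER))
        for i in range(34):
            pid = f"M{i}"
            truth.append(sx.PatientRecord(pid, CANCER, "metastasis"))
            preds.append(_pred(pid, CANCER if i < 24 else NON_CANCER))
        for i in range(10):
            pid = f"N{i}"
            truth.append(sx.PatientRecord(pid, NON_CANCER))
            preds.append(_pred(pid, NON_CANCER))
        return preds, truth

    def test_glioblastoma_subset(self):
        preds, truth = self._cohort()
        p, (lo, hi) = sx.subgroup_sensitivity(preds, truth, "glioblastoma")
        assert round(100 * p) == 91
        assert lo <= p <= hi

    def test_union_of_subgroups_equals_overall(self):
        preds, truth = self._cohort()
        g, _ = sx.subgroup_sensitivity(preds, truth, "glioblastoma")
        m, _ = sx.subgroup_sensitivity(preds, truth, "metastasis")
        overall = sx.DiagnosticAccuracy.from_predictions(preds, truth).fit().sensitivity
        assert overall == pytest.approx((33 * g + 34 * m) / 67)

    def test_single_patient_subgroup(self):
        truth = [sx.PatientRecord("A", CANCER, "ependymoma"),
                 sx.PatientRecord("B", NON_CANCER)]
        preds = [_pred("A", CANCER), _pred("B", NON_CANCER)]
        p, _ = sx.subgroup_sensitivity(preds, truth, "ependymoma")
        assert p == 1.0

    def test_empty_subgroup_flagged(self):
        preds, truth = self._cohort()
        with pytest.raises(UndefinedMetricError):
            sx.subgroup_sensitivity(preds, truth, "schwannoma")


def test_summary_text_mirrors_published_layout():
    res = sx.DiagnosticAccuracy.from_counts(**STUDY).fit()
    text = res.summary()
    assert "sensitivity" in text and "81%" in text and "95%" in text
    assert "119" in text and "266" in text and "385" in text
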