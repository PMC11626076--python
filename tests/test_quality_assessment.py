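import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctqa import (
    RatingTable,
    ScanRecord,
    diagnostic_decision,
    fit_dose_response,
    icc_3k,
    threshold_analysis,
)
from ctqa.quality_assessment import QUALITY_ITEMS, RATING_ITEMS, icc_interpretation
from ctqa.sharpness import ScanSharpness


def make_ratings(scores_by_scan):
    """scores_by_scan: {scan: {reader: {item: score}}} -> RatingTable."""
    rows = []
    for scan, readers in scores_by_scan.items():
        for reader, items in readers.items():
            for item, score in items.items():
                rows.append(
                    {"scan_id": scan, "reader_id": reader, "item": item, "score": score}
                )
    return RatingTable(pd.DataFrame(rows))


def uniform_scores(overall, item_score):
    return {"overall": overall, **{item: item_score for item in QUALITY_ITEMS}}


class TestDiagnosticDecision:
    def test_maximum_scores_diagnostic(self):
        ratings = make_ratings(
            {"s1": {r: uniform_scores(4, 4) for r in ("a", "b", "c")}}
        )
        d = diagnostic_decision(ratings, "s1")
        assert d.mean_item_sum == 20.0 and d.diagnostic

    def test_just_above_both_cutoffs(self):
        ratings = make_ratings(
            {"s1": {r: uniform_scores(3, 3) for r in ("a", "b", "c")}}
        )
        d = diagnostic_decision(ratings, "s1")
        assert d.mean_item_sum == 15.0
        assert d.all_readers_overall_ok and d.diagnostic

    def test_sum_exactly_14_not_diagnostic(self):
        # items (3,3,3,3,2) sum to 14 for every reader: strict inequality fails
        items = dict(zip(QUALITY_ITEMS, (3, 3, 3, 3, 2)))
        ratings = make_ratings(
            {"s1": {r: {"overall": 4, **items} for r in ("a", "b", "c")}}
        )
        d = diagnostic_decision(ratings, "s1")
        assert d.mean_item_sum == 14.0
        assert d.all_readers_overall_ok and not d.diagnostic

    def test_one_reader_overall_below_3_blocks(self):
        scans = {
            "s1": {
                "a": uniform_scores(4, 4),
                "b": uniform_scores(4, 4),
                "c": uniform_scores(2, 4),
            }
        }
        d = diagnostic_decision(make_ratings(scans), "s1")
        assert d.mean_item_sum == 20.0 and not d.diagnostic

    def test_missing_ratings_listed(self):
        rows = pd.DataFrame(
            [{"scan_id": "s1", "reader_id": "a", "item": "overall", "score": 4}]
        )
        ratings = RatingTable(rows)
        with pytest.raises(ValueError, match="missing ratings"):
            diagnostic_decision(ratings, "s1")

    def test_invalid_score_rejected(self):
        rows = pd.DataFrame(
            [{"scan_id": "s1", "reader_id": "a", "item": "overall", "score": 5}]
        )
        with pytest.raises(ValueError, match="1..4"):
            RatingTable(rows)

    @given(
        base=st.lists(st.integers(1, 3), min_size=5, max_size=5),
        overall=st.integers(3, 4),
        bump_idx=st.integers(0, 4),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_raising_a_score_never_breaks_diagnostic(self, base, overall, bump_idx):
        items = dict(zip(QUALITY_ITEMS, base))
        ratings = make_ratings(
            {"s": {r: {"overall": overall, **items} for r in ("a", "b", "c")}}
        )
        before = diagnostic_decision(ratings, "s").diagnostic

        bumped = dict(items)
        key = QUALITY_ITEMS[bump_idx]
        bumped[key] = min(4, bumped[key] + 1)
        ratings_after = make_ratings(
            {"s": {r: {"overall": overall, **bumped} for r in ("a", "b", "c")}}
        )
        after = diagnostic_decision(ratings_after, "s").diagnostic
        assert after or not before  # diagnostic can only turn on, never off


def icc_3k_anova_oracle(matrix):
    """Brute-force two-way ANOVA from sum-of-squares definitions."""
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape
    grand = m.sum() / (n * k)
    ss_rows = 0.0
    for i in range(n):
        ss_rows += k * (m[i, :].sum() / k - grand) ** 2
    ss_cols = 0.0
    for j in range(k):
        ss_cols += n * (m[:, j].sum() / n - grand) ** 2
    ss_total = 0.0
    for i in range(n):
        for j in range(k):
            ss_total += (m[i, j] - grand) ** 2
    msr = ss_rows / (n - 1)
    mse = (ss_total - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / msr


class TestICC3k:
    def test_perfect_agreement(self):
        scores = np.tile(np.array([[1.0], [2.0], [3.0], [4.0]]), (1, 3))
        assert icc_3k(scores).value == pytest.approx(1.0)

    def test_independent_scores_near_zero(self):
        rng = np.random.default_rng(0)
        scores = rng.integers(1, 5, size=(200, 3)).astype(float)
        assert abs(icc_3k(scores).value) < 0.15

    def test_small_matrix_matches_anova_oracle(self):
        scores = np.array([[1, 2], [3, 3], [2, 4], [4, 4]], dtype=float)
        assert icc_3k(scores).value == pytest.approx(icc_3k_anova_oracle(scores), abs=1e-12)

    def test_random_matrices_match_anova_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            scores = rng.normal(size=(10, 3))
            assert icc_3k(scores).value == pytest.approx(
                icc_3k_anova_oracle(scores), abs=1e-10
            )

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        scores = rng.integers(1, 5, size=(12, 3)).astype(float)
        long = pd.DataFrame(
            [
                {"targets": i, "raters": j, "ratings": scores[i, j]}
                for i in range(12)
                for j in range(3)
            ]
        )
        ref = pg.intraclass_corr(
            data=long, targets="targets", raters="raters", ratings="ratings"
        )
        # pingouin labels ICC(3,k) as ICC(C,k): consistency, average measures
        ref_value = ref.loc[ref["Type"] == "ICC(C,k)", "ICC"].item()
        assert icc_3k(scores).value == pytest.approx(ref_value, abs=1e-9)

    def test_reader_offset_invariance(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=(15, 4))
        shifted = scores + np.array([10.0, -3.0, 0.5, 7.0])
        assert icc_3k(shifted).value == pytest.approx(icc_3k(scores).value, abs=1e-10)

    def test_at_most_one(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            scores = rng.normal(size=(6, 3))
            assert icc_3k(scores).value <= 1.0 + 1e-12

    def test_interpretation_bands(self):
        assert icc_interpretation(0.3) == "poor"
        assert icc_interpretation(0.6) == "moderate"
        assert icc_interpretation(0.8) == "good"
        assert icc_interpretation(0.95) == "excellent"

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(42)
        subject = rng.normal(size=(30, 1))
        scores = subject + rng.normal(scale=0.3, size=(30, 3))
        result = icc_3k(scores)
        assert result.ci_low < result.value < result.ci_high
        assert result.ci_high <= 1.0

    def test_missing_cells_rejected(self):
        scores = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="missing"):
            icc_3k(scores)

    def test_degenerate_rows_rejected(self):
        with pytest.raises(ValueError, match="ICC undefined"):
            icc_3k(np.ones((5, 3)))


class TestDoseResponse:
    def test_exact_cubic_recovered(self):
        x = np.linspace(0.05, 1.6, 13)
        coef = np.array([1.0, 250.0, -120.0, 30.0])
        y = np.polynomial.polynomial.polyval(x, coef)
        fit = fit_dose_response(x, y, degree=3)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(fit.coefficients, coef, rtol=1e-8)

    def test_constant_response_zero_higher_order(self):
        x = np.linspace(0, 1, 10)
        fit = fit_dose_response(x, np.full(10, 5.0), degree=2)
        np.testing.assert_allclose(fit.coefficients[1:], 0.0, atol=1e-9)
        assert fit.predict(0.5) == pytest.approx(5.0)

    def test_cubic_beats_linear_on_curved_data(self):
        rng = np.random.default_rng(10)
        x = np.linspace(0.04, 1.6, 13)
        y = 2000 * np.sqrt(x / (x + 0.3)) + rng.normal(0, 20, 13)
        cubic = fit_dose_response(x, y, degree=3)
        linear = fit_dose_response(x, y, degree=1)
        assert cubic.residual_ss < linear.residual_ss

    def test_rank_deficient_rejected(self):
        with pytest.raises(ValueError, match="rank deficient"):
            fit_dose_response([1, 1, 1, 1, 1, 1], [1, 2, 3, 4, 5, 6], degree=2)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            fit_dose_response([1, 2, 3], [1, 2, 3], degree=2)

    def test_ci_band_contains_fit(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0, 1, 20)
        y = 3 * x**2 + rng.normal(0, 0.1, 20)
        fit = fit_dose_response(x, y, degree=2)
        lo, hi = fit.ci_band(x)
        center = fit.predict(x)
        assert np.all(lo <= center) and np.all(center <= hi)


def _sharp(median):
    return ScanSharpness(median_steepness=median, n_total=1, n_converged=1, n_included=1)


def _decision(scan_id, diagnostic):
    from ctqa.quality_assessment import DiagnosticDecision

    return DiagnosticDecision(
        scan_id=scan_id,
        mean_item_sum=17.0 if diagnostic else 10.0,
        all_readers_overall_ok=diagnostic,
        diagnostic=diagnostic,
    )


def _record(ctdi, **kw):
    return ScanRecord(kvp=100, ma=10, rotation_time=0.28, ctdi_vol=ctdi, **kw)


class TestThresholdAnalysis:
    def test_single_diagnostic_scan(self):
        scans = [(_record(0.14), _sharp(713.0), _decision("s1", True))]
        result = threshold_analysis(scans)
        assert result.found
        assert result.sharpness_cutoff == pytest.approx(713.0)

    def test_flip_point_selected(self):
        ctdis = [0.04, 0.07, 0.14, 0.22, 0.32]
        scans = [
            (_record(c), _sharp(100.0 * i), _decision(f"s{i}", c >= 0.14))
            for i, c in enumerate(ctdis)
        ]
        result = threshold_analysis(scans)
        assert result.record.ctdi_vol == pytest.approx(0.14)
        assert result.sharpness_cutoff == pytest.approx(200.0)

    def test_all_diagnostic_returns_minimum_dose(self):
        scans = [
            (_record(c), _sharp(500 + i), _decision(f"s{i}", True))
            for i, c in enumerate([0.32, 0.04, 0.14])
        ]
        result = threshold_analysis(scans)
        assert result.record.ctdi_vol == pytest.approx(0.04)

    def test_no_diagnostic_scan_empty_result(self):
        scans = [(_record(0.14), _sharp(713.0), _decision("s1", False))]
        result = threshold_analysis(scans)
        assert not result.found and result.record is None
        assert math.isnan(result.sharpness_cutoff)

    def test_order_invariance(self):
        scans = [
            (_record(c), _sharp(100.0 * i), _decision(f"s{i}", True))
            for i, c in enumerate([0.32, 0.04, 0.14, 0.22])
        ]
        forward = threshold_analysis(scans)
        backward = threshold_analysis(list(reversed(scans)))
        assert forward.record is backward.record

    def test_effective_dose_preferred_over_ctdi(self):
        from ctqa import default_conversion_table

        table = default_conversion_table()
        # higher CTDIvol but much shorter scan -> lower effective dose
        low_ed = _record(0.10, scan_length=10, ap_diameter=26, ml_diameter=26)
        high_ed = _record(0.08, scan_length=40, ap_diameter=26, ml_diameter=26)
        scans = [
            (high_ed, _sharp(900.0), _decision("a", True)),
            (low_ed, _sharp(700.0), _decision("b", True)),
        ]
        result = threshold_analysis(scans, table=table)
        assert result.record is low_ed
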