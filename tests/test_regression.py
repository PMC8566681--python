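"""Correlation screen and grouped shelf-life regression models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxishelf import (
    GroupedRegressionModel,
    InsufficientDataError,
    OilRecord,
    OxishelfError,
    ParameterError,
    fit_grouped_model,
    pearson_with_significance,
    predict_shelf_life,
    simple_group_regressions,
)


def normal_equations(x1, x2, y):
    """Independent brute-force solver: (X'X) b = X'y via explicit 3x3 solve."""
    n = len(y)
    X = [[1.0, a, b] for a, b in zip(x1, x2)]
    XtX = [[sum(X[k][i] * X[k][j] for k in range(n)) for j in range(3)] for i in range(3)]
    Xty = [sum(X[k][i] * y[k] for k in range(n)) for i in range(3)]
    return np.linalg.solve(np.array(XtX), np.array(Xty))


class TestPearson:
    def test_ufa_against_ambient_shelf_life(self, oil_records):
        x = [r.ufa for r in oil_records]
        y = [r.shelf_life_25 for r in oil_records]
        r, p = pearson_with_significance(x, y)
        assert round(r, 4) == -0.6951
        assert p < 0.05  # reported as significant

    def test_iodine_value_not_significant(self, oil_records):
        x = [r.iodine_value for r in oil_records]
        y = [r.shelf_life_25 for r in oil_records]
        r, p = pearson_with_significance(x, y)
        assert r == pytest.approx(-0.5320, abs=5e-4)
        assert p > 0.05

    def test_exact_linearity(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, p = pearson_with_significance(x, [2 * v + 1 for v in x])
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(OxishelfError, match="zero variance"):
            pearson_with_significance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @settings(deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(st.floats(-50, 50), st.floats(-50, 50)), min_size=4, max_size=12
        ),
        scale=st.floats(0.1, 10.0),
        shift=st.floats(-100, 100),
    )
    def test_invariance_under_positive_affine_maps(self, data, scale, shift):
        x, y = map(np.array, zip(*data))
        if np.ptp(x) < 1e-6 or np.ptp(y) < 1e-6:
            return
        r0, _ = pearson_with_significance(x, y)
        r1, _ = pearson_with_significance(scale * x + shift, y)
        r2, _ = pearson_with_significance(-x, y)
        assert r1 == pytest.approx(r0, abs=1e-9)
        assert r2 == pytest.approx(-r0, abs=1e-9)


class TestGroupedModel:
    def test_ufa_model_at_25C(self, oil_records):
        m = fit_grouped_model(oil_records, "UFAs", 25)
        assert (round(m.b1), round(m.b2), round(m.b0)) == (-88, 347, 7868)
        assert m.multiple_r == pytest.approx(0.8885, abs=5e-4)
        assert m.p_value == pytest.approx(0.0093, abs=5e-4)
        assert m.n == 9

    def test_sfa_model_significance_at_20C(self, oil_records):
        m = fit_grouped_model(oil_records, "SFAs", 20)
        assert m.p_value == pytest.approx(0.0266, abs=5e-4)

    def test_constant_response_guarded(self):
        records = [
            OilRecord(f"o{i}", 100.0, 100.0, sfa=10.0 + i, ufa=90.0 - i, pufa=30.0,
                      group_x2=i % 2)
            for i in range(6)
        ]
        m = fit_grouped_model(records, "SFAs", 25)
        assert m.multiple_r == 0.0
        assert m.p_value == 1.0

    def test_single_group_rejected(self, oil_records):
        one_group = [r for r in oil_records if r.group_x2 == 0]
        with pytest.raises(InsufficientDataError, match="one X2 group"):
            fit_grouped_model(one_group * 2, "UFAs", 25)

    def test_matches_brute_force_normal_equations(self, oil_records):
        rng = np.random.default_rng(1234)
        for _ in range(20):
            n = int(rng.integers(5, 12))
            x1 = rng.uniform(5, 95, n)
            x2 = rng.integers(0, 2, n).astype(float)
            if len(set(x2.tolist())) < 2:
                continue
            y = rng.uniform(50, 2000, n)
            records = [
                OilRecord(f"o{i}", y[i], y[i], sfa=x1[i], ufa=100 - x1[i],
                          pufa=30.0, group_x2=int(x2[i]))
                for i in range(n)
            ]
            m = fit_grouped_model(records, "SFAs", 25)
            b = normal_equations(x1, x2, y)
            assert np.allclose([m.b0, m.b1, m.b2], b, rtol=1e-9, atol=1e-9)


class TestPredict:
    def test_prediction_with_fitted_coefficients(self, oil_records):
        m = fit_grouped_model(oil_records, "UFAs", 25)
        assert predict_shelf_life(m, x1=84.06, x2=1) == 841

    def test_prediction_with_published_integer_coefficients(self):
        m = GroupedRegressionModel(
            predictor_name="UFAs", response=25, b0=7868.0, b1=-88.0, b2=347.0,
            multiple_r=0.8885, p_value=0.0093, n=9,
        )
        assert predict_shelf_life(m, x1=84.06, x2=1) == 818

    def test_intercept_only_model(self):
        m = GroupedRegressionModel(
            predictor_name="UFAs", response=25, b0=500.0, b1=0.0, b2=0.0,
            multiple_r=0.0, p_value=1.0, n=9,
        )
        for x1 in (0.0, 50.0, 99.0):
            assert predict_shelf_life(m, x1=x1, x2=0) == 500

    def test_invalid_group_indicator(self, oil_records):
        m = fit_grouped_model(oil_records, "UFAs", 25)
        with pytest.raises(ParameterError, match="x2"):
            predict_shelf_life(m, x1=85.0, x2=2)

    def test_negative_prediction_warned_not_clamped(self):
        m = GroupedRegressionModel(
            predictor_name="UFAs", response=25, b0=-100.0, b1=0.0, b2=0.0,
            multiple_r=0.5, p_value=0.1, n=9,
        )
        with pytest.warns(UserWarning, match="negative"):
            assert predict_shelf_life(m, x1=50.0, x2=0) == -100


class TestGroupLines:
    def test_ufa_lines_are_tight_in_both_groups(self, oil_records):
        for response in (20, 25):
            lines = simple_group_regressions(oil_records, "UFAs", response)
            for line in lines.values():
                assert abs(line.r) > 0.98
                assert line.p_value < 0.05

    def test_two_point_group_rejected(self, oil_records):
        trimmed = [r for r in oil_records if r.group_x2 == 1] + [
            r for r in oil_records if r.group_x2 == 0
        ][:2]
        with pytest.raises(InsufficientDataError):
            simple_group_regressions(trimmed, "UFAs", 25)

    def test_exact_line_gives_unit_correlation(self):
        records = [
            OilRecord(f"a{i}", 10.0 + 5 * i, 10.0 + 5 * i, sfa=10.0 + i,
                      ufa=90.0 - i, pufa=30.0, group_x2=0)
            for i in range(4)
        ] + [
            OilRecord(f"b{i}", 500.0 - 10 * i, 500.0 - 10 * i, sfa=20.0 + i,
                      ufa=80.0 - i, pufa=30.0, group_x2=1)
            for i in range(4)
        ]
        lines = simple_group_regressions(records, "SFAs", 25)
        assert lines[0].r == pytest.approx(1.0)
        assert lines[1].r == pytest.approx(-1.0)


def test_excluded_oil_never_enters_models(oil_records):
    # the chlorophyll-confounded oil is excluded from the nine-oil analyses
    assert len(oil_records) == 9
    assert all(r.oil_id != "Pumpkin seed oil" for r in oil_records)
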