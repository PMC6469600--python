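import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from socmon.diagnostics import (
    annual_rate_from_total_change,
    compound_annual_change,
    compute_stock,
    log_slope_from_relative_change,
    relative_change_from_log_slope,
    significance_stars,
    soc_at_ratio_threshold,
    soc_clay_ratio,
    spearman_matrix,
    stocks_table,
)
from socmon.data_model import load_table1_fixture


class TestStock:
    def test_low_and_high_carbon_sites(self):
        assert round(compute_stock(11.9, 1.21, 20)) == 29
        assert round(compute_stock(38.2, 1.05, 20)) == 80

    def test_zero_soc_gives_zero_stock(self):
        assert compute_stock(0.0, 1.2, 20) == 0.0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            compute_stock(-1.0, 1.2, 20)

    @settings(deadline=None, max_examples=40)
    @given(
        soc=st.floats(1, 60), ad=st.floats(0.5, 1.6), k=st.floats(0.1, 5.0)
    )
    def test_linearity_in_each_argument(self, soc, ad, k):
        base = compute_stock(soc, ad, 20)
        assert compute_stock(k * soc, ad, 20) == pytest.approx(k * base, rel=1e-12)
        assert compute_stock(soc, k * ad, 20) == pytest.approx(k * base, rel=1e-12)

    def test_stocks_table_carries_printed_column(self):
        tab = stocks_table(load_table1_fixture())
        assert len(tab) == 30
        assert tab.printed_stock_t_ha.notna().all()


class TestSocClayRatio:
    def test_constructed_boundary_case(self):
        assert soc_clay_ratio(24.0, 20.0) == pytest.approx(0.12)

    def test_very_clayey_site(self):
        assert soc_clay_ratio(28.9, 59.0) == pytest.approx(0.049, abs=5e-4)

    def test_linear_in_soc(self):
        assert soc_clay_ratio(20.0, 25.0) * 2 == pytest.approx(soc_clay_ratio(40.0, 25.0))

    def test_zero_clay_rejected(self):
        with pytest.raises(ValueError):
            soc_clay_ratio(20.0, 0.0)

    def test_threshold_line_is_linear_through_origin(self):
        assert soc_at_ratio_threshold(10.0) == pytest.approx(12.0)
        assert soc_at_ratio_threshold(5.0) == pytest.approx(6.0)


class TestSlopeConversions:
    def test_declining_decadal_slope(self):
        assert relative_change_from_log_slope(-0.13) == pytest.approx(-12.19, abs=0.005)

    def test_zero_slope(self):
        assert relative_change_from_log_slope(0.0) == 0.0

    def test_increasing_decadal_slope_exact_value(self):
        # exp(0.11) - 1 = 11.63 %, reported at full precision (not re-rounded)
        assert relative_change_from_log_slope(0.11) == pytest.approx(11.63, abs=0.005)

    def test_inverse_pair(self):
        for pct in (-12.0, 0.0, 11.0):
            s = log_slope_from_relative_change(pct)
            assert relative_change_from_log_slope(s) == pytest.approx(pct, abs=1e-10)

    def test_compound_and_decadal_conversion_agree(self):
        r = 0.5  # % per year
        ten_year = compound_annual_change(r, 10)
        slope = 10 * np.log1p(r / 100)
        assert relative_change_from_log_slope(slope) == pytest.approx(ten_year, rel=1e-12)


class TestCompoundChange:
    def test_two_decade_projection(self):
        total, endpoint = compound_annual_change(0.35, 20, baseline=20.0)
        assert total == pytest.approx(7.24, abs=0.005)
        assert endpoint == pytest.approx(21.45, abs=0.005)

    def test_zero_rate(self):
        total, endpoint = compound_annual_change(0.0, 37, baseline=13.0)
        assert total == 0.0 and endpoint == 13.0

    def test_annualising_a_total_change(self):
        assert annual_rate_from_total_change(7.0, 12) == pytest.approx(0.565, abs=0.002)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compound_annual_change(-100.0, 5)
        with pytest.raises(ValueError):
            annual_rate_from_total_change(5.0, 0)


class TestSpearmanMatrix:
    def test_monotone_transform_gives_unit_correlation(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, 5], "y": [1.0, 4, 9, 16, 25]})
        m = spearman_matrix(df)
        assert m.rho.loc["x", "y"] == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [4.0, 3, 2, 1]})
        assert spearman_matrix(df).rho.loc["x", "y"] == pytest.approx(-1.0)

    def test_pairwise_complete_observations(self, rng):
        df = pd.DataFrame(
            {"a": rng.normal(size=20), "b": rng.normal(size=20), "c": rng.normal(size=20)}
        )
        df.loc[:4, "b"] = np.nan
        m = spearman_matrix(df)
        assert m.n.loc["a", "b"] == 15
        assert m.n.loc["a", "c"] == 20
        assert np.allclose(m.rho.values, m.rho.values.T, equal_nan=True)

    def test_sparse_pair_reported_missing(self):
        df = pd.DataFrame({"a": [1.0, 2, np.nan, np.nan], "b": [1.0, np.nan, 2, 3]})
        m = spearman_matrix(df, min_pairs=3)
        assert np.isnan(m.rho.loc["a", "b"])

    def test_null_star_rate_near_nominal(self, rng):
        hits = 0
        reps = 400
        for _ in range(reps):
            x, y = rng.normal(size=30), rng.normal(size=30)
            m = spearman_matrix(pd.DataFrame({"x": x, "y": y}))
            hits += m.p_value.loc["x", "y"] < 0.05
        rate = hits / reps
        assert 0.02 <= rate <= 0.09  # 3-sigma binomial band around 0.05

    def test_star_codes(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.2) == ""

    def test_annotated_table_combines_rho_and_stars(self):
        df = pd.DataFrame({"x": np.arange(10.0), "y": np.arange(10.0) ** 2})
        ann = spearman_matrix(df).annotated()
        assert ann.loc["x", "y"].endswith("***")
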