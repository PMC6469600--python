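import math

import numpy as np
import pandas as pd
import pytest

from socmon.data_model import ValidationError, aggregate_replicates
from socmon.synthetic_data import DesignSpec, SyntheticNetworkConfig, generate_network
from socmon.trend_inference import (
    back_transform,
    decades_since_start,
    fit_campaign_effects,
    fit_global_trend,
)


def balanced_agg(n_sites, campaign_means, site_effects, noise=None, start_year=1990.0):
    """Site-campaign mean-log table: y = site effect + campaign mean (+ noise)."""
    rows = []
    T = len(campaign_means)
    for i in range(n_sites):
        for t in range(T):
            y = site_effects[i] + campaign_means[t]
            if noise is not None:
                y += noise[i, t]
            rows.append((f"s{i}", t + 1, start_year + 5.0 * t, y, 4))
    return pd.DataFrame(
        rows, columns=["site_id", "campaign", "year", "mean_log_soc", "n_replicates"]
    )


class TestCampaignEffects:
    def test_noiseless_effects_recovered_exactly(self):
        beta = [0.0, 0.05, -0.03, 0.10]
        fit = fit_campaign_effects(balanced_agg(5, beta, np.linspace(2.5, 3.5, 5)))
        assert fit.residual_sd == 0.0
        for c, b in zip((1, 2, 3, 4), beta):
            assert fit.campaign_effects[c] == pytest.approx(b, abs=1e-10)

    def test_balanced_contrast_equals_difference_of_means(self, rng):
        noise = rng.normal(0, 0.05, size=(8, 4))
        agg = balanced_agg(8, [3.0, 3.02, 2.98, 3.05], rng.normal(0, 0.3, 8), noise)
        fit = fit_campaign_effects(agg)
        piv = agg.pivot(index="site_id", columns="campaign", values="mean_log_soc")
        for d in fit.pairwise_differences:
            expected = piv[d.campaign_b].mean() - piv[d.campaign_a].mean()
            assert d.diff_log == pytest.approx(expected, abs=1e-6)

    def test_campaign_estimates_backtransformed_with_ci(self, rng):
        agg = balanced_agg(6, [3.0, 3.1], rng.normal(0, 0.3, 6), rng.normal(0, 0.04, (6, 2)))
        fit = fit_campaign_effects(agg)
        for e in fit.campaign_estimates:
            assert e.ci_low_g_per_kg < e.mean_g_per_kg < e.ci_high_g_per_kg
            assert e.mean_g_per_kg == pytest.approx(math.exp(e.log_mean))

    def test_variance_components_recovered_in_simulation(self):
        """Site-intercept and residual SDs estimated without material bias."""
        true_site, true_resid = 0.3, 0.05
        rng = np.random.default_rng(7)
        est = np.empty((200, 2))
        for k in range(200):
            agg = balanced_agg(
                30, [3.0, 3.01, 2.99, 3.02, 3.0],
                rng.normal(0, true_site, 30), rng.normal(0, true_resid, (30, 5)),
            )
            fit = fit_campaign_effects(agg)
            est[k] = (fit.site_intercept_sd, fit.residual_sd)
        assert est[:, 0].mean() == pytest.approx(true_site, rel=0.05)
        assert est[:, 1].mean() == pytest.approx(true_resid, rel=0.05)

    def test_single_campaign_rejected(self):
        with pytest.raises(ValidationError):
            fit_campaign_effects(balanced_agg(4, [3.0], np.zeros(4)))

    def test_nonfinite_input_rejected(self):
        agg = balanced_agg(3, [3.0, 3.1], np.zeros(3))
        agg.loc[0, "mean_log_soc"] = np.nan
        with pytest.raises(ValidationError, match="finite"):
            fit_campaign_effects(agg)

    def test_holm_adjustment_is_monotone(self, rng):
        agg = balanced_agg(6, [3.0, 3.1, 3.0], rng.normal(0, 0.3, 6), rng.normal(0, 0.05, (6, 3)))
        fit = fit_campaign_effects(agg, holm_adjust=True)
        for d in fit.pairwise_differences:
            assert d.p_adjusted >= d.p_value


class TestGlobalTrend:
    def test_exact_shared_slope_recovered(self):
        slope = 0.05  # log units per decade
        rows = []
        for i, a in enumerate([2.5, 3.0, 3.5]):
            for t in range(4):
                rows.append((f"s{i}", t + 1, 1990 + 5 * t, a + slope * (0.5 * t), 4))
        agg = pd.DataFrame(rows, columns=["site_id", "campaign", "year", "mean_log_soc", "n_replicates"])
        fit = fit_global_trend(agg)
        assert fit.global_slope == pytest.approx(slope, abs=1e-12)
        assert fit.site_slope_sd == pytest.approx(0.0, abs=1e-12)
        assert fit.residual_sd == 0.0
        assert all(v == pytest.approx(slope, abs=1e-12) for v in fit.site_slopes.values())

    def test_shift_invariance(self):
        ds, _ = generate_network(
            SyntheticNetworkConfig(design=DesignSpec(n_sites=12), global_annual_trend=0.3, seed=5)
        )
        agg = aggregate_replicates(ds)
        fit1 = fit_global_trend(agg)
        shifted = agg.assign(mean_log_soc=agg.mean_log_soc + 1.7)
        fit2 = fit_global_trend(shifted)
        assert fit2.mu - fit1.mu == pytest.approx(1.7, abs=1e-6)
        assert fit2.global_slope == pytest.approx(fit1.global_slope, abs=1e-7)
        assert fit2.residual_sd == pytest.approx(fit1.residual_sd, abs=1e-6)

    def test_site_slope_blups_centre_on_global_slope(self):
        ds, _ = generate_network(
            SyntheticNetworkConfig(design=DesignSpec(n_sites=24), global_annual_trend=0.4, seed=9)
        )
        fit = fit_global_trend(aggregate_replicates(ds))
        blup_mean = np.mean(list(fit.site_slopes.values()))
        assert abs(blup_mean - fit.global_slope) < 0.25 * abs(fit.slope_se) + 1e-3

    def test_too_few_sites_rejected_and_short_series_warn(self):
        agg = balanced_agg(1, [3.0, 3.1, 3.2], [0.0])
        with pytest.raises(ValidationError):
            fit_global_trend(agg)
        two_point = balanced_agg(3, [3.0, 3.1], [0.0, 0.2, 0.4])
        with pytest.warns(UserWarning, match="fewer than 3 time points"):
            fit_global_trend(two_point)


class TestBackTransform:
    def test_exp_zero_is_one(self):
        assert back_transform(0.0) == 1.0

    def test_round_trip(self):
        assert back_transform(math.log(20)) == pytest.approx(20.0)

    def test_ci_ordering_preserved(self):
        g, lo, hi = back_transform(math.log(20), math.log(17.1), math.log(23.7))
        assert (g, lo, hi) == (pytest.approx(20.0), pytest.approx(17.1), pytest.approx(23.7))
        assert lo < g < hi


def test_time_is_coded_in_decades():
    t = decades_since_start([1990.0, 1995.0, 2010.0])
    np.testing.assert_allclose(t, [0.0, 0.5, 2.0])
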