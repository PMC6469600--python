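import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from socmon.bootstrap_trends import (
    BootstrapConfig,
    bootstrap_site_slopes,
    classify_trend,
    ols_slope,
    summaries_to_frame,
    trend_class_counts,
)
from socmon.data_model import ValidationError
from conftest import make_measurements


class TestOlsSlope:
    @pytest.mark.parametrize(
        "t,y,expected",
        [
            ([0, 1, 2], [0, 1, 2], 1.0),
            ([0, 1, 2], [5, 5, 5], 0.0),
            ([0, 1, 2], [0, 0, 3], 1.5),  # cov/var closed form by hand
        ],
    )
    def test_closed_form_examples(self, t, y, expected):
        assert ols_slope(t, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_time_rejected(self):
        with pytest.raises(ValidationError):
            ols_slope([1.0, 1.0], [0.0, 1.0])

    @settings(deadline=None, max_examples=40)
    @given(
        scale=st.floats(min_value=0.1, max_value=100.0),
        shift=st.floats(min_value=-50, max_value=50),
        seed=st.integers(0, 1000),
    )
    def test_time_rescaling_inversely_rescales_slope(self, scale, shift, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(5.0)
        y = rng.normal(0, 1, 5)
        base = ols_slope(t, y)
        assert ols_slope(t * scale, y) == pytest.approx(base / scale, rel=1e-9, abs=1e-12)
        assert ols_slope(t, y + shift) == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestClassifyTrend:
    @pytest.mark.parametrize(
        "lo,hi,expected",
        [(0.01, 0.10, "increasing"), (-0.10, -0.01, "decreasing"), (-0.02, 0.03, "stable")],
    )
    def test_interval_rule(self, lo, hi, expected):
        assert classify_trend(lo, hi) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_trend(float("nan"), 0.1)


def exact_linear_dataset(slope_per_decade=0.08, n_campaigns=5):
    """Replicates identical within campaigns; campaign means exactly linear."""
    vals = {
        c: [math.exp(3.0 + slope_per_decade * 0.5 * (c - 1))] * 4
        for c in range(1, n_campaigns + 1)
    }
    return make_measurements({"A": vals})


class TestBootstrapSiteSlopes:
    def test_degenerate_noise_free_collapses_to_true_slope(self):
        df = exact_linear_dataset(slope_per_decade=0.08)
        (s,) = bootstrap_site_slopes(df, BootstrapConfig(n_iterations=50, seed=1))
        assert s.slope_q025 == pytest.approx(0.08, abs=1e-12)
        assert s.slope_q975 == pytest.approx(0.08, abs=1e-12)
        assert s.slope_mean == pytest.approx(0.08, abs=1e-12)
        assert s.trend_class == "increasing"

    def test_ensemble_size_counts_full_and_deletion_slopes(self):
        df = exact_linear_dataset(n_campaigns=5)
        (s,) = bootstrap_site_slopes(df, BootstrapConfig(n_iterations=100, seed=2))
        # 5 campaigns: full-data slope + 5 leave-one-out slopes per iteration
        assert s.n_ensemble == 100 * (1 + 5)

    def test_deletion_subsets_respect_campaign_minimum(self):
        df = exact_linear_dataset(n_campaigns=3)
        (s,) = bootstrap_site_slopes(
            df, BootstrapConfig(n_iterations=10, seed=3, min_campaigns_for_slope=3)
        )
        assert s.n_ensemble == 10  # dropping any campaign would leave only 2

    def test_same_seed_is_bit_identical_and_order_invariant(self, rng):
        vals = {
            s: {c: list(rng.lognormal(3.0, 0.1, 4)) for c in range(1, 6)}
            for s in ("a", "b", "c")
        }
        df = make_measurements(vals)
        cfg = BootstrapConfig(n_iterations=80, seed=11)
        r1 = summaries_to_frame(bootstrap_site_slopes(df, cfg))
        r2 = summaries_to_frame(bootstrap_site_slopes(df, cfg))
        shuffled = df.sample(frac=1.0, random_state=4).reset_index(drop=True)
        r3 = summaries_to_frame(bootstrap_site_slopes(shuffled, cfg))
        assert r1.equals(r2)
        assert r1.equals(r3)

    def test_shift_and_trend_injection(self, rng):
        """Adding c to log values changes nothing; adding d*t shifts slopes by d."""
        base = {c: list(rng.lognormal(3.0, 0.05, 4)) for c in range(1, 6)}
        df = make_measurements({"A": base})
        cfg = BootstrapConfig(n_iterations=60, seed=7)
        (s0,) = bootstrap_site_slopes(df, cfg)

        shifted = df.assign(soc_g_per_kg=df.soc_g_per_kg * math.exp(0.5))
        (s1,) = bootstrap_site_slopes(shifted, cfg)
        assert s1.slope_median == pytest.approx(s0.slope_median, abs=1e-10)

        d = 0.2  # log units per decade
        t_dec = (df.year - df.year.min()) / 10.0
        trended = df.assign(soc_g_per_kg=df.soc_g_per_kg * np.exp(d * t_dec))
        (s2,) = bootstrap_site_slopes(trended, cfg)
        assert s2.slope_median == pytest.approx(s0.slope_median + d, abs=1e-10)
        assert s2.slope_q025 == pytest.approx(s0.slope_q025 + d, abs=1e-10)

    def test_site_below_campaign_minimum_is_skipped_with_warning(self, rng, caplog):
        vals = {
            "ok": {c: list(rng.lognormal(3, 0.1, 4)) for c in range(1, 6)},
            "short": {c: list(rng.lognormal(3, 0.1, 4)) for c in range(1, 3)},
        }
        with caplog.at_level(logging.WARNING, logger="socmon.bootstrap_trends"):
            out = bootstrap_site_slopes(make_measurements(vals), BootstrapConfig(n_iterations=10, seed=1))
        assert [s.site_id for s in out] == ["ok"]
        assert any("skipped" in r.message for r in caplog.records)

    def test_summary_statistics_stabilise_with_iterations(self, rng):
        vals = {c: list(rng.lognormal(3.0, 0.15, 4)) for c in range(1, 6)}
        df = make_measurements({"A": vals})
        (small_a,) = bootstrap_site_slopes(df, BootstrapConfig(n_iterations=100, seed=1))
        (small_b,) = bootstrap_site_slopes(df, BootstrapConfig(n_iterations=100, seed=2))
        (big_a,) = bootstrap_site_slopes(df, BootstrapConfig(n_iterations=4000, seed=1))
        (big_b,) = bootstrap_site_slopes(df, BootstrapConfig(n_iterations=4000, seed=2))
        assert abs(big_a.slope_q975 - big_b.slope_q975) < abs(small_a.slope_q975 - small_b.slope_q975) + 1e-4

    def test_counts_sum_to_sites(self, rng):
        vals = {
            s: {c: list(rng.lognormal(3, 0.1, 4)) for c in range(1, 6)} for s in range(6)
        }
        out = bootstrap_site_slopes(make_measurements(vals), BootstrapConfig(n_iterations=50, seed=5))
        counts = trend_class_counts(out)
        assert sum(counts.values()) == 6
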