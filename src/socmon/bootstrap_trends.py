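"""Hierarchical bootstrap for per-site trend uncertainty and classification.

Within each site and campaign, replicates are resampled with replacement
(default: draw 4, the usual replicate count), the campaign mean of log SOC is
recomputed, and the per-site OLS slope over campaigns is derived.  Within the
same iteration the slope is recomputed once per leave-one-campaign-out subset
that still has enough campaigns, capturing the leverage of single time
points.  All slopes from all iterations are pooled into one ensemble per
site; the ensemble mean, median and 0.025/0.975 quantiles summarise the
probable range of the real trend, and a site is classed increasing if the
whole 0.025-0.975 range is above zero, decreasing if below, stable
otherwise.

Randomness: each site owns an RNG substream derived from the master seed and
a hash of its site id, so results are bit-reproducible and invariant to the
order in which sites are processed.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .data_model import MonitoringDataset, ValidationError

__all__ = [
    "BootstrapConfig",
    "SiteTrendSummary",
    "ols_slope",
    "bootstrap_site_slopes",
    "classify_trend",
    "summaries_to_frame",
    "trend_class_counts",
]

logger = logging.getLogger(__name__)

TREND_INCREASING = "increasing"
TREND_DECREASING = "decreasing"
TREND_STABLE = "stable"


@dataclass(frozen=True)
class BootstrapConfig:
    n_iterations: int = 500
    resample_size: int | None = 4   # None => draw n of n per site-campaign
    seed: int = 0
    min_campaigns_for_slope: int = 3
    pool_deletion_slopes: bool = True  # pool LOO slopes with full-data slopes

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.resample_size is not None and self.resample_size < 1:
            raise ValueError("resample_size must be >= 1")


@dataclass(frozen=True)
class SiteTrendSummary:
    site_id: int | str
    slope_mean: float      # log units per decade
    slope_median: float
    slope_q025: float
    slope_q975: float
    n_ensemble: int
    trend_class: str

    def __post_init__(self) -> None:
        if not (self.slope_q025 <= self.slope_median <= self.slope_q975):
            raise ValueError("summary quantiles are not ordered")


def ols_slope(times, values) -> float:
    """Ordinary least-squares slope of values against times."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 2 or np.ptp(t) == 0:
        raise ValidationError("slope needs at least 2 distinct time points")
    tc = t - t.mean()
    return float(tc @ (y - y.mean()) / (tc @ tc))


def classify_trend(slope_q025: float, slope_q975: float) -> str:
    """Increasing/decreasing when the central 95% slope range excludes zero."""
    if not (np.isfinite(slope_q025) and np.isfinite(slope_q975)):
        raise ValueError("trend classification needs finite quantiles")
    if slope_q025 > 0:
        return TREND_INCREASING
    if slope_q975 < 0:
        return TREND_DECREASING
    return TREND_STABLE


def _site_rng(seed: int, site_id) -> np.random.Generator:
    key = zlib.crc32(str(site_id).encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def _slopes_matrix(times: np.ndarray, means: np.ndarray) -> np.ndarray:
    """OLS slopes for each row of ``means`` against ``times`` (vectorised)."""
    tc = times - times.mean()
    denom = tc @ tc
    yc = means - means.mean(axis=1, keepdims=True)
    return (yc @ tc) / denom


def bootstrap_site_slopes(
    dataset: MonitoringDataset | pd.DataFrame,
    config: BootstrapConfig = BootstrapConfig(),
) -> list[SiteTrendSummary]:
    """Run the hierarchical bootstrap for every site in the dataset.

    Sites with fewer than ``min_campaigns_for_slope`` campaigns are skipped
    with a logged warning.  Fully reproducible given ``config.seed``.
    """
    df = dataset.measurements if isinstance(dataset, MonitoringDataset) else dataset
    year0 = float(df["year"].min())
    summaries = []
    for site in sorted(df["site_id"].unique(), key=str):
        sub = df[df["site_id"] == site]
        campaigns = np.sort(sub["campaign"].unique())
        if len(campaigns) < config.min_campaigns_for_slope:
            logger.warning(
                "site %r skipped: %d campaign(s) < minimum %d",
                site, len(campaigns), config.min_campaigns_for_slope,
            )
            continue
        sub = sub.sort_values(["campaign", "replicate"])  # row-order invariance
        logs = [
            np.log(sub.loc[sub["campaign"] == c, "soc_g_per_kg"].to_numpy(dtype=float))
            for c in campaigns
        ]
        times = np.array(
            [sub.loc[sub["campaign"] == c, "year"].mean() for c in campaigns], dtype=float
        )
        times = (times - year0) / 10.0  # decades
        summaries.append(_bootstrap_one_site(site, times, logs, config))
    return summaries


def _bootstrap_one_site(site, times, logs, config: BootstrapConfig) -> SiteTrendSummary:
    rng = _site_rng(config.seed, site)
    n_iter = config.n_iterations
    T = len(times)
    means = np.empty((n_iter, T))
    for j, vals in enumerate(logs):
        k = len(vals) if config.resample_size is None else config.resample_size
        idx = rng.integers(0, len(vals), size=(n_iter, k))
        means[:, j] = vals[idx].mean(axis=1)

    ensembles = [_slopes_matrix(times, means)]
    if config.pool_deletion_slopes:
        for drop in range(T):
            if T - 1 < config.min_campaigns_for_slope:
                continue
            keep = np.arange(T) != drop
            ensembles.append(_slopes_matrix(times[keep], means[:, keep]))
    pooled = np.concatenate(ensembles)

    q025, med, q975 = np.quantile(pooled, [0.025, 0.5, 0.975], method="linear")
    return SiteTrendSummary(
        site_id=site,
        slope_mean=float(pooled.mean()),
        slope_median=float(med),
        slope_q025=float(q025),
        slope_q975=float(q975),
        n_ensemble=int(pooled.size),
        trend_class=classify_trend(float(q025), float(q975)),
    )


def summaries_to_frame(summaries: Iterable[SiteTrendSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries])


def trend_class_counts(summaries: Iterable[SiteTrendSummary]) -> dict:
    counts = {TREND_INCREASING: 0, TREND_DECREASING: 0, TREND_STABLE: 0}
    for s in summaries:
        counts[s.trend_class] += 1
    return counts
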