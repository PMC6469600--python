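"""Synthetic monitoring networks with the variance structure the analysis assumes.

The generator emulates a NABO-style paired design: ``n_sites`` permanent
plots sampled in ``n_campaigns`` campaigns at ``interval_years`` spacing with
``n_replicates`` bulked replicates per site-campaign.  On the natural-log
scale, the replicate value for site i, campaign t, replicate r is

    y = m_i + (beta + b_i) * t_dec + u_it + e_itr

with m_i the site level (uniform over ``site_mean_log_range``, default
ln 10 .. ln 40 g/kg), beta the global trend in log units per decade derived
from the configured annual relative trend, b_i ~ N(0, site_trend_sd) the
site-specific slope deviation, u_it ~ N(0, campaign_sd) short-term
(site-campaign) noise and e_itr ~ N(0, replicate_sd) replicate noise.
SOC = exp(y) g/kg.  Optionally, the first ``wo_fraction`` of each site's
campaigns are tagged as wet-oxidation results and multiplied by a site
recovery factor drawn uniformly from ``wo_factor_range`` — emulating the
historical method change that harmonisation must undo.

Each site owns an RNG substream derived from the master seed and the site
index, so a given site's data do not change when the network is enlarged.
:class:`SyntheticTruth` carries every generated ground-truth quantity for
recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import Method, MonitoringDataset, SiteRecord, TrendStatus

__all__ = [
    "DesignSpec",
    "SyntheticNetworkConfig",
    "SyntheticTruth",
    "annual_pct_to_log_slope_per_decade",
    "generate_network",
    "generate_site_metadata",
    "nabo_default_config",
]


@dataclass(frozen=True)
class DesignSpec:
    """Sampling design plus log-scale variance components.

    The default variance calibration (campaign_sd 0.06, replicate_sd 0.07,
    i.e. ~6% short-term and ~7% replicate-level relative variation) is chosen
    to sit in the low-percent range that repeated soil sampling under strict
    protocols shows; it is a calibration, not a measured property of any
    particular network.
    """

    n_sites: int = 30
    n_campaigns: int = 5
    interval_years: float = 5.0
    n_replicates: int = 4
    between_site_sd: float = 0.40   # used only when no uniform site-mean range is set
    campaign_sd: float = 0.06       # short-term site-campaign noise, log scale
    replicate_sd: float = 0.07      # within-campaign replicate noise, log scale

    def __post_init__(self) -> None:
        if min(self.n_sites, self.n_campaigns, self.n_replicates) < 1:
            raise ValueError("design counts must all be >= 1")
        if self.interval_years <= 0:
            raise ValueError("interval_years must be > 0")
        for name in ("between_site_sd", "campaign_sd", "replicate_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SyntheticNetworkConfig:
    design: DesignSpec = DesignSpec()
    site_mean_log_range: tuple | None = (math.log(10.0), math.log(40.0))
    global_annual_trend: float = 0.0      # % per year, relative
    site_trend_sd: float = 0.05           # SD of site slope deviations, log/decade
    wo_fraction: float = 0.0              # share of each site's campaigns tagged WO
    wo_factor_range: tuple = (0.77, 0.90)
    management_association: float | None = None  # None => no management covariates
    start_year: float = 1990.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.site_mean_log_range is not None:
            lo, hi = self.site_mean_log_range
            if not lo <= hi:
                raise ValueError("site_mean_log_range must be well ordered")
        if not 0.0 <= self.wo_fraction <= 1.0:
            raise ValueError("wo_fraction must be in [0, 1]")
        lo, hi = self.wo_factor_range
        if not 0 < lo <= hi:
            raise ValueError("wo_factor_range must be positive and well ordered")
        if self.site_trend_sd < 0:
            raise ValueError("site_trend_sd must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth aligned one-to-one with the generated sites."""

    site_ids: list
    site_mean_log: dict
    site_slope_per_decade: dict       # beta + b_i, log units per decade
    wo_factor: dict                   # site -> recovery factor (sites with WO data)
    global_annual_trend: float        # % per year as configured
    global_slope_per_decade: float    # exact log-scale equivalent
    design: DesignSpec = field(default_factory=DesignSpec)
    site_trend_sd: float = 0.0


def annual_pct_to_log_slope_per_decade(annual_trend_pct: float) -> float:
    """Exact log-scale slope per decade for a relative trend of r % per year."""
    if annual_trend_pct <= -100:
        raise ValueError("annual relative trend must exceed -100 %")
    return 10.0 * math.log1p(annual_trend_pct / 100.0)


def _site_rng(seed: int, site_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(site_index)]))


def generate_network(config: SyntheticNetworkConfig) -> tuple[MonitoringDataset, SyntheticTruth]:
    """Generate a full monitoring dataset plus its ground truth."""
    d = config.design
    beta_dec = annual_pct_to_log_slope_per_decade(config.global_annual_trend)
    years = config.start_year + d.interval_years * np.arange(d.n_campaigns)
    t_dec = (years - years[0]) / 10.0
    n_wo = int(round(config.wo_fraction * d.n_campaigns))

    rows = []
    site_ids = list(range(1, d.n_sites + 1))
    mean_log, slope_truth, wo_factors = {}, {}, {}
    for i, site in enumerate(site_ids):
        rng = _site_rng(config.seed, i)
        if config.site_mean_log_range is not None:
            m = rng.uniform(*config.site_mean_log_range)
        else:
            m = math.log(20.0) + rng.normal(0.0, d.between_site_sd)
        b = rng.normal(0.0, config.site_trend_sd) if config.site_trend_sd > 0 else 0.0
        u = rng.normal(0.0, d.campaign_sd, size=d.n_campaigns) if d.campaign_sd > 0 else np.zeros(d.n_campaigns)
        e = (
            rng.normal(0.0, d.replicate_sd, size=(d.n_campaigns, d.n_replicates))
            if d.replicate_sd > 0
            else np.zeros((d.n_campaigns, d.n_replicates))
        )
        factor = rng.uniform(*config.wo_factor_range) if n_wo else None

        mean_log[site] = float(m)
        slope_truth[site] = float(beta_dec + b)
        if factor is not None:
            wo_factors[site] = float(factor)

        y = m + (beta_dec + b) * t_dec[:, None] + u[:, None] + e
        soc = np.exp(y)
        for ti in range(d.n_campaigns):
            is_wo = ti < n_wo
            for r in range(d.n_replicates):
                val = soc[ti, r] * factor if is_wo else soc[ti, r]
                rows.append(
                    (site, ti + 1, float(years[ti]), r + 1, float(val),
                     Method.WO.value if is_wo else Method.DC.value)
                )

    measurements = pd.DataFrame(
        rows, columns=["site_id", "campaign", "year", "replicate", "soc_g_per_kg", "method"]
    )
    if config.management_association is not None:
        sites = {r.site_id: r for r in generate_site_metadata(config, mean_log)}
    else:
        sites = {s: SiteRecord(site_id=s) for s in site_ids}
    truth = SyntheticTruth(
        site_ids=site_ids,
        site_mean_log=mean_log,
        site_slope_per_decade=slope_truth,
        wo_factor=wo_factors,
        global_annual_trend=config.global_annual_trend,
        global_slope_per_decade=beta_dec,
        design=d,
        site_trend_sd=config.site_trend_sd,
    )
    return MonitoringDataset(measurements, sites), truth


def generate_site_metadata(
    config: SyntheticNetworkConfig, site_mean_log: dict | None = None
) -> list[SiteRecord]:
    """Site covariates with a configurable positive SOC-management association.

    Clay is kept within the 6-59 % range typical of cropland fine earth and,
    like manure input and meadow proportion, is tied to the site's mean log
    SOC with strength ``management_association`` in [0, 1] (0 = independent).
    Apparent density decreases with SOC, as observed in real topsoils.
    """
    if config.management_association is None:
        raise ValueError("management_association must be set to generate metadata")
    a = float(config.management_association)
    if not 0.0 <= a <= 1.0:
        raise ValueError("management_association must be in [0, 1]")
    d = config.design
    if site_mean_log is None:
        site_mean_log = generate_network(
            SyntheticNetworkConfig(
                design=d, site_mean_log_range=config.site_mean_log_range,
                seed=config.seed,
            )
        )[1].site_mean_log

    lo, hi = config.site_mean_log_range or (math.log(10), math.log(40))
    records = []
    for i, (site, m) in enumerate(sorted(site_mean_log.items(), key=lambda kv: str(kv[0]))):
        rng = _site_rng(config.seed + 10_000_019, i)
        z = (m - (lo + hi) / 2) / max((hi - lo) / 2, 1e-12)  # roughly in [-1, 1]
        mix = lambda noise_sd: a * z + math.sqrt(max(1 - a**2, 0.0)) * rng.normal(0, noise_sd)

        clay = float(np.clip(32.5 + 26.5 * mix(0.45), 6.0, 59.0))
        silt = float(np.clip(rng.uniform(8.0, 69.0), 0.0, 100.0 - clay))
        ad = float(np.clip(1.75 - 0.22 * m + rng.normal(0, 0.07), 0.70, 1.50))
        meadow = float(np.clip(30 + 30 * mix(0.5), 0.0, 100.0))
        cereal = float(np.clip(rng.uniform(10, 60), 0.0, 100.0 - meadow))
        hoe = float(np.clip(100.0 - meadow - cereal - rng.uniform(0, 15), 0.0, 100.0))
        manure_total = float(np.clip(2000 + 1800 * mix(0.5), 0.0, 5700.0))
        liquid = float(np.clip(manure_total * rng.uniform(0.2, 0.6), 0.0, 2130.0))
        records.append(
            SiteRecord(
                site_id=site,
                altitude_m=float(np.clip(550 + 150 * mix(1.0), 300, 1000)),
                ph_cacl2=float(np.clip(rng.uniform(5.1, 7.5), 0, 14)),
                clay_pct=clay,
                silt_pct=silt,
                apparent_density_g_cm3=ad,
                soc_g_per_kg=float(math.exp(m)),
                manure_liquid=liquid,
                manure_solid=max(manure_total - liquid, 0.0),
                prop_meadow=meadow,
                prop_cereal=cereal,
                prop_hoe=hoe,
                status=TrendStatus.CROPLAND,
            )
        )
    return records


def nabo_default_config(seed: int = 0, **overrides) -> SyntheticNetworkConfig:
    """The NABO-like preset: 30 sites x 5 campaigns x 4 replicates, 5-year spacing."""
    return SyntheticNetworkConfig(seed=seed, **overrides)
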