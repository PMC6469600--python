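"""Deterministic soil-carbon arithmetic and descriptive statistics.

Covers the bookkeeping around the trend analysis: fixed-depth carbon stocks
(t/ha) from concentration and apparent density, the SOC/clay structural-
quality ratio and its 0.12 threshold, conversions between log-scale slopes
and relative percentage changes, compound-interest projections of annual
trends, and a pairwise-complete Spearman correlation matrix with
significance stars.

Units: stock = SOC [g/kg] x apparent density [g/cm3] x depth [cm] x 0.1.
The 0.1 makes the units come out in t/ha: g C per kg soil times g soil per
cm3 gives 1e-3 g C per cm3 = 10 t C per ha per cm of depth, i.e. a factor
10 x 1e-3 x depth... worked through, 1 g/kg x 1 g/cm3 x 1 cm = 0.1 t/ha.
The SOC/clay ratio divides SOC expressed in % of dry matter (g/kg divided
by 10) by clay in % of fine earth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import SiteRecord

__all__ = [
    "StockResult",
    "CorrelationMatrix",
    "compute_stock",
    "stocks_table",
    "soc_clay_ratio",
    "soc_at_ratio_threshold",
    "relative_change_from_log_slope",
    "log_slope_from_relative_change",
    "compound_annual_change",
    "annual_rate_from_total_change",
    "spearman_matrix",
    "significance_stars",
]

SOC_CLAY_THRESHOLD = 0.12  # good/medium structural quality boundary (% per %)


@dataclass(frozen=True)
class StockResult:
    site_id: int | str
    stock_t_ha: float
    depth_cm: float


def compute_stock(soc_g_per_kg, apparent_density_g_cm3, depth_cm: float = 20.0):
    """Organic carbon stock in t/ha over a fixed sampling depth."""
    soc = np.asarray(soc_g_per_kg, dtype=float)
    ad = np.asarray(apparent_density_g_cm3, dtype=float)
    if (soc < 0).any() or (ad < 0).any() or depth_cm < 0:
        raise ValueError("stock inputs must be non-negative")
    out = soc * ad * depth_cm * 0.1
    return float(out) if out.ndim == 0 else out


def stocks_table(sites: Iterable[SiteRecord], depth_cm: float = 20.0) -> pd.DataFrame:
    """Recompute stocks (and SOC/clay ratios) for a set of site records.

    Sites lacking apparent density get a missing stock; the printed stock
    column, when present, is carried along for comparison.
    """
    rows = []
    for r in sites:
        stock = (
            compute_stock(r.soc_g_per_kg, r.apparent_density_g_cm3, depth_cm)
            if r.soc_g_per_kg is not None and r.apparent_density_g_cm3 is not None
            else np.nan
        )
        ratio = (
            soc_clay_ratio(r.soc_g_per_kg, r.clay_pct)
            if r.soc_g_per_kg is not None and r.clay_pct
            else np.nan
        )
        rows.append(
            {
                "site_id": r.site_id,
                "soc_g_per_kg": r.soc_g_per_kg,
                "apparent_density_g_cm3": r.apparent_density_g_cm3,
                "stock_t_ha": stock,
                "printed_stock_t_ha": r.stock_t_ha,
                "soc_clay_ratio": ratio,
                "depth_cm": depth_cm,
            }
        )
    return pd.DataFrame(rows)


def soc_clay_ratio(soc_g_per_kg, clay_pct):
    """SOC/clay ratio in % per %: SOC is converted g/kg -> % before dividing."""
    soc = np.asarray(soc_g_per_kg, dtype=float)
    clay = np.asarray(clay_pct, dtype=float)
    if (clay <= 0).any():
        raise ValueError("clay content must be > 0 for a SOC/clay ratio")
    out = (soc / 10.0) / clay
    return float(out) if out.ndim == 0 else out


def soc_at_ratio_threshold(clay_pct, threshold: float = SOC_CLAY_THRESHOLD):
    """SOC content (g/kg) at which SOC/clay equals ``threshold``."""
    clay = np.asarray(clay_pct, dtype=float)
    if (clay <= 0).any():
        raise ValueError("clay content must be > 0")
    out = threshold * clay * 10.0
    return float(out) if out.ndim == 0 else out


def relative_change_from_log_slope(slope_per_decade):
    """Relative SOC change (% per decade) implied by a log-scale slope."""
    s = np.asarray(slope_per_decade, dtype=float)
    if not np.isfinite(s).all():
        raise ValueError("slope must be finite")
    out = 100.0 * (np.exp(s) - 1.0)
    return float(out) if out.ndim == 0 else out


def log_slope_from_relative_change(pct_per_decade):
    """Inverse of :func:`relative_change_from_log_slope`."""
    p = np.asarray(pct_per_decade, dtype=float)
    out = np.log1p(p / 100.0)
    return float(out) if out.ndim == 0 else out


def compound_annual_change(rate_pct_per_year: float, years: float, baseline: float | None = None):
    """Total % change after compounding, and the projected endpoint if given.

    total = 100 * ((1 + r/100)^years - 1); endpoint = baseline * (1 + r/100)^years.
    """
    if rate_pct_per_year <= -100:
        raise ValueError("annual rate must exceed -100 %")
    growth = (1.0 + rate_pct_per_year / 100.0) ** years
    total = 100.0 * (growth - 1.0)
    if baseline is None:
        return total
    return total, baseline * growth


def annual_rate_from_total_change(total_pct: float, years: float) -> float:
    """Annual rate (% per year) equivalent to a total % change over ``years``."""
    if total_pct <= -100:
        raise ValueError("total change must exceed -100 %")
    if years <= 0:
        raise ValueError("years must be > 0")
    return 100.0 * ((1.0 + total_pct / 100.0) ** (1.0 / years) - 1.0)


@dataclass
class CorrelationMatrix:
    variables: list
    rho: pd.DataFrame
    p_value: pd.DataFrame
    n: pd.DataFrame

    def stars(self) -> pd.DataFrame:
        return self.p_value.map(significance_stars)

    def annotated(self) -> pd.DataFrame:
        """rho rounded to 2 decimals with significance stars appended."""
        out = self.rho.round(2).astype(str) + self.stars()
        np.fill_diagonal(out.values, "1.0")
        return out


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def spearman_matrix(
    table: pd.DataFrame,
    variables: list | None = None,
    min_pairs: int = 3,
    exact_below: int | None = None,
    seed: int = 0,
) -> CorrelationMatrix:
    """Pairwise-complete Spearman rank correlations with p-values.

    Each variable pair uses all rows where both are observed; pairs with
    fewer than ``min_pairs`` complete observations are reported missing.
    P-values use the large-sample t approximation; when ``exact_below`` is
    set, pairs with fewer complete observations than that use a permutation
    p-value instead.
    """
    cols = variables or [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    k = len(cols)
    rho = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    nmat = np.zeros((k, k), dtype=int)
    rng = np.random.default_rng(seed)
    for i in range(k):
        rho[i, i], pval[i, i], nmat[i, i] = 1.0, 0.0, int(table[cols[i]].notna().sum())
        for j in range(i + 1, k):
            pair = table[[cols[i], cols[j]]].dropna()
            nmat[i, j] = nmat[j, i] = len(pair)
            if len(pair) < min_pairs:
                continue
            x, y = pair[cols[i]].to_numpy(float), pair[cols[j]].to_numpy(float)
            r, p = stats.spearmanr(x, y)
            if exact_below is not None and len(pair) < exact_below:
                perm = stats.permutation_test(
                    (x, y),
                    lambda a, b: stats.spearmanr(a, b).statistic,
                    permutation_type="pairings",
                    n_resamples=9999,
                    rng=rng,
                )
                p = perm.pvalue
            rho[i, j] = rho[j, i] = float(r)
            pval[i, j] = pval[j, i] = float(p)
    return CorrelationMatrix(
        variables=list(cols),
        rho=pd.DataFrame(rho, index=cols, columns=cols),
        p_value=pd.DataFrame(pval, index=cols, columns=cols),
        n=pd.DataFrame(nmat, index=cols, columns=cols),
    )
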