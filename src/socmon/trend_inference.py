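"""Linear mixed models for the temporal evolution of log SOC.

Two models, both fitted by REML on site-campaign means of natural-log SOC:

* campaign-effects model -- y_it = mu + a_i + b_t + e_it, with a random
  intercept a_i per site and a factor b_t per sampling campaign.  Answers
  "do individual campaigns differ?", with all pairwise campaign contrasts.
* global-trend model -- y_it = mu + a_i + (beta + b_i) * t + e_it, with a
  random intercept and a random slope per site.  beta is the network-wide
  linear trend; beta + b_i are the site-level predicted slopes (BLUPs).

Time is coded in decades since the first campaign, so slopes read "log-SOC
change per 10 years".  Estimates and confidence bounds are exponentiated to
report concentrations in g/kg.  Random intercept and slope are uncorrelated
by default (``correlated=True`` frees the covariance).  Inference on the
global slope uses a t reference distribution with n_sites - 1 degrees of
freedom, the appropriate small-sample reference for a coefficient whose
uncertainty is dominated by between-site slope variation; campaign contrasts
use the within-site residual degrees of freedom.

Exactly saturated inputs (zero residual variance, e.g. noise-free synthetic
data) are detected up front and returned as closed-form fits with zero
variance components rather than pushed through the iterative optimiser.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ValidationError

__all__ = [
    "CampaignEstimate",
    "PairwiseDifference",
    "CampaignEffectsFit",
    "LinearTrendFit",
    "fit_campaign_effects",
    "fit_global_trend",
    "back_transform",
    "decades_since_start",
]

_SATURATED_TOL = 1e-18  # relative SSE below which the model is treated as exact


@dataclass(frozen=True)
class CampaignEstimate:
    campaign: int
    log_mean: float
    log_se: float
    mean_g_per_kg: float
    ci_low_g_per_kg: float
    ci_high_g_per_kg: float


@dataclass(frozen=True)
class PairwiseDifference:
    campaign_a: int
    campaign_b: int
    diff_log: float       # b_b - b_a on the log scale
    se: float
    p_value: float
    p_adjusted: float | None = None


@dataclass
class CampaignEffectsFit:
    mu: float                                  # log g/kg, campaign-1 level
    campaign_effects: dict                     # campaign -> offset from campaign 1
    site_intercept_sd: float
    residual_sd: float
    campaign_estimates: list = field(default_factory=list)
    pairwise_differences: list = field(default_factory=list)
    n_sites: int = 0
    n_obs: int = 0
    converged: bool = True

    def estimates_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.campaign_estimates])

    def differences_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(d) for d in self.pairwise_differences])


@dataclass
class LinearTrendFit:
    mu: float
    global_slope: float        # log units per decade
    slope_se: float
    slope_ci: tuple            # 95% CI, log units per decade
    p_value: float
    site_slopes: dict          # site_id -> beta + b_i (BLUP)
    site_slope_sd: float
    site_intercept_sd: float
    residual_sd: float
    n_sites: int = 0
    n_obs: int = 0
    converged: bool = True

    def site_slopes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"site_id": list(self.site_slopes), "slope_per_decade": list(self.site_slopes.values())}
        )


def decades_since_start(year, origin_year: float | None = None) -> np.ndarray:
    """Time covariate in decades since the (first) campaign."""
    year = np.asarray(year, dtype=float)
    origin = float(np.min(year)) if origin_year is None else float(origin_year)
    return (year - origin) / 10.0


def _check_aggregated(agg: pd.DataFrame) -> pd.DataFrame:
    required = {"site_id", "campaign", "year", "mean_log_soc"}
    missing = required - set(agg.columns)
    if missing:
        raise ValidationError(f"aggregated table missing column(s): {', '.join(sorted(missing))}")
    vals = agg["mean_log_soc"].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValidationError("non-finite mean_log_soc values in aggregated table")
    return agg


def back_transform(point: float, ci_low: float | None = None, ci_high: float | None = None):
    """Exponentiate a log-scale estimate (and optional CI bounds) to g/kg."""
    if ci_low is None and ci_high is None:
        return float(np.exp(point))
    return float(np.exp(point)), float(np.exp(ci_low)), float(np.exp(ci_high))


def _holm(pvals: list[float]) -> list[float]:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


def fit_campaign_effects(
    agg: pd.DataFrame,
    reml: bool = True,
    alpha: float = 0.05,
    holm_adjust: bool = False,
) -> CampaignEffectsFit:
    """Fit the campaign-effects model to a site-campaign mean-log table.

    Campaign means are reported back-transformed to g/kg with ``1 - alpha``
    confidence intervals; all pairwise campaign contrasts come with Wald
    p-values (unadjusted by default, Holm-adjusted if requested).
    """
    agg = _check_aggregated(agg)
    campaigns = np.sort(agg["campaign"].unique())
    sites = agg["site_id"].unique()
    if len(campaigns) < 2:
        raise ValidationError("campaign-effects model needs at least 2 campaigns")
    if len(sites) < 2:
        raise ValidationError("campaign-effects model needs at least 2 sites")

    y = agg["mean_log_soc"].to_numpy(dtype=float)
    n_obs = len(y)
    # fixed-effects design: intercept (campaign 1 level) + campaign indicators
    X = np.column_stack(
        [np.ones(n_obs)]
        + [(agg["campaign"].to_numpy() == c).astype(float) for c in campaigns[1:]]
    )
    fe_names = ["mu"] + [f"campaign_{c}" for c in campaigns[1:]]

    saturated = _saturated_two_way(agg, campaigns, sites)
    if saturated is not None:
        mu, effects, site_sd = saturated
        params = np.array([mu] + [effects[c] for c in campaigns[1:]])
        cov = np.zeros((len(params), len(params)))
        resid_sd, converged = 0.0, True
    else:
        params, cov, site_sd, resid_sd, converged = _fit_mixedlm(
            y, X, agg["site_id"].to_numpy(), exog_re=np.ones((n_obs, 1)), reml=reml
        )
        site_sd = float(np.sqrt(max(site_sd, 0.0)))

    df_resid = max(n_obs - len(sites) - (len(campaigns) - 1), 1)
    tcrit = stats.t.ppf(1 - alpha / 2, df_resid)

    estimates = []
    for c in campaigns:
        L = np.zeros(len(params))
        L[0] = 1.0
        if c != campaigns[0]:
            L[1 + int(np.flatnonzero(campaigns[1:] == c)[0])] = 1.0
        est = float(L @ params)
        se = float(np.sqrt(max(L @ cov @ L, 0.0)))
        g, lo, hi = back_transform(est, est - tcrit * se, est + tcrit * se)
        estimates.append(CampaignEstimate(int(c), est, se, g, lo, hi))

    diffs = []
    for a, b in itertools.combinations(campaigns, 2):
        L = np.zeros(len(params))
        for c, sign in ((a, -1.0), (b, 1.0)):
            if c != campaigns[0]:
                L[1 + int(np.flatnonzero(campaigns[1:] == c)[0])] = sign
        d = float(L @ params)
        se = float(np.sqrt(max(L @ cov @ L, 0.0)))
        p = 1.0 if se == 0 and d == 0 else (
            0.0 if se == 0 else float(2 * stats.t.sf(abs(d) / se, df_resid))
        )
        diffs.append(PairwiseDifference(int(a), int(b), d, se, p))
    if holm_adjust:
        adj = _holm([d.p_value for d in diffs])
        diffs = [
            PairwiseDifference(d.campaign_a, d.campaign_b, d.diff_log, d.se, d.p_value, a)
            for d, a in zip(diffs, adj)
        ]

    effects = {int(campaigns[0]): 0.0}
    for i, c in enumerate(campaigns[1:]):
        effects[int(c)] = float(params[1 + i])
    return CampaignEffectsFit(
        mu=float(params[0]),
        campaign_effects=effects,
        site_intercept_sd=float(site_sd),
        residual_sd=float(resid_sd),
        campaign_estimates=estimates,
        pairwise_differences=diffs,
        n_sites=len(sites),
        n_obs=n_obs,
        converged=converged,
    )


def fit_global_trend(
    agg: pd.DataFrame,
    reml: bool = True,
    alpha: float = 0.05,
    correlated: bool = False,
    origin_year: float | None = None,
) -> LinearTrendFit:
    """Fit the random-intercept random-slope trend model.

    Returns the global slope in log units per decade with a t-based
    ``1 - alpha`` CI and p-value (df = n_sites - 1), the per-site predicted
    slopes, and the three variance components.
    """
    agg = _check_aggregated(agg).copy()
    sites = agg["site_id"].unique()
    if len(sites) < 2:
        raise ValidationError("trend model needs at least 2 sites")
    if agg["campaign"].nunique() < 2:
        raise ValidationError("trend model needs at least 2 campaigns")
    short = [
        s for s, g in agg.groupby("site_id") if g["campaign"].nunique() < 3
    ]
    if short:
        warnings.warn(
            f"site(s) {short} have fewer than 3 time points; "
            "their slopes are weakly identified",
            stacklevel=2,
        )

    t = decades_since_start(agg["year"].to_numpy(), origin_year)
    y = agg["mean_log_soc"].to_numpy(dtype=float)
    n_obs = len(y)
    X = np.column_stack([np.ones(n_obs), t])

    saturated = _saturated_linear(agg, t, y)
    if saturated is not None:
        return saturated

    params, cov, cov_re, resid_sd, converged, re_dict = _fit_mixedlm_slope(
        y, X, agg["site_id"].to_numpy(), t, reml=reml, correlated=correlated
    )
    beta = float(params[1])
    se = float(np.sqrt(max(cov[1, 1], 0.0)))
    df = max(len(sites) - 1, 1)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    p = float(2 * stats.t.sf(abs(beta) / se, df)) if se > 0 else (0.0 if beta != 0 else 1.0)

    site_slopes = {s: beta + float(re_dict.get(s, 0.0)) for s in sites}
    return LinearTrendFit(
        mu=float(params[0]),
        global_slope=beta,
        slope_se=se,
        slope_ci=(beta - tcrit * se, beta + tcrit * se),
        p_value=p,
        site_slopes=site_slopes,
        site_slope_sd=float(np.sqrt(max(cov_re[1, 1], 0.0))),
        site_intercept_sd=float(np.sqrt(max(cov_re[0, 0], 0.0))),
        residual_sd=float(resid_sd),
        n_sites=len(sites),
        n_obs=n_obs,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# internals

def _saturated_two_way(agg, campaigns, sites):
    """Detect an exactly additive site + campaign structure (zero residual)."""
    piv = agg.pivot_table(index="site_id", columns="campaign", values="mean_log_soc")
    if piv.isna().any().any():
        return None
    M = piv.to_numpy()
    site_eff = M.mean(axis=1, keepdims=True)
    camp_eff = M.mean(axis=0, keepdims=True)
    fitted = site_eff + camp_eff - M.mean()
    sse = float(((M - fitted) ** 2).sum())
    if sse > _SATURATED_TOL * max(1.0, float((M**2).sum())):
        return None
    camp_means = M.mean(axis=0)
    mu = float(camp_means[0])
    effects = {int(c): float(camp_means[i] - camp_means[0]) for i, c in enumerate(piv.columns)}
    site_sd = float(np.std(M.mean(axis=1), ddof=1)) if len(sites) > 1 else 0.0
    return mu, effects, site_sd


def _saturated_linear(agg, t, y):
    """Detect exact per-site lines (zero residual) and return a closed-form fit."""
    df = pd.DataFrame({"site_id": agg["site_id"].to_numpy(), "t": t, "y": y})
    slopes, intercepts, sse, sst = {}, {}, 0.0, float((y**2).sum())
    for s, g in df.groupby("site_id"):
        if g["t"].nunique() < 2:
            return None
        b, a = np.polyfit(g["t"], g["y"], 1)
        slopes[s] = float(b)
        intercepts[s] = float(a)
        sse += float(((g["y"] - (a + b * g["t"])) ** 2).sum())
    if sse > _SATURATED_TOL * max(1.0, sst):
        return None
    svals = np.array(list(slopes.values()))
    beta = float(svals.mean())
    slope_sd = float(np.std(svals, ddof=1)) if len(svals) > 1 else 0.0
    n = len(svals)
    se = slope_sd / np.sqrt(n) if n > 1 else 0.0
    if se > 0:
        tstat = beta / se
        p = float(2 * stats.t.sf(abs(tstat), n - 1))
        tcrit = stats.t.ppf(0.975, n - 1)
        ci = (beta - tcrit * se, beta + tcrit * se)
    else:
        p = 0.0 if beta != 0 else 1.0
        ci = (beta, beta)
    ivals = np.array(list(intercepts.values()))
    return LinearTrendFit(
        mu=float(ivals.mean()),
        global_slope=beta,
        slope_se=float(se),
        slope_ci=ci,
        p_value=p,
        site_slopes=slopes,
        site_slope_sd=slope_sd,
        site_intercept_sd=float(np.std(ivals, ddof=1)) if n > 1 else 0.0,
        residual_sd=0.0,
        n_sites=n,
        n_obs=len(y),
        converged=True,
    )


def _fit_mixedlm(y, X, groups, exog_re, reml):
    """Random-intercept MixedLM; returns fe params, their cov, var comps."""
    from statsmodels.regression.mixed_linear_model import MixedLM

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, X, groups=groups, exog_re=exog_re)
        res = model.fit(reml=reml, method="lbfgs", maxiter=200)
    return (
        np.asarray(res.fe_params, dtype=float),
        np.asarray(res.cov_params())[: X.shape[1], : X.shape[1]].astype(float),
        float(np.asarray(res.cov_re)[0, 0]),
        float(np.sqrt(res.scale)),
        bool(res.converged),
    )


def _fit_mixedlm_slope(y, X, groups, t, reml, correlated):
    """Random intercept + random slope MixedLM (uncorrelated by default)."""
    from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams

    exog_re = np.column_stack([np.ones_like(t), t])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, X, groups=groups, exog_re=exog_re)
        if correlated:
            res = model.fit(reml=reml, method="lbfgs", maxiter=200)
        else:
            free = MixedLMParams.from_components(
                fe_params=np.ones(X.shape[1]), cov_re=np.eye(2)
            )
            res = model.fit(reml=reml, free=free, method="lbfgs", maxiter=200)
    cov_re = np.asarray(res.cov_re, dtype=float)
    re_dict = {}
    for g, vals in res.random_effects.items():
        arr = np.asarray(vals, dtype=float)
        re_dict[g] = float(arr[1]) if arr.size > 1 else 0.0
    return (
        np.asarray(res.fe_params, dtype=float),
        np.asarray(res.cov_params())[: X.shape[1], : X.shape[1]].astype(float),
        cov_re,
        float(np.sqrt(res.scale)),
        bool(res.converged),
        re_dict,
    )
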