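"""Configuration-driven orchestration of the full monitoring analysis.

Stages, in order: read + validate -> harmonise WO results to the DC scale ->
aggregate replicates on the log scale -> campaign-effects model ->
global-trend model -> hierarchical bootstrap + trend classification ->
diagnostics (stocks, SOC/clay ratios, Spearman matrix).  Sites converted out
of cropland (by default sites 5 and 23) are excluded from the trend stages
but kept in the diagnostics.  Every output carries the seed, and a run
manifest records config, package version and file hashes so a run can be
reproduced from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .bootstrap_trends import (
    BootstrapConfig,
    bootstrap_site_slopes,
    summaries_to_frame,
    trend_class_counts,
)
from .data_model import (
    MonitoringDataset,
    aggregate_replicates,
    read_measurements,
    read_sites,
)
from .diagnostics import spearman_matrix, stocks_table
from .harmonisation import DEFAULT_FALLBACK_FACTOR, estimate_factors_by_site, harmonise_measurements
from .trend_inference import fit_campaign_effects, fit_global_trend

__all__ = ["AnalysisConfig", "run_full_analysis"]

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    measurements_csv: str
    sites_csv: str | None = None
    calibration_csv: str | None = None          # paired WO/DC table, optional
    exclude_sites: tuple = (5, 23)              # converted to permanent grassland
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    alpha: float = 0.05
    depth_cm: float = 20.0
    fallback_factor: float = DEFAULT_FALLBACK_FACTOR
    output_dir: str = "socmon_output"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        boot_raw = raw.pop("bootstrap", {})
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if boot_raw:
            cfg.bootstrap = BootstrapConfig(**boot_raw)
        if "exclude_sites" in raw:
            cfg.exclude_sites = tuple(raw["exclude_sites"])
        cfg.bootstrap = dataclasses.replace(cfg.bootstrap, seed=cfg.seed)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["exclude_sites"] = list(self.exclude_sites)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run every stage and write the report bundle; returns output paths."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("socmon")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    outputs: dict[str, Path] = {"run_log": log_path}
    stage = "read"
    try:
        measurements = read_measurements(config.measurements_csv)
        sites = {}
        if config.sites_csv:
            sites = {r.site_id: r for r in read_sites(config.sites_csv)}

        stage = "harmonise"
        factors = {}
        if config.calibration_csv:
            factors = estimate_factors_by_site(pd.read_csv(config.calibration_csv))
        if (measurements["method"] == "WO").any():
            logger.info("harmonising WO measurements with %d site factor(s)", len(factors))
            measurements = harmonise_measurements(measurements, factors, config.fallback_factor)
        dataset = MonitoringDataset(measurements, sites, config.depth_cm)

        stage = "aggregate"
        trend_data = dataset.exclude_sites(config.exclude_sites)
        excluded = sorted(set(dataset.site_ids) - set(trend_data.site_ids))
        if excluded:
            logger.warning("sites excluded from trend stages: %s", excluded)
        agg = aggregate_replicates(trend_data)
        agg.to_csv(out / "aggregated_site_campaign.csv", index=False)
        outputs["aggregated"] = out / "aggregated_site_campaign.csv"

        stage = "campaign_model"
        cfit = fit_campaign_effects(agg, alpha=config.alpha)
        cfit.estimates_frame().to_csv(out / "campaign_estimates.csv", index=False)
        cfit.differences_frame().to_csv(out / "campaign_differences.csv", index=False)
        outputs["campaign_estimates"] = out / "campaign_estimates.csv"
        outputs["campaign_differences"] = out / "campaign_differences.csv"

        stage = "trend_model"
        tfit = fit_global_trend(agg, alpha=config.alpha)
        (out / "trend_model.json").write_text(
            json.dumps(
                {
                    "global_slope_per_decade": tfit.global_slope,
                    "slope_se": tfit.slope_se,
                    "slope_ci": list(tfit.slope_ci),
                    "p_value": tfit.p_value,
                    "site_slope_sd": tfit.site_slope_sd,
                    "site_intercept_sd": tfit.site_intercept_sd,
                    "residual_sd": tfit.residual_sd,
                    "n_sites": tfit.n_sites,
                    "seed": config.seed,
                },
                indent=2,
            )
        )
        tfit.site_slopes_frame().to_csv(out / "model_site_slopes.csv", index=False)
        outputs["trend_model"] = out / "trend_model.json"
        outputs["model_site_slopes"] = out / "model_site_slopes.csv"

        stage = "bootstrap"
        boot_cfg = dataclasses.replace(config.bootstrap, seed=config.seed)
        summaries = bootstrap_site_slopes(trend_data, boot_cfg)
        summaries_to_frame(summaries).to_csv(out / "site_trends.csv", index=False)
        counts = trend_class_counts(summaries)
        (out / "trend_class_counts.json").write_text(json.dumps(counts, indent=2))
        outputs["site_trends"] = out / "site_trends.csv"
        outputs["trend_class_counts"] = out / "trend_class_counts.json"

        stage = "diagnostics"
        if sites:
            stocks = stocks_table(sites.values(), config.depth_cm)
            stocks.to_csv(out / "stocks_ratios.csv", index=False)
            outputs["stocks_ratios"] = out / "stocks_ratios.csv"
            numeric = dataset.site_frame().select_dtypes("number").drop(columns=["site_id"], errors="ignore")
            if numeric.shape[1] >= 2 and len(numeric) >= 3:
                corr = spearman_matrix(numeric)
                corr.rho.to_csv(out / "spearman_rho.csv")
                corr.annotated().to_csv(out / "spearman_annotated.csv")
                outputs["spearman_rho"] = out / "spearman_rho.csv"
                outputs["spearman_annotated"] = out / "spearman_annotated.csv"

        stage = "manifest"
        manifest = {
            "socmon_version": __version__,
            "python": platform.python_version(),
            "seed": config.seed,
            "config": config.to_dict(),
            "outputs": {
                k: {"path": str(p), "sha256": _sha256(p)}
                for k, p in outputs.items()
                if p != log_path and p.exists()
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        outputs["manifest"] = out / "manifest.json"
    except Exception:
        logger.exception("pipeline aborted in stage %r", stage)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
    return outputs
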