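"""Domain types and I/O for paired soil-monitoring data.

The unit of observation is one laboratory replicate: the soil organic carbon
(SOC) concentration of one bulked composite sample from one site in one
sampling campaign, in g per kg of oven-dry fine earth, tagged with the
analytical method that produced it (wet oxidation, ``WO``, or dry combustion,
``DC``).  A :class:`MonitoringDataset` joins replicate measurements to
per-site soil/management metadata and is the object passed between pipeline
stages.

All downstream statistics operate on natural-log SOC, so concentrations must
be strictly positive; :func:`aggregate_replicates` averages replicates on the
log scale, i.e. it computes the log of the geometric mean.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Method",
    "SOCMeasurement",
    "SiteRecord",
    "MonitoringDataset",
    "SchemaError",
    "ValidationError",
    "MEASUREMENT_COLUMNS",
    "read_measurements",
    "write_measurements",
    "read_sites",
    "write_sites",
    "load_table1_fixture",
    "load_table1_frame",
    "aggregate_replicates",
]

MEASUREMENT_COLUMNS = ["site_id", "campaign", "year", "replicate", "soc_g_per_kg", "method"]

#: CSV columns of the core per-site metadata (empty cell = missing).
SITE_COLUMNS = [
    "site_id", "altitude_m", "ph_cacl2", "clay_pct", "silt_pct",
    "apparent_density_g_cm3", "soc_g_per_kg", "stock_t_ha",
    "manure_liquid", "manure_solid",
    "prop_meadow", "prop_cereal", "prop_hoe", "status",
]


class SchemaError(ValueError):
    """A CSV is missing required columns or is otherwise malformed."""


class ValidationError(ValueError):
    """Rows violate a dataset invariant (non-positive SOC, duplicates, ...)."""


class Method(str, enum.Enum):
    """Analytical method for carbon determination."""

    WO = "WO"  # wet oxidation (dichromate); under-recovers relative to DC
    DC = "DC"  # dry combustion (CN analyser); the reference scale


class TrendStatus(str, enum.Enum):
    CROPLAND = "cropland"
    CONVERTED_TO_GRASSLAND = "converted_to_grassland"


@dataclass(frozen=True)
class SOCMeasurement:
    """One replicate SOC analysis."""

    site_id: int | str
    campaign: int          # 1-based chronological index
    year: float            # decimal calendar year of sampling
    replicate: int         # 1..R within the site-campaign
    soc: float             # g per kg dry matter, > 0
    method: Method = Method.DC

    def __post_init__(self) -> None:
        if not (self.soc > 0):
            raise ValidationError(
                f"SOC must be strictly positive (log scale analysis); got {self.soc!r} "
                f"for site {self.site_id} campaign {self.campaign} replicate {self.replicate}"
            )


@dataclass
class SiteRecord:
    """Per-site soil properties and management proxies (one metadata-table row).

    Management fields are ``None`` when no data were reported; an explicit 0
    means "recorded as zero" and is never conflated with missing.
    """

    site_id: int | str
    altitude_m: float | None = None
    ph_cacl2: float | None = None
    clay_pct: float | None = None           # % of fine earth (< 2 mm)
    silt_pct: float | None = None           # % of fine earth
    apparent_density_g_cm3: float | None = None  # fine-earth mass per total volume
    soc_g_per_kg: float | None = None       # mean SOC over campaigns (if known)
    stock_t_ha: float | None = None         # printed stock over sampled depth
    manure_liquid: float | None = None      # kg d.m. / ha / yr (slurry)
    manure_solid: float | None = None       # kg d.m. / ha / yr
    prop_meadow: float | None = None        # % of years with temporary grassland
    prop_cereal: float | None = None
    prop_hoe: float | None = None
    status: TrendStatus = TrendStatus.CROPLAND

    def __post_init__(self) -> None:
        for name in ("clay_pct", "silt_pct", "prop_meadow", "prop_cereal", "prop_hoe"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 100):
                raise ValidationError(f"site {self.site_id}: {name}={v} outside [0, 100]")
        if self.clay_pct is not None and self.silt_pct is not None:
            if self.clay_pct + self.silt_pct > 100 + 1e-9:
                raise ValidationError(
                    f"site {self.site_id}: clay + silt = "
                    f"{self.clay_pct + self.silt_pct} exceeds 100 %"
                )
        for name in ("manure_liquid", "manure_solid"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"site {self.site_id}: {name} negative")

    @property
    def management_available(self) -> bool:
        return self.manure_liquid is not None or self.prop_meadow is not None


@dataclass
class MonitoringDataset:
    """Validated measurements joined to site records.

    ``measurements`` is a DataFrame with columns :data:`MEASUREMENT_COLUMNS`;
    ``sites`` maps site_id to :class:`SiteRecord`.
    """

    measurements: pd.DataFrame
    sites: dict = field(default_factory=dict)
    depth_cm: float = 20.0

    def __post_init__(self) -> None:
        self.measurements = _validate_measurement_frame(self.measurements)
        if self.sites:
            unknown = set(self.measurements["site_id"]) - set(self.sites)
            if unknown:
                raise ValidationError(
                    f"measurements reference sites without a SiteRecord: {sorted(unknown)!r}"
                )
        _check_campaign_chronology(self.measurements)

    @property
    def site_ids(self) -> list:
        return sorted(self.measurements["site_id"].unique().tolist())

    def subset_sites(self, keep: Iterable) -> "MonitoringDataset":
        keep = set(keep)
        m = self.measurements[self.measurements["site_id"].isin(keep)].copy()
        s = {k: v for k, v in self.sites.items() if k in keep}
        return MonitoringDataset(m, s, self.depth_cm)

    def exclude_sites(self, drop: Iterable) -> "MonitoringDataset":
        drop = set(drop)
        return self.subset_sites(set(self.measurements["site_id"]) - drop)

    def site_frame(self) -> pd.DataFrame:
        return sites_to_frame(self.sites.values())


def _validate_measurement_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"measurement table is missing column(s): {', '.join(missing)}")
    df = df[MEASUREMENT_COLUMNS].copy()
    if df["soc_g_per_kg"].isna().any() or not np.isfinite(df["soc_g_per_kg"]).all():
        bad = df.index[~np.isfinite(df["soc_g_per_kg"].astype(float))].tolist()
        raise ValidationError(f"non-finite SOC values in rows {bad}")
    nonpos = df.index[df["soc_g_per_kg"] <= 0].tolist()
    if nonpos:
        raise ValidationError(
            f"SOC must be > 0 (log transform undefined otherwise); offending rows: {nonpos}"
        )
    bad_method = set(df["method"].astype(str)) - {m.value for m in Method}
    if bad_method:
        raise ValidationError(f"unknown analytical method tag(s): {sorted(bad_method)}")
    df["method"] = df["method"].astype(str)
    key = ["site_id", "campaign", "replicate"]
    dup = df.duplicated(key)
    if dup.any():
        rows = df.loc[dup, key].to_dict("records")
        raise ValidationError(f"duplicate (site_id, campaign, replicate) entries: {rows}")
    return df.reset_index(drop=True)


def _check_campaign_chronology(df: pd.DataFrame) -> None:
    """Campaign indices must be strictly increasing in time within each site."""
    years = df.groupby(["site_id", "campaign"])["year"].mean().reset_index()
    for site, grp in years.groupby("site_id"):
        grp = grp.sort_values("campaign")
        if not grp["year"].is_monotonic_increasing or grp["year"].duplicated().any():
            raise ValidationError(f"site {site}: campaign years are not strictly increasing")


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format measurement CSV.

    Required columns: site_id, campaign, year, replicate, soc_g_per_kg, method.
    """
    path = Path(path)
    df = pd.read_csv(path)
    return _validate_measurement_frame(df)


def write_measurements(df: pd.DataFrame, path: str | Path) -> None:
    _validate_measurement_frame(df).to_csv(path, index=False)


def _record_from_row(row: Mapping) -> SiteRecord:
    def get(name):
        v = row.get(name)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return v

    status = get("status") or TrendStatus.CROPLAND
    return SiteRecord(
        site_id=row["site_id"],
        altitude_m=get("altitude_m"),
        ph_cacl2=get("ph_cacl2"),
        clay_pct=get("clay_pct"),
        silt_pct=get("silt_pct"),
        apparent_density_g_cm3=get("apparent_density_g_cm3"),
        soc_g_per_kg=get("soc_g_per_kg"),
        stock_t_ha=get("stock_t_ha"),
        manure_liquid=get("manure_liquid"),
        manure_solid=get("manure_solid"),
        prop_meadow=get("prop_meadow"),
        prop_cereal=get("prop_cereal"),
        prop_hoe=get("prop_hoe"),
        status=TrendStatus(status),
    )


def read_sites(path: str | Path) -> list[SiteRecord]:
    """Read site metadata; empty cells become explicit missing values."""
    df = pd.read_csv(path)
    if "site_id" not in df.columns:
        raise SchemaError("site table is missing column(s): site_id")
    return [_record_from_row(row) for row in df.to_dict("records")]


def sites_to_frame(records: Iterable[SiteRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = {f.name if f.name != "status" else "status": getattr(r, f.name) for f in fields(r)}
        d["status"] = r.status.value
        rows.append(d)
    df = pd.DataFrame(rows)
    return df.rename(columns={})[[c for c in SITE_COLUMNS if c in df.columns]]


def write_sites(records: Iterable[SiteRecord], path: str | Path) -> None:
    sites_to_frame(records).to_csv(path, index=False)


def _fixture_path():
    return resources.files("socmon.data").joinpath("table1_sites.csv")


def load_table1_frame(full: bool = False) -> pd.DataFrame:
    """The bundled 30-site cropland network metadata table.

    With ``full=True`` the sub-period management means (1985-1999 and
    2000-2014 columns) are retained alongside the 1985-2014 overall means.
    """
    with resources.as_file(_fixture_path()) as p:
        df = pd.read_csv(p)
    if not full:
        df = df[[c for c in SITE_COLUMNS if c in df.columns]]
    return df


def load_table1_fixture() -> list[SiteRecord]:
    """The bundled network as :class:`SiteRecord` objects (30 sites)."""
    with resources.as_file(_fixture_path()) as p:
        return read_sites(p)


def aggregate_replicates(data: "MonitoringDataset | pd.DataFrame") -> pd.DataFrame:
    """Mean of natural-log SOC per site and campaign.

    Returns a table with columns site_id, campaign, year, mean_log_soc,
    n_replicates.  Averaging on the log scale makes ``exp(mean_log_soc)`` the
    geometric mean of the replicate concentrations, the aggregation all trend
    models and the bootstrap operate on.
    """
    df = data.measurements if isinstance(data, MonitoringDataset) else data
    df = _validate_measurement_frame(df)
    if df.empty:
        raise ValidationError("no measurements to aggregate")
    g = df.assign(log_soc=np.log(df["soc_g_per_kg"].astype(float))).groupby(
        ["site_id", "campaign"], sort=True
    )
    out = g.agg(
        year=("year", "mean"),
        mean_log_soc=("log_soc", "mean"),
        n_replicates=("log_soc", "size"),
    ).reset_index()
    return out
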