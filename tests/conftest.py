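import numpy as np
import pandas as pd
import pytest

from socmon.data_model import MonitoringDataset, SiteRecord


def make_measurements(values_by_site_campaign, start_year=1990.0, interval=5.0, method="DC"):
    """Build a long-format measurement frame from {site: {campaign: [replicates]}}."""
    rows = []
    for site, campaigns in values_by_site_campaign.items():
        for c, reps in campaigns.items():
            year = start_year + (c - 1) * interval
            for r, v in enumerate(reps, start=1):
                rows.append((site, c, year, r, float(v), method))
    return pd.DataFrame(
        rows, columns=["site_id", "campaign", "year", "replicate", "soc_g_per_kg", "method"]
    )


@pytest.fixture
def tiny_dataset():
    """Two sites, three campaigns, two replicates; well behaved."""
    df = make_measurements(
        {
            "A": {1: [20.0, 22.0], 2: [21.0, 23.0], 3: [22.0, 24.0]},
            "B": {1: [10.0, 11.0], 2: [10.5, 11.5], 3: [11.0, 12.0]},
        }
    )
    sites = {s: SiteRecord(site_id=s) for s in ("A", "B")}
    return MonitoringDataset(df, sites)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
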