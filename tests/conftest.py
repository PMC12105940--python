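import numpy as np
import pandas as pd
import pytest

from synchroscope.simulate import StudyConfig, make_study_fixture


@pytest.fixture(scope="session")
def small_study():
    """A small but complete simulated study shared across read-only tests."""
    cfg = StudyConfig(n_species=4, n_sites=25, n_years=20, gap_prob=0.05, region_km=60.0)
    return make_study_fixture(cfg, seed=20260925)


@pytest.fixture()
def oracle_fixture():
    """5 sites x 20 years x 2 species with planted gaps and zeros."""
    rng = np.random.default_rng(1234)
    sites = pd.DataFrame(
        {
            "site_id": [f"S{i}" for i in range(5)],
            "easting_m": rng.uniform(0, 60_000, 5),
            "northing_m": rng.uniform(0, 60_000, 5),
        }
    )
    years = np.arange(1990, 2010)
    rows = []
    for sp, lam in (("spA", 40.0), ("spB", 1.2)):  # spB small -> natural zeros
        for s in sites["site_id"]:
            counts = rng.poisson(lam * rng.lognormal(0, 0.4), size=len(years))
            surveyed = rng.random(len(years)) > 0.12  # planted gaps
            for y, c, keep in zip(years, counts, surveyed):
                if keep:
                    rows.append({"species": sp, "site": s, "year": int(y), "count": int(c)})
    return pd.DataFrame(rows), sites
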