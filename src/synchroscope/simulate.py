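"""Synthetic landscapes, climate fields and dispersal-coupled populations.

The generator emulates the statistical structure that the synchrony analysis
assumes in real monitoring data:

* a planar landscape of survey sites on a national-grid-like coordinate
  system, each site carrying a habitat-composition vector over a small number
  of biotopes;
* seasonal gridded climate (4 seasons x {temperature, precipitation}) drawn
  from a zero-mean Gaussian random field with exponential spatial covariance
  ``field_sd^2 * exp(-d / phi(year))`` over occupied 5-km grid cells; the
  correlation range ``phi`` may trend linearly in time (a "dynamic Moran
  effect" scenario);
* per-species Gompertz dynamics on log abundance with climate forcing and
  independent site noise, followed by distance-kernel dispersal mixing on the
  natural scale, and a Poisson observation layer so structural zeros arise
  naturally;
* missing-at-random survey gaps per site-year.

All randomness flows from one master seed split into named substreams
(landscape / climate / dynamics / observation / gaps / species) so that
paired scenario comparisons can share noise streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from scipy.spatial.distance import pdist, squareform

SEASONS = ("winter", "spring", "summer", "autumn")
VARIABLES = ("temperature", "precipitation")

#: the eight climate-synchrony variable labels, season-major
CLIMATE_VARIABLES = tuple(f"{s}_{v}" for s in SEASONS for v in VARIABLES)

_STREAMS = ("landscape", "climate", "dynamics", "observation", "gaps", "species")


def substreams(seed: int) -> dict[str, np.random.Generator]:
    """Split ``seed`` into the named independent generator substreams."""
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Landscape:
    """Survey sites with planar coordinates (metres) and habitat composition.

    ``sites`` has columns site_id, easting_m, northing_m; ``habitat`` maps each
    site to a proportion vector over ``n_biotopes`` biotopes (rows sum to 1).
    """

    sites: pd.DataFrame
    habitat: pd.DataFrame  # columns: site_id, biotope, proportion
    grid_cell_size_m: float = 5000.0

    def __post_init__(self) -> None:
        ids = self.sites["site_id"]
        if ids.duplicated().any():
            raise ValueError("site_ids must be unique")
        coords = self.sites[["easting_m", "northing_m"]].to_numpy(float)
        if not np.all(np.isfinite(coords)):
            raise ValueError("site coordinates must be finite")
        sums = self.habitat.groupby("site_id")["proportion"].sum()
        if (self.habitat["proportion"] < -1e-12).any():
            raise ValueError("habitat proportions must be non-negative")
        if not np.allclose(sums.to_numpy(), 1.0, atol=1e-9):
            raise ValueError("habitat proportions must sum to 1 per site")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def coordinates(self) -> np.ndarray:
        return self.sites[["easting_m", "northing_m"]].to_numpy(float)


@dataclass
class ClimateScenario:
    """Gaussian-random-field climate over an inclusive year range.

    ``corr_range_km`` is either a constant or a callable year -> range (km);
    a linear trend in the range is how the dynamic Moran effect is planted.
    """

    start_year: int
    n_years: int
    corr_range_km: float | Callable[[int], float] = 50.0
    field_sd: float = 1.0
    mean_level: Mapping[str, float] = field(
        default_factory=lambda: {"temperature": 8.0, "precipitation": 80.0}
    )

    def __post_init__(self) -> None:
        if self.n_years < 12:
            raise ValueError("climate scenario needs at least 12 years")

    @property
    def years(self) -> range:
        return range(self.start_year, self.start_year + self.n_years)

    def phi(self, year: int) -> float:
        p = self.corr_range_km(year) if callable(self.corr_range_km) else float(self.corr_range_km)
        if not p > 0:
            raise ValueError(f"correlation range must be positive, got {p} for year {year}")
        return p


@dataclass
class SpeciesScenario:
    """Per-species dynamics parameters.

    Gompertz update on log abundance x:
        x[t+1] = a_i + b * x[t] + c_t * eps_clim + eta + trend
    with a_i = (1 - b) * log K_i, eps_clim the site-matched seasonal-mean
    climate anomaly weighted by ``climate_weights``, eta ~ N(0, site_noise_sd),
    and c_t = env_sensitivity + env_sensitivity_trend * (t - start).
    Dispersal mixes abundance with kernel exp(-d/alpha); emigration rate m may
    rise with local abundance when density-dependent emigration is enabled.
    """

    species_id: str
    specialism: str = "generalist"  # generalist | specialist
    mobility: float = 1.0  # kernel scale alpha, km (also used as the rank)
    emigration_rate: float = 0.0  # m in [0, 1)
    density_dependent_emigration: bool = False
    dd_emigration_slope: float = 0.0  # added per unit log1p(N)
    env_sensitivity: float = 0.4  # c
    env_sensitivity_trend: float = 0.0  # per-year additive change in c
    density_dependence: float = 0.3  # b, |b| < 1
    trend: float = 0.0  # per-year additive trend in log abundance
    obs_noise_sd: float = 0.0  # lognormal multiplier sd before Poisson
    site_noise_sd: float = 0.3
    base_abundance: float = 200.0  # equilibrium K at mean habitat suitability
    habitat_affinity: np.ndarray | None = None  # weights over biotopes
    climate_weights: Mapping[str, float] | None = None  # variable label -> weight

    def __post_init__(self) -> None:
        if not 0.0 <= self.emigration_rate < 1.0:
            raise ValueError("emigration rate must lie in [0, 1)")
        if not abs(self.density_dependence) < 1.0:
            raise ValueError("|density dependence| must be < 1")
        if self.mobility < 0:
            raise ValueError("mobility must be non-negative")


# ---------------------------------------------------------------------------
# landscape generation
# ---------------------------------------------------------------------------


def make_landscape(
    n_sites: int,
    region_km: float,
    n_biotopes: int,
    rng: np.random.Generator,
    grid_cell_size_m: float = 5000.0,
    habitat_concentration: float = 1.0,
) -> Landscape:
    """Place ``n_sites`` uniformly in a square region and draw Dirichlet habitat."""
    coords = rng.uniform(0.0, region_km * 1000.0, size=(n_sites, 2))
    ids = [f"S{i:03d}" for i in range(n_sites)]
    sites = pd.DataFrame(
        {"site_id": ids, "easting_m": coords[:, 0], "northing_m": coords[:, 1]}
    )
    props = rng.dirichlet(np.full(n_biotopes, habitat_concentration), size=n_sites)
    habitat = pd.DataFrame(
        {
            "site_id": np.repeat(ids, n_biotopes),
            "biotope": np.tile([f"B{k}" for k in range(n_biotopes)], n_sites),
            "proportion": props.ravel(),
        }
    )
    return Landscape(sites=sites, habitat=habitat, grid_cell_size_m=grid_cell_size_m)


def _occupied_cells(landscape: Landscape) -> tuple[pd.Series, np.ndarray, list[str]]:
    """Map sites to occupied grid cells; return per-site cell ids, centroids, cell ids."""
    from synchroscope.synchrony import site_to_grid_cell

    cell = landscape.sites.apply(
        lambda r: site_to_grid_cell(r["easting_m"], r["northing_m"], landscape.grid_cell_size_m),
        axis=1,
    )
    cell.index = landscape.sites["site_id"].to_numpy()
    cells = sorted(cell.unique())
    size = landscape.grid_cell_size_m
    centroids = np.array(
        [
            ((int(c.split("_")[1]) + 0.5) * size, (int(c.split("_")[2]) + 0.5) * size)
            for c in cells
        ]
    )
    return cell, centroids, cells


# ---------------------------------------------------------------------------
# climate field
# ---------------------------------------------------------------------------


def simulate_climate(
    landscape: Landscape,
    scenario: ClimateScenario,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Draw the seasonal climate table over the landscape's occupied grid cells.

    For every year, season and variable the values across cells are one draw
    from a zero-mean Gaussian random field with covariance
    ``field_sd^2 * exp(-d / phi(year))`` over cell centroids (exact Cholesky
    factorisation of the covariance; desk-scale cell counts), shifted by the
    variable's mean level.
    """
    if landscape.n_sites == 0:
        raise ValueError("landscape has no sites")
    rng = seed if isinstance(seed, np.random.Generator) else substreams(seed)["climate"]
    _, centroids, cells = _occupied_cells(landscape)
    d_km = squareform(pdist(centroids)) / 1000.0
    n = len(cells)
    rows: list[pd.DataFrame] = []
    for year in scenario.years:
        phi = scenario.phi(year)
        cov = scenario.field_sd**2 * np.exp(-d_km / phi)
        # symmetric square root via eigendecomposition: exact for the
        # (possibly numerically singular) fully-correlated limit, unlike a
        # jittered Cholesky
        w, v = np.linalg.eigh(cov)
        L = v * np.sqrt(np.clip(w, 0.0, None))
        for season in SEASONS:
            for variable in VARIABLES:
                z = L @ rng.standard_normal(n)
                rows.append(
                    pd.DataFrame(
                        {
                            "grid_cell": cells,
                            "year": year,
                            "season": season,
                            "variable": variable,
                            "value": z + scenario.mean_level.get(variable, 0.0),
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)


def climate_anomalies(
    climate: pd.DataFrame,
    scenario: ClimateScenario,
    weights: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Season/variable-weighted standardised climate anomaly per cell-year.

    Default weighting is the plain mean over all eight seasonal variables.
    Returns a cell x year DataFrame.
    """
    df = climate.copy()
    df["label"] = df["season"] + "_" + df["variable"]
    means = {v: scenario.mean_level.get(v, 0.0) for v in VARIABLES}
    df["anom"] = (
        df["value"] - df["variable"].map(means).astype(float)
    ) / scenario.field_sd
    if weights is None:
        weights = {lab: 1.0 for lab in CLIMATE_VARIABLES}
    w = df["label"].map(weights).fillna(0.0)
    total = sum(abs(x) for x in weights.values())
    if total == 0:
        raise ValueError("climate weights sum to zero")
    df["w_anom"] = df["anom"] * w / total
    wide = df.pivot_table(index="grid_cell", columns="year", values="w_anom", aggfunc="sum")
    return wide


# ---------------------------------------------------------------------------
# dispersal
# ---------------------------------------------------------------------------


def dispersal_matrix(coords_m: np.ndarray, alpha_km: float) -> np.ndarray:
    """Row-normalised redistribution kernel w_ji ~ exp(-d_ji/alpha), diagonal excluded."""
    if alpha_km <= 0:
        raise ValueError("dispersal kernel scale alpha must be positive")
    d_km = squareform(pdist(coords_m)) / 1000.0
    w = np.exp(-d_km / alpha_km)
    np.fill_diagonal(w, 0.0)
    rows = w.sum(axis=1)
    if np.any(rows == 0):  # single site: nowhere to go
        w = np.zeros_like(w)
        rows = np.ones_like(rows)
    return w / rows[:, None]


def apply_dispersal(n: np.ndarray, m: np.ndarray, w: np.ndarray) -> np.ndarray:
    """N'_i = (1-m_i) N_i + sum_j m_j w_ji N_j (mass-conserving mixing)."""
    return (1.0 - m) * n + (m * n) @ w


# ---------------------------------------------------------------------------
# population dynamics
# ---------------------------------------------------------------------------


def simulate_populations(
    landscape: Landscape,
    species_scenarios: Sequence[SpeciesScenario],
    climate: pd.DataFrame,
    seed: int | dict[str, np.random.Generator],
    climate_scenario: ClimateScenario | None = None,
    gap_prob: float = 0.0,
) -> pd.DataFrame:
    """Simulate the long-format abundance table (species, site, year, count).

    Log abundance follows a Gompertz update with climate forcing and site
    noise, then dispersal mixing on the natural scale, then Poisson observed
    counts. Missing-at-random site-years are dropped with probability
    ``gap_prob``. Deterministic for a fixed seed.
    """
    streams = seed if isinstance(seed, dict) else substreams(seed)
    rng_dyn, rng_obs, rng_gap = streams["dynamics"], streams["observation"], streams["gaps"]

    if climate_scenario is None:
        years = np.array(sorted(climate["year"].unique()))
        climate_scenario = ClimateScenario(
            start_year=int(years[0]), n_years=len(years), field_sd=1.0
        )
    years = np.array(sorted(climate["year"].unique()))
    cell_of_site, _, _ = _occupied_cells(landscape)
    coords = landscape.coordinates()
    site_ids = landscape.sites["site_id"].to_numpy()
    n_sites = len(site_ids)

    # per-site habitat suitability multiplier for each species
    hab_wide = landscape.habitat.pivot(index="site_id", columns="biotope", values="proportion")
    hab_wide = hab_wide.loc[site_ids]

    frames: list[pd.DataFrame] = []
    for sp in species_scenarios:
        if sp.emigration_rate > 0 and sp.mobility == 0:
            raise ValueError(f"{sp.species_id}: dispersal kernel undefined (alpha=0, m>0)")
        anom = climate_anomalies(climate, climate_scenario, sp.climate_weights)
        anom_site = anom.loc[cell_of_site.loc[site_ids].to_numpy()].to_numpy()  # sites x years

        if sp.habitat_affinity is not None:
            suit = hab_wide.to_numpy() @ np.asarray(sp.habitat_affinity, float)
            suit = suit / suit.mean()
        else:
            suit = np.ones(n_sites)
        k_log = np.log(sp.base_abundance * np.clip(suit, 0.05, None))
        a = (1.0 - sp.density_dependence) * k_log

        w = dispersal_matrix(coords, sp.mobility) if sp.emigration_rate > 0 else None

        x = k_log.copy()
        counts = np.empty((n_sites, len(years)))
        for ti, year in enumerate(years):
            c_t = sp.env_sensitivity + sp.env_sensitivity_trend * ti
            eps = c_t * anom_site[:, ti] + rng_dyn.normal(0.0, sp.site_noise_sd, n_sites)
            x = a + sp.density_dependence * x + eps + sp.trend * ti
            n_nat = np.exp(x)
            if w is not None:
                m = np.full(n_sites, sp.emigration_rate)
                if sp.density_dependent_emigration:
                    m = np.minimum(m + sp.dd_emigration_slope * np.log1p(n_nat), 0.999)
                n_nat = apply_dispersal(n_nat, m, w)
                x = np.log(np.clip(n_nat, 1e-12, None))
            lam = n_nat
            if sp.obs_noise_sd > 0:
                lam = lam * np.exp(rng_obs.normal(0.0, sp.obs_noise_sd, n_sites))
            counts[:, ti] = rng_obs.poisson(np.clip(lam, 0, 1e9))
        df = pd.DataFrame(
            {
                "species": sp.species_id,
                "site": np.repeat(site_ids, len(years)),
                "year": np.tile(years, n_sites),
                "count": counts.astype(int).ravel(),
            }
        )
        if gap_prob > 0:
            keep = rng_gap.random(len(df)) >= gap_prob
            df = df.loc[keep]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# study fixture
# ---------------------------------------------------------------------------


@dataclass
class StudyConfig:
    """Configuration for a coherent small synthetic study."""

    n_species: int = 12
    n_sites: int = 60
    n_years: int = 30
    start_year: int = 1986
    region_km: float = 80.0
    n_biotopes: int = 6
    grid_cell_size_m: float = 5000.0
    gap_prob: float = 0.05
    corr_range_km_start: float = 50.0
    corr_range_km_end: float | None = None  # linear trend when set
    field_sd: float = 1.0
    # species-parameter spreads
    prop_specialist: float = 0.5
    mobility_km_range: tuple[float, float] = (5.0, 40.0)
    emigration_range: tuple[float, float] = (0.0, 0.3)
    env_sensitivity: float = 0.4
    env_sensitivity_trend_generalist: float = 0.0
    site_noise_sd: float = 0.3
    trend_sd: float = 0.01
    base_abundance: float = 200.0
    obs_noise_sd: float = 0.0

    def climate_scenario(self) -> ClimateScenario:
        if self.corr_range_km_end is None:
            rng_fn: float | Callable[[int], float] = self.corr_range_km_start
        else:
            y0, span = self.start_year, max(self.n_years - 1, 1)
            a, b = self.corr_range_km_start, self.corr_range_km_end
            rng_fn = lambda year, a=a, b=b, y0=y0, span=span: a + (b - a) * (year - y0) / span
        return ClimateScenario(
            start_year=self.start_year,
            n_years=self.n_years,
            corr_range_km=rng_fn,
            field_sd=self.field_sd,
        )


@dataclass
class StudyData:
    """Bundle of all study input tables plus the ground-truth scenarios."""

    abundance: pd.DataFrame
    sites: pd.DataFrame
    climate: pd.DataFrame
    habitat: pd.DataFrame
    attributes: pd.DataFrame
    landscape: Landscape
    climate_scenario: ClimateScenario
    species_scenarios: list[SpeciesScenario]

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "abundance": self.abundance,
            "sites": self.sites,
            "climate": self.climate,
            "habitat": self.habitat,
            "attributes": self.attributes,
        }


def _species_scenarios(config: StudyConfig, rng: np.random.Generator) -> list[SpeciesScenario]:
    out = []
    n = config.n_species
    n_spec = int(round(config.prop_specialist * n))
    specialisms = ["specialist"] * n_spec + ["generalist"] * (n - n_spec)
    mob = np.linspace(*config.mobility_km_range, n)
    emi = np.linspace(*config.emigration_range, n)
    order = rng.permutation(n)
    for i in range(n):
        spec = specialisms[order[i]]
        out.append(
            SpeciesScenario(
                species_id=f"sp{i:02d}",
                specialism=spec,
                mobility=float(mob[i]),
                emigration_rate=float(emi[i]),
                env_sensitivity=config.env_sensitivity,
                env_sensitivity_trend=(
                    config.env_sensitivity_trend_generalist if spec == "generalist" else 0.0
                ),
                site_noise_sd=config.site_noise_sd,
                trend=float(rng.normal(0.0, config.trend_sd)),
                base_abundance=config.base_abundance,
                obs_noise_sd=config.obs_noise_sd,
                habitat_affinity=rng.dirichlet(np.ones(config.n_biotopes))
                if spec == "specialist"
                else None,
            )
        )
    return out


def make_study_fixture(config: StudyConfig | None = None, seed: int = 0) -> StudyData:
    """Generate a coherent small study with known ground truth.

    The attribute table records the true scenario parameters (``truth_*``
    columns) so recovery tests can compare estimates against them.
    """
    config = config or StudyConfig()
    streams = substreams(seed)
    landscape = make_landscape(
        config.n_sites,
        config.region_km,
        config.n_biotopes,
        streams["landscape"],
        grid_cell_size_m=config.grid_cell_size_m,
    )
    climate_scenario = config.climate_scenario()
    climate = simulate_climate(landscape, climate_scenario, streams["climate"])
    scenarios = _species_scenarios(config, streams["species"])
    abundance = simulate_populations(
        landscape,
        scenarios,
        climate,
        streams,
        climate_scenario=climate_scenario,
        gap_prob=config.gap_prob,
    )
    # mean abundance over the final third of the study, emulating a separate
    # recent-period abundance survey
    recent = abundance[abundance["year"] >= config.start_year + 2 * config.n_years // 3]
    mean_ab = recent.groupby("species")["count"].mean()
    attributes = pd.DataFrame(
        {
            "species": [s.species_id for s in scenarios],
            "specialism": [s.specialism for s in scenarios],
            "mobility": [s.mobility for s in scenarios],
            "mean_abundance": [float(mean_ab.get(s.species_id, np.nan)) for s in scenarios],
            "truth_emigration_rate": [s.emigration_rate for s in scenarios],
            "truth_env_sensitivity": [s.env_sensitivity for s in scenarios],
            "truth_env_sensitivity_trend": [s.env_sensitivity_trend for s in scenarios],
            "truth_trend": [s.trend for s in scenarios],
        }
    )
    return StudyData(
        abundance=abundance,
        sites=landscape.sites,
        climate=climate,
        habitat=landscape.habitat,
        attributes=attributes,
        landscape=landscape,
        climate_scenario=climate_scenario,
        species_scenarios=scenarios,
    )


# ---------------------------------------------------------------------------
# direct null model-table generator (for permutation calibration)
# ---------------------------------------------------------------------------


def simulate_null_synchrony_table(
    n_species: int = 10,
    n_pairs: int = 50,
    n_windows: int = 5,
    species_sd: float = 0.1,
    pair_sd: float = 0.1,
    resid_sd: float = 0.2,
    attribute: str = "mobility",
    seed: int = 0,
) -> pd.DataFrame:
    """A ready-made model table under the null that an attribute is unrelated
    to synchrony.

    Synchrony responses carry species and pair random intercepts plus residual
    noise; controls (distance, mean northing, habitat similarity) are drawn
    independently; the species attribute is assigned at random, independent of
    everything else. Used to calibrate the permutation test's type-I error.
    """
    rng = np.random.default_rng(seed)
    sp_eff = rng.normal(0.0, species_sd, n_species)
    pair_eff = rng.normal(0.0, pair_sd, n_pairs)
    mid_years = np.arange(n_windows) + 0.5
    sp_idx = np.repeat(np.arange(n_species), n_pairs * n_windows)
    pair_idx = np.tile(np.repeat(np.arange(n_pairs), n_windows), n_species)
    win_idx = np.tile(np.arange(n_windows), n_species * n_pairs)
    n = len(sp_idx)
    r = sp_eff[sp_idx] + pair_eff[pair_idx] + rng.normal(0.0, resid_sd, n)
    if attribute == "specialism":
        attr_values = rng.choice(["generalist", "specialist"], size=n_species)
    else:
        attr_values = rng.normal(0.0, 1.0, n_species)
    table = pd.DataFrame(
        {
            "r": r,
            "species": [f"sp{i:02d}" for i in sp_idx],
            "pair_id": [f"P{i:03d}" for i in pair_idx],
            "mid_year": mid_years[win_idx],
            "distance_km": rng.uniform(1, 100, n_pairs)[pair_idx],
            "mean_northing_km": rng.uniform(0, 500, n_pairs)[pair_idx],
            "habitat_similarity": rng.uniform(0, 1, n_pairs)[pair_idx],
            attribute: np.asarray(attr_values)[sp_idx],
        }
    )
    return table


def with_emigration(
    scenarios: Sequence[SpeciesScenario], emigration_rate: float
) -> list[SpeciesScenario]:
    """Copies of ``scenarios`` with a common emigration rate (paired contrasts)."""
    return [replace(s, emigration_rate=emigration_rate) for s in scenarios]
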