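import numpy as np
import pandas as pd
import pytest

from synchroscope.simulate import (
    ClimateScenario,
    Landscape,
    SpeciesScenario,
    StudyConfig,
    dispersal_matrix,
    apply_dispersal,
    make_landscape,
    make_study_fixture,
    simulate_climate,
    simulate_populations,
    substreams,
)
from synchroscope.synchrony import SynchronyParams, moving_window_synchrony


def _flat_landscape(n, spacing_m=6000.0):
    sites = pd.DataFrame(
        {
            "site_id": [f"S{i}" for i in range(n)],
            "easting_m": np.arange(n) * spacing_m,
            "northing_m": np.zeros(n),
        }
    )
    habitat = pd.DataFrame(
        {"site_id": sites["site_id"], "biotope": "B0", "proportion": 1.0}
    )
    return Landscape(sites=sites, habitat=habitat)


class TestClimateField:
    def test_fully_correlated_limit(self):
        land = _flat_landscape(5)
        scen = ClimateScenario(start_year=2000, n_years=12, corr_range_km=1e15)
        clim = simulate_climate(land, scen, seed=1)
        one = clim[(clim["year"] == 2000) & (clim["season"] == "winter") & (clim["variable"] == "temperature")]
        assert one["value"].max() - one["value"].min() < 1e-6

    def test_independent_limit(self):
        land = _flat_landscape(40)
        scen = ClimateScenario(start_year=2000, n_years=30, corr_range_km=1e-9)
        clim = simulate_climate(land, scen, seed=2)
        t = clim[(clim["season"] == "winter") & (clim["variable"] == "temperature")]
        wide = t.pivot(index="year", columns="grid_cell", values="value")
        corr = wide.corr().to_numpy()
        off = corr[np.triu_indices_from(corr, k=1)]
        assert abs(off.mean()) < 0.1

    def test_covariance_matches_exponential_model(self):
        """Empirical cell-pair correlation over many draws matches exp(-d/phi)."""
        land = _flat_landscape(6, spacing_m=20_000.0)
        phi = 40.0
        scen = ClimateScenario(start_year=2000, n_years=300, corr_range_km=phi)
        clim = simulate_climate(land, scen, seed=3)  # 300 yr x 8 draws = 2400 fields
        clim["anom"] = clim["value"] - clim["variable"].map(
            {"temperature": 8.0, "precipitation": 80.0}
        )
        wide = clim.pivot_table(
            index=["year", "season", "variable"], columns="grid_cell", values="anom"
        )
        corr = wide.corr()
        cells = wide.columns
        coords = {c: int(c.split("_")[1]) * 5.0 + 2.5 for c in cells}  # km, cell centroids
        for i, a in enumerate(cells):
            for b in cells[i + 1 :]:
                d = abs(coords[a] - coords[b])
                assert corr.loc[a, b] == pytest.approx(np.exp(-d / phi), abs=0.05)

    def test_deterministic(self):
        land = _flat_landscape(4)
        scen = ClimateScenario(start_year=2000, n_years=12)
        c1 = simulate_climate(land, scen, seed=9)
        c2 = simulate_climate(land, scen, seed=9)
        pd.testing.assert_frame_equal(c1, c2)

    def test_nonpositive_range_rejected(self):
        scen = ClimateScenario(start_year=2000, n_years=12, corr_range_km=-1.0)
        with pytest.raises(ValueError):
            simulate_climate(_flat_landscape(3), scen, seed=0)

    def test_short_scenario_rejected(self):
        with pytest.raises(ValueError):
            ClimateScenario(start_year=2000, n_years=5)


class TestDispersal:
    def test_rows_sum_to_one_and_mass_conserved(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 50_000, (20, 2))
        w = dispersal_matrix(coords, alpha_km=15.0)
        assert np.allclose(w.sum(axis=1), 1.0, atol=1e-9)
        n = rng.uniform(10, 500, 20)
        m = np.full(20, 0.3)
        n2 = apply_dispersal(n, m, w)
        assert n2.sum() == pytest.approx(n.sum(), rel=1e-6)
        assert (n2 > 0).all()

    def test_zero_alpha_with_emigration_rejected(self):
        land = _flat_landscape(3)
        scen = ClimateScenario(start_year=2000, n_years=12)
        clim = simulate_climate(land, scen, seed=0)
        sp = SpeciesScenario(species_id="x", mobility=0.0, emigration_rate=0.2)
        with pytest.raises(ValueError):
            simulate_populations(land, [sp], clim, seed=0, climate_scenario=scen)


class TestPopulationDynamics:
    @staticmethod
    def _mean_sync(ab, sites):
        rec, _ = moving_window_synchrony(ab, sites, SynchronyParams(max_pairs=300))
        return rec["r"].mean()

    def test_independent_sites_are_asynchronous(self):
        land = make_landscape(25, 60.0, 3, np.random.default_rng(5))
        scen = ClimateScenario(start_year=2000, n_years=30)
        clim = simulate_climate(land, scen, seed=5)
        sp = SpeciesScenario(species_id="x", env_sensitivity=0.0, site_noise_sd=0.3)
        ab = simulate_populations(land, [sp], clim, seed=5, climate_scenario=scen)
        assert abs(self._mean_sync(ab, land.sites)) < 0.1

    def test_shared_forcing_dominates(self):
        land = make_landscape(25, 60.0, 3, np.random.default_rng(6))
        scen = ClimateScenario(start_year=2000, n_years=30, corr_range_km=1e6)
        clim = simulate_climate(land, scen, seed=6)
        sp = SpeciesScenario(species_id="x", env_sensitivity=1.0, site_noise_sd=0.15)
        ab = simulate_populations(land, [sp], clim, seed=6, climate_scenario=scen)
        assert self._mean_sync(ab, land.sites) > 0.5

    def test_dispersal_and_forcing_monotonicity(self):
        """Mean synchrony is (statistically) non-decreasing in m and in c."""
        land = make_landscape(20, 50.0, 3, np.random.default_rng(7))
        scen = ClimateScenario(start_year=2000, n_years=25, corr_range_km=40.0)
        clim = simulate_climate(land, scen, seed=7)
        ordered_m = ordered_c = 0
        reps = 10
        for k in range(reps):
            streams = lambda: substreams(1000 + k)
            base = dict(species_id="x", env_sensitivity=0.2, site_noise_sd=0.3, mobility=20.0)
            lo = simulate_populations(
                land, [SpeciesScenario(**base, emigration_rate=0.0)], clim, streams(), climate_scenario=scen
            )
            hi = simulate_populations(
                land, [SpeciesScenario(**base, emigration_rate=0.3)], clim, streams(), climate_scenario=scen
            )
            ordered_m += self._mean_sync(hi, land.sites) > self._mean_sync(lo, land.sites)
            weak = simulate_populations(
                land, [SpeciesScenario(species_id="x", env_sensitivity=0.1, site_noise_sd=0.3)],
                clim, streams(), climate_scenario=scen,
            )
            strong = simulate_populations(
                land, [SpeciesScenario(species_id="x", env_sensitivity=0.6, site_noise_sd=0.3)],
                clim, streams(), climate_scenario=scen,
            )
            ordered_c += self._mean_sync(strong, land.sites) > self._mean_sync(weak, land.sites)
        assert ordered_m >= 9
        assert ordered_c >= 9

    def test_synchrony_decays_with_distance(self):
        """Under an exponential climate field, pair synchrony falls with distance."""
        from scipy import stats
        from synchroscope.synchrony import eligible_pairs, climate_synchrony, windows_for_years
        from synchroscope.covariates import pair_covariates

        negatives = 0
        for k in range(10):
            land = make_landscape(20, 80.0, 3, np.random.default_rng(200 + k))
            scen = ClimateScenario(start_year=2000, n_years=20, corr_range_km=25.0)
            clim = simulate_climate(land, scen, seed=300 + k)
            pairs, _ = eligible_pairs(land.sites)
            rec = climate_synchrony(clim, land.sites, pairs, windows_for_years(range(2000, 2020)))
            cov = pair_covariates(pairs, land.sites, land.habitat)
            rec["pair"] = rec["site_a"] + "~" + rec["site_b"]
            cov["pair"] = cov["site_a"] + "~" + cov["site_b"]
            mean_r = rec.groupby("pair")["r"].mean()
            merged = cov.set_index("pair").join(mean_r)
            rho = stats.spearmanr(merged["distance_km"], merged["r"]).statistic
            negatives += rho < 0
        assert negatives >= 9


class TestStudyFixture:
    def test_row_count_bounds(self):
        cfg = StudyConfig(n_species=3, n_sites=10, n_years=15, gap_prob=0.1)
        study = make_study_fixture(cfg, seed=0)
        assert len(study.abundance) <= 3 * 10 * 15
        cfg0 = StudyConfig(n_species=3, n_sites=10, n_years=15, gap_prob=0.0)
        study0 = make_study_fixture(cfg0, seed=0)
        assert len(study0.abundance) == 3 * 10 * 15

    def test_deterministic_tables(self):
        cfg = StudyConfig(n_species=2, n_sites=8, n_years=12)
        s1 = make_study_fixture(cfg, seed=4)
        s2 = make_study_fixture(cfg, seed=4)
        for name in s1.tables():
            pd.testing.assert_frame_equal(s1.tables()[name], s2.tables()[name])

    def test_truth_columns_present(self):
        study = make_study_fixture(StudyConfig(n_species=2, n_sites=8, n_years=12), seed=1)
        assert {"truth_emigration_rate", "truth_env_sensitivity"} <= set(study.attributes.columns)

    def test_landscape_invariants(self):
        study = make_study_fixture(StudyConfig(n_species=2, n_sites=8, n_years=12), seed=2)
        sums = study.habitat.groupby("site_id")["proportion"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert study.sites["site_id"].is_unique
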