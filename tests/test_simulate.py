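"""Synthetic gradient generators: determinism, monotone responses, round trips."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import spearmanr

from riverhealth.bmwp import score_bmwp
from riverhealth.extension import fit_extension_model
from riverhealth.ndvi import build_buffer, compute_ndvi, summarize_sites, zonal_mean_ndvi
from riverhealth.pipeline import run_pipeline
from riverhealth.simulate import (
    GradientScenario,
    expected_bmwp,
    generate_communities,
    generate_dataset,
    generate_physchem,
    generate_rasters,
    generate_regression_table,
    occurrence_probability,
)
from riverhealth.wqi import compute_wqi


def test_scenario_validation():
    with pytest.raises(ValueError):
        GradientScenario(n_sites=1)
    with pytest.raises(ValueError):
        GradientScenario(gradient=(0.5, 1.2), n_sites=2)
    with pytest.raises(ValueError):
        GradientScenario(seasons=("winter",))


# -- determinism -------------------------------------------------------------


def test_fixed_seed_reproduces_everything(scenario):
    a = generate_dataset(scenario)
    b = generate_dataset(scenario)
    assert a.samples == b.samples
    assert a.physchem == b.physchem
    assert np.array_equal(a.regression.bmwp_obs, b.regression.bmwp_obs)
    assert a.regression.predictors.equals(b.regression.predictors)
    for season in scenario.seasons:
        assert np.array_equal(a.rasters[season][0].values, b.rasters[season][0].values)


def test_different_seeds_differ():
    a = generate_communities(GradientScenario(seed=1))
    b = generate_communities(GradientScenario(seed=2))
    assert a != b


# -- communities -------------------------------------------------------------


def test_logistic_limit_all_families_present_at_clean_site():
    assert occurrence_probability(1, 0.0, 1e6) == pytest.approx(1.0)
    sc = GradientScenario(n_sites=2, gradient=(0.0, 1.0),
                          occurrence_steepness=1e6, seasons=("dry",), seed=0)
    clean, dirty = generate_communities(sc)
    assert len(clean.families) == len(sc.family_pool)
    # at g = 1 every family with s < 10 has p -> 0; the s = 10 stragglers sit at 0.5
    assert set(dirty.families) <= {
        f for f, s in sc.family_pool.entries.items() if s == 10
    }


def test_expected_bmwp_is_non_increasing_in_gradient():
    sc = GradientScenario()
    values = [expected_bmwp(sc, g) for g in np.linspace(0, 1, 21)]
    assert all(b <= a + 1e-12 for a, b in zip(values, values[1:]))


def test_monte_carlo_bmwp_declines_along_gradient():
    """Spearman rho between g and mean score is negative over replicates."""
    gradient = np.linspace(0, 1, 8)
    means = np.zeros(8)
    for seed in range(200):
        sc = GradientScenario(n_sites=8, gradient=tuple(gradient),
                              seasons=("dry",), seed=seed)
        for i, sample in enumerate(generate_communities(sc)):
            means[i] += score_bmwp(sample, sc.family_pool).score
    rho = spearmanr(gradient, means / 200).statistic
    assert rho < -0.9


# -- physicochemistry --------------------------------------------------------


def test_zero_noise_zero_gradient_returns_baselines():
    sc = GradientScenario(n_sites=2, gradient=(0.0, 1.0), seasons=("dry",),
                          seed=0, salty_offsets={}).without_noise()
    clean, dirty = generate_physchem(sc)
    for name, (baseline, slope, _, _) in sc.physchem_response.items():
        assert getattr(clean, name) == pytest.approx(baseline)
    do_slope = sc.physchem_response["dissolved_oxygen"][1]
    assert dirty.dissolved_oxygen - clean.dissolved_oxygen == pytest.approx(do_slope)


def test_salty_sub_basin_offset_raises_ionic_load():
    sc = GradientScenario(n_sites=4, gradient=(0.3, 0.3, 0.3, 0.3),
                          seasons=("dry",), seed=0).without_noise()
    records = generate_physchem(sc)
    salado, grande = records[0], records[-1]
    assert salado.conductivity > grande.conductivity
    assert salado.chlorides > grande.chlorides
    assert salado.hardness > grande.hardness


def test_wqi_non_increasing_along_noiseless_gradient():
    sc = GradientScenario(n_sites=9, seasons=("dry",), seed=0,
                          salty_offsets={}).without_noise()
    wqis = [compute_wqi(r).wqi for r in generate_physchem(sc)]
    assert all(b <= a + 1e-9 for a, b in zip(wqis, wqis[1:]))


# -- rasters -----------------------------------------------------------------


def test_raster_targets_recovered_through_analysis_round_trip():
    sc = GradientScenario(n_sites=2, gradient=(0.0, 1.0), seed=0)
    targets = {
        ("S01", "dry"): 0.63, ("S02", "dry"): 0.20,
        ("S01", "rainy"): 0.55, ("S02", "rainy"): 0.31,
    }
    rasters, sites = generate_rasters(sc, targets=targets)
    for season, (nir, red) in rasters.items():
        ndvi = compute_ndvi(nir, red)
        for site in sites:
            got = zonal_mean_ndvi(ndvi, build_buffer(site), site.site_id, season)
            assert got.mean_ndvi == pytest.approx(
                targets[(site.site_id, season)], abs=1e-12
            )


def test_default_targets_follow_vegetation_link(scenario):
    rasters, sites = generate_rasters(scenario)
    spec = scenario.raster_spec
    results = summarize_sites(*rasters["dry"], sites, "dry")
    for r, g in zip(results, scenario.gradient):
        assert r.mean_ndvi == pytest.approx(
            spec.ndvi_intercept + spec.ndvi_slope * g, abs=1e-12
        )


def test_unattainable_target_rejected():
    sc = GradientScenario(n_sites=2, seed=0, seasons=("dry",))
    with pytest.raises(ValueError, match="target NDVI"):
        generate_rasters(sc, targets={("S01", "dry"): 1.5, ("S02", "dry"): 0.2})


# -- regression tables -------------------------------------------------------


def test_noiseless_table_recovers_model_and_sits_inside_any_band():
    from riverhealth.extension import band_and_flag, predict_bmwp

    data = generate_regression_table(GradientScenario(n_sites=15, seed=7))
    fitted = fit_extension_model(data, selection="none",
                                 variables=["N_total", "NO2"])
    assert fitted.r_squared == pytest.approx(1.0)
    calc = [
        predict_bmwp(fitted, dict(row)) for _, row in data.predictors.iterrows()
    ]
    verdict = band_and_flag(list(zip(data.bmwp_obs, calc)))
    assert verdict.inside_band.all()


# -- full pipeline -----------------------------------------------------------


def test_full_pipeline_smoke(scenario):
    res = run_pipeline(scenario)
    assert len(res.matrix) == scenario.n_sites * len(scenario.seasons)
    assert res.pca.variance_fraction.sum() == pytest.approx(1.0)
    assert res.matrix.data["ndvi"].between(-1, 1).all()
    assert (res.matrix.data["bmwp"] >= 0).all()
    assert res.matrix.data["wqi"].between(0, 100).all()


def test_gradient_discrimination_by_category():
    """Clean sites (g <= 0.2) outrank polluted ones (g >= 0.8) almost surely."""
    from riverhealth.bmwp import DEFAULT_BMWP_SCHEME

    names = DEFAULT_BMWP_SCHEME.names
    wins = 0
    n_rep = 100
    for seed in range(n_rep):
        sc = GradientScenario(
            n_sites=4, gradient=(0.1, 0.2, 0.8, 0.9), seasons=("dry",),
            occurrence_steepness=10.0, seed=seed,
        )
        ranks = [
            names.index(score_bmwp(s, sc.family_pool).category)
            for s in generate_communities(sc)
        ]
        # lower rank index = better category
        if max(ranks[:2]) < min(ranks[2:]):
            wins += 1
    assert wins >= 95
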