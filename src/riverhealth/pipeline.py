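"""End-to-end convenience pipeline over a synthetic or loaded dataset."""

from __future__ import annotations

from dataclasses import dataclass

from . import bmwp as bmwp_mod
from . import integration, ndvi as ndvi_mod, wqi as wqi_mod
from .simulate import GradientScenario, SyntheticDataset, generate_dataset


@dataclass(frozen=True)
class PipelineResult:
    bmwp_results: list
    wqi_results: list
    ndvi_results: list
    matrix: integration.SiteIndexMatrix
    pca: integration.PCAResult
    dataset: SyntheticDataset


def run_pipeline(
    scenario: GradientScenario | None = None,
    dataset: SyntheticDataset | None = None,
    table=None,
) -> PipelineResult:
    """Score BMWP, WQI and NDVI for one dataset and ordinate the results.

    Provide either a scenario (a dataset is generated from it) or a
    pre-built dataset; ``table`` overrides the tolerance table used for
    scoring (default: the scenario's family pool).
    """
    if scenario is None:
        scenario = GradientScenario()
    if dataset is None:
        dataset = generate_dataset(scenario)
    if table is None:
        table = scenario.family_pool
    bmwp_results = bmwp_mod.score_samples(dataset.samples, table)
    wqi_results = [wqi_mod.compute_wqi(r) for r in dataset.physchem]
    ndvi_results = []
    for season, (nir, red) in dataset.rasters.items():
        ndvi_results.extend(
            ndvi_mod.summarize_sites(nir, red, dataset.sites, season)
        )
    matrix = integration.assemble_matrix(bmwp_results, wqi_results, ndvi_results)
    pca = integration.run_pca(matrix)
    return PipelineResult(
        bmwp_results=bmwp_results,
        wqi_results=wqi_results,
        ndvi_results=ndvi_results,
        matrix=matrix,
        pca=pca,
        dataset=dataset,
    )
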