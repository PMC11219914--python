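"""Full synthetic pipeline: gradient -> three indices -> PCA integration.

Generates a 12-site, two-season dataset along an organic-pollution gradient,
scores BMWP, WQI and riparian NDVI for every site x season, assembles the
index matrix, and ordinates it with correlation-matrix PCA.  Group
differences between seasons are reported with the standard diagnostics.
"""

from riverhealth import run_pipeline
from riverhealth.integration import compare_groups
from riverhealth.simulate import GradientScenario

scenario = GradientScenario(n_sites=12, seed=42)
result = run_pipeline(scenario)

m = result.matrix.data
print(m.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

frac = result.pca.variance_fraction
print(f"\nPC1 + PC2 explain {100 * (frac[0] + frac[1]):.2f}% "
      f"of the correlation structure")
print("loadings:\n" + result.pca.loadings.to_string(
    float_format=lambda v: f"{v:+.3f}"))

gc = compare_groups(m["bmwp"], m["season"], grouping="season")
print(f"\nBMWP dry vs rainy: F = {gc.anova_f:.3f}, p = {gc.anova_p:.3f} "
      f"(Levene p = {gc.variance_homogeneity_p:.3f})")
# All three indices load on PC1 with the same sign: the pollution gradient
# drives biology, chemistry and riparian vegetation together.
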