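"""Geographic-extension validation of the BMWP with the published equation.

Generates a qualifier table whose observed BMWP follows the published
extension model (BMWP_calc = 92.697 - 5.982 N_total + 260.634 NO2) with
noise, refits by backward elimination, and flags sites against the 95%
confidence band of the calculated-vs-observed regression.
"""

from riverhealth.extension import (
    PUBLISHED_MODEL,
    band_and_flag,
    fit_extension_model,
    predict_bmwp,
)
from riverhealth.simulate import GradientScenario, generate_regression_table

print(f"published equation at zero nutrients: "
      f"{predict_bmwp(PUBLISHED_MODEL, {'N_total': 0, 'NO2': 0})}")

data = generate_regression_table(
    GradientScenario(n_sites=15, seed=8), noise_sd=6.0
)
model = fit_extension_model(data, selection="backward", alpha=0.05)
print(f"backward elimination kept: {model.selected_variables}, "
      f"R^2 = {model.r_squared:.3f}")
for name, coef in model.coefficients.items():
    print(f"    {name}: {coef:+.3f}")

calc = [predict_bmwp(model, dict(row)) for _, row in data.predictors.iterrows()]
pairs = list(zip(data.bmwp_obs, calc))
for band in ("confidence", "prediction"):
    verdict = band_and_flag(pairs, level=0.95, band=band, site_ids=data.site_ids)
    outside = verdict.outside_sites
    print(f"{len(verdict.site_ids) - len(outside)}/{len(verdict.site_ids)} sites "
          f"inside the 95% {band} band"
          + (f"; outside: {', '.join(outside)}" if outside else ""))
# The confidence band brackets the mean response only, so scattered sites
# fall outside it; the prediction band is the right envelope for judging
# whether individual new sites fit the calibrated relationship.
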