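"""Compute the Dinius multiplicative WQI for two contrasting water samples.

WQI = prod(I_i ** w_i) over 12 subindices built from 13 measured parameters;
each subindex maps a raw measurement onto a 0-100 quality scale.  The score
is graded on a general scale and on water-use scales (agriculture, public
water supply).
"""

from riverhealth.wqi import PhyschemRecord, compute_wqi

mountain_spring = PhyschemRecord(
    site_id="spring", season="dry",
    atmospheric_temperature=22.0, water_temperature=18.0,
    dissolved_oxygen=9.0, pH=7.4, conductivity=250.0, nitrates=0.4,
    alkalinity=90.0, hardness=100.0, chlorides=12.0, color=3.0,
    bod5=0.8, total_coliforms=20.0, fecal_coliforms=5.0,
)
below_discharge = PhyschemRecord(
    site_id="discharge", season="dry",
    atmospheric_temperature=24.0, water_temperature=29.0,
    dissolved_oxygen=3.0, pH=8.1, conductivity=1900.0, nitrates=9.0,
    alkalinity=260.0, hardness=420.0, chlorides=210.0, color=55.0,
    bod5=16.0, total_coliforms=1.5e5, fecal_coliforms=3.0e4,
)

for record in (mountain_spring, below_discharge):
    r = compute_wqi(record)
    print(f"{r.site_id}: WQI = {r.wqi:.2f} -> {r.general_category}")
    for use, category in r.use_categories.items():
        print(f"    {use}: {category}")
    worst = sorted(r.subindices.items(), key=lambda kv: kv[1])[:3]
    print(f"    weakest subindices: "
          + ", ".join(f"{p} = {v:.1f}" for p, v in worst))
# The multiplicative form means one very poor parameter (e.g. coliforms)
# drags the whole index down even when the others are good.
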