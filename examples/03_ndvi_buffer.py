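"""Riparian-buffer NDVI: from reflectance bands to a per-site mean.

Builds a small synthetic NIR/red band pair in which the vegetation inside a
site's upstream buffer is denser than the surroundings, then recovers the
buffer-mean NDVI with the standard 200 m (upstream) x 120 m (each side)
rectangle.
"""

import numpy as np

from riverhealth.ndvi import SitePoint, build_buffer, compute_ndvi, zonal_mean_ndvi
from riverhealth.raster import RasterBand

# 60 x 60 pixels of 10 m: a 600 m x 600 m scene
red = RasterBand(np.full((60, 60), 0.20), origin=(0.0, 600.0), pixel_size=10.0)
ndvi_field = np.full((60, 60), 0.12)          # sparse dryland background
ndvi_field[10:40, 20:35] = 0.55               # denser riparian strip
nir = red.with_values(red.values * (1 + ndvi_field) / (1 - ndvi_field))

site = SitePoint("gauge", x=320.0, y=200.0, upstream_azimuth=0.0)
buffer = build_buffer(site)                   # defaults: 200 m x 2 x 120 m
print(f"buffer area: {buffer.area:,.0f} m^2")

ndvi = compute_ndvi(nir, red)
result = zonal_mean_ndvi(ndvi, buffer, site.site_id, "dry")
print(f"{result.site_id}: mean NDVI = {result.mean_ndvi:.3f} "
      f"over {result.n_pixels} pixels")
# The buffer mean sits between the riparian (0.55) and background (0.12)
# values, weighted by how much of the rectangle each covers.
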