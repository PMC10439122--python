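"""Infer tree respiration and NPP from a synthetic flux-tower year.

A half-hourly tower record with known truth is generated, then the
observation-side chain runs: Q10 interpolation of sparse soil-respiration
chamber visits, tree respiration by differencing ecosystem respiration and
the non-root soil share (root fraction 0.42, range 0.30-0.50), and NPP as
GPP minus tree respiration.  Because the generator and the inference share
their constants, the mid-band recovers the hidden truth to floating point.
"""

import numpy as np

from sprucestand import (
    RootFraction,
    gen_flux_series,
    gen_weather,
    infer_npp,
    infer_tree_respiration,
    interpolate_soil_resp_q10,
)

drivers = gen_weather(years=1, cadence="half-hourly", seed=42)
tower, chambers, truth = gen_flux_series(drivers, f_root=0.42, q10_soil=2.0, seed=42)

soil = interpolate_soil_resp_q10(chambers, tower["tair_c"], q10=2.0)
tree_resp = infer_tree_respiration(tower["reco"], soil, RootFraction())
npp = infer_npp(tower["gpp"], tree_resp)

to_annual = 1.0  # series already in kgC m^-2 per half hour; sums give totals
print(f"chamber visits used:          {len(chambers)}")
print(f"annual GPP:                   {tower['gpp'].sum():.3f} kgC m^-2 yr^-1")
print(f"annual tree respiration:      {tree_resp.mid.sum():.3f} "
      f"[{tree_resp.low.sum():.3f}, {tree_resp.high.sum():.3f}] kgC m^-2 yr^-1")
print(f"annual NPP:                   {npp.mid.sum():.3f} "
      f"[{npp.low.sum():.3f}, {npp.high.sum():.3f}] kgC m^-2 yr^-1")
print(f"max |NPP - truth| (mid band): {np.max(np.abs(npp.mid - truth['npp'])):.2e}")
print("Brackets are the uncertainty band from the 30-50% root-fraction range; "
      "the mid band reproduces the generator's hidden NPP exactly.")
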