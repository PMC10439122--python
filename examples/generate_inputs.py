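"""Write every synthetic input kind as CSV, ready for the package readers.

Produces a daily driver file, a half-hourly tower file with fluxes and
chamber visits, an annual CO2 series, a plot survey and a WCC-style yield
table under ./synthetic_inputs/ (column schemas match the package readers,
so real site files in the same layout can be dropped in).
"""

from pathlib import Path

import pandas as pd

from sprucestand import (
    gen_co2_series,
    gen_flux_series,
    gen_survey,
    gen_weather,
    gen_wcc_table,
)

out = Path("synthetic_inputs")
out.mkdir(exist_ok=True)
seed = 1

daily = gen_weather(years=3, cadence="daily", seed=seed)
daily.rename_axis("time").to_csv(out / "drivers_daily.csv")

hh = gen_weather(years=1, cadence="half-hourly", seed=seed)
tower, chambers, _ = gen_flux_series(hh, seed=seed)
tower.rename_axis("time").to_csv(out / "tower_halfhourly.csv")
chambers.rename_axis("time").to_csv(out / "soil_chambers.csv")

gen_co2_series(1973, 2018, mode="ramp").to_csv(out / "co2_annual.csv")

survey = gen_survey(seed=seed)
rows = [
    {"plot_id": p + 1, "dbh_cm": d}
    for p, plot in enumerate(survey.dbh_by_plot)
    for d in plot
]
pd.DataFrame(rows).to_csv(out / "survey.csv", index=False)

wcc = pd.concat(
    [gen_wcc_table(thinned=True), gen_wcc_table(thinned=False)], ignore_index=True
)
wcc.to_csv(out / "wcc_table.csv", index=False)

for f in sorted(out.iterdir()):
    print(f"{f}  ({f.stat().st_size // 1024} KiB)")
print("Files mirror the reader schemas: daily/half-hourly drivers, tower "
      "fluxes, chamber visits, annual CO2, plot survey, WCC yield table.")
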