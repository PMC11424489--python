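"""Fire-regime trends: is fire size increasing over the record?

Builds a 40-year synthetic event registry whose mean size drifts upward,
filters to fires > 2 km2, and summarises annual mean size, extreme
(95th-percentile) size and burnt area with the Mann-Kendall test, the
Theil-Sen slope and the fitted-endpoint relative change.
"""

import numpy as np
import pandas as pd

from pyrodelta import annual_fire_stats, generate_fire_sizes, trend_summary

rng = np.random.default_rng(3)
rows = []
for i, year in enumerate(range(1981, 2021)):
    mu = 0.55 + 0.006 * i          # slow upward drift of log10 mean size
    sizes = generate_fire_sizes(int(rng.integers(60, 120)), mu, 0.5,
                                min_size=1.0, seed=rng)
    rows.append(pd.DataFrame({"year": year, "size_km2": sizes}))
events = pd.concat(rows, ignore_index=True)

stats = annual_fire_stats(events, min_size_km2=2.0)
print(stats.head(3).round(2))

for col in ("mean_size", "p95_size", "burnt_area"):
    tr = trend_summary(stats.index.to_numpy(dtype=float),
                       stats[col].to_numpy())
    print(f"\n{col}: Sen slope {tr.sen_slope:+.3f} per yr, "
          f"MK S={tr.mk_s}, p={tr.mk_p:.2g}, "
          f"change {tr.relative_change_pct:+.0f}% over the record")
# Positive Sen slopes with small Mann-Kendall p-values across all three
# series indicate a coherent intensification of the fire regime; the
# relative change compares the Theil-Sen fit at the end vs start year.
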