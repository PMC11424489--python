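"""Run the whole pipeline on a synthetic landscape and read the report.

simulate -> counterfactual deltas -> energy decomposition -> event
characterisation -> size regressions (with field significance) -> trends,
all seeded, writing every stage artifact plus a JSON report.
The same run is available from the shell:

    pyrodelta run-all --seed 7 --out-dir pyrodelta_out
"""

import tempfile
from pathlib import Path

from pyrodelta import ControlCriteria, RunConfig, SyntheticConfig, run_pipeline

config = RunConfig(
    synthetic=SyntheticConfig(grid_nx=110, grid_ny=110, n_fires=35,
                              years=tuple(range(2002, 2009))),
    criteria=ControlCriteria(),        # 50 x 25 km window, <20% loss, same type
    lags=(1, 2), min_fires=5, cell_size_px=55, seed=7)

out_dir = Path(tempfile.mkdtemp()) / "run"
report = run_pipeline(config, out_dir)

print("artifacts:", sorted(p.name for p in out_dir.iterdir()))
head = report["headline"]
print(f"\ndomain-wide beta_dT (JJA, lag 1): {head['beta_dT_jja_lag1']:.3f} "
      "K per log10(km2)")
print(f"warming per doubling: {head['warming_per_doubling_K']:.3f} K")
print(f"regional mean warming: {head['regional_mean_warming_K']:.3f} K")
per_type = report.get("per_type_beta_dT", {})
if "error" not in per_type:
    print("per-type slopes:",
          {k: round(v, 3) for k, v in per_type.items()})
print(f"cells fitted {report['n_cells_fit']}, field-significant "
      f"{report['n_cells_field_significant']}")
# The report's per-doubling value is exactly beta * log10(2), and two runs
# with the same config and seed reproduce the report byte for byte.
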