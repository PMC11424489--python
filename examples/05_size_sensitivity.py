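"""Quantify how postfire warming is amplified by fire size.

Fits dT = a + beta * log10(size) domain-wide and per grid cell, converts
the slope into warming per doubling of fire size, and screens the
per-cell slopes with a Benjamini-Hochberg field-significance test.
"""

import numpy as np

from pyrodelta import (apply_field_significance, cell_regression,
                       domain_regression, fraction_of_mean_warming,
                       generate_fire_sizes, warming_per_doubling)

rng = np.random.default_rng(0)

# Event population: log-normal sizes truncated at 1 km2; summer dT built
# from an injected slope of 0.44 K per log10(km2) plus 1 K observation noise.
sizes = generate_fire_sizes(5000, mu=0.8, sigma=0.6, min_size=1.0, seed=1)
dT = 0.2 + 0.44 * np.log10(sizes) + rng.normal(0, 1.0, sizes.size)

beta, se, p = domain_regression(sizes, dT)
per2x = warming_per_doubling(beta)
print(f"domain-wide beta_dT: {beta:.3f} +/- {se:.3f} K per log10(km2), p={p:.2g}")
print(f"warming per doubling of fire size: {per2x:.3f} K")
print(f"as a share of the mean warming ({dT.mean():.2f} K): "
      f"{fraction_of_mean_warming(per2x, dT.mean()):.0f}%")

# Per-cell regressions (>= 10 fires each) and FDR-controlled screening.
cells = rng.integers(0, 40, size=sizes.size)
results = [cell_regression(sizes[cells == c], dT[cells == c], cell_id=c)
           for c in range(40)]
results = [r for r in results if r is not None]
apply_field_significance(results, alpha_fdr=0.10)
print(f"\ncells fitted: {len(results)}, locally significant: "
      f"{sum(r.locally_significant for r in results)}, "
      f"field significant (BH, alpha_FDR=0.10): "
      f"{sum(r.field_significant for r in results)}")
# With a real injected effect everywhere, essentially every cell survives
# the FDR screen; under a null it would control false discoveries at 10%.
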