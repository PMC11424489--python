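# pyrodelta

Postfire biogeophysical change attribution for northern temperate and
boreal forest landscapes: how much does a forest fire change land surface
temperature, albedo, evapotranspiration and leaf area — and how do those
changes grow with fire size?

The package is a library-first toolkit for fire ecologists and
land-surface scientists working with gridded satellite-style data
(500-m seasonal rasters, fire-event patch tables, active-fire
detections). Every stage of the analysis is exercisable on a built-in
synthetic landscape generator, so the full pipeline runs and is tested
without any data download.

## What it computes

**Space-and-time counterfactual (Δ).** For a burnt pixel, the gross
change of a variable *v* between the year before fire and lag *L* years
after mixes the fire effect with interannual climate variability. The
fire-induced change is

    Δv = Δv_gross − Δv_res,

where Δv_res is the mean gross change of matched *control pixels*:
unburnt from the fire year through the analysis year, same (prefire)
forest type, cumulative tree-cover loss < 20% over that period, and
within a 50 × 25 km search window. Event-level Δ is the unweighted mean
over the event's burnt pixels.

**Surface energy balance.** Event deltas are decomposed under the
local-effect assumption (ΔSW_in = ΔLW_in = 0):

    ΔSW_out = Δα · SW_in
    ΔLW_out = ½σ[(T_d⁴Δε + 4εT_d³ΔT_d) + (T_n⁴Δε + 4εT_n³ΔT_n)]
    ΔLE     = ΔET · ρL_v  (= 28.94 W m⁻² per mm day⁻¹)
    Δ(H+G)  = −ΔSW_out − ΔLW_out − ΔLE        (budget residual)
    ΔR_n    = −ΔSW_out − ΔLW_out = ΔLE + Δ(H+G)

with broadband emissivity ε = 0.2122ε₂₉ + 0.3859ε₃₁ + 0.4029ε₃₂.

**Fire-size sensitivity.** OLS fits of Δ = α + β·log₁₀(fire size km²),
per grid cell (≥ 10 fires, events ≥ 1 km²) and domain-wide; local slope
significance (two-tailed t, P < 0.05) plus Benjamini–Hochberg field
significance across cells (α_FDR = 0.10); per-forest-type slopes via a
categorical interaction model; fire-vulnerability means with one-tailed
t-tests and Tukey HSD. β converts to warming per doubling of fire size
as β·log₁₀2.

**Fire characteristics.** FRP density (total fire radiative power over
scan-angle-corrected detection area, MW km⁻²), two-year-window forest
mortality from 30-m loss subpixels, and 50%-dominance forest typing
(ENF/DNF/DBF, with a mixed-forest fallback).

**Fire-regime trends.** Annual mean size, extreme (95th-percentile)
size and burnt area over fires > 2 km², with Mann–Kendall tests,
Theil–Sen slopes and fitted-endpoint relative change.

## Worked example

`examples/` holds one short script per capability. Recovering injected
fire effects on a zero-noise synthetic scene
(`python examples/02_counterfactual_deltas.py`):

```
event  type  size_km2   recovered dT (K)   injected dT (K)
    0  ENF       2.75           0.441633          0.441633
    1  DBF       8.75           0.076520          0.076520
    2  MF        4.25           0.268517          0.268517
    3  ENF       3.25           0.481536          0.481536
    4  DBF      24.75           0.103615          0.103615
    5  ENF       2.00           0.365566          0.365566
```

The counterfactual reproduces the generator's injected summer warming to
machine precision — conifer stands (ENF) warm most, broadleaf (DBF)
barely at all, and within a type the warming grows with log fire size.
Fitting that growth on a noisy population of 5,000 events
(`python examples/05_size_sensitivity.py`):

```
domain-wide beta_dT: 0.430 +/- 0.027 K per log10(km2), p=5.9e-54
warming per doubling of fire size: 0.129 K
as a share of the mean warming (0.59 K): 22%

cells fitted: 40, locally significant: 27, field significant (BH, alpha_FDR=0.10): 27
```

A slope of ~0.43 K per tenfold size increase means each doubling of
fire size adds ~0.13 K of postfire summer warming — about a fifth of
the mean warming signal itself.

The full orchestrated run (simulate → deltas → energy → characterize →
regress → trends) is `examples/07_full_pipeline.py`, or from the shell:

```bash
pyrodelta run-all --seed 7 --out-dir out/
```

## Layout

```
src/pyrodelta/
  synthetic.py         # landscape + fire-event + detection generator
  counterfactual.py    # control matching, pixel/event deltas, seasonal means
  energy.py            # energy-balance decomposition
  characterization.py  # FRP density, mortality, forest typing
  sensitivity.py       # size regressions, FDR, interaction model, Tukey
  trends.py            # Mann-Kendall, Theil-Sen, annual fire statistics
  pipeline.py, cli.py  # orchestration and the thin CLI
  io.py                # NetCDF / CSV / GeoJSON readers and writers
examples/              # one narrative script per capability
docs/methods.md        # model assumptions, parameters, limitations
```
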