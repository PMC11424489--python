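# Methods

This note documents the models implemented in `pyrodelta`, the choices
made where the design was genuinely open, and what the synthetic tests
do and do not demonstrate about real satellite data.

## The counterfactual model

The attribution problem is to separate a fire-induced change in a land
surface variable (LST, albedo, ET, LAI) from the interannual background
signal shared by the whole region. We assume additivity:

    Δv_gross = Δv_fire + Δv_background,

where Δv_gross is the observed change of a burnt pixel between the year
before the fire and the analysis year (lag L ≥ 1), and Δv_background is
estimated as the mean Δv_gross of matched unburnt control pixels. Four
admission rules define a control: (i) inside a window centred on the
target (default 50 × 25 km, ≈ 100 × 50 pixels at 500 m); (ii) unburnt in
every year from the fire year through the analysis year; (iii) the same
forest type as the target on the prefire-year map (postfire type can be
altered by the fire itself); (iv) cumulative tree-cover loss below 20%
over the fire year .. analysis year, excluding pixels disturbed by
harvest or windthrow. The target pixel is excluded; a pixel with no
admissible control is dropped and counted, never gap-filled. Event-level
Δ is the unweighted mean over the event's valid pixels.

Conventions worth making explicit:

* "one year after fire" means calendar year `fire_year + 1`; "the year
  before" means `fire_year − 1`.
* The winter season (DJF) is labelled by the year of its January and
  February (December of year y−1 + January/February of year y → DJF of
  year y), keeping the "first winter after fire" entirely postfire.
* The window is converted to pixels with floor(window_km / pixel_km) and
  clipped at grid edges; `min_controls` defaults to 1, and records carry
  the mean control count so stricter thresholds can be applied post hoc.
* Controls burnt in years *before* the fire year are admissible — the
  admission rule is deliberately the literal per-lag rule, not a
  never-burnt rule. See "Limitations" for the consequence.

## Energy-balance decomposition

Under the local-effect assumption (fire does not change incoming short-
or longwave radiation at the pixel scale) the net-radiation change is
ΔR_n = −ΔSW_out − ΔLW_out, and the surface budget closes as
ΔR_n = ΔLE + Δ(H+G). Components:

* ΔSW_out = Δα × SW_in, with SW_in taken from the (coarse) radiation
  field at the event location for the analysis season.
* ΔLW_out linearises the Stefan–Boltzmann law separately around daytime
  and nighttime reference temperatures and averages the two, with a
  single Δε for day and night. The linearisation point is the prefire
  control-mean state (a config switch allows the burnt pixels' own
  prefire state instead); for |ΔT| ≤ 3 K near 290 K the first-order form
  is within 2% of the exact quartic difference.
* ΔLE = ΔET × ρL_v, evaluated from the constants (ρ = 1000 kg m⁻³,
  L_v = 2.5 MJ kg⁻¹ → 28.935 W m⁻² per mm day⁻¹, printed as 28.94);
  the coefficient is derived once, never hard-coded twice.
* Δ(H+G) is the residual closing the budget. It therefore integrates
  the observation errors of every other term and should be interpreted
  with that caveat; surface heat-storage changes are neglected.
* Broadband emissivity ε = 0.2122ε₂₉ + 0.3859ε₃₁ + 0.4029ε₃₂; the
  weights sum to 1.0010 and the result is intentionally not clamped.

## Fire-size sensitivity

Fire sizes are approximately log-normal, so responses are regressed on
log₁₀(size km²). Per-cell OLS requires ≥ 10 fires of ≥ 1 km²; slopes are
locally significant at P < 0.05 (two-tailed t). Field significance
applies Benjamini–Hochberg at α_FDR = 0.10 across exactly the set of
cells that produced a regression — only tested hypotheses enter the FDR
family — and is reported jointly with the local flag. The per-type
analysis fits one categorical interaction model (type, log size, and
their product); per-type slopes are the reference slope plus the
interaction contrast and are algebraically identical to stratified
per-type fits, which the tests assert to 1e-9. Fire vulnerability
(per-type mean Δ) uses one-tailed t-tests in the direction fixed per
variable (warming > 0, LAI loss < 0) and Tukey HSD at α = 0.05 for
pairwise type comparisons. Grid cells on synthetic scenes are
configurable pixel blocks; the 2° cell of continental analyses is a map
choice, not intrinsic to the method.

## Fire characteristics

Active-fire detections are assigned to an event if their centre lies
within 500 m of the patch perimeter (boundary inclusive) and their date
falls inside the event's burning window (both ends inclusive). The
detection footprint uses the flat-Earth scan-geometry approximation —
along-track ∝ sec θ, along-scan ∝ sec²θ, area = nominal² · sec³θ —
isolated behind one function so a curvature-aware variant can be swapped
in. FRP density is total FRP over total footprint area. Forest mortality
is the fraction of baseline forest subpixels (30-m cells with > 15% tree
cover) lost during the fire year and the following year: a two-year
window balances missed delayed mortality against salvage-logging
commission; mortality is monotonically non-decreasing in the window
length. Dominant forest typing: a single type (ENF/DNF/DBF) at ≥ 50% of
burnt pixels wins (exact-tie priority ENF > DNF > DBF, fixed and
documented); otherwise total forest > 50% (strict) gives MF; otherwise
unclassified.

## Fire-regime trends

Annual mean size, 95th-percentile size (linear-interpolation order
statistic; convention configurable, as registries do not fix one) and
burnt area are computed over fires strictly larger than 2 km², for
cross-registry consistency. Trends use the Mann–Kendall test
(tie-corrected variance, continuity correction, two-tailed) and the
Theil–Sen slope with intercept median(y − slope·t); relative change is
the fitted end-minus-start difference over the fitted start value.
Years without qualifying events are missing, not zero.

## The synthetic landscape generator

The generator emulates the statistical structure the analysis assumes,
not fire physics. A forest-type mosaic (Voronoi patches with target
area shares ENF 0.35 / DNF 0.20 / DBF 0.15 / MF 0.20 / non-forest 0.10)
carries seasonal baselines per type; each year adds one spatially
uniform background anomaly per field and season, plus independent
per-pixel Gaussian noise. Fires are compact 4-connected patches grown
from random seeds, disjoint across the scene, with sizes from a base-10
log-normal (default μ = 0.8, σ = 0.6 in log₁₀ km²) truncated at 1 km²
by resampling. A burnt pixel of an event with dominant type f carries,
at lag L and season s, the injected effect

    [intercept(v,f) + slope(v,f)·log₁₀(size)] · scale(s) · 2^(−(L−1)/h),

with half-life h = 7 yr referenced to lag 1 (the lag-1 effect is the
undecayed regression line, so lag-1 recovery tests have closed-form
expectations). The per-season scale (JJA 1.0, DJF 0.1, annual 0.6)
encodes the summer dominance of postfire signals and keeps winter
injections inside physical bounds — winter ET baselines are small, and
values are clipped to [0,1] (albedo, emissivity) or ≥ 0 (ET, LAI) after
noise. Default effect tables are ordered ENF > DNF > MF > DBF in
magnitude with near-zero DBF effects, and the default summer temperature
line (intercept ≈ 0.2 K, slopes averaging near 0.44 K per log₁₀ km²
over the type mix) puts the event-mean summer warming near 0.6 K. The
albedo and emissivity magnitudes are set so that the outgoing-longwave
increase from warming exceeds the extra shortwave absorption: decomposed
synthetic events show net radiative cooling alongside surface warming,
the sign structure the decomposition is meant to resolve. Mortality
(also linear in log size) converts to 30-m loss-subpixel counts split
70/30 over the fire year and the next; unburnt pixels receive a small
background loss rate plus occasional ~30% "harvest" disturbances to
exercise the 20% control filter. Detections are Poisson per km² over
patch pixels, with moment-matched log-normal FRP and uniform scan
angles.

What the generator does *not* emulate: spatially correlated background
anomalies (an optional smooth-gradient mode was considered and left
out; uniform-per-year backgrounds make counterfactual recovery exact in
the zero-noise limit, which is the sharpest available test of the Δ
machinery), weather/fuel-driven spread, ignition processes, partial-
pixel burning, sensor orbital artefacts, or spatially autocorrelated
observation noise. Passing tests therefore demonstrate the correctness
of the estimators under the stated assumptions, not the accuracy of
those assumptions for any particular satellite product.

## Problem sizes used in tests

The suite runs on scenes of 60–170 pixels per side with 6–500 events:
exactness checks use a zero-noise 90×90 scene with all fires pinned to
one year (so no control carries another year's decaying effect and no
injected value is clipped); unbiasedness uses 500 four-pixel fires;
slope-CI coverage uses 100 replicates of 5,000 regression-level events;
the FDR null simulation uses 200 replicates × 100 cells × 12 fires.
These sizes were chosen to give stable Monte-Carlo verdicts at
interactive runtimes.

## Known limitations

* Controls burnt before the fire year are admissible (the literal
  admission rule). On landscapes where old burns still carry decaying
  effects this leaks a small bias into Δ; the effect is absent when
  analysis windows do not overlap prior burns and is negligible when
  burnt fraction is low. A never-burnt rule would be a one-line stricter
  criteria variant.
* No propensity/covariate matching beyond the four rules, no pixel-level
  spatial-autocorrelation correction, and no autocorrelation-adjusted
  standard errors in the regressions (the α_FDR = 0.10 screen is the
  only multiplicity control).
* The scan-geometry footprint ignores Earth curvature (few-percent area
  error at extreme scan angles).
* Energy closure is exact by construction; it validates bookkeeping,
  not flux observations. The residual Δ(H+G) absorbs all component
  errors.
* The pipeline's energy context (linearisation temperatures) defaults to
  the control mean of a representative event pixel; per-pixel contexts
  would be costlier and change little on synthetic scenes.
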