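"""Isolate fire-induced changes with the space-and-time counterfactual.

A burnt pixel's gross change between the year before and the year after
fire mixes the fire effect with regional interannual variability. The
counterfactual subtracts the mean gross change of matched control pixels
(nearby, same forest type, unburnt, undisturbed), leaving the fire
signal. On a zero-noise scene the recovery is exact, which is the sharp
test of the method; with noise it is unbiased.
"""

from pyrodelta import SyntheticConfig, event_delta, generate_scene, injected_effect

cfg = SyntheticConfig(grid_nx=90, grid_ny=90, n_fires=6, seed=5,
                      lognormal_mu=0.6, lognormal_sigma=0.3,
                      years=tuple(range(2002, 2010)),
                      fire_years=(2003,)).zero_noise()
scene, events = generate_scene(cfg)

print("event  type  size_km2   recovered dT (K)   injected dT (K)")
for ev in events:
    rec = event_delta(ev, "T", "JJA", lag=1, scene=scene)
    truth = injected_effect(cfg, "T", ev.dominant_type, ev.size_km2, "JJA", 1)
    print(f"{ev.event_id:5d}  {ev.dominant_type:4s}  {ev.size_km2:8.2f}"
          f"   {rec.delta:16.6f}   {truth:15.6f}")
# The two columns agree to machine precision: with a spatially uniform
# background the control mean removes the interannual term exactly.

rec5 = event_delta(events[0], "T", "JJA", lag=5, scene=scene)
print(f"\nlag-5 summer dT for event 0: {rec5.delta:.4f} K "
      "(the injected effect decays with a 7-year half-life)")
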