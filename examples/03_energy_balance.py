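"""Decompose a postfire temperature change into energy-balance terms.

Given event-level changes in albedo, day/night temperature, ET and
emissivity, the decomposition yields the changes in outgoing shortwave
(albedo effect), outgoing longwave (linearised Stefan-Boltzmann), latent
heat (from ET), and the sensible+ground heat residual that closes the
budget.
"""

from pyrodelta import CONSTANTS, decompose_event

# A typical postfire summer: darker surface (d_alpha < 0), warmer surface
# (dT > 0), reduced evapotranspiration (dET < 0), slightly lower emissivity.
rec = decompose_event(
    event_id=0, season="JJA", lag_years=1,
    d_alpha=-0.010, d_t_day=0.8, d_t_night=0.4, d_et=-0.30, d_eps=-0.001,
    t_day=299.0, t_night=283.0, eps=0.975, sw_in=250.0)

print(f"ET -> LE conversion: {CONSTANTS.et_to_le_coeff:.2f} W m-2 per mm/day")
print(f"dSW_out = {rec.d_sw_out:7.3f} W m-2   (albedo drop -> more absorption)")
print(f"dLW_out = {rec.d_lw_out:7.3f} W m-2   (warmer surface -> more emission)")
print(f"dLE     = {rec.d_le:7.3f} W m-2   (less evapotranspiration)")
print(f"dRn     = {rec.d_rn:7.3f} W m-2   (net radiation)")
print(f"d(H+G)  = {rec.d_hg:7.3f} W m-2   (residual: sensible + ground heat)")
# dRn < 0 while the surface warms: the longwave loss from warming exceeds
# the extra absorbed shortwave, so the warming is sustained by suppressed
# non-radiative cooling (latent heat), not by a radiative surplus.
assert abs(rec.d_rn - (rec.d_le + rec.d_hg)) < 1e-9  # budget closes exactly
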