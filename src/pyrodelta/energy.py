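"""Surface energy-balance decomposition of postfire changes.

Under the local-effect assumption (fire does not alter incoming short-
or longwave radiation at the pixel scale) the change in net radiation is

    dRn = -dSW_out - dLW_out,          dRn = dLE + d(H+G),

so the sensible+ground heat term is recovered as the balance residual

    d(H+G) = -dSW_out - dLW_out - dLE.

Outgoing shortwave responds to albedo change (dSW_out = d_alpha * SW_in);
outgoing longwave is linearised from the Stefan-Boltzmann law separately
for the day and night overpasses; latent heat converts from
evapotranspiration with rho * L_v (28.94 W m-2 per mm day-1). Surface
heat-storage changes are neglected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhysicalConstants",
    "CONSTANTS",
    "EnergyFluxDelta",
    "broadband_emissivity",
    "delta_sw_out",
    "delta_lw_out",
    "et_to_le",
    "residual_flux",
    "decompose_event",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Stefan-Boltzmann constant, water density and latent heat of
    vapourisation; the ET->LE coefficient is derived, not restated."""

    sigma: float = 5.67e-8       # W m-2 K-4
    rho_water: float = 1.0e3     # kg m-3
    lv: float = 2.5e6            # J kg-1

    @property
    def et_to_le_coeff(self) -> float:
        """W m-2 per mm day-1 of evapotranspiration (prints as 28.94)."""
        return self.rho_water * self.lv * 1e-3 / 86400.0


CONSTANTS = PhysicalConstants()

# Band weights of the empirical broadband-emissivity formula
# (MODIS bands 29, 31, 32); they sum to 1.0010, which is not renormalised.
_W29, _W31, _W32 = 0.2122, 0.3859, 0.4029


@dataclass
class EnergyFluxDelta:
    """Per-event changes in surface energy fluxes (W m-2).

    Satisfies by construction: d_rn = -d_sw_out - d_lw_out and
    d_hg = -d_sw_out - d_lw_out - d_le, hence d_rn = d_le + d_hg.
    The residual d_hg integrates the observation errors of all other
    terms and should be interpreted accordingly.
    """

    event_id: int
    season: str
    lag_years: int
    d_sw_out: float
    d_lw_out: float
    d_le: float
    d_rn: float
    d_hg: float


def broadband_emissivity(e29: float, e31: float, e32: float) -> float:
    """Broadband surface emissivity from MODIS band emissivities 29/31/32.

    Empirical weighted sum 0.2122*e29 + 0.3859*e31 + 0.4029*e32; the
    weights sum to 1.0010, so the output may slightly exceed 1 and is
    deliberately not clamped.
    """
    for name, v in (("e29", e29), ("e31", e31), ("e32", e32)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    return _W29 * e29 + _W31 * e31 + _W32 * e32


def delta_sw_out(delta_alpha: float, sw_in: float) -> float:
    """Change in outgoing shortwave: d_alpha x incoming shortwave."""
    if sw_in < 0:
        raise ValueError("sw_in must be >= 0")
    return delta_alpha * sw_in


def delta_lw_out(t_day: float, t_night: float, d_t_day: float, d_t_night: float,
                 eps: float, d_eps: float,
                 constants: PhysicalConstants = CONSTANTS) -> float:
    """First-order change in outgoing longwave radiation (W m-2).

    Linearises the Stefan-Boltzmann law separately around the daytime and
    nighttime reference temperatures (the undisturbed, prefire state) and
    averages the two; a single emissivity change applies to both:

        1/2 sigma [ (T_d^4 d_eps + 4 eps T_d^3 dT_d)
                  + (T_n^4 d_eps + 4 eps T_n^3 dT_n) ]
    """
    if t_day <= 0 or t_night <= 0:
        raise ValueError("reference temperatures must be > 0 K")
    s = constants.sigma
    day = t_day ** 4 * d_eps + 4.0 * eps * t_day ** 3 * d_t_day
    night = t_night ** 4 * d_eps + 4.0 * eps * t_night ** 3 * d_t_night
    return 0.5 * s * (day + night)


def et_to_le(delta_et: float, constants: PhysicalConstants = CONSTANTS) -> float:
    """Latent-heat-flux change (W m-2) from an ET change (mm day-1)."""
    return delta_et * constants.et_to_le_coeff


def residual_flux(d_sw_out: float, d_lw_out: float, d_le: float) -> float:
    """Sensible + ground heat change as the energy-balance residual.

    Exact negative sum -d_sw_out - d_lw_out - d_le; note this term
    integrates the uncertainties of every other component.
    """
    return -d_sw_out - d_lw_out - d_le


def decompose_event(event_id: int, season: str, lag_years: int, *,
                    d_alpha: float, d_t_day: float, d_t_night: float,
                    d_et: float, d_eps: float,
                    t_day: float, t_night: float, eps: float, sw_in: float,
                    constants: PhysicalConstants = CONSTANTS,
                    ) -> EnergyFluxDelta | None:
    """Assemble the full flux decomposition for one event/season/lag.

    ``t_day``/``t_night``/``eps`` are the linearisation context (prefire
    control-mean state); ``sw_in`` the seasonal incoming shortwave at the
    event location. Returns None when any input is missing (NaN), since a
    partial decomposition would break the closure identities.
    """
    parts = (d_alpha, d_t_day, d_t_night, d_et, d_eps, t_day, t_night, eps, sw_in)
    if any(p is None or not math.isfinite(p) for p in parts):
        return None
    dsw = delta_sw_out(d_alpha, sw_in)
    dlw = delta_lw_out(t_day, t_night, d_t_day, d_t_night, eps, d_eps, constants)
    dle = et_to_le(d_et, constants)
    dhg = residual_flux(dsw, dlw, dle)
    return EnergyFluxDelta(event_id=event_id, season=season, lag_years=lag_years,
                           d_sw_out=dsw, d_lw_out=dlw, d_le=dle,
                           d_rn=-dsw - dlw, d_hg=dhg)
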