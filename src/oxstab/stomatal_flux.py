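"""Multiplicative stomatal-conductance model, ozone flux and POD_Y.

A clean-room implementation of the Jarvis-type multiplicative model used
for flux-based ozone risk assessment of forests:

    gsto = gmax * f_phen * f_light * max(fmin, f_temp * f_vpd * f_swp)

with gmax the species maximum stomatal conductance to O₃ (mmol m⁻² PLA
s⁻¹) and each f-factor in [0, 1].  The hourly leaf-level stomatal flux is

    Fst = c(O₃) * gsto_ms * rc / (rb + rc),   rc = 1 / (gsto_ms + gext)

where c is the ozone concentration converted to nmol m⁻³ via the ideal-gas
state, gsto_ms the conductance in m s⁻¹, rb the leaf boundary-layer
resistance and gext the external (cuticular) leaf conductance.  POD_Y is
the accumulated dose Σ max(0, Fst − Y)·3600·10⁻⁶ over daylight growing-
season hours, in mmol m⁻² PLA.

Projecting a flat seasonal-average concentration through the same chain
yields the flux-based critical level CL(OxS) when that concentration is the
one producing the −0.05 oxidative-stability threshold.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .season_exposure import DAYLIGHT_RAD_WM2, GrowingSeason

log = logging.getLogger(__name__)

R_GAS = 8.31446  # J mol-1 K-1
STANDARD_PRESSURE_KPA = 101.325
#: PPFD per unit global radiation (µmol J⁻¹); folds the ~0.45 PAR fraction
#: and the ~4.57 µmol J⁻¹ quantum conversion into one constant.
PPFD_PER_GLOBAL_RAD = 2.0


@dataclass(frozen=True)
class SpeciesFluxParams:
    """Species parameter set for the multiplicative conductance model.

    Defaults are the boreal-conifer convention used in European ozone
    flux-risk mapping; every value is overridable per species file.
    """

    name: str = "boreal-coniferous-default"
    gmax: float = 112.0          # mmol O3 m-2 PLA s-1
    fmin: float = 0.1
    light_a: float = 0.006       # (umol m-2 s-1)^-1
    t_min: float = 0.0           # degC
    t_opt: float = 14.0
    t_max: float = 35.0
    vpd_min: float = 0.8         # kPa; f_vpd = 1 at or below
    vpd_max: float = 2.8         # kPa; f_vpd = fmin at or beyond
    phen_ramp_days: int = 0      # evergreen default: no ramp inside the GS
    fswp: float = 1.0            # externally supplied soil-water factor
    y_threshold: float = 0.0     # nmol m-2 s-1
    leaf_dimension: float = 0.008  # m, needle cross-wind dimension
    gext: float = 1.0 / 2500.0   # m s-1 (external resistance 2500 s m-1)
    wind_speed: float = 2.0      # m s-1, constant default

    def __post_init__(self) -> None:
        if not self.t_min < self.t_opt < self.t_max:
            raise ValidationError("need t_min < t_opt < t_max")
        if not self.vpd_min < self.vpd_max:
            raise ValidationError("need vpd_min < vpd_max")
        if not 0 < self.fmin < 1:
            raise ValidationError("fmin must lie in (0, 1)")
        if self.gmax <= 0:
            raise ValidationError("gmax must be positive")


def species_preset(species: str, **overrides) -> SpeciesFluxParams:
    """Named parameter sets; related species share a parameterisation
    (P. sylvestris borrows from P. cembra, A. alba from P. abies)."""
    aliases = {"Pinus sylvestris": "Pinus cembra", "Abies alba": "Picea abies"}
    key = aliases.get(species, species)
    base = _PRESETS.get(key, _PRESETS["boreal-coniferous-default"])
    return dataclasses.replace(base, name=species, **overrides)


_PRESETS = {
    "boreal-coniferous-default": SpeciesFluxParams(),
    # Dwarf pine at the treeline: lower gmax, wider thermal window.
    "Pinus mugo": SpeciesFluxParams(name="Pinus mugo", gmax=104.0, t_opt=16.0),
    "Pinus cembra": SpeciesFluxParams(name="Pinus cembra", gmax=100.0),
    "Picea abies": SpeciesFluxParams(name="Picea abies", gmax=112.0),
}


# --- the f-functions -------------------------------------------------------

def f_temp(t_c, p: SpeciesFluxParams):
    """Bell-shaped temperature response, 1 at t_opt, 0 outside (t_min, t_max)."""
    t = np.asarray(t_c, float)
    with np.errstate(invalid="ignore"):
        rise = (t - p.t_min) / (p.t_opt - p.t_min)
        beta = (p.t_max - p.t_opt) / (p.t_opt - p.t_min)
        fall = np.where(t < p.t_max, (p.t_max - t) / (p.t_max - p.t_opt), 0.0)
        f = rise * np.power(np.maximum(fall, 0.0), beta)
    f = np.where((t <= p.t_min) | (t >= p.t_max), 0.0, f)
    return np.clip(f, 0.0, 1.0)


def f_light(ppfd, p: SpeciesFluxParams):
    """Saturating light response 1 - exp(-a * PPFD), in [0, 1)."""
    q = np.asarray(ppfd, float)
    if np.any(q < 0):
        raise ValidationError("PPFD must be non-negative")
    return 1.0 - np.exp(-p.light_a * q)


def f_vpd(vpd_kpa, p: SpeciesFluxParams):
    """1 below vpd_min, fmin above vpd_max, linear in between."""
    v = np.asarray(vpd_kpa, float)
    frac = (p.vpd_max - v) / (p.vpd_max - p.vpd_min)
    return np.clip(p.fmin + (1.0 - p.fmin) * frac, p.fmin, 1.0)


def f_phen(dates, gs: GrowingSeason, p: SpeciesFluxParams):
    """Trapezoidal phenology factor over the growing-season window."""
    d = pd.to_datetime(pd.Series(np.atleast_1d(dates))).dt.normalize()
    days_in = (d - gs.start).dt.days.to_numpy(float)
    days_left = (gs.end - d).dt.days.to_numpy(float)
    inside = (days_in >= 0) & (days_left >= 0)
    if p.phen_ramp_days > 0:
        ramp_up = np.clip(days_in / p.phen_ramp_days, 0.0, 1.0)
        ramp_down = np.clip(days_left / p.phen_ramp_days, 0.0, 1.0)
        f = np.minimum(ramp_up, ramp_down)
    else:
        f = np.ones_like(days_in)
    f = np.where(inside, f, 0.0)
    return f if f.size > 1 else float(f[0])


def global_rad_to_ppfd(glob_rad_wm2, factor: float = PPFD_PER_GLOBAL_RAD):
    return np.maximum(0.0, np.asarray(glob_rad_wm2, float)) * factor


def stomatal_conductance(t_c, ppfd, vpd_kpa, dates, gs: GrowingSeason,
                         p: SpeciesFluxParams, fswp=None):
    """Hourly stomatal conductance to O₃, mmol m⁻² PLA s⁻¹, in [0, gmax]."""
    fswp = p.fswp if fswp is None else fswp
    limiting = np.maximum(p.fmin, f_temp(t_c, p) * f_vpd(vpd_kpa, p) * fswp)
    return p.gmax * f_phen(dates, gs, p) * f_light(ppfd, p) * limiting


# --- gas state and resistances --------------------------------------------

def ppb_to_nmol_m3(o3_ppb, t_c, pressure_kpa=STANDARD_PRESSURE_KPA):
    """Concentration conversion via the ideal gas state: 1 ppb equals
    P/(R·T) nmol m⁻³ (≈41.6 at 20 °C and standard pressure)."""
    molar_density = 1000.0 * np.asarray(pressure_kpa, float) / (
        R_GAS * (np.asarray(t_c, float) + 273.15))  # mol m-3
    return np.asarray(o3_ppb, float) * molar_density


def conductance_mmol_to_ms(g_mmol, t_c, pressure_kpa=STANDARD_PRESSURE_KPA):
    """mmol m⁻² s⁻¹ → m s⁻¹ using the same ideal-gas molar density."""
    molar_density = 1000.0 * np.asarray(pressure_kpa, float) / (
        R_GAS * (np.asarray(t_c, float) + 273.15))
    return np.asarray(g_mmol, float) * 1e-3 / molar_density


def boundary_layer_resistance(p: SpeciesFluxParams, wind_speed=None):
    """Leaf boundary-layer resistance rb = 1.3 · 150 · sqrt(L/u), s m⁻¹."""
    u = p.wind_speed if wind_speed is None else wind_speed
    if np.any(np.asarray(u) <= 0):
        raise ValidationError("wind speed must be positive for rb")
    return 1.3 * 150.0 * np.sqrt(p.leaf_dimension / np.asarray(u, float))


def stomatal_flux(o3_ppb, t_c, ppfd, vpd_kpa, dates, gs: GrowingSeason,
                  p: SpeciesFluxParams, pressure_kpa=STANDARD_PRESSURE_KPA,
                  wind_speed=None, fswp=None):
    """Hourly stomatal O₃ flux Fst, nmol m⁻² PLA s⁻¹.

    The deposition chain partitions the flux between the stomatal and
    external leaf paths: total conductance 1/(rb + rc) with surface
    resistance rc = 1/(gsto + gext); the stomatal fraction is gsto·rc.
    """
    if np.any(np.asarray(o3_ppb) < 0):
        raise ValidationError("O3 concentration must be non-negative")
    gsto_mmol = stomatal_conductance(t_c, ppfd, vpd_kpa, dates, gs, p, fswp)
    gsto_ms = conductance_mmol_to_ms(gsto_mmol, t_c, pressure_kpa)
    rb = boundary_layer_resistance(p, wind_speed)
    c_nmol = ppb_to_nmol_m3(o3_ppb, t_c, pressure_kpa)
    total_g = gsto_ms + p.gext
    with np.errstate(divide="ignore", invalid="ignore"):
        rc = np.where(total_g > 0, 1.0 / total_g, np.inf)
        fst = np.where(np.isinf(rc), 0.0, c_nmol * gsto_ms * rc / (rb + rc))
    return fst


def accumulate_pod(fst, glob_rad_wm2, y: float = 0.0,
                   daylight_wm2: float = DAYLIGHT_RAD_WM2) -> float:
    """POD_Y: Σ max(0, Fst − Y)·3600·10⁻⁶ over daylight hours, mmol m⁻²."""
    fst = np.asarray(fst, float)
    daylight = np.asarray(glob_rad_wm2, float) >= daylight_wm2
    exceed = np.maximum(0.0, fst[daylight] - y)
    return float(exceed.sum() * 3600.0 * 1e-6)


def pod_from_series(df: pd.DataFrame, gs: GrowingSeason,
                    p: SpeciesFluxParams, y: float | None = None,
                    o3_override=None) -> dict:
    """Run the flux chain over the GS hours of an hourly met series.

    ``o3_override`` substitutes a fixed concentration (ppb) for every hour,
    as used for flat-profile critical-level projection.  Returns the hourly
    flux vector and the accumulated POD_Y.
    """
    y = p.y_threshold if y is None else y
    sub = df.loc[gs.mask(df["timestamp"])].reset_index(drop=True)
    o3 = np.full(len(sub), float(o3_override)) if o3_override is not None \
        else sub["o3_ppb"].to_numpy(float)
    if "vpd_kpa" in sub.columns:
        vpd = sub["vpd_kpa"].to_numpy(float)
    elif "rh_pct" in sub.columns:
        vpd = vpd_from_rh(sub["t_air_c"].to_numpy(float),
                          sub["rh_pct"].to_numpy(float))
    else:
        raise ValidationError("need a vpd_kpa or rh_pct column")
    pressure = sub["pressure_kpa"].to_numpy(float) \
        if "pressure_kpa" in sub.columns else STANDARD_PRESSURE_KPA
    ppfd = global_rad_to_ppfd(sub["glob_rad_wm2"].to_numpy(float))
    fst = stomatal_flux(o3, sub["t_air_c"].to_numpy(float), ppfd, vpd,
                        sub["timestamp"], gs, p, pressure_kpa=pressure)
    pod = accumulate_pod(fst, sub["glob_rad_wm2"].to_numpy(float), y=y)
    return {"fst": fst, "pod": pod, "timestamps": sub["timestamp"]}


def project_cl_oxs(avg_o3_ppb: float, df: pd.DataFrame, gs: GrowingSeason,
                   p: SpeciesFluxParams, y: float = 0.0) -> float:
    """POD0 for a flat seasonal-average concentration: the CL(OxS) value
    when ``avg_o3_ppb`` derives from the −0.05 oxidative-stability dose."""
    return pod_from_series(df, gs, p, y=y, o3_override=avg_o3_ppb)["pod"]


def tolerance_utilisation(pod_ambient: float, pod_cl: float) -> float:
    """Percentage of the ozone-tolerance potential used under ambient O₃."""
    if pod_cl <= 0:
        raise ValidationError("CL(OxS) POD must be positive")
    return 100.0 * pod_ambient / pod_cl


def vpd_from_rh(t_c, rh_pct):
    """Vapour-pressure deficit (kPa) from air temperature and RH, using the
    Tetens saturation curve."""
    es = 0.6108 * np.exp(17.27 * np.asarray(t_c, float) /
                         (np.asarray(t_c, float) + 237.3))
    return es * (1.0 - np.asarray(rh_pct, float) / 100.0)


def read_params_file(path) -> SpeciesFluxParams:
    """Flat key-value species parameter file (``key = value`` lines,
    ``#`` comments)."""
    fields = {f.name: f.type for f in dataclasses.fields(SpeciesFluxParams)}
    kwargs = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"{path}:{lineno}: expected key = value")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ValidationError(f"{path}:{lineno}: unknown key {key!r}")
            kwargs[key] = value if key == "name" else (
                int(value) if key == "phen_ramp_days" else float(value))
    return SpeciesFluxParams(**kwargs)
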