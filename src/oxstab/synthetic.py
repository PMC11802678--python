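"""Seeded generators emulating the study's inputs.

Every stage of the pipeline can run without downloads: hourly mountain
met/O₃ series (near-flat alpine vs diurnal foothill profiles), chamber
ozonation dose ladders, electrolyte-leakage conductivity tables consistent
with an exponential injury-dose truth, and GC–MS peak tables with
Dirichlet-distributed class composition.

One integer seed drives one documented stream per generator call (no
global state); a fixed seed reproduces bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .el_injury import ConductivityMeasurement
from .errors import ValidationError
from .gcms_composition import (MONOTERPENE, OXID_C7_8, OXID_C20P,
                               SESQUITERPENE)
from .tables import EXPOSURE_TIMES_H, GCMS_COMPOUNDS

#: Distinct sub-streams so generators never share random numbers.
_STREAM = {"env": 1, "ozonation": 2, "conductivity": 3, "peaks": 4}

#: Climate/O₃ presets for the two zone profiles. Monthly cold snaps outside
#: the target season guarantee the 5 °C rule reproduces the study's season
#: bounds (alpine: Jun 1–Sep 30; foothill: May 1–Sep 30).
ZONE_PROFILES = {
    "alpine-flat": {
        "t_jan_mean": -8.0, "t_jul_mean": 12.0, "t_diurnal_amp": 4.0,
        "o3_mean": 52.7, "o3_diurnal_amplitude": 0.0,
        "cold_snap_months": (1, 2, 3, 4, 5, 10, 11, 12),
        "gs_hours": 2928,
    },
    "foothill-diurnal": {
        "t_jan_mean": -4.0, "t_jul_mean": 16.0, "t_diurnal_amp": 5.0,
        "o3_mean": 27.5, "o3_diurnal_amplitude": 12.0,
        "cold_snap_months": (1, 2, 3, 4, 10, 11, 12),
        "gs_hours": 3672,
    },
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generators.

    Defaults mirror the study: ~150 ppm h⁻¹ chamber concentration with
    1/3/5/7/10 h exposures on top of the ambient seasonal sum, exponential
    injury truth INX(x) = a·exp(b·x) with 5 % multiplicative lognormal
    measurement noise, and near-flat alpine vs diurnal foothill O₃.
    """

    seed: int = 0
    zone_profile: str = "alpine-flat"
    o3_mean: float | None = None            # ppb; profile default if None
    o3_diurnal_amplitude: float | None = None
    injury_a: float = 10.0                  # %, zero-ozone baseline
    injury_b: float = 0.0008                # per ppm
    noise_sd: float = 0.05                  # lognormal sigma (relative)
    exposure_times: tuple[int, ...] = EXPOSURE_TIMES_H
    chamber_concentration: float = 150.0    # ppm (held for each exposure hour)
    chamber_jitter_sd: float = 0.05         # relative rate variability
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.zone_profile not in ZONE_PROFILES:
            raise ValidationError(f"unknown zone_profile {self.zone_profile!r}")
        if self.noise_sd < 0 or self.chamber_jitter_sd < 0:
            raise ValidationError("noise parameters must be non-negative")

    @property
    def profile(self) -> dict:
        return ZONE_PROFILES[self.zone_profile]

    @property
    def o3_mean_ppb(self) -> float:
        return self.profile["o3_mean"] if self.o3_mean is None else self.o3_mean

    @property
    def o3_amplitude_ppb(self) -> float:
        if self.zone_profile == "alpine-flat":
            return 0.0  # flat profile by construction
        return (self.profile["o3_diurnal_amplitude"]
                if self.o3_diurnal_amplitude is None
                else self.o3_diurnal_amplitude)

    @property
    def ambient_sum_ppm(self) -> float:
        """Nominal ambient seasonal sum: mean ppb × nominal GS hours / 1000
        (≈154 ppm alpine, ≈101 ppm foothill at the defaults)."""
        return self.o3_mean_ppb * self.profile["gs_hours"] / 1000.0


def _rng(cfg: SyntheticConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAM[stream], cfg.seed])


def generate_env_series(cfg: SyntheticConfig, year: int = 2023) -> pd.DataFrame:
    """Hourly met + O₃ series for one calendar year.

    Temperature is a seasonal plus diurnal harmonic with noise; one
    deterministic all-cold day is inserted mid-month in every month outside
    the profile's target season so the 5 °C season rule is unambiguous.
    Radiation follows a clear-sky day-arch with multiplicative cloud noise;
    O₃ is the profile mean plus a zero-mean diurnal harmonic (afternoon
    peak), truncated at 0; RH noise feeds a Tetens VPD.
    """
    rng = _rng(cfg, "env")
    prof = cfg.profile
    ts = pd.date_range(f"{year}-01-01", f"{year}-12-31 23:00", freq="h")
    doy = ts.dayofyear.to_numpy(float)
    hour = ts.hour.to_numpy(float)

    seasonal01 = 0.5 * (1.0 - np.cos(2 * np.pi * (doy - 15.0) / 365.0))
    t_mean = prof["t_jan_mean"] + \
        (prof["t_jul_mean"] - prof["t_jan_mean"]) * seasonal01
    diurnal = prof["t_diurnal_amp"] * np.sin(2 * np.pi * (hour - 9.0) / 24.0)
    t_air = t_mean + diurnal + rng.normal(0.0, 1.0, len(ts))
    # deterministic cold-snap day (15th) in each out-of-season month
    snap = np.isin(ts.month, cfg.profile["cold_snap_months"]) & (ts.day == 15)
    t_air = np.where(snap, np.minimum(t_air, 1.0), t_air)

    arch = np.maximum(0.0, np.cos(2 * np.pi * (hour - 12.0) / 24.0)) ** 1.5
    clouds = rng.uniform(0.4, 1.0, len(ts))
    glob_rad = (250.0 + 600.0 * seasonal01) * arch * clouds

    o3 = cfg.o3_mean_ppb + \
        cfg.o3_amplitude_ppb * np.cos(2 * np.pi * (hour - 15.0) / 24.0)
    o3 = np.maximum(0.0, o3)

    rh = np.clip(70.0 - 10.0 * arch + rng.normal(0.0, 5.0, len(ts)), 20.0, 100.0)
    es = 0.6108 * np.exp(17.27 * t_air / (t_air + 237.3))
    vpd = np.maximum(0.0, es * (1.0 - rh / 100.0))

    return pd.DataFrame({"timestamp": ts, "t_air_c": t_air, "o3_ppb": o3,
                         "glob_rad_wm2": glob_rad, "rh_pct": rh,
                         "vpd_kpa": vpd})


def generate_ozonation_series(cfg: SyntheticConfig,
                              ambient_sum_ppm: float | None = None
                              ) -> list[float]:
    """Dose ladder: ambient seasonal sum, then ambient + chamber doses.

    Element 1 is the ambient sum; elements 2..6 add ``chamber_concentration
    × exposure_time`` with optional relative rate jitter (lognormal,
    ``chamber_jitter_sd``) applied per exposure interval, which keeps the
    ladder strictly increasing.
    """
    rng = _rng(cfg, "ozonation")
    ambient = cfg.ambient_sum_ppm if ambient_sum_ppm is None else ambient_sum_ppm
    times = list(cfg.exposure_times)
    if sorted(times) != times:
        raise ValidationError("exposure_times must be increasing")
    doses = [float(ambient)]
    prev_t = 0.0
    total = float(ambient)
    for t in times:
        rate = cfg.chamber_concentration
        if cfg.chamber_jitter_sd > 0:
            rate *= float(np.exp(rng.normal(0.0, cfg.chamber_jitter_sd)))
        total += rate * (t - prev_t)
        doses.append(total)
        prev_t = t
    return doses


@dataclass(frozen=True)
class ConductivityExperiment:
    """A synthetic ozonation assay with its generating truth."""

    measurements: tuple[ConductivityMeasurement, ...]
    sum_o3_ppm: tuple[float, ...]
    truth_a: float
    truth_b: float

    @property
    def analytic_critical_dose(self) -> float:
        """Exact dose at which the generating curve reaches OxS = -0.05."""
        return float(np.log(1.0 + 5.0 / self.truth_a) / self.truth_b)


def generate_conductivity_experiment(cfg: SyntheticConfig,
                                     species: str = "synthetic conifer",
                                     zone: str = "SYN"
                                     ) -> ConductivityExperiment:
    """EL conductivity tables whose injury indices follow the exponential
    truth with multiplicative lognormal noise.

    Conductivities are constructed by inversion (blanks fixed at 2 µS cm⁻¹,
    post-autoclave span 100 µS cm⁻¹, the fresh reading solves for the noisy
    index), so the injury-index stage recovers the noisy INX exactly.
    """
    rng = _rng(cfg, "conductivity")
    doses = generate_ozonation_series(cfg)
    measurements = []
    for n, dose in enumerate(doses, start=1):
        truth = cfg.injury_a * np.exp(cfg.injury_b * dose)
        for rep in range(cfg.n_replicates):
            noisy = truth
            if cfg.noise_sd > 0:
                noisy = truth * float(np.exp(rng.normal(0.0, cfg.noise_sd)))
            noisy = min(noisy, 100.0)
            measurements.append(ConductivityMeasurement(
                sample_id=f"{zone}-{n}-{rep + 1}", species=species, zone=zone,
                series_index=n, c_blank_fresh=2.0, c_fresh=2.0 + noisy,
                c_blank_auto=2.0, c_auto=102.0))
    return ConductivityExperiment(
        measurements=tuple(measurements),
        sum_o3_ppm=tuple(doses), truth_a=cfg.injury_a, truth_b=cfg.injury_b)


#: Base class shares of the composition simplex (sesquiterpene-dominated,
#: as in the study's needle extracts) and within-class compound weights.
_BASE_SHARES = {MONOTERPENE: 0.30, SESQUITERPENE: 0.46,
                OXID_C7_8: 0.10, OXID_C20P: 0.14}
#: Per ozonation step A→B→C: monoterpenes break down, oxygenated C7–8
#: products accumulate (scaled by the ``effect`` argument).
_CATEGORY_SHIFT = {MONOTERPENE: -0.06, OXID_C7_8: +0.06}
_DIRICHLET_CONCENTRATION = 150.0


def generate_peak_table(cfg: SyntheticConfig, n_samples: int = 6,
                        effect: float = 1.0,
                        categories: tuple[str, ...] = ("A", "B", "C")
                        ) -> pd.DataFrame:
    """GC–MS peak table over the study's 13 compounds.

    Class proportions are Dirichlet-distributed around category-shifted
    means (``effect=0`` gives the exchangeable null used for type-I-error
    checks); class shares are split across that class's compounds with
    fixed geometric weights and scaled to arbitrary total areas.
    """
    from .gcms_composition import classify_compound

    rng = _rng(cfg, "peaks")
    by_class: dict[str, list[tuple[int, str, str]]] = {}
    for ri, name, formula in GCMS_COMPOUNDS:
        by_class.setdefault(classify_compound(formula), []).append(
            (ri, name, formula))
    rows = []
    for step, cat in enumerate(categories):
        shares = np.array([
            max(1e-3, _BASE_SHARES[c] + effect * step * _CATEGORY_SHIFT.get(c, 0.0))
            for c in _BASE_SHARES], float)
        alpha = _DIRICHLET_CONCENTRATION * shares / shares.sum()
        for i in range(n_samples):
            sample_id = f"{cfg.zone_profile}-{cat}-{i + 1}"
            props = rng.dirichlet(alpha)
            total_area = rng.uniform(5e5, 2e6)
            for cls, prop in zip(_BASE_SHARES, props):
                members = by_class[cls]
                w = np.array([0.6 ** k for k in range(len(members))])
                w /= w.sum()
                for (ri, name, formula), wk in zip(members, w):
                    rows.append({
                        "sample_id": sample_id, "species": "synthetic conifer",
                        "zone": cfg.zone_profile, "ozonation_category": cat,
                        "retention_index": ri, "compound": name,
                        "formula": formula, "area": total_area * prop * wk})
    return pd.DataFrame(rows)
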